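"""Unfolding-time, helix-content and region-ordered unfolding statistics.

The unfolding time ``t_u`` of a run is the time of the first stored frame that
contains no alpha-helical (H) residue; a run with at least one H residue in
every frame never unfolds.  The unfolding order ranks named chain regions by
their mean H content over the window from the start of the run up to and
including ``t_u``: the region with the least helix over that window unfolded
first.

Helix content follows the field's convention of pooling H and G (3_10-helix)
residue-frames unless a different label set is requested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory import ALPHABET, RegionPartition, RunEnsemble, SSTrajectory

logger = logging.getLogger(__name__)

#: Labels pooled as "helix content" by default: alpha- plus 3_10-helix.
HELIX_LABELS = frozenset({"H", "G"})


@dataclass(frozen=True)
class UnfoldingSummary:
    """Per-run unfolding record: time, region order, helix content.

    ``t_u_ns`` is ``None`` for a run that never unfolds, in which case
    ``order`` is ``None`` as well.  ``helix_content`` is the pooled
    P(H)+P(G) fraction over the analyzed window of the run.
    """

    run_id: str
    t_u_ns: float | None
    order: tuple[str, ...] | None
    helix_content: float


@dataclass(frozen=True)
class EnsembleStats:
    """Aggregate unfolding statistics over one set of run summaries."""

    n_runs: int
    n_unfolded: int
    mean_t_u_ns: float
    median_t_u_ns: float
    sd_t_u_ns: float
    order_counts: dict[tuple[str, ...], int]

    def count_first(self, region: str) -> int:
        """Number of unfolded runs whose order starts with ``region``."""
        return sum(n for order, n in self.order_counts.items() if order and order[0] == region)

    def count_terminus_to_terminus(self, part: RegionPartition | None = None) -> int:
        """Runs unfolding strictly from one terminus to the opposite one.

        With the default N/M/C partition these are the orders (N, M, C) and
        (C, M, N): the coil appears at a terminus and sweeps across, leaving
        the middle region for last but one.
        """
        names = part.names if part is not None else ("N", "M", "C")
        fwd = tuple(names)
        rev = tuple(reversed(names))
        return self.order_counts.get(fwd, 0) + self.order_counts.get(rev, 0)


def unfolding_time(traj: SSTrajectory) -> float | None:
    """Time (ps) of the first frame with no H residue, or ``None`` if never."""
    has_h = (traj.labels == "H").any(axis=1)
    idx = np.flatnonzero(~has_h)
    if idx.size == 0:
        return None
    return float(traj.times[idx[0]])


def _pooled_cells(source: SSTrajectory | RunEnsemble) -> Iterable[SSTrajectory]:
    if isinstance(source, SSTrajectory):
        yield source
    else:
        yield from source.iter_members()


def residue_content(source: RunEnsemble | SSTrajectory,
                    labels: Iterable[str] = ("H",)) -> np.ndarray:
    """Per-residue fraction of frames whose label falls in ``labels``.

    Counts are pooled over all frames of all members (after ensemble
    truncation), i.e. every residue-frame cell carries equal weight.
    """
    label_list = sorted(set(labels))
    counts: np.ndarray | None = None
    total = 0
    for traj in _pooled_cells(source):
        hit = np.isin(traj.labels, label_list)
        c = hit.sum(axis=0)
        counts = c if counts is None else counts + c
        total += traj.n_frames
    assert counts is not None
    return counts / total


def content_profile(source: RunEnsemble | SSTrajectory) -> pd.DataFrame:
    """P(x; i) for every class x and residue i, as a residues x classes table.

    Rows are 1-based residue positions; each row sums to 1.
    """
    cols = {x: residue_content(source, labels=[x]) for x in ALPHABET}
    df = pd.DataFrame(cols)
    df.index = pd.RangeIndex(1, len(df) + 1, name="residue")
    return df


def helix_content(source: RunEnsemble | SSTrajectory,
                  window_ps: tuple[float | None, float | None] | None = None,
                  labels: Iterable[str] = HELIX_LABELS) -> float:
    """Pooled fraction of residue-frames labeled H or G (by default).

    ``window_ps`` restricts each trajectory to ``t0 <= time <= t1`` before
    pooling; an empty window raises.
    """
    label_list = sorted(set(labels))
    hits = 0
    cells = 0
    for traj in _pooled_cells(source):
        if window_ps is not None:
            traj = traj.window(*window_ps)
        hits += int(np.isin(traj.labels, label_list).sum())
        cells += traj.labels.size
    return hits / cells


def running_helix_content(traj: SSTrajectory,
                          labels: Iterable[str] = HELIX_LABELS) -> pd.DataFrame:
    """Helix content averaged over the accumulated duration up to each frame.

    Returns a frame-indexed table with columns ``time_ps`` and ``content``;
    the final row equals :func:`helix_content` of the full trajectory.
    """
    label_list = sorted(set(labels))
    per_frame = np.isin(traj.labels, label_list).mean(axis=1)
    running = np.cumsum(per_frame) / np.arange(1, traj.n_frames + 1)
    return pd.DataFrame({"time_ps": traj.times, "content": running})


def unfolding_order(traj: SSTrajectory, part: RegionPartition | None = None, *,
                    labels: Iterable[str] = ("H",)) -> tuple[str, ...]:
    """Rank regions by how early they lost helix before the unfolding time.

    For each region the mean helix content (H only, by default) is computed
    over frames with time <= t_u; regions are returned lowest-content first.
    Ties break by the earlier time of the region's first helix-free frame,
    then by the partition's region order.

    Raises
    ------
    ValueError
        If the run never unfolds (t_u undefined).
    """
    if part is None:
        part = RegionPartition.default()
    t_u = unfolding_time(traj)
    if t_u is None:
        raise ValueError(f"run {traj.run_id!r} did not unfold; order undefined")
    sub = traj.truncated(t_u)
    label_list = sorted(set(labels))
    hit = np.isin(sub.labels, label_list)

    keys = []
    for rank, name in enumerate(part.names):
        cols = [p - 1 for p in part.positions(name)]
        block = hit[:, cols]
        mean_content = float(block.mean())
        free = np.flatnonzero(~block.any(axis=1))
        first_free = float(sub.times[free[0]]) if free.size else math.inf
        keys.append((mean_content, first_free, rank, name))
    keys.sort()
    return tuple(k[-1] for k in keys)


def summarize_run(traj: SSTrajectory, part: RegionPartition | None = None, *,
                  order_labels: Iterable[str] = ("H",)) -> UnfoldingSummary:
    """Build the per-run record: t_u (ns), region order, P(H)+P(G)."""
    t_u = unfolding_time(traj)
    order = None if t_u is None else unfolding_order(traj, part, labels=order_labels)
    return UnfoldingSummary(
        run_id=traj.run_id,
        t_u_ns=None if t_u is None else t_u / 1000.0,
        order=order,
        helix_content=helix_content(traj),
    )


def ensemble_stats(summaries: Sequence[UnfoldingSummary]) -> EnsembleStats:
    """Aggregate a list of run summaries (from this package or a published table).

    Runs that never unfolded are excluded from the t_u statistics and order
    counts; their number is logged.  The standard deviation is the sample SD
    (n-1 denominator), NaN for fewer than two unfolded runs.
    """
    unfolded = [s for s in summaries if s.t_u_ns is not None]
    n_never = len(summaries) - len(unfolded)
    if n_never:
        logger.info("%d of %d runs never unfolded; excluded from t_u statistics",
                    n_never, len(summaries))
    t = np.array([s.t_u_ns for s in unfolded], dtype=float)
    order_counts: dict[tuple[str, ...], int] = {}
    for s in unfolded:
        assert s.order is not None
        order_counts[s.order] = order_counts.get(s.order, 0) + 1
    return EnsembleStats(
        n_runs=len(summaries),
        n_unfolded=len(unfolded),
        mean_t_u_ns=float(t.mean()) if t.size else math.nan,
        median_t_u_ns=float(np.median(t)) if t.size else math.nan,
        sd_t_u_ns=float(t.std(ddof=1)) if t.size > 1 else math.nan,
        order_counts=order_counts,
    )


def summarize_runs(ens: RunEnsemble, part: RegionPartition | None = None, *,
                   order_labels: Iterable[str] = ("H",)
                   ) -> tuple[list[UnfoldingSummary], EnsembleStats]:
    """Per-run unfolding summaries plus ensemble aggregates for one ensemble."""
    summaries = [summarize_run(m, part, order_labels=order_labels)
                 for m in ens.iter_members()]
    return summaries, ensemble_stats(summaries)


def summaries_to_frame(summaries: Sequence[UnfoldingSummary]) -> pd.DataFrame:
    """Run summaries as a tidy table (run_id, t_u_ns, order, helix_content)."""
    return pd.DataFrame({
        "run_id": [s.run_id for s in summaries],
        "t_u_ns": [s.t_u_ns if s.t_u_ns is not None else math.nan for s in summaries],
        "order": [",".join(s.order) if s.order else "never" for s in summaries],
        "helix_content": [s.helix_content for s in summaries],
    })
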