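"""Single-lag secondary-structure transition probabilities and triad statistics.

Transition probabilities are empirical: for residue ``i`` the pairs
(label at frame t, label at frame t+lag) are counted over every member of an
ensemble (the last ``lag`` frames of each member are never sources), pooled
across members, and row-normalized.  The default lag is one stored frame
(20 ps).  Two classings are available: the full 8-letter alphabet, or the
reduced set {H, G, T, other} where "other" pools {I, E, S, B, O}.

Triad statistics measure helix-end kinetics: each three-residue segment is
classified by the H / non-H pattern of its residues at frame t (seven
possible classes; "-H-" is geometrically impossible for genuine alpha-helices,
which span at least four residues, and is counted as an anomaly), and the
probability that the center residue is H at frame t+1 is estimated per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trajectory import ALPHABET, RegionPartition, RunEnsemble

#: Reduced classing: 3 named classes plus the pooled complement.
REDUCED_CLASSES: tuple[str, ...] = ("H", "G", "T", "other")
#: Alphabet members pooled into the reduced "other" class.
OTHER_MEMBERS = frozenset({"I", "E", "S", "B", "O"})

#: The seven admissible triad classes, in conventional order.
TRIAD_CLASSES: tuple[str, ...] = ("HHH", "HH-", "-HH", "H-H", "H--", "--H", "---")
#: The impossible pattern - an isolated helical residue between coil neighbors.
TRIAD_ANOMALY = "-H-"

_TRIAD_BY_CODE = {  # code = 4*left + 2*center + right, bits = is-H
    0b111: "HHH", 0b110: "HH-", 0b011: "-HH", 0b101: "H-H",
    0b100: "H--", 0b001: "--H", 0b000: "---", 0b010: TRIAD_ANOMALY,
}


def reduce_label(x: str) -> str:
    """Collapse a full-alphabet label into {H, G, T, other}."""
    return x if x in ("H", "G", "T") else "other"


@dataclass(frozen=True)
class TransitionTable:
    """Counts and row-normalized probabilities of x -> y over one lag.

    ``counts`` and ``probabilities`` are square DataFrames indexed by source
    class (rows) and destination class (columns).  Rows with zero source
    counts have all-NaN probabilities: "never observed" is distinct from
    "observed, never left".
    """

    scope: str
    classes: tuple[str, ...]
    counts: pd.DataFrame
    lag: int = 1

    @property
    def probabilities(self) -> pd.DataFrame:
        row_sums = self.counts.sum(axis=1)
        probs = self.counts.div(row_sums.where(row_sums > 0), axis=0)
        return probs

    def probability(self, y: str, x: str) -> float:
        """P(y, x): probability of landing in ``y`` given source ``x``."""
        return float(self.probabilities.loc[x, y])

    @property
    def n_transitions(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class TriadStats:
    """Triad class counts and next-frame center-H probabilities for one scope."""

    scope: str
    counts: dict[str, int]
    next_h_counts: dict[str, int]
    anomaly_count: int

    def p_next_h(self, triad_class: str) -> float:
        """P(center is H at the next frame | triad class); NaN if unobserved."""
        if triad_class not in self.counts:
            raise KeyError(f"unknown triad class {triad_class!r}")
        n = self.counts[triad_class]
        return self.next_h_counts[triad_class] / n if n else float("nan")

    def p_next_coil(self, triad_class: str) -> float:
        """P(center is non-H at the next frame | triad class) = 1 - P(H, class)."""
        return 1.0 - self.p_next_h(triad_class)


def _encode(labels: np.ndarray, classes: tuple[str, ...], reduced: bool) -> np.ndarray:
    """Map a label matrix onto integer class codes (index into ``classes``)."""
    code = np.empty(labels.shape, dtype=np.int64)
    if reduced:
        code.fill(classes.index("other"))
        for k, cls in enumerate(classes):
            if cls != "other":
                code[labels == cls] = k
    else:
        for k, cls in enumerate(classes):
            code[labels == cls] = k
    return code


def _classes_for(classing: str) -> tuple[tuple[str, ...], bool]:
    if classing == "reduced":
        return REDUCED_CLASSES, True
    if classing == "full":
        return ALPHABET, False
    raise ValueError(f"classing must be 'full' or 'reduced', got {classing!r}")


def transition_table(ens: RunEnsemble, i: int, classing: str = "reduced", *,
                     lag: int = 1) -> TransitionTable:
    """Empirical transition table for residue ``i`` (1-based), pooled over runs.

    Counts every (frame t, frame t+lag) pair of every ensemble member; the
    pooled counts are normalized once per ensemble, not averaged per run.
    """
    if not 1 <= i <= ens.n_residues:
        raise ValueError(f"residue {i} out of range 1..{ens.n_residues}")
    classes, reduced = _classes_for(classing)
    K = len(classes)
    acc = np.zeros((K, K), dtype=np.int64)
    for traj in ens.iter_members():
        col = traj.labels[:, i - 1]
        code = _encode(col[:, None], classes, reduced)[:, 0]
        if len(code) > lag:
            np.add.at(acc, (code[:-lag], code[lag:]), 1)
    counts = pd.DataFrame(acc, index=list(classes), columns=list(classes))
    return TransitionTable(scope=f"residue {i}", classes=classes, counts=counts, lag=lag)


def flux_ratio(tab: TransitionTable, from_class: str, via_class: str) -> float:
    """Fraction of departures from ``from_class`` that land in ``via_class``.

    Returns ``P(via, from) / sum_{y != from} P(y, from)``, i.e. the share of
    class-changing transitions routed through ``via_class``.  NaN when the
    source class never departs (zero off-diagonal counts).
    """
    if from_class == via_class:
        raise ValueError("via_class must differ from from_class")
    row = tab.counts.loc[from_class]
    departures = int(row.sum() - row[from_class])
    if departures == 0:
        return float("nan")
    return float(row[via_class]) / departures


def transition_profile(ens: RunEnsemble, classing: str = "reduced", *,
                       lag: int = 1) -> pd.DataFrame:
    """Per-residue transition tables as one tidy frame (residue, from, to, ...)."""
    records = []
    for i in range(1, ens.n_residues + 1):
        tab = transition_table(ens, i, classing, lag=lag)
        probs = tab.probabilities
        for x in tab.classes:
            for y in tab.classes:
                records.append({
                    "residue": i, "from": x, "to": y,
                    "count": int(tab.counts.loc[x, y]),
                    "probability": float(probs.loc[x, y]),
                })
    return pd.DataFrame.from_records(records)


def _triad_centers(ens: RunEnsemble, part: RegionPartition | None, scope: str) -> np.ndarray:
    interior = np.arange(2, ens.n_residues)  # both neighbors must exist
    if scope == "All":
        return interior
    if part is None:
        part = RegionPartition.default()
    pos = np.array(part.positions(scope))
    return pos[(pos >= 2) & (pos <= ens.n_residues - 1)]


def triad_stats(ens: RunEnsemble, part: RegionPartition | None = None,
                scope: str = "All") -> TriadStats:
    """Classify every (frame, center) triad and tally next-frame center-H.

    ``scope`` is ``"All"`` (every interior center, positions 2..n-1) or a
    region name from ``part``; in the latter case centers are the region's
    positions that have both neighbors.  Occurrences of the impossible
    pattern -H- are excluded from the seven classes and reported as
    ``anomaly_count``.
    """
    if part is None:
        part = RegionPartition.default()
    if scope != "All" and scope not in part.regions:
        raise KeyError(f"unknown scope {scope!r}; expected 'All' or one of {list(part.regions)}")
    centers = _triad_centers(ens, part, scope)
    tallies = np.zeros(16, dtype=np.int64)  # 2*code + next_is_h
    for traj in ens.iter_members():
        if traj.n_frames < 2:
            continue
        H = traj.labels == "H"
        c = centers - 1  # to 0-based columns
        code = 4 * H[:-1, c - 1].astype(np.int64) + 2 * H[:-1, c] + H[:-1, c + 1]
        nxt = H[1:, c].astype(np.int64)
        tallies += np.bincount((2 * code + nxt).ravel(), minlength=16)
    counts: dict[str, int] = {cls: 0 for cls in TRIAD_CLASSES}
    next_h: dict[str, int] = {cls: 0 for cls in TRIAD_CLASSES}
    anomalies = 0
    for code, cls in _TRIAD_BY_CODE.items():
        n0, n1 = int(tallies[2 * code]), int(tallies[2 * code + 1])
        if cls == TRIAD_ANOMALY:
            anomalies = n0 + n1
        else:
            counts[cls] = n0 + n1
            next_h[cls] = n1
    return TriadStats(scope=scope, counts=counts, next_h_counts=next_h,
                      anomaly_count=anomalies)


def triad_region_matrix(ens: RunEnsemble,
                        part: RegionPartition | None = None) -> pd.DataFrame:
    """Triad next-H probabilities for scope All and each region, side by side.

    Rows are P(H, class) for the seven classes plus the unwinding complements
    P(-, HH-) and P(-, -HH); columns are All followed by the partition's
    region names.
    """
    if part is None:
        part = RegionPartition.default()
    scopes = ("All", *part.names)
    stats = {s: triad_stats(ens, part, s) for s in scopes}
    rows: dict[str, list[float]] = {}
    for cls in TRIAD_CLASSES:
        rows[f"P(H,{cls})"] = [stats[s].p_next_h(cls) for s in scopes]
    for cls in ("HH-", "-HH"):
        rows[f"P(-,{cls})"] = [stats[s].p_next_coil(cls) for s in scopes]
    df = pd.DataFrame(rows, index=list(scopes)).T
    df.index.name = "quantity"
    return df
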