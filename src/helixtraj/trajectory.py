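"""Core data model for per-residue secondary-structure label trajectories.

A trajectory is a frames x residues matrix of one-letter DSSP classes.  The
eight admissible symbols are H (alpha-helix), G (3_10-helix), I (pi-helix),
E (extended strand), B (isolated bridge), T (hydrogen-bonded turn), S (bend)
and O (no recognized element).  DSSP itself prints the last class as a blank;
``O`` is the canonical internal spelling here, and readers normalize the
common synonyms (space, ``-``, ``C``) on input.

Residue positions are 1-based throughout; capping groups are never residues.
The time of frame ``k`` (0-based) is ``time_offset + k * frame_interval`` in
picoseconds, with a default offset of one frame interval (the first stored
snapshot comes after the initial structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: The eight admissible one-letter secondary-structure classes.
ALPHABET: tuple[str, ...] = ("H", "G", "I", "E", "B", "T", "S", "O")

ALPHABET_SET = frozenset(ALPHABET)

#: Input spellings accepted for the "no recognized element" class.
BLANK_SYNONYMS = {" ": "O", "-": "O", "C": "O", "O": "O", "": "O"}


class LabelError(ValueError):
    """A character outside the 8-letter secondary-structure alphabet."""


def normalize_symbol(ch: str, *, line: int | None = None, column: int | None = None) -> str:
    """Map one input character to a canonical label, or raise :class:`LabelError`.

    Blank-class synonyms (space, ``-``, ``C``) normalize to ``O``.
    ``line``/``column`` (1-based) are included in the error message when given.
    """
    ch = BLANK_SYNONYMS.get(ch, ch)
    if ch not in ALPHABET_SET:
        where = ""
        if line is not None:
            where = f" at line {line}" + (f", column {column}" if column is not None else "")
        raise LabelError(f"unknown secondary-structure symbol {ch!r}{where}")
    return ch


@dataclass(frozen=True)
class SSTrajectory:
    """Secondary-structure label trajectory of one simulation run.

    Parameters
    ----------
    run_id:
        Short text label, e.g. ``"Ide1"``.
    labels:
        ``(n_frames, n_residues)`` array of single-character labels from
        :data:`ALPHABET`.
    frame_interval:
        Time between stored frames, in ps (default 20).
    time_offset:
        Time of the first stored frame, in ps.  Defaults to ``frame_interval``.
    """

    run_id: str
    labels: np.ndarray
    frame_interval: float = 20.0
    time_offset: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype="<U1")
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(
                f"labels must be a nonempty frames x residues matrix, got shape {arr.shape}"
            )
        bad = ~np.isin(arr, ALPHABET)
        if bad.any():
            f, r = np.argwhere(bad)[0]
            raise LabelError(
                f"inadmissible label {arr[f, r]!r} at frame {f}, residue {r + 1} "
                f"of run {self.run_id!r}"
            )
        object.__setattr__(self, "labels", arr)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.time_offset is None:
            object.__setattr__(self, "time_offset", float(self.frame_interval))

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps: ``time_offset + k * frame_interval``."""
        return self.time_offset + np.arange(self.n_frames) * self.frame_interval

    def truncated(self, max_time_ps: float) -> "SSTrajectory":
        """Return the prefix whose frame times are all <= ``max_time_ps``."""
        keep = self.times <= max_time_ps
        n = int(keep.sum())
        if n == 0:
            raise ValueError(
                f"truncation at {max_time_ps} ps leaves no frames of run {self.run_id!r}"
            )
        if n == self.n_frames:
            return self
        return replace(self, labels=self.labels[:n])

    def window(self, t0_ps: float | None, t1_ps: float | None) -> "SSTrajectory":
        """Return the sub-trajectory with ``t0_ps <= time <= t1_ps``."""
        t = self.times
        keep = np.ones(self.n_frames, dtype=bool)
        if t0_ps is not None:
            keep &= t >= t0_ps
        if t1_ps is not None:
            keep &= t <= t1_ps
        if not keep.any():
            raise ValueError("empty time window")
        return replace(self, labels=self.labels[keep],
                       time_offset=float(t[keep][0]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSTrajectory):
            return NotImplemented
        return (
            self.run_id == other.run_id
            and self.frame_interval == other.frame_interval
            and self.time_offset == other.time_offset
            and self.labels.shape == other.labels.shape
            and bool((self.labels == other.labels).all())
        )


@dataclass
class RunEnsemble:
    """A named, ordered collection of trajectories with shared geometry.

    ``truncation_ns``, when set, limits every member to frames whose time is
    <= that duration; all aggregate operations see only the truncated prefix.
    """

    name: str
    members: list[SSTrajectory]
    truncation_ns: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"ensemble {self.name!r} has no members")
        n_res = {m.n_residues for m in self.members}
        if len(n_res) != 1:
            raise ValueError(
                f"ensemble {self.name!r}: inconsistent residue counts {sorted(n_res)}"
            )
        dt = {m.frame_interval for m in self.members}
        if len(dt) != 1:
            raise ValueError(
                f"ensemble {self.name!r}: inconsistent frame intervals {sorted(dt)}"
            )

    @property
    def n_residues(self) -> int:
        return self.members[0].n_residues

    @property
    def frame_interval(self) -> float:
        return self.members[0].frame_interval

    def iter_members(self) -> Iterator[SSTrajectory]:
        """Yield members with the ensemble truncation applied."""
        if self.truncation_ns is None:
            yield from self.members
        else:
            limit_ps = self.truncation_ns * 1000.0
            for m in self.members:
                yield m.truncated(limit_ps)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint named residue regions plus a set of excluded positions.

    The default splits a 20-residue chain into an N-terminal region
    (residues 2-7), a middle region (8-13) and a C-terminal region (14-19),
    discarding the chain-end residues 1 and 20.
    """

    regions: Mapping[str, frozenset[int]]
    excluded: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        regions = {name: frozenset(pos) for name, pos in self.regions.items()}
        seen: set[int] = set()
        for name, pos in regions.items():
            if not pos:
                raise ValueError(f"region {name!r} is empty")
            if pos & seen:
                raise ValueError(f"region {name!r} overlaps another region")
            seen |= pos
        if seen & set(self.excluded):
            raise ValueError("excluded positions overlap a region")
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "excluded", frozenset(self.excluded))

    @classmethod
    def default(cls) -> "RegionPartition":
        return cls(
            regions={
                "N": frozenset(range(2, 8)),
                "M": frozenset(range(8, 14)),
                "C": frozenset(range(14, 20)),
            },
            excluded=frozenset({1, 20}),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def positions(self, name: str) -> tuple[int, ...]:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; have {list(self.regions)}")
        return tuple(sorted(self.regions[name]))


def trajectory_from_lines(lines: Sequence[str], run_id: str = "run",
                          frame_interval: float = 20.0,
                          time_offset: float | None = None) -> SSTrajectory:
    """Build a trajectory from one label string per frame (convenience)."""
    mat = [[normalize_symbol(c) for c in row] for row in lines]
    return SSTrajectory(run_id=run_id, labels=np.array(mat, dtype="<U1"),
                        frame_interval=frame_interval, time_offset=time_offset)
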