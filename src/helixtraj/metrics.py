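"""Coordinate-based chain metrics: end-to-end distance and radius of gyration.

Coordinate trajectories come from multi-model PDB files (read with biotite;
one MODEL per stored frame).  The metrics themselves are deliberately small:
an atom-pair Euclidean distance and the (optionally mass-weighted) RMS
distance of a selection from its centroid.  Default atom choices — C-alpha of
the first and last residues for the end-to-end distance, all heavy atoms
unweighted for Rg — are conventions of this package and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

try:  # biotite is only needed when PDB files are actually read
    from biotite.structure.io.pdb import PDBFile
except ImportError:  # pragma: no cover
    PDBFile = None


@dataclass(frozen=True)
class CoordTrajectory:
    """Atomic coordinate trajectory with a fixed atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atom_names``,
    ``residue_ids`` and ``elements`` describe the roster, identical in every
    frame.
    """

    run_id: str
    coords: np.ndarray
    atom_names: np.ndarray
    residue_ids: np.ndarray
    elements: np.ndarray
    frame_interval: float = 20.0
    time_offset: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3 or c.shape[0] < 1:
            raise ValueError(f"coords must have shape (frames, atoms, 3), got {c.shape}")
        if not np.isfinite(c).all():
            raise ValueError("non-finite coordinates")
        n_atoms = c.shape[1]
        for name in ("atom_names", "residue_ids", "elements"):
            if len(getattr(self, name)) != n_atoms:
                raise ValueError(f"{name} length does not match atom count {n_atoms}")
        object.__setattr__(self, "coords", c)
        if self.time_offset is None:
            object.__setattr__(self, "time_offset", float(self.frame_interval))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.time_offset + np.arange(self.n_frames) * self.frame_interval

    def select(self, *, atom_name: str | None = None,
               residue_id: int | None = None,
               heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if residue_id is not None:
            mask &= self.residue_ids == residue_id
        if heavy_only:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)


def read_coord_trajectory(path: str | Path, run_id: str | None = None, *,
                          frame_interval: float = 20.0) -> CoordTrajectory:
    """Read a multi-model PDB file into a :class:`CoordTrajectory`."""
    if PDBFile is None:  # pragma: no cover
        raise ImportError("biotite is required to read PDB files")
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack, all models
    return CoordTrajectory(
        run_id=run_id or path.stem,
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        residue_ids=np.asarray(stack.res_id),
        elements=np.asarray(stack.element),
        frame_interval=frame_interval,
    )


def _resolve_single(traj: CoordTrajectory, selector: Mapping[str, object]) -> int:
    idx = traj.select(**selector)  # type: ignore[arg-type]
    if idx.size != 1:
        raise ValueError(f"selector {dict(selector)} matched {idx.size} atoms, need exactly 1")
    return int(idx[0])


def end_to_end_distance(traj: CoordTrajectory, frame: int, *,
                        start: Mapping[str, object] | None = None,
                        end: Mapping[str, object] | None = None) -> float:
    """Euclidean distance (Angstrom) between two uniquely selected atoms.

    Defaults to the C-alpha atoms of the first and last residues.
    """
    if start is None:
        start = {"atom_name": "CA", "residue_id": int(traj.residue_ids.min())}
    if end is None:
        end = {"atom_name": "CA", "residue_id": int(traj.residue_ids.max())}
    a = traj.coords[frame, _resolve_single(traj, start)]
    b = traj.coords[frame, _resolve_single(traj, end)]
    return float(np.linalg.norm(a - b))


# Masses for the elements that occur in a capped peptide.
_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def radius_of_gyration(traj: CoordTrajectory, frame: int, *,
                       selection: np.ndarray | None = None,
                       mass_weighted: bool = False) -> float:
    """RMS distance (Angstrom) of the selection from its (weighted) centroid.

    The default selection is all heavy atoms, unweighted; ``mass_weighted``
    switches to atomic-mass weights for both the centroid and the average.
    """
    if selection is None:
        selection = traj.select(heavy_only=True)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    r = traj.coords[frame, selection]
    if mass_weighted:
        w = np.array([_ATOMIC_MASS.get(str(e), 12.011)
                      for e in traj.elements[selection]], dtype=float)
    else:
        w = np.ones(len(selection))
    centroid = (w[:, None] * r).sum(axis=0) / w.sum()
    sq = ((r - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def metric_timecourse(trajs: Sequence[CoordTrajectory],
                      metric: Callable[[CoordTrajectory, int], float]) -> pd.DataFrame:
    """Per-frame metric for each run, with across-run mean and SD per time point.

    All runs must share frame timing; the output has one row per frame with
    columns ``time_ps``, one column per run id, ``mean`` and ``sd``
    (population SD across runs, so a single run gives 0).
    """
    if not trajs:
        raise ValueError("no trajectories given")
    n_frames = {t.n_frames for t in trajs}
    if len(n_frames) != 1:
        raise ValueError("trajectories differ in frame count")
    values = {t.run_id: np.array([metric(t, k) for k in range(t.n_frames)])
              for t in trajs}
    df = pd.DataFrame(values)
    arr = df.to_numpy()
    df.insert(0, "time_ps", trajs[0].times)
    df["mean"] = arr.mean(axis=1)
    df["sd"] = arr.std(axis=1, ddof=0)
    return df
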