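"""Readers and writers for label trajectories, manifests and result tables.

Three input dialects are supported:

``frames-as-lines``
    One line per frame, one character per residue (the format the package
    itself writes).  Blank-class synonyms (space, ``-``, ``C``) are accepted.
``dssp-per-frame``
    Concatenated standard DSSP output blocks, one block per frame; only the
    one-letter STRUCTURE summary column is consumed.
``table``
    Delimited rows of ``frame``, ``residue``, ``label`` (header optional,
    ``#`` comments ignored).

When no dialect is given the reader sniffs in the fixed order
table -> dssp-per-frame -> frames-as-lines and fails loudly if none fits.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .trajectory import (
    ALPHABET_SET,
    BLANK_SYNONYMS,
    LabelError,
    RunEnsemble,
    SSTrajectory,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

DIALECTS = ("frames-as-lines", "dssp-per-frame", "table")

# Column index of the one-letter summary in a standard DSSP residue line
# ("  #  RESIDUE AA STRUCTURE ..." header; the letter sits under STRUCTURE).
_DSSP_SUMMARY_COL = 16


class TrajectoryParseError(ValueError):
    """Structural problem in a trajectory file (raggedness, emptiness, ...)."""


def read_label_trajectory(path: str | Path, dialect: str | None = None, *,
                          run_id: str | None = None,
                          frame_interval: float = 20.0,
                          time_offset: float | None = None) -> SSTrajectory:
    """Read one secondary-structure label trajectory.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        One of ``frames-as-lines``, ``dssp-per-frame``, ``table``; ``None``
        sniffs (table -> dssp-per-frame -> frames-as-lines).
    run_id:
        Defaults to the file stem.
    frame_interval, time_offset:
        Frame timing in ps (see :class:`~helixtraj.trajectory.SSTrajectory`).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise TrajectoryParseError(f"{path}: empty trajectory file")
    if run_id is None:
        run_id = path.stem
    if dialect is None:
        dialect = sniff_dialect(text)
        logger.debug("%s: sniffed dialect %s", path, dialect)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect == "table":
        labels = _parse_table(text, path)
    elif dialect == "dssp-per-frame":
        labels = _parse_dssp_blocks(text, path)
    else:
        labels = _parse_frame_lines(text, path)
    return SSTrajectory(run_id=run_id, labels=labels,
                        frame_interval=frame_interval, time_offset=time_offset)


def sniff_dialect(text: str) -> str:
    """Guess the dialect of trajectory ``text`` (table -> dssp -> lines)."""
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not stripped:
        raise TrajectoryParseError("no data lines in trajectory file")
    first = stripped[0]
    if any(sep in first for sep in ("\t", ",")) and len(first.replace(" ", "")) > 1:
        return "table"
    if any("  #  RESIDUE" in ln for ln in stripped[:40]) or first.startswith("===="):
        return "dssp-per-frame"
    return "frames-as-lines"


def _parse_frame_lines(text: str, path: Path) -> np.ndarray:
    rows: list[list[str]] = []
    width: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        line = raw.rstrip("\n")
        if width is None:
            width = len(line)
        elif len(line) != width:
            raise TrajectoryParseError(
                f"{path}: ragged frame at line {lineno}: "
                f"{len(line)} residues, expected {width}"
            )
        rows.append([normalize_symbol(c, line=lineno, column=col + 1)
                     for col, c in enumerate(line)])
    if not rows:
        raise TrajectoryParseError(f"{path}: no frames found")
    return np.array(rows, dtype="<U1")


def _parse_dssp_blocks(text: str, path: Path) -> np.ndarray:
    frames: list[list[str]] = []
    current: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if "  #  RESIDUE" in line:
            if current is not None:
                frames.append(current)
            current = []
            continue
        if current is None:
            continue  # header material before the residue table
        if len(line.rstrip()) == 0 or not line[:5].strip().isdigit():
            # end of the residue table (e.g. the next block's headers)
            frames.append(current)
            current = None
            continue
        if len(line) > 13 and line[13] == "!":
            continue  # chain break marker, not a residue
        if len(line) <= _DSSP_SUMMARY_COL:
            # residue line shorter than the STRUCTURE column: blank class
            ch = " "
        else:
            ch = line[_DSSP_SUMMARY_COL]
        current.append(normalize_symbol(ch, line=lineno, column=_DSSP_SUMMARY_COL + 1))
    if current is not None:
        frames.append(current)
    if not frames:
        raise TrajectoryParseError(f"{path}: no DSSP residue blocks found")
    widths = {len(f) for f in frames}
    if len(widths) != 1:
        raise TrajectoryParseError(
            f"{path}: DSSP blocks disagree on residue count: {sorted(widths)}"
        )
    return np.array(frames, dtype="<U1")


def _parse_table(text: str, path: Path) -> np.ndarray:
    try:
        df = pd.read_csv(_io.StringIO(text), sep=None, engine="python", comment="#",
                         header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message is wrapped
        raise TrajectoryParseError(f"{path}: cannot parse table dialect: {exc}") from exc
    if df.shape[1] < 3:
        raise TrajectoryParseError(
            f"{path}: table dialect needs frame, residue, label columns"
        )
    df = df.iloc[:, :3]
    df.columns = ["frame", "residue", "label"]
    # Optional header row
    if not str(df.iloc[0, 0]).lstrip("-").isdigit():
        df = df.iloc[1:]
    if df.empty:
        raise TrajectoryParseError(f"{path}: table has no data rows")
    frame = df["frame"].astype(int).to_numpy()
    residue = df["residue"].astype(int).to_numpy()
    labels = df["label"].fillna(" ").astype(str).to_numpy()
    f0, r0 = frame.min(), residue.min()
    n_frames = frame.max() - f0 + 1
    n_res = residue.max() - r0 + 1
    if len(df) != n_frames * n_res:
        raise TrajectoryParseError(
            f"{path}: table is not a complete frame x residue grid "
            f"({len(df)} rows for {n_frames} frames x {n_res} residues)"
        )
    out = np.full((n_frames, n_res), "?", dtype="<U1")
    for k, (f, r, lab) in enumerate(zip(frame, residue, labels)):
        lab = lab.strip() or " "
        out[f - f0, r - r0] = normalize_symbol(lab[0], line=k + 1)
    if (out == "?").any():
        raise TrajectoryParseError(f"{path}: duplicate or missing (frame, residue) cells")
    return out


def write_label_trajectory(traj: SSTrajectory, path: str | Path, *,
                           header: bool = True) -> None:
    """Write ``traj`` in the frames-as-lines dialect (UTF-8, LF, O spelled out)."""
    path = Path(path)
    lines: list[str] = []
    if header:
        lines += [
            f"# secondary-structure label trajectory, run {traj.run_id}",
            f"# one line per frame; residues 1..{traj.n_residues} left to right (1-based)",
            f"# frame_interval_ps={traj.frame_interval:g} time_offset_ps={traj.time_offset:g}",
        ]
    lines += ["".join(row) for row in traj.labels]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def load_manifest(path: str | Path) -> list[RunEnsemble]:
    """Load a YAML run manifest into validated ensembles.

    Expected layout::

        ensembles:
          - name: Ide
            truncation_ns: 400        # optional
            frame_interval_ps: 20     # optional, default 20
            time_offset_ps: 20        # optional, default = frame interval
            members:                  # strings, or {file, run_id, dialect}
              - Ide1.sst
              - {file: Ide2.sst, run_id: Ide2}

    Member paths are resolved relative to the manifest file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ensembles" not in doc:
        raise ValueError(f"{path}: manifest must contain an 'ensembles' list")
    base = path.parent
    ensembles: list[RunEnsemble] = []
    for ent in doc["ensembles"]:
        name = ent.get("name")
        if not name:
            raise ValueError(f"{path}: ensemble without a name")
        dt = float(ent.get("frame_interval_ps", 20.0))
        t0 = ent.get("time_offset_ps")
        t0 = float(t0) if t0 is not None else None
        members: list[SSTrajectory] = []
        for spec in ent.get("members", []):
            if isinstance(spec, str):
                spec = {"file": spec}
            fpath = base / spec["file"]
            if not fpath.exists():
                raise FileNotFoundError(f"{path}: member file not found: {fpath}")
            members.append(read_label_trajectory(
                fpath, dialect=spec.get("dialect"),
                run_id=spec.get("run_id"), frame_interval=dt, time_offset=t0))
        trunc = ent.get("truncation_ns")
        ens = RunEnsemble(name=name, members=members,
                          truncation_ns=float(trunc) if trunc is not None else None)
        logger.info("manifest %s: ensemble %s with %d members", path, name, len(members))
        ensembles.append(ens)
    return ensembles


def write_tsv(df: pd.DataFrame, path: str | Path, comment_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV with ``#``-commented provenance header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
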