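"""Bundled reference data: the published run table of the 28-run study.

The table carries, for each of 20 "Ide" and 8 "Sim" molecular-dynamics runs
of a 20-residue protonated poly-glutamic acid, the published unfolding time
(ns), the region unfolding order over the default N/M/C partition, and the
per-run helix content.  It serves as a ready-made input to the ensemble
aggregation routines and as the reference point for the package's own
statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .unfolding import UnfoldingSummary


def reference_run_table() -> pd.DataFrame:
    """The published per-run unfolding table as a DataFrame.

    Columns: ``run_id``, ``group`` (Ide/Sim), ``t_u_ns``, ``order``
    (comma-separated region names), ``helix_content``.
    """
    ref = resources.files("helixtraj.data").joinpath("reference_runs.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def reference_summaries(group: str | None = None) -> list[UnfoldingSummary]:
    """The published runs as :class:`UnfoldingSummary` records.

    ``group`` restricts to ``"Ide"`` or ``"Sim"``; ``None`` returns all 28.
    """
    df = reference_run_table()
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise ValueError(f"unknown group {group!r}")
    return [
        UnfoldingSummary(
            run_id=row.run_id,
            t_u_ns=float(row.t_u_ns),
            order=tuple(row.order.split(",")),
            helix_content=float(row.helix_content),
        )
        for row in df.itertuples()
    ]
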