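"""Transition tables, flux ratios, triad statistics — vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from helixtraj import (
    REDUCED_CLASSES,
    TRIAD_CLASSES,
    RegionPartition,
    RunEnsemble,
    flux_ratio,
    reduce_label,
    trajectory_from_lines,
    transition_profile,
    transition_table,
    triad_region_matrix,
    triad_stats,
)
from helixtraj.trajectory import ALPHABET

from conftest import random_ensemble


def brute_force_transition_counts(ens, i, classes, mapper):
    """Independent double-loop counter over all successive frame pairs."""
    counts = {(x, y): 0 for x in classes for y in classes}
    for m in ens.iter_members():
        for f in range(m.n_frames - 1):
            x = mapper(m.labels[f, i - 1])
            y = mapper(m.labels[f + 1, i - 1])
            counts[(x, y)] += 1
    return counts


def brute_force_triads(ens, centers):
    """Independent double-loop triad classifier."""
    counts = {c: 0 for c in TRIAD_CLASSES}
    next_h = {c: 0 for c in TRIAD_CLASSES}
    anomalies = 0
    for m in ens.iter_members():
        for f in range(m.n_frames - 1):
            for c in centers:
                pat = "".join(
                    "H" if m.labels[f, p - 1] == "H" else "-"
                    for p in (c - 1, c, c + 1))
                if pat == "-H-":
                    anomalies += 1
                    continue
                counts[pat] += 1
                if m.labels[f + 1, c - 1] == "H":
                    next_h[pat] += 1
    return counts, next_h, anomalies


class TestTransitionTable:
    def test_two_frame_toy_reduced(self):
        ens = RunEnsemble(name="toy", members=[
            trajectory_from_lines(["H" * 20, "T" * 20])])
        tab = transition_table(ens, 5, "reduced")
        assert tab.probability("T", "H") == 1.0
        assert tab.counts.loc["H"].sum() == 1

    def test_constant_trajectory_identity_rows(self):
        ens = RunEnsemble(name="const", members=[
            trajectory_from_lines(["HGETB" + "O" * 15] * 6)])
        tab = transition_table(ens, 2, "full")
        assert tab.probability("G", "G") == 1.0
        # unobserved sources carry undefined (NaN) probabilities, not zeros
        assert np.isnan(tab.probability("T", "T"))

    def test_out_of_range_residue(self, rng):
        ens = random_ensemble(rng)
        with pytest.raises(ValueError, match="out of range"):
            transition_table(ens, 21)

    @pytest.mark.parametrize("classing,classes,mapper", [
        ("full", ALPHABET, lambda x: x),
        ("reduced", REDUCED_CLASSES, reduce_label),
    ])
    def test_matches_brute_force_exactly(self, rng, classing, classes, mapper):
        ens = random_ensemble(rng, n_runs=5, n_frames=50, n_residues=6)
        for i in (1, 3, 6):
            tab = transition_table(ens, i, classing)
            expect = brute_force_transition_counts(ens, i, classes, mapper)
            for x in classes:
                for y in classes:
                    assert tab.counts.loc[x, y] == expect[(x, y)]

    def test_count_conservation(self, rng):
        ens = random_ensemble(rng, n_runs=3, n_frames=40)
        total = sum(m.n_frames - 1 for m in ens.members)
        for i in (1, 10, 20):
            assert transition_table(ens, i).n_transitions == total

    def test_row_normalization(self, rng):
        ens = random_ensemble(rng, n_runs=2, n_frames=60)
        tab = transition_table(ens, 4, "full")
        sums = tab.probabilities.sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_reduced_equals_collapsed_full(self, rng):
        ens = random_ensemble(rng, n_runs=3, n_frames=50)
        full = transition_table(ens, 7, "full").counts
        reduced = transition_table(ens, 7, "reduced").counts
        collapse = {x: reduce_label(x) for x in ALPHABET}
        collapsed = full.groupby(collapse).sum().T.groupby(collapse).sum().T
        assert (collapsed.loc[list(REDUCED_CLASSES), list(REDUCED_CLASSES)]
                == reduced).all().all()

    def test_respects_ensemble_truncation(self, rng):
        ens = random_ensemble(rng, n_runs=2, n_frames=30)
        short = RunEnsemble(name="cut", members=ens.members,
                            truncation_ns=0.2)  # 200 ps -> 10 frames
        assert transition_table(short, 1).n_transitions == 2 * 9


class TestFluxRatio:
    def test_share_of_departures(self):
        counts = pd.DataFrame(
            [[94, 1, 3, 2], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]],
            index=list(REDUCED_CLASSES), columns=list(REDUCED_CLASSES))
        from helixtraj.transitions import TransitionTable
        tab = TransitionTable(scope="x", classes=REDUCED_CLASSES, counts=counts)
        assert flux_ratio(tab, "H", "T") == pytest.approx(3 / 6)

    def test_ratios_over_all_destinations_sum_to_one(self, rng):
        ens = random_ensemble(rng, n_runs=2, n_frames=50)
        tab = transition_table(ens, 3, "reduced")
        total = sum(flux_ratio(tab, "H", y) for y in REDUCED_CLASSES if y != "H")
        assert total == pytest.approx(1.0)

    def test_undefined_when_no_departures(self):
        ens = RunEnsemble(name="c", members=[trajectory_from_lines(["H" * 4] * 5)])
        tab = transition_table(ens, 1)
        assert np.isnan(flux_ratio(tab, "T", "H"))


class TestTransitionProfile:
    def test_all_h_ensemble(self):
        ens = RunEnsemble(name="h", members=[trajectory_from_lines(["H" * 8] * 4)])
        prof = transition_profile(ens)
        hh = prof[(prof["from"] == "H") & (prof["to"] == "H")]
        assert (hh["probability"] == 1.0).all() and len(hh) == 8

    def test_row_sums_one_wherever_observed(self, rng):
        ens = random_ensemble(rng, n_runs=2, n_frames=40, n_residues=5)
        prof = transition_profile(ens, "full")
        sums = prof.groupby(["residue", "from"])["probability"].sum()
        observed = prof.groupby(["residue", "from"])["count"].sum() > 0
        assert np.allclose(sums[observed], 1.0, atol=1e-9)


class TestTriads:
    def test_all_h_two_frames(self, part):
        ens = RunEnsemble(name="h", members=[trajectory_from_lines(["H" * 20] * 2)])
        ts = triad_stats(ens, part, "All")
        assert ts.counts["HHH"] == 18 and ts.p_next_h("HHH") == 1.0
        assert sum(v for k, v in ts.counts.items() if k != "HHH") == 0

    def test_matches_brute_force(self, rng, part):
        ens = random_ensemble(rng, n_runs=4, n_frames=30)
        for scope, centers in [("All", range(2, 20)),
                               ("N", part.positions("N")),
                               ("C", part.positions("C"))]:
            ts = triad_stats(ens, part, scope)
            counts, next_h, anomalies = brute_force_triads(ens, list(centers))
            assert ts.counts == counts
            assert ts.next_h_counts == next_h
            assert ts.anomaly_count == anomalies

    def test_unknown_region_rejected(self, rng, part):
        with pytest.raises(KeyError):
            triad_stats(random_ensemble(rng), part, "Z")

    def test_complement_identity(self, rng, part):
        ens = random_ensemble(rng, n_runs=2, n_frames=40)
        ts = triad_stats(ens, part, "All")
        for cls in TRIAD_CLASSES:
            if ts.counts[cls]:
                assert ts.p_next_coil(cls) == pytest.approx(1 - ts.p_next_h(cls))

    def test_all_pools_regions_plus_outside_centers(self, rng, part):
        # count-weighted pooling of N, M, C equals All for the default
        # partition, whose regions cover every interior center
        ens = random_ensemble(rng, n_runs=3, n_frames=25)
        all_ts = triad_stats(ens, part, "All")
        by_region = [triad_stats(ens, part, s) for s in ("N", "M", "C")]
        for cls in TRIAD_CLASSES:
            assert all_ts.counts[cls] == sum(t.counts[cls] for t in by_region)
            assert all_ts.next_h_counts[cls] == sum(
                t.next_h_counts[cls] for t in by_region)

    def test_region_matrix_all_h(self, part):
        ens = RunEnsemble(name="h", members=[trajectory_from_lines(["H" * 20] * 3)])
        mat = triad_region_matrix(ens, part)
        assert (mat.loc["P(H,HHH)"] == 1.0).all()
        assert list(mat.columns) == ["All", "N", "M", "C"]
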