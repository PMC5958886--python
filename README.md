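# helixtraj

Helix–coil transition kinetics from per-residue secondary-structure
trajectories of molecular-dynamics simulations.

## The problem

All-atom MD simulations of short helical peptides — the motivating system is
a 20-residue, fully protonated poly-glutamic acid — produce, after DSSP
assignment, a *label trajectory*: one letter per residue per stored snapshot
from the 8-class alphabet `H G I E B T S O` (α-helix, 3₁₀-helix, π-helix,
strand, bridge, turn, bend, none; `O` spells DSSP's blank class).  From such
matrices one wants to know *how* a helix falls apart: when it is fully gone,
which end unravels first, through which intermediate conformations each
residue passes, and how the ends of a surviving helix elongate or unwind.

`helixtraj` implements that analysis as a reusable library plus CLI:

* **Unfolding time** `t_u` — the time of the first snapshot with no `H`
  residue — and run summaries over ensembles of runs (mean / median / SD,
  with never-unfolding runs reported separately).
* **Region-ordered unfolding** — residues 2–7 (N), 8–13 (M), 14–19 (C) are
  ranked by their mean helix content up to `t_u`; the region with the least
  helix unfolded first.
* **Transition kinetics** — per-residue empirical probabilities
  `P(y, x; i)` of moving from class `x` to `y` over one 20 ps snapshot lag,
  over the full alphabet or the reduced classes `{H, G, T, other}`, plus
  flux ratios such as the fraction of helix departures routed through the
  turn.
* **Triad statistics** — three-residue windows classified by their
  helix/non-helix pattern (`HHH`, `HH–`, `–HH`, `H–H`, `H– –`, `– –H`,
  `– – –`; `–H–` is geometrically impossible and counted as an anomaly)
  and the probability that the center is helical one snapshot later:
  elongation and unwinding propensities of helix ends.
* **Chain metrics** — end-to-end distance and radius of gyration from
  multi-model PDB coordinate trajectories.
* **Synthetic data** — a kinetic Zimm–Bragg Monte-Carlo generator
  (per-residue propensity `s_i`, nucleation penalty `σ`, minimum helix run
  length, boundary `G`/`T` decoration) so the whole pipeline can be
  validated without running MD.  See `docs/methods.md` for the model.

The package also bundles the published per-run unfolding table of the
28-run study of this system (20 `Ide` + 8 `Sim` runs) as a ready-made input.

## Worked example

```python
import helixtraj as ht

# published run table bundled with the package
stats = ht.ensemble_stats(ht.reference_summaries())
print(f"28 runs, median t_u = {stats.median_t_u_ns:.2f} ns")
ide = ht.ensemble_stats(ht.reference_summaries("Ide"))
print(f"Ide runs unfolding C-first: {ide.count_first('C')}/20, "
      f"terminus-to-terminus: {ide.count_terminus_to_terminus()}")

# a synthetic ensemble, analyzed with the same machinery
ens = ht.make_paperlike_ensemble(10, ht.HelixKineticsParams(n_frames=1000), seed=7)
summaries, s = ht.summarize_runs(ens)
print(f"synthetic: {s.n_unfolded}/10 unfolded, median t_u = {s.median_t_u_ns:.2f} ns, "
      f"C-first {s.count_first('C')}, N-first {s.count_first('N')}")
ts = ht.triad_stats(ens)
print(f"P(H,HH-) = {ts.p_next_h('HH-'):.2f}, P(H,-HH) = {ts.p_next_h('-HH'):.2f}, "
      f"anomalies = {ts.anomaly_count}")
```

prints

```
28 runs, median t_u = 36.02 ns
Ide runs unfolding C-first: 13/20, terminus-to-terminus: 3
synthetic: 10/10 unfolded, median t_u = 0.75 ns, C-first 4, N-first 1
P(H,HH-) = 0.70, P(H,-HH) = 0.74, anomalies = 0
```

Reading: the 28 published runs have a median unfolding time of 36.02 ns and
unfold preferentially from the C-terminus (13 of 20 `Ide` runs), almost never
by a clean terminus-to-opposite-terminus sweep (3 of 20).  The synthetic
C-destabilized ensemble reproduces the C-first preference; its helix ends
retain helix at the next snapshot ~70 % of the time, with no impossible
`–H–` triads (the generator enforces the 4-residue minimum helix length).

### Command line

```sh
helixtraj simulate --out sim/ --n-runs 8 --n-frames 1000 --seed 1
helixtraj analyze  --manifest sim/manifest.yaml --out report/
helixtraj raster   --traj sim/syn01.sst --out syn01.png
helixtraj recover  --manifest sim/manifest.yaml --out recovery.tsv
```

`analyze` writes, per ensemble, a run-summary TSV, a per-residue content
profile, tidy transition probabilities, and the triad probability matrix.

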