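# Methods

## Data model and conventions

A label trajectory is a frames × residues matrix over the 8-letter DSSP
alphabet `H G I E B T S O`, with `O` the canonical spelling of DSSP's blank
("no recognized element") class; readers normalize the common synonyms
(space, `-`, `C`) on input.  Residue positions are 1-based.  The time of
frame *k* (0-based) is `time_offset + k·frame_interval`, in ps, with a
default interval of 20 ps and a default offset of one interval: the first
stored snapshot is taken to follow the initial structure, so a trajectory
whose very first frame is helix-free has `t_u` = 20 ps, not 0.  The offset
is configurable because deposited datasets do not always state their
convention.

Ensembles are ordered collections of runs sharing chain length and frame
interval.  A truncation (in ns) limits every member to frames with
time ≤ the limit for *all* aggregate operations; this is how 400 ns
prefixes of longer runs are analyzed as a separate ensemble.

Input dialects: `frames-as-lines` (one label string per frame — the format
the package writes), `table` (delimited frame/residue/label rows), and
`dssp-per-frame` (concatenated standard DSSP text outputs, one block per
frame, reading only the one-letter STRUCTURE summary column).  Sniffing
tries table, then DSSP, then frames-as-lines, and fails loudly rather than
guessing: a mis-detected dialect would silently corrupt every downstream
count.  The classic `.dssp` text layout has no parser in the scientific
Python stack (existing packages run or re-implement the assignment
algorithm, which is out of scope here), so the small column-position reader
is hand-written.

## Unfolding statistics

`t_u` is the time of the first frame containing no `H` residue.  Only the
α-helix class counts: `G` (3₁₀) is a kinetic intermediate, not surviving
helix.  Runs without such a frame "never" unfold; they are excluded from
the `t_u` mean/median/SD (sample SD, n−1) and counted separately.

Helix content is the pooled fraction of residue-frame cells labeled `H` or
`G`; per-residue profiles `P(x; i)` pool all frames of all members with
equal weight, so each residue's eight class fractions sum to 1.

The unfolding order of the default partition (N = residues 2–7, M = 8–13,
C = 14–19, chain ends excluded) ranks regions by mean `H` content over
frames with time ≤ `t_u`, ascending — least helix unfolded first.  Two
choices here were genuinely open:

* the content metric uses `H` only (consistent with the definition of
  `t_u`); an `order_labels` switch allows `{H, G}`;
* the window is closed at `t_u`, i.e. includes the first helix-free frame.

Ties (rare on real data, common on toy inputs) break by the earlier time of
the region's first helix-free frame, then by partition order.

The bundled published run table (28 runs) notes one erratum: the printed
ensemble mean `t_u` of 75.63 ns is not recomputable from the printed
per-run values (they give 78.12 ns), and the printed per-group medians
appear garbled.  The package therefore leans on the median, which is
self-consistent (36.02 ns pooled); means are reported but never asserted.

## Transition kinetics

For residue *i*, every (frame *t*, frame *t*+lag) pair of every member is a
transition count; the last `lag` frames of a member are never sources.  The
default lag is one stored frame (20 ps); a `lag` parameter exists but no
multi-lag analysis (Markov-state models, implied timescales) is attempted —
the quantities here are single-lag empirical probabilities.  Counts are
pooled across runs *before* normalizing: the ensemble estimate is a single
ratio estimator, not an average of per-run ratios, so long runs weigh more.
Rows with zero source counts report NaN probabilities — "never observed"
is distinct from "observed, never left".

The reduced classing keeps `H`, `G`, `T` and pools `{I, E, S, B, O}` into
`other`.  The flux ratio from class *x* through *y* is
`P(y,x) / Σ_{z≠x} P(z,x)` — the share of departures routed through *y*
(e.g. helix lost via turn).

Triads: centers run over positions 2..n−1 ("All" scope) or a region's
positions with both neighbors present.  Each (frame, center) with a
successor frame contributes one count to the class given by the H/non-H
pattern of (c−1, c, c+1); the next-frame probability is the fraction whose
center is `H` one lag later.  The pattern `–H–` cannot arise from genuine
DSSP α-helix assignments (minimum run length 4) and is tallied as an
anomaly rather than an eighth class — a nonzero anomaly count flags
corrupted input or an assignment that does not respect helix geometry.
For the default partition the three regions tile the interior exactly, so
the "All" column equals their count-weighted pooling; for custom partitions
"All" also includes centers outside every region.

## Coordinate metrics

End-to-end distance defaults to Cα(first residue)–Cα(last residue); the
atoms behind published end-to-end values are often unstated, so both
selectors are explicit dictionaries.  Radius of gyration defaults to all
heavy atoms, unweighted, with optional mass weighting; it is the RMS
distance of the selection from its (weighted) centroid.  Both are plain
Euclidean functionals and are checked for rigid-motion invariance at
1e-8 Å.  Multi-model PDB files are read with biotite; reproducing any
particular published end-to-end average is out of scope (the coordinate
trajectories behind them are not deposited), so this module is exercised
on synthetic coordinates.

## Synthetic kinetic Zimm–Bragg generator

The generator evolves a binary helix(h)/coil(c) chain under the energy

    E = − Σ_i h_i ln s_i − R ln σ,

with `s_i` the per-position helix propensity, `σ ∈ (0, 1]` the nucleation
penalty, and `R` the number of maximal helical runs.  Dynamics are
Metropolis: each stored frame is one sweep of `sweep_moves` proposals
(default = chain length), each accepted with probability `min(1, e^−ΔE)`.

Two proposal kinds are mixed:

* **single flips** (probability `1 − p_block_move`): flip one uniformly
  chosen residue;
* **block moves** (probability `p_block_move`, default 0.1): choose a
  window of `min_run` contiguous residues uniformly and flip it between
  all-h and all-c; mixed windows are a no-op.

The block move exists because the `min_run` constraint (enforced by
rejecting any accepted state containing a helical run shorter than
`min_run`) makes single flips non-ergodic: a run of exactly `min_run`
residues could neither shrink nor vanish, and a helix could never nucleate
from coil.  With blocks, runs are created and annihilated atomically.  Both
proposal kinds are symmetric, so the chain satisfies detailed balance with
respect to the Boltzmann distribution of E restricted to `min_run`-valid
states; the test suite verifies this against a brute-force partition
function over all 2⁸ states of an 8-residue chain (total-variation
distance < 0.02 at 10⁵ sweeps — the bound sits just above the multinomial
sampling floor of 10⁵ draws over 256 states, so the check is run at a
concentrated parameter point, s = 2, σ = 0.1, where the floor is ≈ 0.013).

Emission decorates the binary state into labels: h → `H`; a coil residue
adjacent to a helix-run end → `G` with `p_decorate_G`, else `T` with
`p_decorate_T`, else `O`; interior coil → `O`.  Decoration models the
observation that 3₁₀-helix and especially turn conformations concentrate at
helix boundaries as kinetic intermediates; it is cosmetic labeling, takes
no part in the energy, and is exactly invertible from label frequencies of
boundary cells — which is how `recover_parameters` estimates it.

### Default study conditions

Chosen once to emulate the qualitative structure of helix-unfolding MD of
protonated poly-glutamic acid, and then left alone:

| parameter | default | rationale |
|---|---|---|
| `n_residues` | 20 | the study chain length |
| `n_frames` | 2000 | 40 ns at 20 ps/frame — every default run unfolds well inside the horizon |
| `ln s_i` | linear, −0.05 (res 1) → −0.9 (res 20) | helix-averse everywhere (full unfolding completes, helix reformation is rare), weakest at the C-terminus (C-first unwinding preference) |
| `σ` | 0.05 | strong nucleation penalty: helix lives in few long runs, spontaneous nucleation is rare |
| `min_run` | 4 | α-helix geometry; guarantees zero `–H–` triads |
| `p_decorate_G`, `p_decorate_T` | 0.15, 0.55 | turn is the dominant boundary intermediate, 3₁₀ the minor one |
| `p_block_move` | 0.1 | mostly local dynamics, occasional run creation/annihilation |

What the generator does *not* emulate: absolute time scales (a sweep is
"20 ps" by convention only; default-parameter median `t_u` is ~0.7 ns
versus tens of ns in the MD study), strand/bridge/bend classes (never
emitted), helix-content magnitudes of any particular force field, and
within-run time correlations beyond the Markov dynamics itself.  Passing
tests on synthetic data therefore demonstrate the correctness of the
counting and classification machinery and the qualitative direction of the
C-destabilization analysis — not quantitative agreement with any MD result.

## Problem sizes

The validation suite and the acceptance script use: 50-run default
ensembles (≈2×10⁶ Monte-Carlo moves, a few seconds), 4-run neutral-model
ensembles of 3000 frames for flatness checks, and 10⁵ sweeps of an
8-residue chain for the stationarity check.  All random streams derive
from explicit seeds via `numpy.random.SeedSequence` spawning, so every
reported number is bit-reproducible.

## Known limitations

* The deposited raw label trajectories of the original 28-run study are
  not shipped (tens of MB); the four reproduction tests that need them
  fail with a pointed message until the data are placed under
  `data/deposited/`.  All other results are computed from the bundled
  published run table or from synthetic data.
* The dialect sniffer has only been validated against files this package
  writes and standard DSSP text output; the deposited dataset's exact
  layout should be checked against it before batch use.
* `ensemble_stats` trusts its input summaries; feeding it summaries from
  differently truncated runs is not detected.
* The triad "All" scope uses centers 2..n−1.  Published tables of this
  kind do not state their center range; for the default partition the
  distinction is invisible (the regions tile the interior exactly).
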