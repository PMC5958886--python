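"""Kinetic Zimm-Bragg generator of synthetic label trajectories.

The generator evolves a binary helix/coil chain by Metropolis Monte Carlo on
the Zimm-Bragg energy

    E = - sum_i h_i ln s_i  -  (number of helical runs) ln sigma,

where ``s_i`` is the per-position helix propensity and ``sigma`` in (0, 1]
the nucleation penalty: every helical residue is rewarded by its propensity
and every distinct helical run pays the nucleation cost once.  Each stored
frame is one sweep of single-residue flip proposals accepted with probability
``min(1, exp(-dE))``.  With ``min_run > 1`` any accepted state containing a
helical run shorter than ``min_run`` is rejected, which reproduces the
geometric fact that genuine alpha-helices span at least four residues (and,
as a consequence, makes nucleation from an all-coil chain impossible under
single flips — the intended use starts from an all-helix state, mirroring
helix-unfolding simulations).

Emission decorates the binary state into the 8-letter alphabet: helical
residues emit H; coil residues adjacent to a helix-run end emit G or T with
configurable probabilities (3_10 and turn conformations act as boundary
intermediates of helix-coil kinetics); all remaining coil residues emit O.
Decoration is cosmetic labeling and takes no part in the energy.

The default parameters describe a 20-residue chain whose helix propensity
decays from the N- to the C-terminus, so that runs started from a full helix
unwind preferentially from the C-terminal end — the qualitative behavior of
protonated poly-glutamic acid in all-atom simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trajectory import RunEnsemble, SSTrajectory


def default_propensity_profile(n_residues: int = 20) -> np.ndarray:
    """Per-position helix propensity decaying toward the C-terminus.

    ``ln s`` falls linearly from -0.05 at the first residue to -0.9 at the
    last: the whole chain is helix-averse at equilibrium (a full helix
    unwinds completely within a few thousand sweeps, as protonated
    poly-glutamic acid does in all-atom simulations), and the C-terminal end
    is clearly the weakest, so unwinding sets in there first.
    """
    return np.exp(np.linspace(-0.05, -0.9, n_residues))


@dataclass
class HelixKineticsParams:
    """Parameters of the kinetic Zimm-Bragg generator.

    Attributes
    ----------
    n_residues, n_frames:
        Chain length and number of stored frames (one frame per sweep).
    s:
        Per-position helix propensities (positive); default is the
        C-destabilized profile of :func:`default_propensity_profile`.
    sigma:
        Nucleation penalty in (0, 1]; each distinct helical run pays
        ``-ln sigma``.  Default 0.05 keeps helix in few long runs.
    min_run:
        Minimum helical run length; 4 matches the alpha-helix geometry,
        1 disables the constraint.
    p_decorate_G, p_decorate_T:
        Boundary-coil emission: a coil residue adjacent to a helix end emits
        G with ``p_decorate_G``, otherwise T with ``p_decorate_T``, else O.
        Defaults make the turn the dominant boundary intermediate.
    sweep_moves:
        Flip proposals per stored frame; default ``n_residues``.
    p_block_move:
        Probability that a proposal is a block move: a window of
        ``min_run`` contiguous residues is flipped between all-helix and
        all-coil (a no-op on mixed windows).  Block moves keep the chain
        ergodic under the ``min_run`` constraint — without them a helical
        run could never shrink below ``min_run`` nor nucleate — and their
        proposal distribution is symmetric, so detailed balance holds.
    frame_interval:
        Nominal time per frame in ps (default 20, the stored-snapshot
        spacing the analysis assumes).
    """

    n_residues: int = 20
    n_frames: int = 2000
    s: np.ndarray | None = None
    sigma: float = 0.05
    min_run: int = 4
    p_decorate_G: float = 0.15
    p_decorate_T: float = 0.55
    sweep_moves: int | None = None
    p_block_move: float = 0.1
    frame_interval: float = 20.0

    def __post_init__(self) -> None:
        if self.s is None:
            self.s = default_propensity_profile(self.n_residues)
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (self.n_residues,):
            raise ValueError(f"s must have length {self.n_residues}")
        if (self.s <= 0).any():
            raise ValueError("helix propensities must be positive")
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must be in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        for name in ("p_decorate_G", "p_decorate_T", "p_block_move"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sweep_moves is None:
            self.sweep_moves = self.n_residues


def _run_lengths(h: np.ndarray) -> list[int]:
    lengths = []
    run = 0
    for x in h:
        if x:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def _run_length_at(h: np.ndarray, k: int) -> int:
    """Length of the maximal helical run containing position k (h[k] must be True)."""
    n = len(h)
    lo = k
    while lo > 0 and h[lo - 1]:
        lo -= 1
    hi = k
    while hi < n - 1 and h[hi + 1]:
        hi += 1
    return hi - lo + 1


def _min_run_ok_local(h: np.ndarray, i: int, min_run: int) -> bool:
    """Check the runs affected by a flip at i: the run containing i (if any)
    and, when i is coil, the two flanking runs a split may have shortened."""
    n = len(h)
    if h[i]:
        return _run_length_at(h, i) >= min_run
    if i > 0 and h[i - 1] and _run_length_at(h, i - 1) < min_run:
        return False
    if i < n - 1 and h[i + 1] and _run_length_at(h, i + 1) < min_run:
        return False
    return True


def simulate_states(params: HelixKineticsParams,
                    initial: str | np.ndarray = "all-helix", *,
                    rng: np.random.Generator | int) -> np.ndarray:
    """Run the Metropolis chain; return the boolean state after each sweep.

    ``initial`` is ``"all-helix"``, ``"all-coil"`` or an explicit boolean
    array.  Returns shape ``(n_frames, n_residues)``.  Identical seeds give
    identical outputs.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = params.n_residues
    if isinstance(initial, str):
        if initial == "all-helix":
            h = np.ones(n, dtype=bool)
        elif initial == "all-coil":
            h = np.zeros(n, dtype=bool)
        else:
            raise ValueError(f"unknown initial state {initial!r}")
    else:
        h = np.asarray(initial, dtype=bool).copy()
        if h.shape != (n,):
            raise ValueError(f"initial state must have length {n}")
        if params.min_run > 1:
            if any(r < params.min_run for r in _run_lengths(h)):
                raise ValueError("initial state violates min_run")
    ln_s = np.log(params.s)
    ln_sigma = math.log(params.sigma)
    check_runs = params.min_run > 1
    moves = params.sweep_moves
    block = params.min_run
    n_starts = n - block + 1
    out = np.empty((params.n_frames, n), dtype=bool)

    # Draw per-sweep randomness in blocks: move type, site, and acceptance.
    for frame in range(params.n_frames):
        idx = rng.integers(0, n, size=moves)
        starts = rng.integers(0, n_starts, size=moves)
        kind = rng.random(moves)
        u = rng.random(moves)
        for m in range(moves):
            if kind[m] < params.p_block_move:
                # block move: flip a min_run window all-h <-> all-c
                a = int(starts[m])
                b = a + block
                win = h[a:b]
                all_h = bool(win.all())
                if not all_h and win.any():
                    continue  # mixed window: no-op (keeps proposals symmetric)
                left = bool(h[a - 1]) if a > 0 else False
                right = bool(h[b]) if b < n else False
                if all_h:
                    d_runs = (left + right) - 1
                    dE = float(ln_s[a:b].sum()) - ln_sigma * d_runs
                else:
                    d_runs = 1 - (left + right)
                    dE = -float(ln_s[a:b].sum()) - ln_sigma * d_runs
                if dE > 0 and u[m] >= math.exp(-dE):
                    continue
                h[a:b] = not all_h
                if check_runs and not (
                    _min_run_ok_local(h, a, params.min_run)
                    and _min_run_ok_local(h, b - 1, params.min_run)
                ):
                    h[a:b] = all_h  # reject: constraint violated
                continue
            i = int(idx[m])
            left = bool(h[i - 1]) if i > 0 else False
            right = bool(h[i + 1]) if i < n - 1 else False
            if h[i]:
                d_runs = (left + right) - 1
                dE = ln_s[i] - ln_sigma * d_runs
            else:
                d_runs = 1 - (left + right)
                dE = -ln_s[i] - ln_sigma * d_runs
            if dE > 0 and u[m] >= math.exp(-dE):
                continue
            h[i] = not h[i]
            if check_runs and not _min_run_ok_local(h, i, params.min_run):
                h[i] = not h[i]  # reject: constraint violated
        out[frame] = h
    return out


def decorate_states(states: np.ndarray, params: HelixKineticsParams, *,
                    rng: np.random.Generator | int) -> np.ndarray:
    """Emit 8-letter labels from binary states (H / boundary G,T / O)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_frames, n = states.shape
    labels = np.full((n_frames, n), "O", dtype="<U1")
    labels[states] = "H"
    # boundary coil: non-helical with at least one helical neighbor
    left = np.zeros_like(states)
    left[:, 1:] = states[:, :-1]
    right = np.zeros_like(states)
    right[:, :-1] = states[:, 1:]
    boundary = ~states & (left | right)
    nb = int(boundary.sum())
    if nb:
        u = rng.random(nb)
        decorated = np.full(nb, "O", dtype="<U1")
        decorated[u < params.p_decorate_G] = "G"
        rest = u >= params.p_decorate_G
        # second draw folded into the same deviate: rescale the remainder
        u2 = (u[rest] - params.p_decorate_G) / max(1 - params.p_decorate_G, 1e-300)
        tmp = decorated[rest]
        tmp[u2 < params.p_decorate_T] = "T"
        decorated[rest] = tmp
        labels[boundary] = decorated
    return labels


def simulate_trajectory(params: HelixKineticsParams,
                        initial: str | np.ndarray = "all-helix", *,
                        seed: int, run_id: str = "syn") -> SSTrajectory:
    """Generate one synthetic label trajectory (states + decoration).

    The state evolution and the emission decoration use independent streams
    spawned from ``seed``, so trajectories are reproducible bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    state_rng, emit_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    states = simulate_states(params, initial, rng=state_rng)
    labels = decorate_states(states, params, rng=emit_rng)
    return SSTrajectory(run_id=run_id, labels=labels,
                        frame_interval=params.frame_interval)


def make_paperlike_ensemble(n_runs: int = 28,
                            params: HelixKineticsParams | None = None, *,
                            seed: int, name: str = "synthetic") -> RunEnsemble:
    """Independent all-helix-start runs with distinct derived seeds.

    Mirrors a many-run helix-unfolding study design: every member begins
    from a full helix and evolves under the same kinetics.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if params is None:
        params = HelixKineticsParams()
    children = np.random.SeedSequence(seed).spawn(n_runs)
    members = []
    for k, child in enumerate(children, start=1):
        ss = child.spawn(2)
        states = simulate_states(params, "all-helix", rng=np.random.default_rng(ss[0]))
        labels = decorate_states(states, params, rng=np.random.default_rng(ss[1]))
        members.append(SSTrajectory(run_id=f"{name}{k:02d}", labels=labels,
                                    frame_interval=params.frame_interval))
    return RunEnsemble(name=name, members=members)


def enumerate_boltzmann(params: HelixKineticsParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact Zimm-Bragg stationary distribution by brute-force enumeration.

    Enumerates all 2^n binary states (n <= 20), zeroing those that violate
    ``min_run``; returns ``(probabilities, per-residue helix marginal)`` with
    probabilities indexed by the integer whose bit k is residue k's state.
    """
    n = params.n_residues
    if n > 20:
        raise ValueError("enumeration limited to 20 residues")
    ln_s = np.log(params.s)
    ln_sigma = math.log(params.sigma)
    n_states = 1 << n
    log_w = np.full(n_states, -np.inf)
    for code in range(n_states):
        h = np.array([(code >> k) & 1 for k in range(n)], dtype=bool)
        runs = _run_lengths(h)
        if params.min_run > 1 and any(r < params.min_run for r in runs):
            continue
        log_w[code] = float(ln_s[h].sum()) + len(runs) * ln_sigma
    log_w -= log_w.max()
    w = np.exp(log_w)
    p = w / w.sum()
    marginal = np.zeros(n)
    for k in range(n):
        mask = np.array([(code >> k) & 1 for code in range(n_states)], dtype=bool)
        marginal[k] = p[mask].sum()
    return p, marginal


@dataclass(frozen=True)
class ParameterRecovery:
    """Empirical estimates recovered from a generated ensemble."""

    p_hh: np.ndarray            # P(H, H; i) per residue (NaN where H unobserved)
    p_hh_se: np.ndarray         # binomial standard error of each estimate
    n_h_sources: np.ndarray     # transition pairs with H source, per residue
    p_decorate_G_hat: float
    p_decorate_T_hat: float
    n_boundary: int


def recover_parameters(ens: RunEnsemble) -> ParameterRecovery:
    """Estimate retention and decoration probabilities from labels alone.

    ``P(H, H; i)`` comes from per-residue transition counting; the decoration
    probabilities from the label frequencies of boundary coil cells (non-H
    cells with an H neighbor), inverting the G-then-T emission rule.
    """
    from .transitions import transition_table  # local import avoids a cycle

    n = ens.n_residues
    p_hh = np.full(n, np.nan)
    se = np.full(n, np.nan)
    n_src = np.zeros(n, dtype=int)
    for i in range(1, n + 1):
        tab = transition_table(ens, i, classing="reduced")
        row = tab.counts.loc["H"]
        total = int(row.sum())
        n_src[i - 1] = total
        if total:
            p = float(row["H"]) / total
            p_hh[i - 1] = p
            se[i - 1] = math.sqrt(max(p * (1 - p), 1e-12) / total)

    n_boundary = n_g = n_t = 0
    for traj in ens.iter_members():
        is_h = traj.labels == "H"
        left = np.zeros_like(is_h)
        left[:, 1:] = is_h[:, :-1]
        right = np.zeros_like(is_h)
        right[:, :-1] = is_h[:, 1:]
        boundary = ~is_h & (left | right)
        n_boundary += int(boundary.sum())
        n_g += int((traj.labels[boundary] == "G").sum())
        n_t += int((traj.labels[boundary] == "T").sum())
    if n_boundary:
        p_g = n_g / n_boundary
        p_t = (n_t / n_boundary) / max(1 - p_g, 1e-12)
    else:
        p_g = p_t = float("nan")
    return ParameterRecovery(p_hh=p_hh, p_hh_se=se, n_h_sources=n_src,
                             p_decorate_G_hat=p_g, p_decorate_T_hat=p_t,
                             n_boundary=n_boundary)
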