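"""Exact continuous-time stochastic simulation of the length dynamics.

Implements the Gillespie algorithm for the master equation of ``M`` filaments
with per-filament growth rate ``k_plus * (free pool)`` and shrinkage rate
``gamma(L_i)``, trajectory recording, time-grid stationary sampling, the
in-silico flagellar severing experiment, and the deterministic (mean-field)
rate-balance ODE ``dL_i/dt = r({L}) - gamma(L_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _ssa
from .large_pool import LengthDistribution
from .model import KineticModel, PoolMode

__all__ = [
    "Trajectory",
    "SeveringResult",
    "simulate",
    "stationary_sample",
    "sample_lengths",
    "severing_experiment",
    "mean_field_trajectory",
    "relaxation_time_estimate",
]

_CHUNK = 1 << 20


@dataclass
class Trajectory:
    """Event-time series of filament lengths from one SSA run.

    ``times[0] = 0`` carries the initial state; every later row differs from
    its predecessor by +/-1 in exactly one filament.
    """

    times: np.ndarray
    lengths: np.ndarray  # shape (n_events + 1, M)
    model: KineticModel
    seed: int
    initial_lengths: tuple[int, ...]
    rng: str = field(default="mt19937")

    @property
    def n_events(self) -> int:
        return self.times.size - 1

    def final_state(self) -> np.ndarray:
        return self.lengths[-1].copy()


def _check_initial(model: KineticModel, initial_lengths) -> np.ndarray:
    m = model.m_filaments
    if initial_lengths is None:
        L0 = np.zeros(m, dtype=np.int64)
    else:
        L0 = np.asarray(initial_lengths, dtype=np.int64)
        if L0.shape != (m,):
            raise ValueError(f"initial_lengths must have length M={m}")
        if np.any(L0 < 0):
            raise ValueError("initial lengths must be >= 0")
        if model.pool_mode is PoolMode.FINITE and L0.sum() > model.n_total:
            raise ValueError("initial lengths exceed the total pool N")
    return L0


def simulate(
    model: KineticModel,
    t_max: float,
    initial_lengths=None,
    seed: int = 0,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Run the exact SSA up to ``t_max``, recording every event.

    Reproducible: the same ``(model, initial_lengths, seed, t_max)`` yields
    an identical trajectory (single RNG stream, two draws per event).
    """
    if not t_max > 0:
        raise ValueError("t_max must be > 0")
    args = _ssa.pack_model(model)
    L = _check_initial(model, initial_lengths)
    L0 = tuple(int(v) for v in L)
    _ssa.seed_stream(seed)

    m = model.m_filaments
    chunks_t, chunks_l = [], []
    t = 0.0
    total = 0
    while True:
        cap = min(_CHUNK, max_events - total)
        if cap <= 0:
            raise RuntimeError(
                f"event budget max_events={max_events} exhausted at t={t:g} "
                f"(of t_max={t_max:g}); raise max_events or lower t_max"
            )
        times = np.empty(cap, dtype=np.float64)
        lengths = np.empty((cap, m), dtype=np.int64)
        n, t, full = _ssa.run_events(*args, L, t, float(t_max), times, lengths)
        chunks_t.append(times[:n])
        chunks_l.append(lengths[:n])
        total += n
        if not full:
            break

    times = np.concatenate([np.zeros(1)] + chunks_t)
    lengths = np.concatenate([np.asarray([L0], dtype=np.int64)] + chunks_l)
    return Trajectory(
        times=times, lengths=lengths, model=model, seed=int(seed), initial_lengths=L0
    )


def relaxation_time_estimate(model: KineticModel) -> float:
    """Heuristic relaxation time ``lam * max(1, 1/(QN-1))`` in model time units."""
    lam = model.lam
    try:
        qn = model.q_n
    except ZeroDivisionError:
        return lam
    if qn > 1.0:
        return lam * max(1.0, 1.0 / (qn - 1.0))
    return 10.0 * lam


def sample_lengths(
    model: KineticModel,
    n_samples: int,
    burn_in: float | None = None,
    thin_interval: float | None = None,
    seed: int = 0,
    initial_lengths=None,
) -> np.ndarray:
    """Sample joint lengths on a fixed time grid after burn-in.

    Returns an ``(n_samples, M)`` integer array.  Time-grid (not per-event)
    sampling avoids the event-frequency bias of jump-chain averages.
    Defaults: ``burn_in`` is ten relaxation-time estimates, ``thin_interval``
    one fifth of one.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    tau = relaxation_time_estimate(model)
    if burn_in is None:
        burn_in = 10.0 * tau
    if thin_interval is None:
        thin_interval = tau / 5.0
    if burn_in < 0 or not thin_interval > 0:
        raise ValueError("burn_in must be >= 0 and thin_interval > 0")
    args = _ssa.pack_model(model)
    L = _check_initial(model, initial_lengths)
    _ssa.seed_stream(seed)
    grid = burn_in + thin_interval * np.arange(n_samples, dtype=np.float64)
    out = np.empty((n_samples, model.m_filaments), dtype=np.int64)
    _ssa.run_sample_grid(*args, L, 0.0, grid, out)
    return out


def stationary_sample(
    model: KineticModel,
    n_samples: int = 10_000,
    burn_in: float | None = None,
    thin_interval: float | None = None,
    seed: int = 0,
    initial_lengths=None,
    filament_index: int = 0,
) -> LengthDistribution:
    """Empirical stationary length histogram of one filament."""
    if not 0 <= filament_index < model.m_filaments:
        raise IndexError("filament_index out of range")
    samples = sample_lengths(
        model,
        n_samples,
        burn_in=burn_in,
        thin_interval=thin_interval,
        seed=seed,
        initial_lengths=initial_lengths,
    )[:, filament_index]
    lo, hi = int(samples.min()), int(samples.max())
    counts = np.bincount(samples - lo, minlength=hi - lo + 1)
    return LengthDistribution(
        lengths=np.arange(lo, hi + 1),
        probs=counts / counts.sum(),
        truncation_mass=0.0,
        n_samples=int(n_samples),
    )


@dataclass
class SeveringResult:
    """Replicate-averaged response to severing filament 1 at ``t = 0``.

    ``times`` is the post-cut sampling grid; ``mean_lengths[k, i]`` the mean
    length of filament ``i`` at ``times[k]`` over replicates.  ``pre_cut_mean``
    holds the replicate-mean lengths immediately before the cut.
    """

    times: np.ndarray
    mean_lengths: np.ndarray
    pre_cut_mean: np.ndarray
    n_replicates: int
    severed_monomers_discarded: bool


def severing_experiment(
    model: KineticModel,
    t_equilibrate: float,
    t_post: float,
    n_replicates: int = 100,
    seed: int = 0,
    n_grid: int = 200,
    discard_severed: bool = True,
) -> SeveringResult:
    """Equilibrate two pool-coupled filaments, cut one, follow the recovery.

    At ``t_equilibrate`` filament 1 is set to length 0.  By default the
    severed monomers leave the system (the flagellum is discarded, so the
    effective pool shrinks by the pre-cut length of filament 1); with
    ``discard_severed=False`` they return to the free pool.  Replicates start
    from the deterministic balance point to shorten equilibration.
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("severing requires a finite (shared) monomer pool")
    if model.m_filaments != 2:
        raise ValueError("severing experiment is defined for M = 2 filaments")
    if not (t_equilibrate >= 0 and t_post > 0):
        raise ValueError("t_equilibrate must be >= 0 and t_post > 0")

    from .finite_pool import steady_state_length_finite
    from .model import NoSteadyStateError

    try:
        balance = int(round(steady_state_length_finite(model)))
    except NoSteadyStateError:
        balance = 0
    L_start = np.array([balance, balance], dtype=np.int64)

    grid = np.linspace(0.0, t_post, n_grid)
    acc = np.zeros((n_grid, 2), dtype=np.float64)
    pre_acc = np.zeros(2, dtype=np.float64)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)

    args_pre = _ssa.pack_model(model)
    for r in range(n_replicates):
        _ssa.seed_stream(int(child_seeds[r]))
        L = L_start.copy()
        if t_equilibrate > 0:
            pre = np.empty((1, 2), dtype=np.int64)
            _ssa.run_sample_grid(*args_pre, L, 0.0, np.array([t_equilibrate]), pre)
            L = pre[0].copy()
        pre_acc += L
        cut = int(L[0])
        L[0] = 0
        post_model = model if not discard_severed else model.with_(
            n_total=model.n_total - cut
        )
        out = np.empty((n_grid, 2), dtype=np.int64)
        _ssa.run_sample_grid(*_ssa.pack_model(post_model), L, 0.0, grid, out)
        acc += out

    return SeveringResult(
        times=grid,
        mean_lengths=acc / n_replicates,
        pre_cut_mean=pre_acc / n_replicates,
        n_replicates=n_replicates,
        severed_monomers_discarded=discard_severed,
    )


def mean_field_trajectory(
    model: KineticModel,
    initial_lengths,
    t_max: float,
    n_points: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic rate-balance dynamics ``dL_i/dt = r({L}) - gamma(L_i)``.

    Continuous-length ODE whose fixed points coincide with the steady-state
    solvers.  Lengths are clamped at 0 (no disassembly of an empty filament).
    Returns ``(times, lengths)`` with ``lengths`` of shape ``(n_points, M)``.
    """
    L0 = np.asarray(initial_lengths, dtype=float)
    if L0.shape != (model.m_filaments,):
        raise ValueError(f"initial_lengths must have length M={model.m_filaments}")
    if np.any(L0 < 0):
        raise ValueError("initial lengths must be >= 0")
    finite = model.pool_mode is PoolMode.FINITE
    n, kp, km = model.n_total, model.k_plus, model.k_minus
    grad = model.gradient

    def rhs(_t, L):
        Lc = np.clip(L, 0.0, None)
        r = kp * ((n - Lc.sum()) if finite else n)
        gam = km * grad.concentration_at(Lc)
        dL = r - gam
        return np.where((Lc <= 0.0) & (dL < 0.0), 0.0, dL)

    t_eval = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(rhs, (0.0, t_max), L0, t_eval=t_eval, method="LSODA", rtol=1e-8, atol=1e-8)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"mean-field integration failed: {sol.message} "
            f"(kind={model.kind.value}, QN={model.q_n:g}, lam={model.lam:g})"
        )
    return sol.t, sol.y.T
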