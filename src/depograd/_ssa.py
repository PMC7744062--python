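"""Inner loops of the exact stochastic simulation algorithm.

The kernels are written once in plain Python/NumPy and jitted with numba when
it is importable; otherwise the interpreted versions run as-is (identical
algorithm, much slower).  Random-number protocol: a single Mersenne-Twister
stream per simulation, seeded once; each event consumes exactly two uniforms
— one for the exponential waiting time, one for the reaction channel.

State encoding shared by all kernels:
  kind_lin : 1 for the linear gradient, 0 for exponential
  finite   : 1 for finite-pool assembly, 0 for the large-pool constant rate
  L        : int64[M], current filament lengths (modified in place)
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def seed_stream(seed: int) -> None:
    """Seed the (numba or numpy-global) Mersenne-Twister stream."""
    s = int(seed) % 2147483647
    if HAVE_NUMBA:
        _seed(s)
    else:
        np.random.seed(s)


@njit(cache=True, inline="always")
def _total_rates(kind_lin, c0, lam, kp, km, n_total, finite, L, dr):
    """Fill per-filament death rates into ``dr``; return (g, R)."""
    M = L.shape[0]
    s = 0
    for i in range(M):
        s += L[i]
    if finite == 1:
        g = kp * (n_total - s)
        if g < 0.0:
            g = 0.0
    else:
        g = kp * n_total
    D = 0.0
    for i in range(M):
        if L[i] > 0:
            if kind_lin == 1:
                d = km * c0 * (1.0 + L[i] / lam)
            else:
                d = km * c0 * math.exp(L[i] / lam)
        else:
            d = 0.0
        dr[i] = d
        D += d
    return g, M * g + D


@njit(cache=True, inline="always")
def _apply_channel(g, L, dr, R):
    """Pick a channel with one uniform and apply the +/-1 transition."""
    M = L.shape[0]
    u = np.random.random() * R
    if u < M * g:
        j = int(u / g)
        if j >= M:
            j = M - 1
        L[j] += 1
    else:
        rem = u - M * g
        j = 0
        acc = dr[0]
        while rem > acc and j < M - 1:
            j += 1
            acc += dr[j]
        L[j] -= 1


@njit(cache=True)
def run_events(kind_lin, c0, lam, kp, km, n_total, finite, L, t0, t_max, times, lengths):
    """Record every event up to ``t_max`` or until the buffers fill.

    Returns ``(n_recorded, t, full)``; ``full`` signals the caller to resume
    with a fresh buffer from the returned state.  An event whose firing time
    would exceed ``t_max`` is not applied.
    """
    M = L.shape[0]
    cap = times.shape[0]
    dr = np.empty(M, dtype=np.float64)
    n = 0
    t = t0
    while True:
        g, R = _total_rates(kind_lin, c0, lam, kp, km, n_total, finite, L, dr)
        if R <= 0.0:
            return n, t, False
        dt = -math.log(np.random.random()) / R
        if t + dt > t_max:
            return n, t_max, False
        t += dt
        _apply_channel(g, L, dr, R)
        times[n] = t
        for i in range(M):
            lengths[n, i] = L[i]
        n += 1
        if n == cap:
            return n, t, True


@njit(cache=True)
def run_sample_grid(kind_lin, c0, lam, kp, km, n_total, finite, L, t0, grid, out):
    """Record the state holding at each time in ``grid`` (time-grid sampling).

    ``grid`` must be increasing and start at or after ``t0``.  Returns the
    final event time reached.
    """
    M = L.shape[0]
    n_grid = grid.shape[0]
    dr = np.empty(M, dtype=np.float64)
    idx = 0
    t = t0
    while idx < n_grid:
        g, R = _total_rates(kind_lin, c0, lam, kp, km, n_total, finite, L, dr)
        if R <= 0.0:  # frozen state persists forever
            while idx < n_grid:
                for i in range(M):
                    out[idx, i] = L[i]
                idx += 1
            return t
        dt = -math.log(np.random.random()) / R
        t_next = t + dt
        while idx < n_grid and grid[idx] < t_next:
            for i in range(M):
                out[idx, i] = L[i]
            idx += 1
        if idx == n_grid:
            return t
        _apply_channel(g, L, dr, R)
        t = t_next
    return t


def pack_model(model):
    """Flatten a KineticModel into the scalar kernel arguments."""
    from .model import GradientKind, PoolMode

    return (
        1 if model.kind is GradientKind.LINEAR else 0,
        float(model.gradient.c0),
        float(model.lam),
        float(model.k_plus),
        float(model.k_minus),
        int(model.n_total),
        1 if model.pool_mode is PoolMode.FINITE else 0,
    )
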