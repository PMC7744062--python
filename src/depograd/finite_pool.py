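"""Exact stationary solution for filaments coupled by a finite monomer pool.

When ``M`` filaments draw on a pool of ``N`` monomers, assembly of each
filament proceeds at ``k_plus (N - sum_i L_i)`` and disassembly of filament
``i`` at ``gamma(L_i)``.  Every transition is reversible, so the chain obeys
detailed balance and the stationary joint law has the product form

    P(L_1..L_M)  propto  k_plus^(sum L_i) / ( prod_i f(L_i) * (N - sum L_i)! )

with ``f(L) = prod_{l=1..L} gamma(l)`` and ``f(0) = 1``.  The neighbor-state
ratio reproduces the one-step balance condition

    gamma(L_i + 1) P(.., L_i + 1, ..) = k_plus (N - sum L) P(.., L_i, ..)

exactly, which pins down the placement of the factorial and ``f`` factors and
is verified against a brute-force generator null-space solve in the tests.
Everything is computed in log space; the ``M = 2`` joint distribution is
enumerated on a window around the deterministic balance point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .large_pool import (
    LengthDistribution,
    _scale_sd,
    steady_state_length_large_pool,
)
from .model import (
    GradientKind,
    KineticModel,
    MomentSummary,
    NoSteadyStateError,
    PoolMode,
)

__all__ = [
    "JointLengthDistribution",
    "log_stationary_weight",
    "joint_stationary_distribution",
    "marginal_distribution",
    "steady_state_length_finite",
    "finite_vs_infinite_difference",
    "pool_fraction_in_filaments",
]


def _log_f(model: KineticModel, L) -> np.ndarray:
    """``ln f(L) = sum_{l=1..L} ln gamma(l)`` in closed form, ``f(0)=1``.

    linear       ``L ln(k_minus c0 / lam) + lnGamma(L+lam+1) - lnGamma(lam+1)``
    exponential  ``L ln(k_minus c0) + L(L+1)/(2 lam)``
    """
    La = np.asarray(L, dtype=float)
    base = model.k_minus * model.gradient.c0
    lam = model.lam
    if model.kind is GradientKind.LINEAR:
        return (
            La * np.log(base / lam)
            + gammaln(La + lam + 1.0)
            - gammaln(lam + 1.0)
        )
    return La * np.log(base) + La * (La + 1.0) / (2.0 * lam)


def log_stationary_weight(model: KineticModel, lengths) -> float | np.ndarray:
    """Log unnormalized stationary probability of a joint length state.

    Accepts a length-``M`` sequence or an array whose last axis has size
    ``M``.  States with ``sum L_i > N`` are rejected.
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("log_stationary_weight requires finite pool mode")
    arr = np.asarray(lengths, dtype=float)
    if arr.shape[-1] != model.m_filaments:
        raise ValueError(
            f"expected {model.m_filaments} lengths per state, got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValueError("filament lengths must be >= 0")
    s = arr.sum(axis=-1)
    if np.any(s > model.n_total):
        raise ValueError("sum of lengths exceeds the total pool N")
    out = (
        s * np.log(model.k_plus)
        - _log_f(model, arr).sum(axis=-1)
        - gammaln(model.n_total - s + 1.0)
    )
    return out if isinstance(lengths, np.ndarray) and arr.ndim > 1 else float(out)


@dataclass
class JointLengthDistribution:
    """Normalized joint law of two filament lengths on a rectangular window.

    ``l1``/``l2`` are the contiguous integer supports of the two axes;
    ``probs[i, j] = P(L1 = l1[i], L2 = l2[j])``.  States outside the simplex
    ``L1 + L2 <= N`` carry zero probability.
    """

    l1: np.ndarray
    l2: np.ndarray
    probs: np.ndarray
    truncation_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.probs.shape != (self.l1.size, self.l2.size):
            raise ValueError("probs shape must match the support grids")

    def marginal(self, filament_index: int) -> LengthDistribution:
        return marginal_distribution(self, filament_index)

    def moments(self, filament_index: int = 0) -> MomentSummary:
        return self.marginal(filament_index).moments()


def steady_state_length_finite(model: KineticModel) -> float:
    """Symmetric balance point ``k_plus (N - M L) = gamma(L)``.

    Linear gradient (closed form, the two-filament formula generalized from
    ``N/2`` to ``N/M``):

        L_ss = lam (QN - 1) N / (N + M QN lam)

    Exponential gradient: numeric root of ``QN (1 - M L / N) = e^(L/lam)``
    on ``[0, N/M]``, solved by bisection to 1e-6 monomer.
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("steady_state_length_finite requires finite pool mode")
    qn, lam = model.q_n, model.lam
    n, m = model.n_total, model.m_filaments
    if qn < 1.0:
        raise NoSteadyStateError(
            f"no positive steady state: QN={qn:g} < 1 for the {model.kind.value} gradient"
        )
    if model.kind is GradientKind.LINEAR:
        return lam * (qn - 1.0) * n / (n + m * qn * lam)
    if qn == 1.0:
        return 0.0

    def g(L: float) -> float:
        return np.log(qn) + np.log1p(-m * L / n) - L / lam

    hi = n / m * (1.0 - 1e-12)
    if g(hi) > 0:  # pool exhausted before the gradient catches up
        return n / m
    return float(brentq(g, 0.0, hi, xtol=1e-6))


def finite_vs_infinite_difference(model: KineticModel) -> float:
    """Relative steady-state length difference ``(L_large - L_finite)/L_finite``."""
    l_fin = steady_state_length_finite(model)
    l_inf = steady_state_length_large_pool(model.with_(pool_mode=PoolMode.LARGE))
    if l_fin == 0:
        raise NoSteadyStateError("finite-pool steady state is 0; difference undefined")
    return (l_inf - l_fin) / l_fin


def _lw_line(model: KineticModel, l1: int, L2: np.ndarray) -> np.ndarray:
    """Log weights along one row ``L1 = l1`` (states past the simplex: -inf)."""
    n = model.n_total
    g = -_log_f(model, float(l1)) + l1 * np.log(model.k_plus)
    g2 = -_log_f(model, L2.astype(float)) + L2 * np.log(model.k_plus)
    free = n - l1 - L2
    out = np.full(L2.shape, -np.inf)
    ok = free >= 0
    out[ok] = g + g2[ok] - gammaln(free[ok] + 1.0)
    return out


def joint_stationary_distribution(
    model: KineticModel, tail_tol: float = 1e-12
) -> JointLengthDistribution:
    """Exact stationary joint law for ``M = 2`` filaments (log-space window).

    The window is centered on the deterministic balance point and expanded —
    probing only its four boundary lines — until the boundary weights fall
    below ``tail_tol`` times the peak weight; windows are clipped to
    ``L >= 0`` and the simplex ``L1 + L2 <= N``.  The final matrix is then
    filled row-block by row-block with a streaming log-sum-exp, so peak
    memory is a single float64 matrix of the window.
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("joint_stationary_distribution requires finite pool mode")
    if model.m_filaments != 2:
        raise NotImplementedError(
            "exact joint enumeration is limited to M = 2; "
            "use the stochastic simulator for M > 2"
        )
    if not (0.0 < tail_tol < 1.0):
        raise ValueError("tail_tol must lie in (0, 1)")
    n = model.n_total
    try:
        center = int(round(steady_state_length_finite(model)))
    except NoSteadyStateError:
        center = 0
    sd = max(_scale_sd(model), 2.0)
    log_tol = np.log(tail_tol)

    # symmetric model: probing the L1-edge rows covers the L2 edges too
    half = int(np.ceil(6.0 * sd))
    for _ in range(64):
        lo = max(0, center - half)
        hi = min(n, center + half)
        L = np.arange(lo, hi + 1)
        peak = _lw_line(model, center, np.asarray([min(center, n - center)])).item()
        edge = []
        if lo > 0:
            edge.append(_lw_line(model, lo, L).max())
        if hi < n:
            edge.append(_lw_line(model, hi, L).max())
        if not edge or max(edge) - peak < log_tol:
            break
        half += int(np.ceil(2.0 * sd))
    else:  # pragma: no cover
        raise RuntimeError("joint window expansion failed to converge")

    width = L.size
    lw = np.empty((width, width))
    for i in range(width):
        lw[i, :] = _lw_line(model, int(L[i]), L)
    m = lw.max()
    z = 0.0
    block = max(1, (1 << 22) // width)
    for i0 in range(0, width, block):
        z += float(np.exp(lw[i0 : i0 + block] - m).sum())
    logZ = m + np.log(z)
    for i0 in range(0, width, block):
        sl = lw[i0 : i0 + block]
        np.exp(sl - logZ, out=sl)
    probs = lw  # renamed: exponentiated in place
    probs /= probs.sum()  # exact renormalization over the window
    trunc = 0.0
    if lo > 0:
        trunc += probs[0, :].sum() + probs[:, 0].sum()
    if hi < n:
        trunc += probs[-1, :].sum() + probs[:, -1].sum()
    return JointLengthDistribution(l1=L, l2=L.copy(), probs=probs, truncation_mass=trunc)


def marginal_distribution(
    joint: JointLengthDistribution, filament_index: int
) -> LengthDistribution:
    """Marginal law of one filament, summing the joint over the other."""
    if filament_index not in (0, 1):
        raise IndexError("filament_index must be 0 or 1")
    if filament_index == 0:
        probs = joint.probs.sum(axis=1)
        lengths = joint.l1
    else:
        probs = joint.probs.sum(axis=0)
        lengths = joint.l2
    return LengthDistribution(
        lengths=lengths, probs=probs, truncation_mass=joint.truncation_mass
    )


def pool_fraction_in_filaments(model: KineticModel, method: str = "balance") -> float:
    """Fraction ``M <L> / N`` of all monomers bound in filaments.

    ``method="balance"`` uses the deterministic balance point (fast);
    ``method="marginal"`` uses the exact marginal mean (M = 2 only).
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("pool_fraction_in_filaments requires finite pool mode")
    if method == "balance":
        try:
            mean = steady_state_length_finite(model)
        except NoSteadyStateError:
            return 0.0
    elif method == "marginal":
        mean = joint_stationary_distribution(model).moments(0).mean
    else:
        raise ValueError("method must be 'balance' or 'marginal'")
    return model.m_filaments * mean / model.n_total
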