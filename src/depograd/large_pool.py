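"""Single-filament steady states and stationary distributions, large pool.

With an effectively infinite monomer pool the assembly rate is the constant
``r = k_plus N`` and each filament is an independent one-dimensional
birth-death chain with birth rate ``r`` and death rate ``gamma(L)``.  Its
stationary distribution is the product form

    P(L)  propto  prod_{l=1..L} r / gamma(l),

which for the linear gradient collapses to the closed form

    P_l(L)  propto  (QN lam_l)^L / Gamma(L + lam_l + 1),

and for the exponential gradient to a discretized Gaussian with mean
``lam_e ln(QN) - 1/2`` and variance ``lam_e``.  All weights are handled in
log space (log-gamma, log-sum-exp); at the biologically relevant scales
``L ~ 1e5`` the factorials overflow any fixed-precision representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    GradientKind,
    KineticModel,
    MomentSummary,
    NoSteadyStateError,
    PoolMode,
)

__all__ = [
    "LengthDistribution",
    "steady_state_length_large_pool",
    "stationary_distribution_large_pool",
    "log_product_form_weight",
    "closed_form_density",
    "log_closed_form_density",
    "approximate_moments",
    "moments",
]


@dataclass
class LengthDistribution:
    """Discrete probability law over a contiguous range of filament lengths.

    ``truncation_mass`` estimates the stationary probability outside the
    stored support (geometric extrapolation of the edge weights).
    ``n_samples`` is set when the distribution is an empirical histogram.
    """

    lengths: np.ndarray
    probs: np.ndarray
    truncation_mass: float = 0.0
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.lengths.shape != self.probs.shape:
            raise ValueError("lengths and probs must have the same shape")
        if self.lengths.size == 0:
            raise ValueError("empty support")
        if np.any(self.probs < -1e-15):
            raise ValueError("negative probabilities")

    @property
    def support(self) -> tuple[int, int]:
        return int(self.lengths[0]), int(self.lengths[-1])

    def moments(self) -> MomentSummary:
        return moments(self)


def moments(dist: LengthDistribution) -> MomentSummary:
    """Mean, variance and coefficient of variation by direct summation."""
    p = dist.probs / dist.probs.sum()
    x = dist.lengths.astype(float)
    mean = float(np.dot(x, p))
    var = float(np.dot((x - mean) ** 2, p))
    return MomentSummary(mean=mean, variance=var)


def steady_state_length_large_pool(model: KineticModel) -> float:
    """Deterministic balance point ``r = gamma(L)`` for a single filament.

    Linear gradient: ``L_ss = lam_l (QN - 1)``;
    exponential gradient: ``L_ss = lam_e ln(QN)``.
    Raises :class:`NoSteadyStateError` when ``QN < 1`` (depolymerization
    dominates everywhere and no positive balance point exists).
    """
    qn = model.q_n
    lam = model.lam
    if qn < 1.0:
        raise NoSteadyStateError(
            f"no positive steady state: QN={qn:g} < 1 for the {model.kind.value} gradient"
        )
    if model.kind is GradientKind.LINEAR:
        return lam * (qn - 1.0)
    return lam * float(np.log(qn))


def log_product_form_weight(model: KineticModel, L) -> np.ndarray:
    """Exact log stationary weight ``sum_{l<=L} ln(r/gamma(l))`` (+ const).

    Closed forms of the telescoped product:
      linear       ``L ln(QN lam) - lnGamma(L+lam+1) + lnGamma(lam+1)``
      exponential  ``L ln(QN) - L(L+1)/(2 lam)``
    """
    La = np.asarray(L, dtype=float)
    qn, lam = model.q_n, model.lam
    if model.kind is GradientKind.LINEAR:
        return La * np.log(qn * lam) - gammaln(La + lam + 1.0) + gammaln(lam + 1.0)
    return La * np.log(qn) - La * (La + 1.0) / (2.0 * lam)


def _peak_length(model: KineticModel) -> int:
    """Integer mode of the stationary law (balance point, clipped at 0)."""
    qn = model.q_n
    if qn <= 1.0:
        return 0
    lam = model.lam
    if model.kind is GradientKind.LINEAR:
        return max(0, int(round(lam * (qn - 1.0))))
    return max(0, int(round(lam * np.log(qn))))


def _scale_sd(model: KineticModel) -> float:
    """Large-pool standard-deviation scale used to size support windows."""
    qn, lam = model.q_n, model.lam
    if model.kind is GradientKind.LINEAR:
        return float(np.sqrt(max(qn, 1.0) * lam))
    return float(np.sqrt(lam))


def stationary_distribution_large_pool(
    model: KineticModel, tail_tol: float = 1e-12
) -> LengthDistribution:
    """Exact stationary distribution of the single-filament chain.

    The support window starts around the deterministic balance point and is
    expanded symmetrically until the edge weights fall below ``tail_tol``
    times the peak weight; the omitted tail mass is estimated geometrically
    from the edge weight ratios.
    """
    if model.pool_mode is not PoolMode.LARGE:
        raise ValueError("model must be in large-pool mode")
    if not (0.0 < tail_tol < 1.0):
        raise ValueError("tail_tol must lie in (0, 1)")
    center = _peak_length(model)
    sd = max(_scale_sd(model), 2.0)
    log_tol = np.log(tail_tol)

    half = int(np.ceil(6.0 * sd))
    for _ in range(64):
        lo = max(0, center - half)
        hi = center + half
        L = np.arange(lo, hi + 1)
        lw = log_product_form_weight(model, L)
        peak = lw.max()
        left_ok = lo == 0 or (lw[0] - peak) < log_tol
        right_ok = (lw[-1] - peak) < log_tol
        if left_ok and right_ok:
            break
        half = int(half * 1.6) + 1
    else:  # pragma: no cover - gamma growth guarantees termination
        raise RuntimeError("support expansion failed to converge")

    logZ = logsumexp(lw)
    probs = np.exp(lw - logZ)
    probs /= probs.sum()  # exact renormalization over the truncated support
    trunc = 0.0
    # one-step weight ratios at the edges bound the omitted geometric tails
    if lo > 0:
        ratio = float(np.exp(lw[0] - lw[1]))
        if ratio < 1.0:
            trunc += probs[0] * ratio / (1.0 - ratio)
    ratio = float(np.exp(lw[-1] - lw[-2]))
    if ratio < 1.0:
        trunc += probs[-1] * ratio / (1.0 - ratio)
    return LengthDistribution(lengths=L, probs=probs, truncation_mass=trunc)


def log_closed_form_density(model: KineticModel, L) -> np.ndarray:
    """Log of the closed-form (unnormalized) stationary weight.

    Linear gradient: ``(QN lam)^L / Gamma(L + lam + 1)`` — identical (up to
    normalization) to the exact product form.  Exponential gradient: the
    Gaussian approximation ``exp(-(L - lam ln QN + 1/2)^2 / (2 lam)) /
    sqrt(2 pi lam)``; whether the mode or the mean sits at ``lam ln QN`` is a
    half-monomer convention, kept here with the ``-1/2`` offset.
    """
    La = np.asarray(L, dtype=float)
    qn, lam = model.q_n, model.lam
    if model.kind is GradientKind.LINEAR:
        return La * np.log(qn * lam) - gammaln(La + lam + 1.0)
    mu = lam * np.log(qn) - 0.5
    return -((La - mu) ** 2) / (2.0 * lam) - 0.5 * np.log(2.0 * np.pi * lam)


def closed_form_density(model: KineticModel, L):
    """Closed-form unnormalized stationary weight (linear scale)."""
    out = np.exp(log_closed_form_density(model, L))
    return out if isinstance(L, np.ndarray) else float(out)


def approximate_moments(model: KineticModel) -> MomentSummary:
    """Closed-form moment approximations of the stationary law.

    Linear: mean ``(QN-1) lam``, variance ``QN lam``; exponential: mean
    ``lam ln QN - 1/2``, variance ``lam``.  Practically indistinguishable
    from the exact moments for ``QN, lam >~ 2``.
    """
    qn, lam = model.q_n, model.lam
    if model.kind is GradientKind.LINEAR:
        if qn <= 1.0:
            raise NoSteadyStateError("approximate moments require QN > 1 (linear)")
        return MomentSummary(mean=(qn - 1.0) * lam, variance=qn * lam)
    if qn < 1.0:
        raise NoSteadyStateError("approximate moments require QN >= 1 (exponential)")
    return MomentSummary(mean=lam * float(np.log(qn)) - 0.5, variance=lam)
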