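"""Model parameterization and elementary rate functions.

The model describes ``M`` filaments assembled from a shared pool of ``N``
monomers.  Each filament grows by one monomer at a rate proportional to the
number of free monomers and shrinks by one monomer at a rate set by the local
concentration of a depolymerizing protein at its tip.  Directed transport plus
diffusion of the depolymerizer along the filament produces a concentration
profile that increases with distance from the base — either linearly,

    C(x) = C0 (1 + x / lam_l),

when the depolymerizer is loaded only at the base, or exponentially,

    C(x) = C0 exp(x / lam_e),

when it can bind transport motors anywhere along the filament.  ``C0`` is the
cytoplasmic concentration and ``lam`` the gradient length scale, measured in
monomer units (one tubulin dimer of flagellum length; 20,000 per micron).

Disassembly occurs at the tip, so a filament of length ``L`` depolymerizes at

    gamma(L) = k_minus * C(L),

while every filament polymerizes at

    r({L_i}) = k_plus * (N - sum_i L_i)

when the pool is finite, or at the constant ``k_plus * N`` in the large-pool
limit.  All stationary quantities depend on the rate constants only through
the dimensionless ratio

    QN = k_plus * N / (k_minus * C0),

the maximal polymerization rate over the baseline depolymerization rate, and
through ``lam``, ``N`` and ``M``.  The dimensionless constructor therefore
fixes the time unit by ``k_minus * C0 = 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GradientKind",
    "PoolMode",
    "Gradient",
    "KineticModel",
    "MomentSummary",
    "NoSteadyStateError",
    "concentration_at",
    "depolymerization_rate",
    "polymerization_rate",
    "q_n",
]


class NoSteadyStateError(ValueError):
    """Raised when the rate-balance equation has no positive solution."""


class GradientKind(str, enum.Enum):
    LINEAR = "linear"
    EXPONENTIAL = "exponential"


class PoolMode(str, enum.Enum):
    LARGE = "large"
    FINITE = "finite"


@dataclass(frozen=True)
class Gradient:
    """Concentration profile of the depolymerizer along the filament.

    Parameters
    ----------
    kind
        ``"linear"`` or ``"exponential"``.
    lam
        Gradient length scale in monomer units (> 0, real-valued).
    c0
        Cytoplasmic (base) concentration in arbitrary units (> 0).  Only the
        product ``k_minus * c0`` ever enters results.
    """

    kind: GradientKind
    lam: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GradientKind(self.kind))
        if not self.c0 > 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")

    def concentration_at(self, x):
        """Concentration at position ``x`` (monomer units) from the base."""
        xa = np.asarray(x, dtype=float)
        if np.any(xa < 0):
            raise ValueError("position x must be >= 0")
        if self.kind is GradientKind.LINEAR:
            out = self.c0 * (1.0 + xa / self.lam)
        else:
            out = self.c0 * np.exp(xa / self.lam)
        return out if isinstance(x, np.ndarray) else float(out)


@dataclass(frozen=True)
class KineticModel:
    """Full kinetic parameterization of the filament/pool system.

    Attributes
    ----------
    gradient
        Depolymerizer concentration profile.
    k_plus
        Assembly rate per free monomer (1/time/monomer).
    k_minus
        Depolymerization rate per unit depolymerizer concentration.
    n_total
        Total monomer count ``N`` (shared pool plus filaments).
    m_filaments
        Number of filaments ``M``.
    pool_mode
        ``"large"``: assembly rate is the constant ``k_plus * N``.
        ``"finite"``: assembly rate is ``k_plus * (N - sum(L_i))``.
    """

    gradient: Gradient
    k_plus: float
    k_minus: float
    n_total: int
    m_filaments: int = 1
    pool_mode: PoolMode = PoolMode.LARGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool_mode", PoolMode(self.pool_mode))
        object.__setattr__(self, "n_total", int(self.n_total))
        object.__setattr__(self, "m_filaments", int(self.m_filaments))
        if not self.k_plus > 0:
            raise ValueError("k_plus must be > 0")
        if self.k_minus < 0:
            raise ValueError("k_minus must be >= 0")
        if self.n_total < 1:
            raise ValueError("n_total must be a positive integer")
        if self.m_filaments < 1:
            raise ValueError("m_filaments must be >= 1")

    # -- dimensionless parameterization -------------------------------------

    @classmethod
    def from_dimensionless(
        cls,
        q_n: float,
        lam: float,
        kind: GradientKind | str,
        n_total: int,
        m_filaments: int = 1,
        pool_mode: PoolMode | str = PoolMode.LARGE,
    ) -> "KineticModel":
        """Build a model from ``(QN, lam, N, M)`` with ``k_minus * C0 = 1``.

        One time unit is then the mean waiting time of the baseline
        depolymerization event.  Stationary quantities depend only on
        ``(QN, lam, N, M, kind)``; any other choice of ``k_minus * C0``
        rescales time only.
        """
        if not q_n > 0:
            raise ValueError("q_n must be > 0")
        if int(n_total) < 1:
            raise ValueError("n_total must be a positive integer")
        return cls(
            gradient=Gradient(kind=GradientKind(kind), lam=lam, c0=1.0),
            k_plus=q_n / int(n_total),
            k_minus=1.0,
            n_total=int(n_total),
            m_filaments=m_filaments,
            pool_mode=PoolMode(pool_mode),
        )

    @property
    def q_n(self) -> float:
        """Dimensionless ratio ``QN = k_plus N / (k_minus C0)``."""
        denom = self.k_minus * self.gradient.c0
        if denom == 0:
            raise ZeroDivisionError("q_n undefined for k_minus = 0")
        return self.k_plus * self.n_total / denom

    @property
    def kind(self) -> GradientKind:
        return self.gradient.kind

    @property
    def lam(self) -> float:
        return self.gradient.lam

    def with_(self, **changes) -> "KineticModel":
        """Return a copy with the given top-level fields replaced."""
        return replace(self, **changes)

    # -- elementary rates ---------------------------------------------------

    def depolymerization_rate(self, L):
        """Disassembly rate ``gamma(L) = k_minus C(L)``; 0 at ``L = 0``.

        An empty filament cannot shrink, so the chain is reflecting at 0.
        """
        La = np.asarray(L, dtype=float)
        if np.any(La < 0):
            raise ValueError("filament length must be >= 0")
        out = np.where(La > 0, self.k_minus * self.gradient.concentration_at(np.maximum(La, 0.0)), 0.0)
        return out if isinstance(L, np.ndarray) else float(out)

    def polymerization_rate(self, lengths: Sequence[int]) -> float:
        """Assembly rate per filament given the current lengths."""
        la = np.asarray(lengths, dtype=float)
        if np.any(la < 0):
            raise ValueError("filament lengths must be >= 0")
        if self.pool_mode is PoolMode.LARGE:
            return self.k_plus * self.n_total
        total = float(la.sum())
        if total > self.n_total:
            raise ValueError(
                f"sum of lengths {total} exceeds the total pool N={self.n_total}"
            )
        return self.k_plus * (self.n_total - total)


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and noise (coefficient of variation) of a length law."""

    mean: float
    variance: float
    noise: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variance < -1e-9:
            raise ValueError("variance must be >= 0")
        object.__setattr__(self, "variance", max(float(self.variance), 0.0))
        cv = float(np.sqrt(self.variance) / self.mean) if self.mean > 0 else float("nan")
        object.__setattr__(self, "noise", cv)

    def as_dict(self) -> dict:
        return {"mean": self.mean, "variance": self.variance, "noise": self.noise}


# -- thin functional aliases mirroring the operation names ------------------

def concentration_at(gradient: Gradient, x):
    return gradient.concentration_at(x)


def depolymerization_rate(model: KineticModel, L):
    return model.depolymerization_rate(L)


def polymerization_rate(model: KineticModel, lengths) -> float:
    return model.polymerization_rate(lengths)


def q_n(model: KineticModel) -> float:
    return model.q_n
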