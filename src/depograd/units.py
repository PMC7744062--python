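"""Unit conventions and inversion of the steady-state relations.

Lengths are bookkept in monomer units: one tubulin dimer's contribution to
flagellar length.  A micron of a single microtubule holds about 2000 dimers
and a flagellum bundles about 10 microtubules, so the default convention is
20,000 monomers per micron of flagellum.  From a measured steady-state length
the relations

    linear:        L_ss = lam_l (QN - 1) N / (N + M QN lam_l)
    exponential:   QN (1 - M L_ss / N) = exp(L_ss / lam_e)

(and their large-pool limits) are inverted for ``QN`` or ``lam``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import GradientKind, PoolMode

__all__ = [
    "UnitConvention",
    "DEFAULT_CONVENTION",
    "microns_to_monomers",
    "monomers_to_microns",
    "estimate_total_pool",
    "solve_qn_for_length",
    "solve_lambda_for_length",
    "InfeasibleTargetError",
]

QN_PLAUSIBLE = (1.0, 1000.0)


class InfeasibleTargetError(ValueError):
    """Raised when no parameter value can produce the requested length."""


@dataclass(frozen=True)
class UnitConvention:
    """Monomer/micron conversion constants."""

    dimers_per_micron_per_microtubule: int = 2000
    microtubules_per_flagellum: int = 10

    @property
    def monomers_per_micron(self) -> int:
        return self.dimers_per_micron_per_microtubule * self.microtubules_per_flagellum


DEFAULT_CONVENTION = UnitConvention()


def microns_to_monomers(length_um: float, convention: UnitConvention = DEFAULT_CONVENTION) -> float:
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return length_um * convention.monomers_per_micron


def monomers_to_microns(length_monomers: float, convention: UnitConvention = DEFAULT_CONVENTION) -> float:
    if length_monomers < 0:
        raise ValueError("length must be >= 0")
    return length_monomers / convention.monomers_per_micron


def estimate_total_pool(
    n_filaments: int,
    filament_length_um: float,
    flagellar_fraction: float,
    convention: UnitConvention = DEFAULT_CONVENTION,
) -> float:
    """Total monomer count N from the filament content and its pool share.

    With ``n_filaments`` filaments of the given length holding a fraction
    ``flagellar_fraction`` of the cell's monomers:
    ``N = n_filaments * monomers(filament) / fraction``.
    """
    if not (0.0 < flagellar_fraction <= 1.0):
        raise ValueError("flagellar_fraction must lie in (0, 1]")
    return n_filaments * microns_to_monomers(filament_length_um, convention) / flagellar_fraction


def _depletion_factor(target: float, n_total: float, m_filaments: int, pool_mode) -> float:
    """``1 - M L / N`` in finite mode (feasibility-checked), 1 otherwise."""
    if PoolMode(pool_mode) is PoolMode.LARGE:
        return 1.0
    depl = 1.0 - m_filaments * target / n_total
    if depl <= 0.0:
        raise InfeasibleTargetError(
            f"target length {target:g} requires more than the pool N={n_total:g} "
            f"across M={m_filaments} filaments"
        )
    return depl


def _warn_qn(qn: float) -> None:
    lo, hi = QN_PLAUSIBLE
    if not (lo < qn < hi):
        warnings.warn(
            f"estimated QN={qn:g} lies outside the plausible range ({lo:g}, {hi:g})",
            UserWarning,
            stacklevel=3,
        )


def solve_qn_for_length(
    target_length_monomers: float,
    lam: float,
    n_total: float,
    m_filaments: int = 2,
    kind: GradientKind | str = GradientKind.LINEAR,
    pool_mode: PoolMode | str = PoolMode.FINITE,
) -> float:
    """Invert the steady-state relation for the dimensionless ratio QN.

    linear:       ``QN = (1 + L/lam) / (1 - M L / N)``
    exponential:  ``QN = exp(L/lam) / (1 - M L / N)``
    (large-pool mode drops the depletion factor).
    """
    if target_length_monomers < 0:
        raise ValueError("target length must be >= 0")
    depl = _depletion_factor(target_length_monomers, n_total, m_filaments, pool_mode)
    if GradientKind(kind) is GradientKind.LINEAR:
        qn = (1.0 + target_length_monomers / lam) / depl
    else:
        qn = float(np.exp(target_length_monomers / lam)) / depl
    _warn_qn(qn)
    return qn


def solve_lambda_for_length(
    target_length_monomers: float,
    q_n: float,
    n_total: float,
    m_filaments: int = 2,
    kind: GradientKind | str = GradientKind.LINEAR,
    pool_mode: PoolMode | str = PoolMode.FINITE,
) -> float:
    """Invert the steady-state relation for the gradient length scale.

    linear:       ``lam = L / (QN (1 - M L / N) - 1)``
    exponential:  ``lam = L / ln(QN (1 - M L / N))``
    """
    if target_length_monomers <= 0:
        raise InfeasibleTargetError("target length must be > 0 to determine lam")
    depl = _depletion_factor(target_length_monomers, n_total, m_filaments, pool_mode)
    eff = q_n * depl  # effective polymerization/depolymerization ratio at L_ss
    if GradientKind(kind) is GradientKind.LINEAR:
        if eff <= 1.0:
            raise InfeasibleTargetError(
                f"QN (1 - M L/N) = {eff:g} <= 1: depolymerization wins at the "
                "target length; no gradient scale can balance it"
            )
        return target_length_monomers / (eff - 1.0)
    if eff <= 1.0:
        raise InfeasibleTargetError(
            f"ln(QN (1 - M L/N)) undefined or non-positive (argument {eff:g})"
        )
    return target_length_monomers / float(np.log(eff))
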