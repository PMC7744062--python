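"""Brute-force stationary distributions for small pools.

Enumerates the full state space ``{(L_1..L_M): L_i >= 0, sum L_i <= N}`` of
the finite-pool master equation, builds the sparse generator from the same
elementary rates the rest of the package uses, and solves for its stationary
vector by replacing one balance equation with the normalization constraint.
This is the independent certificate for the detailed-balance product form and
for the stochastic simulator; it scales only to small ``N`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .model import KineticModel, PoolMode

__all__ = ["StateSpace", "build_generator", "stationary_from_generator", "joint_matrix"]

DEFAULT_CAP = 60


@dataclass
class StateSpace:
    """Enumerated admissible joint-length states with index maps."""

    n_total: int
    m_filaments: int
    states: np.ndarray  # (K, M) int64
    index: dict

    @classmethod
    def build(cls, n_total: int, m_filaments: int) -> "StateSpace":
        states = [
            s
            for s in product(range(n_total + 1), repeat=m_filaments)
            if sum(s) <= n_total
        ]
        arr = np.array(states, dtype=np.int64)
        return cls(
            n_total=n_total,
            m_filaments=m_filaments,
            states=arr,
            index={tuple(s): i for i, s in enumerate(states)},
        )

    def __len__(self) -> int:
        return self.states.shape[0]


def build_generator(
    model: KineticModel, cap: int = DEFAULT_CAP
) -> tuple[sp.csr_matrix, StateSpace]:
    """Sparse rate matrix Q (rows sum to zero) of the finite-pool chain.

    ``Q[i, j]`` is the rate from state ``i`` to state ``j``; off-diagonals
    come directly from ``polymerization_rate`` and ``depolymerization_rate``.
    """
    if model.pool_mode is not PoolMode.FINITE:
        raise ValueError("the exact oracle applies to finite-pool models")
    if model.n_total > cap:
        raise ValueError(
            f"N={model.n_total} exceeds the oracle cap {cap}; "
            "the brute-force solve is meant for small pools only"
        )
    space = StateSpace.build(model.n_total, model.m_filaments)
    rows, cols, vals = [], [], []
    for i, state in enumerate(space.states):
        s = int(state.sum())
        total = 0.0
        grow = model.polymerization_rate(state)
        for f in range(space.m_filaments):
            if s < model.n_total and grow > 0:
                nxt = list(state)
                nxt[f] += 1
                j = space.index[tuple(nxt)]
                rows.append(i)
                cols.append(j)
                vals.append(grow)
                total += grow
            if state[f] > 0:
                rate = model.depolymerization_rate(int(state[f]))
                nxt = list(state)
                nxt[f] -= 1
                j = space.index[tuple(nxt)]
                rows.append(i)
                cols.append(j)
                vals.append(rate)
                total += rate
        rows.append(i)
        cols.append(i)
        vals.append(-total)
    Q = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(space), len(space)), dtype=float
    )
    return Q, space


def stationary_from_generator(
    model: KineticModel, cap: int = DEFAULT_CAP
) -> tuple[np.ndarray, StateSpace]:
    """Stationary probability vector from the generator null space.

    Solves ``Q^T p = 0`` with one balance equation replaced by
    ``sum(p) = 1``; robust for these sparse reversible generators without
    resorting to eigensolvers.  Returns ``(p, state_space)``.
    """
    Q, space = build_generator(model, cap=cap)
    A = Q.T.tolil()
    A[-1, :] = 1.0
    b = np.zeros(len(space))
    b[-1] = 1.0
    p = spsolve(A.tocsr(), b)
    resid = np.abs(Q.T @ p)
    resid[-1] = 0.0
    if np.max(resid) > 1e-8 * max(1.0, np.abs(p).max()):
        raise RuntimeError("stationary solve did not converge (rank issue?)")
    if np.min(p) < -1e-12:
        raise RuntimeError("stationary solve produced negative probabilities")
    p = np.clip(p, 0.0, None)
    return p / p.sum(), space


def joint_matrix(p: np.ndarray, space: StateSpace) -> np.ndarray:
    """Arrange an M=2 stationary vector as a (N+1) x (N+1) matrix."""
    if space.m_filaments != 2:
        raise ValueError("joint_matrix requires M = 2")
    n = space.n_total
    out = np.zeros((n + 1, n + 1))
    for (l1, l2), i in space.index.items():
        out[l1, l2] = p[i]
    return out
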