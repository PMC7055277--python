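"""Spectral analysis of the transition matrix and the OD rank.

The row-stochastic transition matrix W is a Perron-Frobenius operator: its
spectrum lies in the unit disc and the unit eigenvalue is simple exactly
when the positive-weight digraph is strongly connected (given aperiodicity,
which self-loops guarantee in practice). The left unit eigenvector P_inf is
the stationary distribution of the trip-driven random walk — the "OD rank"
of the zones. A one-parameter mean-field approximation

    P_i(q) = q / N + (1 - q) k_in_i / T

mixes a uniform term with in-degree popularity; the q minimizing the
quadratic error S(q) = sum_i (P_inf_i - P_i(q))^2 has the closed form
implemented in :func:`optimal_q`.

No teleportation or damping is added: a disconnected input is an error, not
something to patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .errors import (ContractViolationError, ConvergenceError,
                     DegenerateInputError, InvalidConfigError)

__all__ = [
    "SpectrumResult",
    "ODRankResult",
    "spectrum",
    "stationary",
    "meanfield_rank",
    "optimal_q",
]

_SPECTRAL_TOL = 1e-8
_POWER_TOL = 1e-12
_POWER_MAXITER = 100_000


def _check_stochastic(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidConfigError("W must be square")
    if np.any(W < 0) or np.max(np.abs(W.sum(axis=1) - 1.0)) > 1e-10:
        raise ContractViolationError("W is not row-stochastic")
    return W


@dataclass
class SpectrumResult:
    """Full complex spectrum with connectivity diagnostics.

    unit_multiplicity counts eigenvalues within tolerance of 1;
    leading_multiplicity counts eigenvalues whose modulus is within
    tolerance of the largest modulus (these differ for periodic chains).
    """

    eigenvalues: np.ndarray
    leading_modulus: float
    leading_multiplicity: int
    unit_multiplicity: int
    strongly_connected: bool


def spectrum(W, tol: float = _SPECTRAL_TOL) -> SpectrumResult:
    """Dense eigenvalue spectrum of a row-stochastic matrix.

    Strong connectivity is cross-checked on the positive-entry pattern so a
    degenerate unit eigenvalue can be attributed to disconnection.
    """
    W = _check_stochastic(W)
    lam = np.linalg.eigvals(W)
    mods = np.abs(lam)
    lead = float(mods.max())
    n_comp, _ = csgraph.connected_components(sparse.csr_matrix(W > 0),
                                             connection="strong")
    return SpectrumResult(
        eigenvalues=lam,
        leading_modulus=lead,
        leading_multiplicity=int(np.sum(mods >= lead - tol)),
        unit_multiplicity=int(np.sum(np.abs(lam - 1.0) <= tol)),
        strongly_connected=bool(n_comp == 1),
    )


def stationary(W, method: str = "power", tol: float = _POWER_TOL,
               maxiter: int = _POWER_MAXITER) -> np.ndarray:
    """Stationary distribution: left unit eigenvector, normalized to sum 1.

    method='power' iterates p <- p W from uniform until the sup-norm update
    is below ``tol``; method='eig' uses the dense left eigensolver. Either
    way the result is coerced real non-negative and must satisfy
    ||P W - P||_inf < 1e-10, asserted before returning. Inputs whose
    positive pattern is not strongly connected are rejected (degenerate unit
    eigenvalue).
    """
    W = _check_stochastic(W)
    N = W.shape[0]
    n_comp, _ = csgraph.connected_components(sparse.csr_matrix(W > 0),
                                             connection="strong")
    if n_comp != 1:
        raise DegenerateInputError(
            f"transition graph has {n_comp} strongly connected components; "
            "the unit eigenvalue is degenerate")
    if method == "power":
        p = np.full(N, 1.0 / N)
        for _ in range(maxiter):
            p_new = p @ W
            if np.max(np.abs(p_new - p)) < tol:
                p = p_new
                break
            p = p_new
        else:
            raise ConvergenceError(
                f"power iteration did not reach {tol} in {maxiter} sweeps "
                f"(last update {np.max(np.abs(p_new - p)):.3e})")
    elif method == "eig":
        vals, vecs = np.linalg.eig(W.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        p = np.real(vecs[:, idx])
        if p.sum() < 0:
            p = -p
    else:
        raise InvalidConfigError(f"unknown method: {method!r}")
    p = np.clip(np.real(p), 0.0, None)
    p = p / p.sum()
    resid = float(np.max(np.abs(p @ W - p)))
    if resid > 1e-10:
        raise ConvergenceError(f"stationary residual {resid:.3e} exceeds 1e-10")
    return p


def meanfield_rank(k_in, total: float, N: int | None = None, q: float = 0.0) -> np.ndarray:
    """Mean-field approximation P_i(q) = q/N + (1-q) k_in_i / total."""
    k_in = np.asarray(k_in, dtype=float)
    if N is None:
        N = k_in.size
    if not 0.0 <= q <= 1.0:
        raise InvalidConfigError("q must lie in [0, 1]")
    if not np.isclose(k_in.sum(), total):
        raise InvalidConfigError("k_in must sum to total")
    return q / N + (1.0 - q) * k_in / total


@dataclass
class ODRankResult:
    """Stationary vector with its best mean-field parameter."""

    P_inf: np.ndarray
    q_star: float
    S_at_qstar: float
    p: np.ndarray  # k_in / total


def optimal_q(P_inf, k_in, total: float) -> ODRankResult:
    """Closed-form q minimizing S(q) = sum (P_inf - P(q))^2.

        q* = [sum p^2 - sum P_inf p] / [sum p^2 - 1/N],   p = k_in / total.

    A uniform p makes the denominator vanish (every q fits equally) and is
    reported as a degenerate input.
    """
    P_inf = np.asarray(P_inf, dtype=float)
    p = np.asarray(k_in, dtype=float) / float(total)
    N = p.size
    denom = float(np.sum(p ** 2) - 1.0 / N)
    if abs(denom) < 1e-15:
        raise DegenerateInputError("p is uniform: q* is 0/0, undefined")
    q_star = float((np.sum(p ** 2) - np.sum(P_inf * p)) / denom)
    approx = q_star / N + (1.0 - q_star) * p
    S = float(np.sum((P_inf - approx) ** 2))
    return ODRankResult(P_inf=P_inf, q_star=q_star, S_at_qstar=S, p=p)
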