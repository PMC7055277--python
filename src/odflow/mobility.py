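"""Local / long-range mobility model and Monte Carlo trip simulation.

The model assigns every ordered zone pair (i, j) a weight

    Omega_ij(R, beta) = 1                                for 0 <= d_ij <= R
                      = (R / d_ij) * exp(-beta (d_ij - R))  for d_ij > R

i.e. destinations within a radius ``R`` of the origin are equally likely
regardless of distance, while beyond ``R`` the weight decays as a power law
with an exponential cutoff (a truncated Levy-flight kernel; 1/beta is the
characteristic long-range distance imposed by the finite size of the city).
Row-normalizing Omega yields the model transition matrix

    w_ij = Omega_ij / sum_l Omega_il,

and trips are simulated by drawing an origin zone with probability
proportional to a supplied importance weight (in practice the empirical
out-degree) and then a destination from the origin's row of w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyResultError, InvalidConfigError

__all__ = [
    "ModelKernel",
    "omega_weight",
    "model_transition_matrix",
    "simulate_trips",
    "displacement_density",
    "compare_densities",
]


def omega_weight(d, R: float, beta: float):
    """Pair weight Omega(d; R, beta) of the piecewise mobility kernel.

    Parameters
    ----------
    d : float or array
        Geographic distance(s), same length unit as ``R``.
    R : float
        Local-neighbourhood radius (> 0).
    beta : float
        Long-range decay rate in inverse distance units (>= 0).

    Returns
    -------
    float or ndarray
        1 on [0, R]; (R/d) exp(-beta (d - R)) beyond. Continuous at d = R
        and strictly decreasing for d > R.
    """
    d = np.asarray(d, dtype=float)
    if R <= 0:
        raise InvalidConfigError(f"R must be positive, got {R}")
    if beta < 0:
        raise InvalidConfigError(f"beta must be non-negative, got {beta}")
    if np.any(d < 0):
        raise InvalidConfigError("distances must be non-negative")
    out = np.ones_like(d)
    far = d > R
    df = d[far]
    out[far] = (R / df) * np.exp(-beta * (df - R))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ModelKernel:
    """Mobility model bound to a concrete zone geometry.

    Attributes
    ----------
    R, beta : kernel parameters (km and 1/km).
    omega : raw pair-weight matrix Omega_ij.
    w : row-stochastic model transition matrix (row-normalized omega).
    origin_weights : origin sampling distribution pi (sums to 1), or None.
    """

    R: float
    beta: float
    omega: np.ndarray
    w: np.ndarray
    origin_weights: np.ndarray | None = field(default=None)


def model_transition_matrix(D: np.ndarray, R: float, beta: float) -> np.ndarray:
    """Row-stochastic model matrix w_ij from a distance matrix (Omega, normalized).

    The diagonal is included: d_ii = 0 gives Omega = 1, so self-loop trips are
    part of the model, matching the OD-matrix convention.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidConfigError("D must be a square distance matrix")
    if np.any(np.diag(D) != 0):
        raise InvalidConfigError("distance matrix must have a zero diagonal")
    omega = omega_weight(D, R, beta)
    return omega / omega.sum(axis=1, keepdims=True)


def build_model_kernel(D: np.ndarray, R: float, beta: float,
                       origin_weights=None) -> ModelKernel:
    """Convenience constructor bundling Omega, w and the origin distribution."""
    omega = omega_weight(np.asarray(D, dtype=float), R, beta)
    w = omega / omega.sum(axis=1, keepdims=True)
    pi = None
    if origin_weights is not None:
        pi = np.asarray(origin_weights, dtype=float)
        if np.any(pi < 0) or pi.sum() <= 0:
            raise InvalidConfigError("origin weights must be non-negative, not all zero")
        pi = pi / pi.sum()
    return ModelKernel(R=R, beta=beta, omega=omega, w=w, origin_weights=pi)


def simulate_trips(w_model: np.ndarray, origin_weights, n: int, seed,
                   D: np.ndarray | None = None):
    """Draw ``n`` independent (origin, destination) trips from the model.

    Each trip's origin zone is drawn with probability proportional to
    ``origin_weights`` and its destination from the origin's row of
    ``w_model``. Destination draws use per-row cumulative tables built once,
    so the output is a deterministic function of the seed.

    Returns
    -------
    (origins, destinations) int arrays, plus a distances array if ``D``
    is given (self-loops get distance 0).
    """
    if n < 0:
        raise InvalidConfigError("n must be non-negative")
    w_model = np.asarray(w_model, dtype=float)
    pi = np.asarray(origin_weights, dtype=float)
    if np.any(pi < 0) or pi.sum() <= 0:
        raise InvalidConfigError("origin weights must be non-negative, not all zero")
    pi = pi / pi.sum()
    rng = np.random.default_rng(seed)
    N = w_model.shape[0]
    if n == 0:
        o = np.empty(0, dtype=np.int64)
        d = np.empty(0, dtype=np.int64)
        return (o, d) if D is None else (o, d, np.empty(0))
    origins = rng.choice(N, size=n, p=pi)
    row_cum = np.cumsum(w_model, axis=1)
    row_cum[:, -1] = 1.0  # guard against rounding in the last column
    u = rng.random(n)
    # vectorized per-row inverse-CDF: offset each row's cumulative into its
    # own unit slot and searchsorted once over the flattened table
    dests = np.empty(n, dtype=np.int64)
    order = np.argsort(origins, kind="stable")
    o_sorted = origins[order]
    u_sorted = u[order]
    starts = np.searchsorted(o_sorted, np.arange(N))
    ends = np.searchsorted(o_sorted, np.arange(N), side="right")
    for i in range(N):
        s, e = starts[i], ends[i]
        if s == e:
            continue
        dests[order[s:e]] = np.searchsorted(row_cum[i], u_sorted[s:e], side="right")
    np.clip(dests, 0, N - 1, out=dests)
    if D is None:
        return origins, dests
    return origins, dests, np.asarray(D, dtype=float)[origins, dests]


def displacement_density(distances_m, log_bins=None):
    """Normalized displacement density p(d) on logarithmically spaced bins.

    Parameters
    ----------
    distances_m : array of trip displacements in metres.
    log_bins : bin edges in metres; default 50 log-spaced bins on
        [1e2, 4e4] m. Distances outside the window are dropped (the default
        window starts at 100 m, so zone-level self-loops at d = 0 are
        excluded from this view).

    Returns
    -------
    (edges, density, n_in_window): density integrates to 1 over the bins.
    """
    d = np.asarray(distances_m, dtype=float)
    if d.size == 0:
        raise EmptyResultError("no displacements supplied")
    if np.any(d < 0):
        raise InvalidConfigError("distances must be non-negative")
    if log_bins is None:
        log_bins = np.logspace(2.0, np.log10(4.0e4), 51)
    edges = np.asarray(log_bins, dtype=float)
    counts, _ = np.histogram(d, bins=edges)
    n_in = int(counts.sum())
    if n_in == 0:
        raise EmptyResultError("no displacements inside the binning window")
    widths = np.diff(edges)
    density = counts / (n_in * widths)
    return edges, density, n_in


def compare_densities(distances_a_m, distances_b_m, log_bins=None):
    """Binned comparison of two displacement samples.

    Reports the KS distance between the binned CDFs and the total-variation
    distance between bin masses; the comparison is descriptive (reported,
    not thresholded).
    """
    if log_bins is None:
        log_bins = np.logspace(2.0, np.log10(4.0e4), 51)
    edges = np.asarray(log_bins, dtype=float)
    out = {}
    masses = []
    for d in (distances_a_m, distances_b_m):
        c, _ = np.histogram(np.asarray(d, dtype=float), bins=edges)
        tot = c.sum()
        if tot == 0:
            raise EmptyResultError("a sample has no mass in the binning window")
        masses.append(c / tot)
    pa, pb = masses
    out["ks"] = float(np.max(np.abs(np.cumsum(pa) - np.cumsum(pb))))
    out["tv"] = float(0.5 * np.sum(np.abs(pa - pb)))
    out["n"] = [int(len(np.asarray(distances_a_m))), int(len(np.asarray(distances_b_m)))]
    return out
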