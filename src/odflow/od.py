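"""Origin-destination matrix construction and displacement statistics.

The OD matrix T holds integer trip counts between zones (diagonal entries
are self-loop trips). Its row sums k_out and column sums k_in are the zone
out- and in-degrees; by construction sum(k_out) = sum(k_in) = total trips,
an identity asserted on every build.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ContractViolationError, EmptyResultError, InvalidConfigError

__all__ = ["ODMatrix", "DisplacementStats", "build_od", "displacement_stats"]


@dataclass
class ODMatrix:
    """Sparse integer trip-count matrix with derived degrees.

    counts : scipy CSR matrix, shape (N, N), T_ij = trips from i to j.
    k_in, k_out : arrival / departure totals per zone.
    total : grand total of trips.
    """

    counts: sparse.csr_matrix
    k_in: np.ndarray
    k_out: np.ndarray
    total: int

    @property
    def n_zones(self) -> int:
        return self.counts.shape[0]

    def toarray(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def build_od(origin_zones, dest_zones, n_zones: int) -> ODMatrix:
    """Count (origin, destination) index pairs into an N x N OD matrix.

    Raises on indices outside [0, n_zones) — that is an upstream contract
    violation, not a skippable record. The degree identity
    sum(k_in) = sum(k_out) = total is asserted before returning.
    """
    o = np.asarray(origin_zones, dtype=np.int64)
    d = np.asarray(dest_zones, dtype=np.int64)
    if o.shape != d.shape:
        raise InvalidConfigError("origin and destination arrays must align")
    if o.size and (o.min() < 0 or o.max() >= n_zones or d.min() < 0 or d.max() >= n_zones):
        raise ContractViolationError("trip references a zone outside the zone set")
    counts = sparse.coo_matrix(
        (np.ones(o.size, dtype=np.int64), (o, d)), shape=(n_zones, n_zones)
    ).tocsr()
    k_out = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)
    k_in = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    total = int(counts.sum())
    if not (k_out.sum() == k_in.sum() == total == o.size):
        raise ContractViolationError("degree/total conservation failed")
    return ODMatrix(counts=counts, k_in=k_in, k_out=k_out, total=total)


@dataclass
class DisplacementStats:
    """Summary of trip displacement lengths.

    f : counts per uniform bin of width ``bin_width_km``.
    bin_edges_km : the uniform bin edges (len(f) + 1).
    mean_km, max_km : average and largest displacement.
    interval_fractions : share of trips per half-open interval [a, b).
    intervals_km : the (a, b) interval bounds.
    n : number of trips.
    """

    f: np.ndarray
    bin_edges_km: np.ndarray
    mean_km: float
    max_km: float
    interval_fractions: np.ndarray
    intervals_km: tuple
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_km": self.mean_km,
            "max_km": self.max_km,
            "bin_width_km": float(self.bin_edges_km[1] - self.bin_edges_km[0]),
            "intervals_km": [[a, (None if np.isinf(b) else b)] for a, b in self.intervals_km],
            "interval_fractions": self.interval_fractions.tolist(),
        }


DEFAULT_INTERVALS_KM = ((0.0, 1.8), (1.8, 20.0), (20.0, np.inf))


def displacement_stats(distances_km, bin_width_km: float = 0.5,
                       intervals_km=DEFAULT_INTERVALS_KM) -> DisplacementStats:
    """Uniform-bin frequencies f(d), mean, max and interval fractions.

    Bins have width ``bin_width_km`` (default 500 m) starting at 0; all
    intervals are half-open [a, b), so self-loop trips (d = 0) fall into the
    local interval. Fractions sum to 1 when the intervals partition [0, inf).
    """
    d = np.asarray(distances_km, dtype=float)
    if d.size == 0:
        raise EmptyResultError("no displacements supplied")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise InvalidConfigError("distances must be finite and non-negative")
    if bin_width_km <= 0:
        raise InvalidConfigError("bin width must be positive")
    n_bins = int(np.floor(d.max() / bin_width_km)) + 1
    edges = np.arange(n_bins + 1) * bin_width_km
    # np.histogram closes the last bin; widen the final edge so counting
    # stays half-open for every displacement including the maximum
    count_edges = edges.copy()
    count_edges[-1] = np.nextafter(edges[-1], np.inf)
    f, _ = np.histogram(d, bins=count_edges)
    if f.sum() != d.size:
        raise ContractViolationError("binning lost trips")
    fracs = np.array([np.mean((d >= a) & (d < b)) for a, b in intervals_km])
    return DisplacementStats(
        f=f.astype(np.int64),
        bin_edges_km=edges,
        mean_km=float(d.mean()),
        max_km=float(d.max()),
        interval_fractions=fracs,
        intervals_km=tuple(tuple(iv) for iv in intervals_km),
        n=int(d.size),
    )
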