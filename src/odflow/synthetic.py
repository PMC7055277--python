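"""Synthetic trip-table generator.

Produces trip records with the statistical structure the downstream analysis
assumes: zones on a plane (lattice, uniform-random or clustered layouts),
heavy-tailed zone attractiveness (stretched-exponential or
power-law-with-cutoff weights), and destinations drawn from the truncated
Levy mobility kernel. Every draw is a deterministic function of the seed, so
a fixed configuration reproduces a byte-identical trip table.

Emitted trip tables follow a TLC-like CSV dialect (pickup/dropoff datetime +
longitude/latitude); coordinates are planar metres by default, optionally
wrapped onto lon/lat around a reference latitude so the gridding stage can
be exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mobility
from .errors import InvalidConfigError
from .gridding import M_PER_DEG

__all__ = [
    "ZoneLayout",
    "GeneratorConfig",
    "make_zone_layout",
    "sample_degree_values",
    "generate_trips",
    "write_trip_csv",
    "write_zone_csv",
]


@dataclass(frozen=True)
class ZoneLayout:
    """N zones on a plane: positions are cell-centre coordinates in metres."""

    positions_m: np.ndarray  # (N, 2)
    cell_side: float = 100.0

    def __post_init__(self):
        pos = np.asarray(self.positions_m, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise InvalidConfigError("layout needs at least 2 zones with 2-D positions")
        if self.cell_side <= 0:
            raise InvalidConfigError("cell_side must be positive")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise InvalidConfigError("zone positions must be unique")
        object.__setattr__(self, "positions_m", pos)

    def __len__(self):
        return self.positions_m.shape[0]

    def distance_matrix_km(self) -> np.ndarray:
        diff = self.positions_m[:, None, :] - self.positions_m[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1)) / 1000.0
        np.fill_diagonal(D, 0.0)
        return D


@dataclass
class GeneratorConfig:
    """Complete recipe for one synthetic trip table (see module docstring)."""

    n_zones: int = 800
    extent_km: tuple = (14.0, 14.0)
    layout_kind: str = "uniform-random"
    attractiveness_model: str = "powerlaw_cutoff"
    attractiveness_params: dict | None = None
    kernel_R: float = 1.8
    kernel_beta: float = 0.15
    n_trips: int = 100_000
    seed: int = 0
    jitter: bool = True
    emit: str = "planar"  # 'planar' or 'lonlat'
    origin_lonlat: tuple = (-74.05, 40.55)

    def __post_init__(self):
        if self.n_trips < 0:
            raise InvalidConfigError("n_trips must be >= 0")
        if self.kernel_R <= 0:
            raise InvalidConfigError("kernel_R must be positive")
        if self.kernel_beta < 0:
            raise InvalidConfigError("kernel_beta must be non-negative")


def make_zone_layout(kind: str, n_zones: int, extent_km=(14.0, 14.0), seed=None,
                     cell_side: float = 100.0) -> ZoneLayout:
    """Place ``n_zones`` distinct zones inside an extent (km).

    kinds
    -----
    lattice : zones at the centres of consecutive ``cell_side`` cells
        (row-major from the south-west corner).
    uniform-random : positions uniform in the box.
    clustered : Gaussian blobs around uniformly placed cluster centres,
        clipped to the box (mimics demand hot-spots).
    """
    ex, ey = (float(extent_km[0]), float(extent_km[1]))
    if n_zones < 2:
        raise InvalidConfigError("n_zones must be >= 2")
    if ex <= 0 or ey <= 0:
        raise InvalidConfigError("extent must be positive")
    wx, wy = ex * 1000.0, ey * 1000.0
    rng = np.random.default_rng(seed)
    if kind == "lattice":
        n_cols = max(int(wx // cell_side), 1)
        n_rows = max(int(wy // cell_side), 1)
        if n_zones > n_cols * n_rows:
            raise InvalidConfigError(
                f"lattice of {n_rows}x{n_cols} cells cannot hold {n_zones} zones")
        idx = np.arange(n_zones)
        rows, cols = idx // n_cols, idx % n_cols
        pos = np.column_stack(((cols + 0.5) * cell_side, (rows + 0.5) * cell_side))
    elif kind == "uniform-random":
        pos = rng.random((n_zones, 2)) * np.array([wx, wy])
    elif kind == "clustered":
        n_clusters = max(2, n_zones // 50)
        centers = rng.random((n_clusters, 2)) * np.array([wx, wy])
        which = rng.integers(0, n_clusters, size=n_zones)
        sigma = 0.08 * min(wx, wy)
        pos = centers[which] + rng.normal(scale=sigma, size=(n_zones, 2))
        pos[:, 0] = np.clip(pos[:, 0], 0.0, np.nextafter(wx, 0.0))
        pos[:, 1] = np.clip(pos[:, 1], 0.0, np.nextafter(wy, 0.0))
    else:
        raise InvalidConfigError(f"unknown layout kind: {kind!r}")
    return ZoneLayout(positions_m=pos, cell_side=cell_side)


def sample_degree_values(model_id: str, params: dict, k_min: float, n: int,
                         seed) -> np.ndarray:
    """Draw ``n`` values >= k_min from a supported heavy-tailed model.

    models and parameters
    ---------------------
    stretched_exponential : beta > 0, lam > 0; inverse-CDF
        k = (k_min^beta - ln(1-u)/lam)^(1/beta).
    powerlaw_cutoff : gamma, lam > 0; rejection sampling with a shifted
        exponential proposal and acceptance ratio (k_min/k)^gamma.
    powerlaw : gamma > 1; inverse-CDF k = k_min (1-u)^(-1/(gamma-1)).
    exponential : lam > 0; shifted exponential.
    lognormal : mu, sigma; inverse-CDF on the truncated normal of ln k.
    """
    if n < 0:
        raise InvalidConfigError("n must be >= 0")
    if k_min <= 0:
        raise InvalidConfigError("k_min must be positive")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if model_id == "stretched_exponential":
        beta, lam = float(params["beta"]), float(params["lam"])
        if beta <= 0 or lam <= 0:
            raise InvalidConfigError("SE needs beta > 0 and lam > 0")
        u = rng.random(n)
        return (k_min ** beta - np.log1p(-u) / lam) ** (1.0 / beta)
    if model_id == "exponential":
        lam = float(params["lam"])
        if lam <= 0:
            raise InvalidConfigError("exponential needs lam > 0")
        return k_min - np.log1p(-rng.random(n)) / lam
    if model_id == "powerlaw":
        gamma = float(params["gamma"])
        if gamma <= 1:
            raise InvalidConfigError("powerlaw needs gamma > 1")
        return k_min * (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))
    if model_id == "lognormal":
        mu, sigma = float(params["mu"]), float(params["sigma"])
        if sigma <= 0:
            raise InvalidConfigError("lognormal needs sigma > 0")
        from scipy import stats
        zlo = (np.log(k_min) - mu) / sigma
        u = rng.random(n)
        cdf_lo = stats.norm.cdf(zlo)
        z = stats.norm.ppf(cdf_lo + u * (1.0 - cdf_lo))
        return np.exp(mu + sigma * z)
    if model_id == "powerlaw_cutoff":
        gamma, lam = float(params["gamma"]), float(params["lam"])
        if lam <= 0:
            raise InvalidConfigError("powerlaw_cutoff needs lam > 0")
        # rejection against the shifted-exponential envelope: on [k_min, inf)
        # p_EC(k) proportional to k^-gamma e^-lam k <= k_min^-gamma e^-lam k,
        # so accept a proposal k with probability (k_min/k)^gamma
        out = np.empty(n)
        filled = 0
        total_proposed = 0
        warned = False
        while filled < n:
            batch = max(4 * (n - filled), 1024)
            k = k_min - np.log1p(-rng.random(batch)) / lam
            acc = rng.random(batch) < (k_min / k) ** gamma
            total_proposed += batch
            got = k[acc]
            take = min(len(got), n - filled)
            out[filled:filled + take] = got[:take]
            filled += take
            if not warned and total_proposed > 2000 and filled / total_proposed < 1e-3:
                warnings.warn(
                    "powerlaw_cutoff rejection acceptance rate below 1e-3; "
                    "sampling will be slow for these (gamma, lam, k_min)",
                    RuntimeWarning,
                )
                warned = True
        return out
    raise InvalidConfigError(f"unknown model: {model_id!r}")


def generate_trips(layout: ZoneLayout, attractiveness_weights, kernel_R: float,
                   kernel_beta: float, n_trips: int, seed, jitter: bool = True,
                   emit: str = "planar", origin_lonlat=(-74.05, 40.55)) -> pd.DataFrame:
    """Draw a trip table from the mobility model on ``layout``.

    Origin zones are drawn with probability proportional to
    ``attractiveness_weights`` (the synthetic out-degree field); destinations
    come from the origin's row of the model transition matrix. Emitted
    endpoint coordinates are the zone position plus, when ``jitter`` is on, a
    uniform offset within the half-open cell square.

    With ``emit='lonlat'`` the planar metres are wrapped onto longitude /
    latitude around ``origin_lonlat`` using the equirectangular scale at the
    reference latitude, producing a TLC-like table.
    """
    weights = np.asarray(attractiveness_weights, dtype=float)
    if len(weights) != len(layout):
        raise InvalidConfigError("one weight per zone required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise InvalidConfigError("weights must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    D = layout.distance_matrix_km()
    w_model = mobility.model_transition_matrix(D, kernel_R, kernel_beta)
    origins, dests = mobility.simulate_trips(
        w_model, weights, n_trips, rng.integers(0, 2 ** 31 - 1))
    L = layout.cell_side
    if n_trips > 0 and jitter:
        off = (rng.random((n_trips, 4)) - 0.5) * L
    else:
        off = np.zeros((n_trips, 4))
    po = layout.positions_m[origins] + off[:, :2]
    do = layout.positions_m[dests] + off[:, 2:]
    base = pd.Timestamp("2015-01-01 00:00:00")
    step = pd.to_timedelta(np.arange(n_trips), unit="min")
    df = pd.DataFrame({
        "pickup_datetime": base + step,
        "dropoff_datetime": base + step + pd.Timedelta(minutes=10),
        "origin_zone": origins,
        "dest_zone": dests,
    })
    if emit == "planar":
        df["pickup_x_m"], df["pickup_y_m"] = po[:, 0], po[:, 1]
        df["dropoff_x_m"], df["dropoff_y_m"] = do[:, 0], do[:, 1]
    elif emit == "lonlat":
        lon0, lat0 = origin_lonlat
        sx = M_PER_DEG * np.cos(np.radians(lat0))
        df["pickup_longitude"] = lon0 + po[:, 0] / sx
        df["pickup_latitude"] = lat0 + po[:, 1] / M_PER_DEG
        df["dropoff_longitude"] = lon0 + do[:, 0] / sx
        df["dropoff_latitude"] = lat0 + do[:, 1] / M_PER_DEG
    else:
        raise InvalidConfigError(f"unknown emit mode: {emit!r}")
    return df


def generate_from_config(config: GeneratorConfig):
    """Layout + weights + trips from one GeneratorConfig; returns all three."""
    rng = np.random.default_rng(config.seed)
    layout = make_zone_layout(config.layout_kind, config.n_zones,
                              config.extent_km, seed=rng.integers(0, 2 ** 31 - 1))
    model = config.attractiveness_model
    if model == "uniform":
        weights = np.ones(config.n_zones)
    else:
        defaults = {
            "stretched_exponential": {"beta": 0.708, "lam": 4.138e-5},
            "powerlaw_cutoff": {"gamma": 1.0, "lam": 6.086e-6},
        }
        params = config.attractiveness_params or defaults.get(model)
        if params is None:
            raise InvalidConfigError(f"no parameters for attractiveness model {model!r}")
        weights = sample_degree_values(model, params, k_min=1000.0,
                                       n=config.n_zones,
                                       seed=rng.integers(0, 2 ** 31 - 1))
    trips = generate_trips(layout, weights, config.kernel_R, config.kernel_beta,
                           config.n_trips, seed=rng.integers(0, 2 ** 31 - 1),
                           jitter=config.jitter, emit=config.emit,
                           origin_lonlat=config.origin_lonlat)
    return layout, weights, trips


def write_trip_csv(trips: pd.DataFrame, path):
    """Write a TLC-like trip CSV (floats at 6 decimals)."""
    cols = [c for c in trips.columns if c not in ("origin_zone", "dest_zone")]
    trips[cols].to_csv(path, index=False, float_format="%.6f")


def write_zone_csv(layout: ZoneLayout, path):
    pd.DataFrame({
        "zone_id": np.arange(len(layout)),
        "x_m": layout.positions_m[:, 0],
        "y_m": layout.positions_m[:, 1],
    }).to_csv(path, index=False, float_format="%.6f")
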