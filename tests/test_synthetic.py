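"""Generator correctness: layouts, heavy-tailed samplers, trip tables."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from odflow import mobility, synthetic
from odflow.errors import InvalidConfigError


class TestZoneLayout:
    def test_lattice_places_zones_at_cell_centres(self):
        layout = synthetic.make_zone_layout("lattice", 4, (0.2, 0.2))
        expected = {(50.0, 50.0), (150.0, 50.0), (50.0, 150.0), (150.0, 150.0)}
        assert {tuple(p) for p in layout.positions_m} == expected

    def test_uniform_random_inside_box_and_reproducible(self):
        a = synthetic.make_zone_layout("uniform-random", 800, (14, 14), seed=1)
        b = synthetic.make_zone_layout("uniform-random", 800, (14, 14), seed=1)
        assert np.array_equal(a.positions_m, b.positions_m)
        assert len(a) == 800
        assert a.positions_m.min() >= 0
        assert a.positions_m.max() < 14_000

    def test_clustered_inside_box(self):
        lay = synthetic.make_zone_layout("clustered", 300, (10, 10), seed=2)
        assert lay.positions_m.min() >= 0 and lay.positions_m.max() <= 10_000

    def test_pairwise_distances_match_brute_force(self):
        layout = synthetic.make_zone_layout("uniform-random", 10, (1, 1), seed=7)
        D = layout.distance_matrix_km()
        pos = layout.positions_m
        for i in range(10):
            for j in range(10):
                expect = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1]) / 1000
                assert D[i, j] == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("kind,n,extent", [
        ("uniform-random", 1, (1, 1)),
        ("uniform-random", 5, (0, 1)),
        ("lattice", 100, (0.2, 0.2)),
        ("bogus", 5, (1, 1)),
    ])
    def test_invalid_layout_config(self, kind, n, extent):
        with pytest.raises(InvalidConfigError):
            synthetic.make_zone_layout(kind, n, extent, seed=0)


class TestDegreeSamplers:
    def test_se_beta_one_is_shifted_exponential(self):
        lam, k_min, n = 1e-4, 1000.0, 40_000
        k = synthetic.sample_degree_values(
            "stretched_exponential", {"beta": 1.0, "lam": lam}, k_min, n, seed=5)
        se_of_mean = (1 / lam) / np.sqrt(n)
        assert abs(k.mean() - (k_min + 1 / lam)) < 4 * se_of_mean

    def test_se_sampler_matches_analytic_cdf(self):
        beta, lam, k_min = 0.708, 4.138e-5, 1000.0
        k = np.sort(synthetic.sample_degree_values(
            "stretched_exponential", {"beta": beta, "lam": lam}, k_min, 100_000,
            seed=3))
        cdf = 1.0 - np.exp(-lam * (k ** beta - k_min ** beta))
        n = k.size
        ks = max(np.max(np.arange(1, n + 1) / n - cdf),
                 np.max(cdf - np.arange(0, n) / n))
        assert ks < 0.01

    def test_ec_sampler_matches_quadrature_cdf(self):
        gamma, lam, k_min = 1.0, 6.086e-6, 1000.0
        k = np.sort(synthetic.sample_degree_values(
            "powerlaw_cutoff", {"gamma": gamma, "lam": lam}, k_min, 10_000, seed=3))
        # independent oracle: cumulative trapezoid integration of the
        # unnormalized density on a dense log grid
        grid = np.logspace(np.log10(k_min), np.log10(k.max()) + 1, 200_000)
        pdf = grid ** -gamma * np.exp(-lam * grid)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        tail = (grid[-1] ** -gamma * np.exp(-lam * grid[-1])) / lam  # < upper bound
        cdf_grid = cum / (cum[-1] + tail)
        cdf = np.interp(k, grid, cdf_grid)
        n = k.size
        ks = max(np.max(np.arange(1, n + 1) / n - cdf),
                 np.max(cdf - np.arange(0, n) / n))
        assert ks < 0.02

    def test_sampler_determinism_and_support(self):
        for model, params in [
            ("stretched_exponential", {"beta": 0.7, "lam": 1e-4}),
            ("powerlaw_cutoff", {"gamma": 1.0, "lam": 1e-5}),
            ("powerlaw", {"gamma": 2.5}),
            ("exponential", {"lam": 1e-4}),
            ("lognormal", {"mu": 7.0, "sigma": 1.0}),
        ]:
            a = synthetic.sample_degree_values(model, params, 1000.0, 500, seed=11)
            b = synthetic.sample_degree_values(model, params, 1000.0, 500, seed=11)
            assert np.array_equal(a, b), model
            assert np.all(a >= 1000.0), model

    def test_invalid_sampler_config(self):
        with pytest.raises(InvalidConfigError):
            synthetic.sample_degree_values(
                "stretched_exponential", {"beta": 0.7, "lam": -1.0}, 1000, 10, seed=0)
        with pytest.raises(InvalidConfigError):
            synthetic.sample_degree_values(
                "powerlaw_cutoff", {"gamma": 1.0, "lam": 1e-5}, 1000, -5, seed=0)


class TestGenerateTrips:
    def test_zero_trips_gives_empty_table(self):
        layout = synthetic.make_zone_layout("uniform-random", 5, (1, 1), seed=0)
        trips = synthetic.generate_trips(layout, np.ones(5), 1.8, 0.15, 0, seed=0)
        assert len(trips) == 0

    def test_two_close_zones_split_uniformly(self):
        # both zones within R of each other: all four ordered pairs
        # (self-loops included) carry weight 1, so each gets ~25% of trips
        layout = synthetic.ZoneLayout(positions_m=np.array([[0.0, 0.0], [500.0, 0.0]]))
        n = 100_000
        trips = synthetic.generate_trips(layout, np.ones(2), 1.8, 0.15, n, seed=2)
        sigma3 = 3 * np.sqrt(n * 0.25 * 0.75)
        for i in range(2):
            for j in range(2):
                got = ((trips["origin_zone"] == i) & (trips["dest_zone"] == j)).sum()
                assert abs(got - n * 0.25) < sigma3

    def test_ten_zone_pair_frequencies_match_model(self):
        # 10 zones / 1000 trips; the exact pair law pi_i * w_ij is the oracle
        layout = synthetic.make_zone_layout("uniform-random", 10, (3, 3), seed=4)
        weights = np.arange(1.0, 11.0)
        n = 1000
        trips = synthetic.generate_trips(layout, weights, 1.8, 0.15, n, seed=4)
        w = mobility.model_transition_matrix(layout.distance_matrix_km(), 1.8, 0.15)
        probs = (weights / weights.sum())[:, None] * w
        counts = np.zeros((10, 10))
        np.add.at(counts, (trips["origin_zone"], trips["dest_zone"]), 1)
        chi2 = np.sum((counts - n * probs) ** 2 / (n * probs))
        dof = probs.size - 1
        assert stats.chi2.sf(chi2, dof) > 1e-3
        assert np.all(np.abs(counts - n * probs) <
                      4 * np.sqrt(n * probs * (1 - probs)) + 1e-9)

    def test_trip_table_byte_reproducible(self):
        cfg = dict(layout_kind="uniform-random", n_zones=20, extent_km=(2, 2),
                   attractiveness_model="uniform", n_trips=500, seed=9,
                   emit="lonlat")
        outs = []
        for _ in range(2):
            _, _, trips = synthetic.generate_from_config(
                synthetic.GeneratorConfig(**cfg))
            buf = io.StringIO()
            synthetic.write_trip_csv(trips, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_jitter_stays_inside_cell(self):
        layout = synthetic.make_zone_layout("lattice", 4, (0.2, 0.2))
        trips = synthetic.generate_trips(layout, np.ones(4), 1.8, 0.15, 2000,
                                         seed=1, jitter=True)
        ox = trips["pickup_x_m"].to_numpy()
        centres = layout.positions_m[trips["origin_zone"].to_numpy(), 0]
        assert np.all(np.abs(ox - centres) <= 50.0)

    def test_all_zero_weights_rejected(self):
        layout = synthetic.make_zone_layout("uniform-random", 5, (1, 1), seed=0)
        with pytest.raises(InvalidConfigError):
            synthetic.generate_trips(layout, np.zeros(5), 1.8, 0.15, 10, seed=0)

    def test_lonlat_emission_roundtrips_planar_metres(self):
        layout = synthetic.make_zone_layout("uniform-random", 8, (2, 2), seed=3)
        t_pl = synthetic.generate_trips(layout, np.ones(8), 1.8, 0.15, 50, seed=6,
                                        jitter=False, emit="planar")
        t_ll = synthetic.generate_trips(layout, np.ones(8), 1.8, 0.15, 50, seed=6,
                                        jitter=False, emit="lonlat",
                                        origin_lonlat=(-74.0, 40.7))
        sx = 111_320.0 * np.cos(np.radians(40.7))
        back = (t_ll["pickup_longitude"] + 74.0) * sx
        assert np.allclose(back, t_pl["pickup_x_m"], atol=1e-6)
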