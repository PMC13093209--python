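import numpy as np
import pytest

import sdmshift as s
from sdmshift.synthetic import VirtualSpecies


def _two_layer_config(r=0.95, n=200, seed=0, trend=0.0):
    return s.LandscapeConfig(
        n_rows=n,
        n_cols=n,
        layer_specs=[
            s.LayerSpec("a", trend_slope=trend),
            s.LayerSpec("b"),
        ],
        target_correlation=np.array([[1.0, r], [r, 1.0]]),
        seed=seed,
    )


class TestGenerateEnvStack:
    def test_pairwise_correlation_matches_target(self):
        stack = s.generate_env_stack(_two_layer_config(r=0.95))
        a = stack.layers["a"].values.ravel()
        b = stack.layers["b"].values.ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert 0.90 <= r <= 0.99
        assert r == pytest.approx(0.95, abs=0.05)

    def test_same_seed_reproduces_identical_stack(self):
        s1 = s.generate_env_stack(_two_layer_config(seed=7))
        s2 = s.generate_env_stack(_two_layer_config(seed=7))
        for name in s1.layer_names:
            assert np.array_equal(s1.layers[name].values, s2.layers[name].values)

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            s.LandscapeConfig(
                n_rows=10,
                n_cols=10,
                layer_specs=[s.LayerSpec(n) for n in "abc"],
                target_correlation=bad,
            )

    def test_latitudinal_trend_recovered_by_regression(self):
        cfg = s.LandscapeConfig(
            n_rows=200, n_cols=200, layer_specs=[s.LayerSpec("t", trend_slope=-1.0)],
            seed=3,
        )
        stack = s.generate_env_stack(cfg)
        lat = np.repeat(stack.grid.lat_centers(), stack.grid.n_cols)
        slope = np.polyfit(lat, stack.layers["t"].values.ravel(), 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.10)
        # decreasing northward, visible once row means are averaged past the
        # smoothing noise (adjacent 2.5' rows differ by only 1/24 unit of trend)
        block_means = stack.layers["t"].values.reshape(10, 20, -1).mean(axis=(1, 2))
        assert np.all(np.diff(block_means) > 0)  # rows run north -> south

    def test_categorical_layer_has_contiguous_integer_patches(self):
        cfg = s.LandscapeConfig(
            n_rows=40, n_cols=40,
            layer_specs=[s.LayerSpec("lc", kind="categorical", n_classes=3)], seed=5,
        )
        vals = s.generate_env_stack(cfg).layers["lc"].values
        assert set(np.unique(vals)) <= {1.0, 2.0, 3.0}


class TestVirtualSpecies:
    def test_prevalence_calibrated_to_target(self, small_stack):
        sp = s.make_virtual_species(small_stack, [("temp", 0.0, 1.0, 5.0)], 0.10)
        assert float(np.nanmean(sp.suitability(small_stack))) == pytest.approx(
            0.10, abs=0.005
        )

    def test_zero_weight_terms_give_constant_suitability(self, small_stack):
        sp = s.make_virtual_species(small_stack, [("temp", 0.0, 1.0, 0.0)], 0.3)
        p = sp.suitability(small_stack)
        vals = p[small_stack.mask]
        assert np.allclose(vals, vals[0])

    def test_suitability_invariant_under_layer_renaming(self, small_stack):
        renamed = s.EnvStack(
            small_stack.grid,
            {f"x_{n}": l for n, l in small_stack.layers.items()},
            small_stack.mask.copy(),
        )
        sp1 = s.make_virtual_species(small_stack, [("temp", 0.0, 0.5, 10.0)], 0.1)
        sp2 = s.make_virtual_species(renamed, [("x_temp", 0.0, 0.5, 10.0)], 0.1)
        assert np.array_equal(
            sp1.suitability(small_stack), sp2.suitability(renamed), equal_nan=True
        )

    def test_unattainable_prevalence_reports_achievable_interval(self, small_stack):
        with pytest.raises(ValueError, match="achievable interval"):
            s.make_virtual_species(small_stack, [("temp", 0.0, 1.0, 5.0)], 1.5)

    def test_categorical_layer_rejected_as_niche_axis(self, small_stack):
        with pytest.raises(ValueError, match="continuous"):
            s.make_virtual_species(small_stack, [("landcov", 1.0, 1.0, 5.0)], 0.1)


class TestSamplePresences:
    def test_exhaustive_sampling_returns_exactly_the_positive_cells(self, small_stack):
        # float-underflowed logistic: suitability is exactly 0 except where temp
        # sits in a narrow band, so the positive set is finite and known
        sp = VirtualSpecies([("temp", 0.0, 0.05, 1600.0)], -800.0, 0.1)
        p = sp.suitability(small_stack)
        positive = np.argwhere(np.nan_to_num(p) > 0)
        k = len(positive)
        assert k > 3
        occ = s.sample_presences(sp, small_stack, k, seed=1)
        got = set(zip(occ.frame["grid_row"], occ.frame["grid_col"]))
        assert got == {tuple(rc) for rc in positive}
        with pytest.raises(ValueError, match="positive suitability"):
            s.sample_presences(sp, small_stack, k + 1, seed=1)

    def test_samples_concentrate_near_the_niche_optimum(self, small_stack):
        mu = 0.8  # off the landscape mean, so 'closer to mu' is informative
        sp = s.make_virtual_species(small_stack, [("temp", mu, 0.5, 10.0)], 0.08)
        temp = small_stack.layers["temp"].values
        landscape_dev = abs(float(temp.mean()) - mu)
        hits = 0
        for seed in range(100):
            occ = s.sample_presences(sp, small_stack, 200, seed=seed)
            t = temp[occ.frame["grid_row"], occ.frame["grid_col"]]
            hits += abs(float(t.mean()) - mu) < landscape_dev
        assert hits >= 95

    def test_same_seed_reproduces_the_sample(self, small_stack, strong_species):
        o1 = s.sample_presences(strong_species, small_stack, 50, seed=9)
        o2 = s.sample_presences(strong_species, small_stack, 50, seed=9)
        assert o1.frame.equals(o2.frame)


class TestScenarioDelta:
    def test_zero_offsets_leave_stack_equal(self, small_stack):
        out = s.apply_scenario_delta(small_stack, s.ScenarioDelta("noop", {"temp": 0.0}))
        assert np.array_equal(out.layers["temp"].values, small_stack.layers["temp"].values)

    def test_input_stack_not_modified(self, small_stack):
        before = small_stack.layers["temp"].values.copy()
        s.apply_scenario_delta(small_stack, s.ScenarioDelta("w", {"temp": 2.0}))
        assert np.array_equal(small_stack.layers["temp"].values, before)

    def test_categorical_offset_rejected(self, small_stack):
        with pytest.raises(ValueError, match="categorical"):
            s.apply_scenario_delta(small_stack, s.ScenarioDelta("w", {"landcov": 1.0}))

    def test_nan_offset_rejected(self, small_stack):
        bad = np.full(small_stack.grid.shape, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            s.apply_scenario_delta(small_stack, s.ScenarioDelta("w", {"temp": bad}))

    def test_warming_shifts_isoline_poleward_by_dt_over_b(self):
        # noise-free linear trend: the crossing latitude has a closed form
        cfg = s.LandscapeConfig(
            n_rows=240, n_cols=4, origin_lat=40.0,
            layer_specs=[s.LayerSpec("t", trend_slope=-2.0, std=0.0)], seed=0,
        )
        stack = s.generate_env_stack(cfg)
        warmed = s.apply_scenario_delta(stack, s.ScenarioDelta("w", {"t": 3.0}))
        lats = stack.grid.lat_centers()

        def crossing(values, level=0.0):
            col = values[:, 0]
            i = np.argmin(np.abs(col - level))
            return lats[i]

        shift = crossing(warmed.layers["t"].values) - crossing(stack.layers["t"].values)
        assert shift == pytest.approx(3.0 / 2.0, abs=stack.grid.res_deg)


class TestAnalyticCentroidShift:
    def test_true_suitability_centroid_moves_poleward_by_dt_over_b(self):
        cfg = s.LandscapeConfig(
            n_rows=240, n_cols=80, origin_lat=40.0,
            layer_specs=[
                s.LayerSpec("temp", trend_slope=-1.0, smoothing_length=7, std=0.3),
                s.LayerSpec("precip"),
            ],
            seed=3,
        )
        stack = s.generate_env_stack(cfg)
        sp = s.make_virtual_species(stack, [("temp", 0.0, 0.5, 30.0)], 0.05)
        warmed = s.apply_scenario_delta(stack, s.ScenarioDelta("w", {"temp": 1.0}))
        lat = stack.grid.lat_centers()[:, None] * np.ones(stack.grid.shape)
        p0, p1 = sp.suitability(stack), sp.suitability(warmed)
        shift = np.nansum(p1 * lat) / np.nansum(p1) - np.nansum(p0 * lat) / np.nansum(p0)
        assert shift == pytest.approx(1.0, rel=0.15)


class TestOccurrenceTableStandIn:
    def test_cleaning_and_thinning_recover_the_cell_count(self, small_stack):
        grid = small_stack.grid
        table = s.make_occurrence_table(grid, n_cells=97, seed=4)
        assert len(table) > 97  # raw table is messy
        import io

        occ = s.read_occurrences(io.StringIO(table.to_csv(index=False)))
        thinned = s.thin_to_grid(s.clean_occurrences(occ), grid)
        assert len(thinned) == 97
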