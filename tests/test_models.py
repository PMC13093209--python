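import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdmshift as s
from sdmshift.models import ALGORITHMS, evaluate_algorithms, fit_model, make_folds


def _separable_data(k=4, seed=0):
    """Discrete separable 1-D data: presences on {2..3}, absences on {0..1}.

    Values repeat so every fold's training set spans the full presence
    range (keeps the SRE envelope covering held-out presences).
    """
    pres_vals = np.tile(np.linspace(2.0, 3.0, 5), 8)
    abs_vals = np.tile(np.linspace(0.0, 1.0, 5), 16)
    pres = pd.DataFrame({"x": pres_vals})
    ab = pd.DataFrame({"x": abs_vals})
    return make_folds(pres, ab, k=k, seed=seed)


class TestPseudoAbsences:
    def test_exhaustion_returns_every_eligible_cell(self, small_stack, strong_species):
        occ = s.sample_presences(strong_species, small_stack, 100, seed=1)
        n_eligible = int(small_stack.mask.sum()) - 100
        pa = s.sample_pseudo_absences(small_stack, occ, n=n_eligible, seed=2)
        assert len(pa) == n_eligible
        with pytest.raises(ValueError, match="eligible"):
            s.sample_pseudo_absences(small_stack, occ, n=n_eligible + 1, seed=2)

    def test_never_overlaps_presence_cells(self, small_stack, strong_species):
        occ = s.sample_presences(strong_species, small_stack, 100, seed=1)
        pa = s.sample_pseudo_absences(small_stack, occ, n=500, seed=3)
        pres = set(zip(occ.frame["grid_row"], occ.frame["grid_col"]))
        assert pres.isdisjoint(zip(pa["grid_row"], pa["grid_col"]))

    def test_same_seed_reproduces_sample(self, small_stack, strong_species):
        occ = s.sample_presences(strong_species, small_stack, 100, seed=1)
        a = s.sample_pseudo_absences(small_stack, occ, n=500, seed=4)
        b = s.sample_pseudo_absences(small_stack, occ, n=500, seed=4)
        assert a.equals(b)


class TestMakeFolds:
    def test_stratified_counts_with_eight_of_each(self):
        data = make_folds(
            pd.DataFrame({"x": np.arange(8.0)}),
            pd.DataFrame({"x": np.arange(8.0)}),
            k=4,
            seed=0,
        )
        for f in range(1, 5):
            _, y_tr, _, y_te = data.split(f)
            assert (y_te == 1).sum() == 2 and (y_te == 0).sum() == 2
            assert (y_tr == 1).sum() == 6 and (y_tr == 0).sum() == 6

    def test_test_folds_partition_all_rows(self):
        data = _separable_data()
        total = data.test_masks.sum(axis=0)
        assert np.all(total == 1)  # each row in exactly one test fold

    def test_same_seed_reproduces_folds(self):
        a = _separable_data(seed=5)
        b = _separable_data(seed=5)
        assert np.array_equal(a.test_masks, b.test_masks)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(pd.DataFrame({"x": [1.0]}), pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}))

    def test_random_split_masks_are_quarter_sized(self):
        data = make_folds(
            pd.DataFrame({"x": np.arange(40.0)}),
            pd.DataFrame({"x": np.arange(40.0)}),
            k=4,
            seed=0,
            method="random_split",
        )
        assert data.test_masks.shape == (4, 80)
        assert np.all(data.test_masks.sum(axis=1) == 20)


class TestSurfaceRangeEnvelope:
    def _fit(self, pres_vals, q):
        X = pd.DataFrame({"v": np.concatenate([pres_vals, [-50.0, 150.0]])})
        y = np.concatenate([np.ones(len(pres_vals)), [0, 0]])
        return fit_model("SRE", X, y, continuous=["v"], sre_quantile=q)

    def test_percentile_envelope_on_uniform_presences(self):
        model = self._fit(np.linspace(0.0, 100.0, 101), q=2.5)
        scores = model.score(pd.DataFrame({"v": [50.0, 1.0, 101.0]}))
        assert list(scores) == [1.0, 0.0, 0.0]

    def test_q_zero_envelope_is_presence_min_max(self):
        model = self._fit(np.array([3.0, 7.0, 5.0]), q=0.0)
        lo, hi = model.envelope
        assert lo[0] == 3.0 and hi[0] == 7.0
        assert list(model.score(pd.DataFrame({"v": [3.0, 7.0, 2.9, 7.1]}))) == [1, 1, 0, 0]

    def test_score_monotone_non_increasing_in_q(self):
        pres = np.random.default_rng(0).uniform(0, 100, 200)
        x = pd.DataFrame({"v": [4.0]})  # fixed probe outside the median
        scores = [self._fit(pres, q).score(x)[0] for q in (0.0, 2.5, 10.0, 25.0)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestFitModel:
    def test_single_class_training_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="both classes"):
            fit_model("GLM", X, [1, 1])

    def test_unknown_algorithm_lists_valid_names(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="GBM"):
            fit_model("BOOSTME", X, [1, 0])

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_data_scores_perfectly_held_out(self, algorithm):
        data = _separable_data()
        evals = evaluate_algorithms([algorithm], data, sre_quantile=0.0, seed=1)
        for ev in evals:
            assert ev.auc == 1.0
            assert ev.tss == 1.0

    def test_regression_learners_skillful_on_a_strong_niche(self, fitted_ensemble):
        # sharp Gaussian niche, low noise: the regression family (GLM, GAM,
        # MARS) should clear the conventional TSS > 0.70 skill bar
        data = fitted_ensemble["data"]
        stack = fitted_ensemble["stack"]
        evals = evaluate_algorithms(
            ["GLM", "GAM", "MARS"],
            data,
            continuous=stack.continuous_names(),
            seed=24,
            categorical_levels=fitted_ensemble["levels"],
        )
        by_alg = {}
        for ev in evals:
            by_alg.setdefault(ev.algorithm, []).append(ev.tss)
        for alg, tss in by_alg.items():
            assert np.mean(tss) > 0.70, alg

    def test_scores_within_unit_interval(self, fitted_ensemble):
        data = fitted_ensemble["data"]
        for m, _tau in fitted_ensemble["committee"].members:
            scores = m.score(data.X)
            assert scores.min() >= 0.0 and scores.max() <= 1.0


class TestPredictMap:
    def test_constant_stack_gives_constant_map(self, fitted_ensemble):
        stack = fitted_ensemble["stack"]
        const_layers = {
            n: s.Layer(l.kind, np.full(stack.grid.shape, 1.0 if l.kind == "categorical" else 0.2))
            for n, l in stack.layers.items()
        }
        const = s.EnvStack(stack.grid, const_layers, stack.mask.copy())
        model = fitted_ensemble["committee"].members[0][0]
        smap = s.predict_map(model, const)
        vals = smap.masked_values()
        assert np.allclose(vals, vals[0])

    def test_sre_map_is_binary(self, small_stack, strong_species):
        occ = s.sample_presences(strong_species, small_stack, 80, seed=5)
        pa = s.sample_pseudo_absences(small_stack, occ, n=300, seed=6)
        cont = small_stack.continuous_names()
        pres = s.extract_values(small_stack, occ)[cont]
        ab = s.extract_values(small_stack, pa)[cont]
        X = pd.concat([pres, ab], ignore_index=True)
        y = np.r_[np.ones(len(pres)), np.zeros(len(ab))]
        model = fit_model("SRE", X, y, continuous=cont)
        smap = s.predict_map(model, small_stack.subset(cont))
        assert set(np.unique(smap.masked_values())) <= {0.0, 1.0}

    def test_map_matches_pointwise_scoring(self, fitted_ensemble):
        stack = fitted_ensemble["stack"]
        model = fitted_ensemble["committee"].members[0][0]
        smap = s.predict_map(model, stack)
        table = stack.table()
        enc = s.encode_predictors(table, model.categorical_levels)
        scores = model.score(enc)
        assert np.allclose(
            smap.values[table["row"], table["col"]], scores, atol=1e-12
        )

    def test_missing_layer_named_in_error(self, fitted_ensemble, small_stack):
        model = fitted_ensemble["committee"].members[0][0]
        partial = small_stack.subset(["precip", "elev"])
        with pytest.raises(KeyError, match="temp"):
            s.predict_map(model, partial)


class TestAuc:
    def test_enumerated_pair_example(self):
        # pairs: (.9,.5)+, (.9,.1)+, (.4,.5)-, (.4,.1)+ -> 3/4
        assert s.auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert s.auc([1.0, 0.9], [0.1, 0.2]) == 1.0
        assert s.auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_matches_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            sp = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 25))
            sa = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 25))
            wins = sum((p > a) + 0.5 * (p == a) for p in sp for a in sa)
            assert s.auc(sp, sa) == pytest.approx(wins / (len(sp) * len(sa)), abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=15),
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=15),
    )
    def test_invariant_under_strictly_increasing_transform(self, sp, sa):
        sp, sa = np.array(sp), np.array(sa)
        assert s.auc(sp, sa) == pytest.approx(s.auc(sp**3, sa**3), abs=1e-12)
        assert s.auc(sp, sa) == pytest.approx(
            s.auc(np.log(sp), np.log(sa)), abs=1e-12
        )


class TestOptimizeTss:
    def test_confusion_matrix_arithmetic(self):
        # at tau = 0.5: TP=40 FN=5 FP=10 TN=45 -> TSS = 40/45 + 45/55 - 1
        scores = np.r_[np.full(40, 0.9), np.full(5, 0.1), np.full(10, 0.9), np.full(45, 0.1)]
        labels = np.r_[np.ones(45), np.zeros(55)].astype(int)
        tau, tss, sens, spec = s.optimize_tss(scores, labels)
        assert tss == pytest.approx(40 / 45 + 45 / 55 - 1, abs=1e-12)
        assert sens == pytest.approx(40 / 45)
        assert spec == pytest.approx(45 / 55)

    def test_perfect_separation_gives_tss_one(self):
        tau, tss, _, _ = s.optimize_tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert tss == 1.0
        assert 0.2 < tau <= 0.8

    def test_uninformative_scores_give_tss_zero(self):
        _, tss, _, _ = s.optimize_tss([0.5] * 10, [1, 0] * 5)
        assert tss == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(4, 50))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            tau, tss, _, _ = s.optimize_tss(scores, labels)
            # oracle: every candidate threshold, brute force
            uniq = np.unique(scores)
            cands = np.unique(np.r_[0.0, (uniq[:-1] + uniq[1:]) / 2, 1.0])
            best = max(
                (np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t) - 1)
                for t in cands
            )
            assert tss == pytest.approx(best, abs=1e-12)
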