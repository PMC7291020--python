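import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lipidflow.discover import (
    DiscoverConfig,
    SelectionThresholds,
    amounts_matrix,
    analyze,
    combined_select,
    crossvalidate,
    differential_test,
    glog,
    glog_autoscale,
    impact_factor,
    iqr_filter,
    median_lower_cl,
    plsda_fit,
    ranking_order,
    top_discriminants,
    vip_scores,
    volcano_select,
)
from lipidflow.preprocess import protein_normalize
from lipidflow.simulate import SimConfig, generate_batch


def _null_matrix(rng, n_samples=6, n_features=50):
    return rng.lognormal(mean=8, sigma=1, size=(n_samples, n_features))


class TestIqrFilter:
    def test_constant_feature_dropped(self):
        X = np.column_stack([np.full(6, 5.0),
                             np.array([1.0, 9, 2, 8, 3, 7])])
        _, keep = iqr_filter(X, keep_fraction=0.5, min_features=0)
        assert list(keep) == [False, True]

    def test_keep_fraction_one_identity(self):
        X = np.random.default_rng(0).uniform(size=(6, 10))
        out, keep = iqr_filter(X, keep_fraction=1.0, min_features=0)
        assert keep.all()
        np.testing.assert_array_equal(out, X)

    def test_counting(self):
        X = np.random.default_rng(1).uniform(size=(6, 1000))
        out, keep = iqr_filter(X, keep_fraction=0.75, min_features=250)
        assert out.shape[1] == 750 and keep.sum() == 750

    def test_noop_below_min_features(self):
        X = np.random.default_rng(2).uniform(size=(6, 100))
        _, keep = iqr_filter(X, keep_fraction=0.5, min_features=250)
        assert keep.all()

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            iqr_filter(np.ones((6, 4)), keep_fraction=0.0)


class TestGlogAutoscale:
    def test_glog_zero_with_unit_offset(self):
        # glog(0) with a = 1 -> log2(1/2) = -1
        assert glog(np.array([0.0]), 1.0)[0] == pytest.approx(-1.0)

    def test_glog_approaches_log2(self):
        a = 1.0
        x = 10.0 * a
        rel_err = abs(glog(np.array([x]), a)[0] - np.log2(x)) / np.log2(x)
        assert rel_err < 0.01

    def test_autoscaled_mean_zero_sd_one(self):
        X = np.random.default_rng(0).lognormal(size=(8, 5))
        Z, _ = glog_autoscale(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_zeroed(self):
        X = np.column_stack([np.full(6, 3.0),
                             np.random.default_rng(0).uniform(1, 2, 6)])
        Z, _ = glog_autoscale(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)

    def test_offset_is_min_positive(self):
        X = np.array([[0.0, 5.0], [2.0, 7.0]])
        _, a = glog_autoscale(X)
        assert a == 2.0


class TestDifferentialTest:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(10, 20, size=5)
        X = np.tile(row, (6, 1))
        Z, _ = glog_autoscale(X)
        y = np.array([0, 0, 0, 1, 1, 1])
        stats = differential_test(X, Z, y)
        np.testing.assert_allclose(stats["fold_change"], 1.0)
        np.testing.assert_allclose(stats["q_fdr"], 1.0, atol=0.02)

    def test_null_fdr_control(self):
        # fraction with q < 0.05 averaged over 20 null replicates stays <= 0.05
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _null_matrix(rng, 6, 1000)
            Z, _ = glog_autoscale(X)
            y = np.array([0, 0, 0, 1, 1, 1])
            stats = differential_test(X, Z, y)
            fracs.append((stats["q_fdr"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_power_on_spiked_features(self):
        # FC 4 spikes at n = 3+3, sigma = 0.1 recovered with q < 0.05 in
        # >= 95% of replicates (pooled-variance t: at n = 3 per group the
        # Welch degrees-of-freedom penalty costs a few percent of power)
        hits, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            base = rng.lognormal(mean=8, sigma=1, size=200)
            noise = rng.lognormal(sigma=0.1, size=(6, 200))
            X = base[None, :] * noise
            spiked = rng.choice(200, size=10, replace=False)
            X[3:, spiked] *= 4.0
            Z, _ = glog_autoscale(X)
            y = np.array([0, 0, 0, 1, 1, 1])
            stats = differential_test(X, Z, y, equal_var=True)
            hits += (stats["q_fdr"].to_numpy()[spiked] < 0.05).sum()
            total += len(spiked)
        assert hits / total >= 0.95

    def test_zero_control_mean_undefined_fc(self):
        X = np.ones((6, 2))
        X[:3, 0] = 0.0  # control group zero
        Z, _ = glog_autoscale(X)
        y = np.array([0, 0, 0, 1, 1, 1])
        stats = differential_test(X, Z, y)
        assert np.isnan(stats["fold_change"].iloc[0])
        sel, _, _ = volcano_select(stats)
        assert not sel[0]

    def test_bh_qvalues_monotone_in_p_order(self):
        rng = np.random.default_rng(5)
        X = _null_matrix(rng, 8, 100)
        Z, _ = glog_autoscale(X)
        y = np.array([0] * 4 + [1] * 4)
        stats = differential_test(X, Z, y)
        ordered = stats.sort_values("p_raw")["q_fdr"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()


class TestVolcanoSelect:
    def _stats(self, fc, q):
        return pd.DataFrame({"fold_change": fc, "q_fdr": q})

    def test_fc_exactly_two_not_selected(self):
        sel, n_up, n_down = volcano_select(self._stats([2.0], [0.001]))
        assert not sel[0] and n_up == 0

    def test_down_direction_counted(self):
        sel, n_up, n_down = volcano_select(self._stats([0.4], [0.01]))
        assert sel[0] and n_down == 1 and n_up == 0

    def test_printed_split_percentage(self):
        # 514 up / 118 down -> 81.3% elevated
        n_up, n_down = 514, 118
        assert round(100.0 * n_up / (n_up + n_down), 1) == 81.3


class TestPlsda:
    def _toy(self):
        y = np.array([0.0, 0, 1, 1])
        Z = np.column_stack([
            np.array([-1.0, -1, 1, 1]),
            np.array([-1.0, 1, -1, 1]),  # orthogonal to y
        ])
        return Z, y

    def test_single_informative_feature_weight(self):
        Z, y = self._toy()
        model = plsda_fit(Z, y, 1)
        assert abs(model.weights[0, 0]) > 0.99

    def test_vip_hand_algebra_two_features(self):
        # one informative + one orthogonal feature, single component:
        # VIP = (sqrt(2), 0)
        Z, y = self._toy()
        model = plsda_fit(Z, y, 1)
        vip = vip_scores(model)
        assert vip[0] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert vip[1] == pytest.approx(0.0, abs=1e-9)

    def test_determinism_on_duplicated_samples(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(8, 5))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m1 = plsda_fit(Z, y, 2)
        m2 = plsda_fit(Z.copy(), y.copy(), 2)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.scores, m2.scores)

    def test_orthogonal_noise_later_components_explain_less(self):
        # one informative feature + noise columns orthogonal to the response:
        # component 1 captures the signal, later components explain ~nothing
        rng = np.random.default_rng(3)
        y = np.array([0.0] * 6 + [1.0] * 6)
        yc = y - y.mean()
        noise = rng.normal(size=(12, 5))
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)  # orthogonalize to y
        Z = np.column_stack([yc, noise])
        model = plsda_fit(Z, y, 3)
        assert (np.diff(model.explained_y) <= 1e-9).all()
        assert model.explained_y[0] > 0.99
        assert np.all(model.explained_y[1:] < 1e-6)

    def test_too_many_components(self):
        Z, y = self._toy()
        with pytest.raises(ValueError):
            plsda_fit(Z, y, 5)

    def test_vip_mean_square_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Z = rng.normal(size=(8, 6))
            y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
            model = plsda_fit(Z, y, 2)
            vip = vip_scores(model)
            assert np.mean(vip ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_matches_sklearn_predictions(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(10, 7))
        y = np.array([0.0] * 5 + [1.0] * 5)
        model = plsda_fit(Z, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(Z, y)
        np.testing.assert_allclose(
            model.predict(Z), ref.predict(Z).ravel(), atol=1e-8)


class TestCrossvalidate:
    def test_strong_signal_high_q2(self):
        rng = np.random.default_rng(0)
        y = np.array([0.0] * 5 + [1.0] * 5)
        signal = np.outer(y - y.mean(), rng.uniform(1, 2, 20))
        Z = signal + rng.normal(scale=0.05, size=(10, 20))
        r2, q2 = crossvalidate(Z, y, 2)
        assert q2 > 0.8

    def test_pure_noise_median_q2_nonpositive(self):
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(8, 30))
            y = np.array([0.0] * 4 + [1.0] * 4)
            _, q2 = crossvalidate(Z, y, 2)
            q2s.append(q2)
        assert np.median(q2s) <= 0.0

    def test_r2_at_least_q2(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(10, 15))
            y = np.array([0.0] * 5 + [1.0] * 5)
            r2, q2 = crossvalidate(Z, y, 2)
            assert r2 >= q2


class TestImpactFactor:
    def test_fc_one_gives_zero(self):
        assert impact_factor(0.0, 0.01, 2.0) == 0.0

    def test_hand_computed_value(self):
        # FC 2, p 0.05, VIP 1 -> 1 * 1.30103 * 1
        val = impact_factor(np.log2(2.0), 0.05, 1.0)
        assert val == pytest.approx(1.30103, abs=1e-5)

    def test_p_one_gives_zero(self):
        assert impact_factor(1.0, 1.0, 1.0) == 0.0

    def test_p_zero_clipped(self):
        val = impact_factor(1.0, 0.0, 1.0)
        assert np.isfinite(val) and val > 0

    def test_monotone_in_each_argument(self):
        base = impact_factor(1.0, 0.01, 1.0)
        assert impact_factor(2.0, 0.01, 1.0) > base
        assert impact_factor(1.0, 0.001, 1.0) > base
        assert impact_factor(1.0, 0.01, 2.0) > base


class TestCombinedSelect:
    def _stats(self):
        return pd.DataFrame({
            "feature_id": ["a", "b", "c"],
            "log2_fc": [2.0, 2.0, 0.5],
            "selected_volcano": [True, False, True],
            "vip": [1.5, 1.5, 0.5],
            "impact_factor": [3.0, 2.0, 1.0],
        })

    def test_intersection_rule(self):
        sel = combined_select(self._stats())
        assert list(sel) == [True, False, False]

    def test_subset_of_volcano(self):
        stats = self._stats()
        sel = combined_select(stats)
        assert not np.any(sel & ~stats["selected_volcano"].to_numpy())

    def test_empty_intersection_ok(self):
        stats = self._stats()
        stats["vip"] = 0.1
        assert combined_select(stats).sum() == 0


class TestTopDiscriminants:
    def _stats(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "feature_id": [f"F{i:03d}" for i in range(n)],
            "log2_fc": rng.normal(size=n),
            "impact_factor": rng.uniform(size=n),
        })

    def test_n1_is_argmax(self):
        stats = self._stats()
        top = top_discriminants(stats, 1)
        assert top["impact_factor"].iloc[0] == stats["impact_factor"].max()

    def test_stable_under_permutation(self):
        stats = self._stats(20)
        shuffled = stats.sample(frac=1, random_state=1).reset_index(drop=True)
        a = top_discriminants(stats, 5)["feature_id"].tolist()
        b = top_discriminants(shuffled, 5)["feature_id"].tolist()
        assert a == b

    def test_fewer_than_n_returns_all(self):
        stats = self._stats(3)
        assert len(top_discriminants(stats, 100)) == 3

    def test_tie_break_by_abs_fc_then_id(self):
        stats = pd.DataFrame({
            "feature_id": ["b", "a", "c"],
            "log2_fc": [1.0, 2.0, 2.0],
            "impact_factor": [5.0, 5.0, 5.0],
        })
        assert top_discriminants(stats, 3)["feature_id"].tolist() == \
            ["a", "c", "b"]


def _binomial_median_ci_oracle(n, confidence=0.95):
    """Largest k with P(Binomial(n, 1/2) < k) <= alpha/2, by enumeration."""
    alpha = (1 - confidence) / 2
    k = 1
    for cand in range(1, n + 1):
        below = sum(sps.binom.pmf(i, n, 0.5) for i in range(cand))
        if below <= alpha + 1e-12:
            k = cand
    return k


class TestMedianLowerCl:
    def test_exact_binomial_oracle_1_to_9(self):
        values = np.arange(1, 10, dtype=float)
        k = _binomial_median_ci_oracle(9)
        assert k == 2  # frozen from the enumeration oracle
        assert median_lower_cl(values) == float(np.sort(values)[k - 1]) == 2.0

    @pytest.mark.parametrize("n", [5, 9, 15, 30, 101])
    def test_matches_oracle_across_sizes(self, n):
        rng = np.random.default_rng(n)
        values = rng.normal(size=n)
        k = _binomial_median_ci_oracle(n)
        assert median_lower_cl(values) == float(np.sort(values)[k - 1])

    def test_bootstrap_method_close_for_large_n(self):
        rng = np.random.default_rng(0)
        values = rng.normal(loc=10, size=200)
        order = median_lower_cl(values, method="order")
        boot = median_lower_cl(values, method="bootstrap", seed=1)
        assert abs(order - boot) < 0.2

    def test_empty_error(self):
        with pytest.raises(ValueError):
            median_lower_cl([])


class TestClassIfDiscrimination:
    def test_all_equal_ifs_none_pass(self):
        from lipidflow.discover import class_if_discrimination
        stats = pd.DataFrame({
            "feature_id": [f"F{i}" for i in range(10)],
            "impact_factor": [3.0] * 10,
            "selected_combined": [True] * 10,
        })
        classes = pd.Series({f"F{i}": "PC" if i < 5 else "Cer"
                             for i in range(10)})
        summaries, cutoff = class_if_discrimination(stats, classes)
        assert cutoff == 3.0
        assert all(not s.passes_cutoff for s in summaries)

    def test_top_decile_class_passes(self):
        from lipidflow.discover import class_if_discrimination
        rng = np.random.default_rng(0)
        n = 100
        ifs = rng.uniform(1, 5, size=n)
        classes = {}
        for i in range(n):
            classes[f"F{i}"] = "CE" if i < 10 else "PC"
        ifs[:10] = rng.uniform(9, 10, size=10)  # CE uniformly top-decile
        stats = pd.DataFrame({
            "feature_id": [f"F{i}" for i in range(n)],
            "impact_factor": ifs,
            "selected_combined": [True] * n,
        })
        summaries, cutoff = class_if_discrimination(stats, pd.Series(classes))
        by_class = {s.lipid_class: s for s in summaries}
        assert by_class["CE"].passes_cutoff

    def test_low_n_flagged(self):
        from lipidflow.discover import class_if_discrimination
        stats = pd.DataFrame({
            "feature_id": ["F0", "F1", "F2", "F3"],
            "impact_factor": [1.0, 2.0, 3.0, 4.0],
            "selected_combined": [True] * 4,
        })
        classes = pd.Series({"F0": "PC", "F1": "PC", "F2": "PC", "F3": "CE"})
        summaries, _ = class_if_discrimination(stats, classes)
        by_class = {s.lipid_class: s for s in summaries}
        assert by_class["CE"].low_n and not by_class["PC"].low_n


class TestAnalyzeEndToEnd:
    def test_spiked_batch_recovery(self):
        cfg = SimConfig(seed=42, n_case=6, n_control=6, noise_cv=0.1,
                        n_random_spikes=10, random_spike_fc=4.0)
        ft, manifest = generate_batch(cfg)
        ft = protein_normalize(ft)
        result = analyze(ft, "CF", "H",
                         DiscoverConfig(iqr_keep_fraction=1.0))
        stats = result.stats.set_index("feature_id")
        spiked_q = stats.loc[manifest.spiked, "q_fdr"]
        assert (spiked_q < 0.05).mean() >= 0.9
        # combined selection subset invariant
        assert not np.any(result.stats["selected_combined"]
                          & ~result.stats["selected_volcano"])

    def test_if_composition_invariant(self):
        cfg = SimConfig(seed=2, n_case=4, n_control=4, n_random_spikes=5)
        ft, _ = generate_batch(cfg)
        ft = protein_normalize(ft)
        result = analyze(ft, "CF", "H")
        s = result.stats
        expected = impact_factor(s["log2_fc"].to_numpy(),
                                 s["q_fdr"].to_numpy(), s["vip"].to_numpy())
        np.testing.assert_allclose(
            s["impact_factor"].to_numpy(), expected, equal_nan=True)
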