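import numpy as np
import pandas as pd
import pytest

from batchrank import SimConfig, merge_experiments
from batchrank.linearbcm import (apply_combat, correct_combat, correct_limma,
                                 correct_naive_ruv, correct_q_combat,
                                 fit_combat, load_housekeeping_genes,
                                 quantile_normalize)
from batchrank.simulate import simulate_microarray_meta

from conftest import make_meta


class TestQuantileNormalize:
    def test_two_column_order_statistics(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = [5.0, 1.0, 3.0]
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_ties_get_mean_of_reference_ranks(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 4.0], "b": [2.0, 3.0, 5.0]})
        out = quantile_normalize(m)
        ref = (np.sort(m["a"]) + np.sort(m["b"])) / 2  # [1.5, 2.0, 4.5]
        # tied entries of column a share the mean of reference ranks 1-2
        np.testing.assert_allclose(out["a"], [(ref[0] + ref[1]) / 2,
                                              (ref[0] + ref[1]) / 2, ref[2]])
        np.testing.assert_allclose(out["b"], ref)

    def test_matches_rank_and_average_oracle(self, rng):
        values = rng.integers(0, 6, size=(30, 5)).astype(float)  # many ties
        m = pd.DataFrame(values, columns=list("abcde"))
        out = quantile_normalize(m)
        ref = np.sort(values, axis=0).mean(axis=1)
        for j in range(5):
            col = values[:, j]
            expected = np.empty(30)
            for i, v in enumerate(col):
                positions = np.where(np.sort(col) == v)[0]
                expected[i] = ref[positions].mean()
            np.testing.assert_allclose(out.iloc[:, j], expected, atol=1e-12)

    def test_single_sample_warns_and_returns_input(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())


class TestLimma:
    def test_symmetric_offsets_removed(self):
        meta = make_meta([[1.0, 1.0, 3.0, 3.0]], ["A", "A", "B", "B"])
        out = correct_limma(meta, preserve_bio=False)
        np.testing.assert_allclose(out.matrix.to_numpy(), 2.0)

    def test_single_batch_is_identity(self, rng):
        values = rng.normal(size=(10, 4))
        meta = make_meta(values, ["A"] * 4, strict=False)
        out = correct_limma(meta, preserve_bio=False)
        np.testing.assert_allclose(out.matrix.to_numpy(), values)

    def test_matches_normal_equations_oracle(self, rng):
        values = rng.normal(size=(20, 12))
        batch = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        bio = ["x", "y"] * 6
        meta = make_meta(values, batch, bio)
        out = correct_limma(meta, preserve_bio=True)
        # explicit normal-equations solve with the same coding
        n = 12
        X = np.zeros((n, 4))
        X[:, 0] = 1.0
        X[:, 1] = [1.0 if b == "y" else 0.0 for b in bio]
        for i, b in enumerate(batch):
            if b == "A":
                X[i, 2] = 1.0
            elif b == "B":
                X[i, 3] = 1.0
            else:
                X[i, 2] = X[i, 3] = -1.0
        expected = np.empty_like(values)
        for g in range(20):
            beta = np.linalg.solve(X.T @ X, X.T @ values[g])
            expected[g] = values[g] - X[:, 2:] @ beta[2:]
        np.testing.assert_allclose(out.matrix.to_numpy(), expected, atol=1e-10)

    def test_grand_mean_preserved(self, rng):
        values = rng.normal(5, 1, size=(15, 10))
        meta = make_meta(values, ["A"] * 5 + ["B"] * 5)
        out = correct_limma(meta, preserve_bio=False)
        np.testing.assert_allclose(out.matrix.mean(axis=1), values.mean(axis=1),
                                   atol=1e-10)

    def test_confounded_design_rejected(self):
        meta = make_meta(np.zeros((3, 4)) + np.arange(4), ["A", "A", "B", "B"],
                         ["x", "x", "y", "y"])
        with pytest.raises(ValueError, match="rank-deficient"):
            correct_limma(meta, preserve_bio=True)


def combat_oracle(values, codes, mode="parametric"):
    """Step-by-step EB location/scale oracle, scalar math per batch/gene."""
    G, n = values.shape
    B = codes.max() + 1
    n_b = np.array([(codes == b).sum() for b in range(B)])
    X = np.zeros((n, B))
    for i, c in enumerate(codes):
        X[i, c] = 1.0
    beta = np.linalg.solve(X.T @ X, X.T @ values.T)
    grand = (n_b / n) @ beta
    resid = values.T - X @ beta
    var_pooled = (resid**2).sum(axis=0) / n
    Z = (values - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.column_stack([Z[:, codes == b].mean(axis=1) for b in range(B)])
    delta_hat = np.column_stack([Z[:, codes == b].var(axis=1, ddof=1) for b in range(B)])
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    hyper = []
    for b in range(B):
        gbar = gamma_hat[:, b].mean()
        t2 = gamma_hat[:, b].var(ddof=1)
        m, s2 = delta_hat[:, b].mean(), delta_hat[:, b].var(ddof=1)
        a = (2 * s2 + m**2) / s2
        bb = (m * s2 + m**3) / s2
        hyper.append((gbar, t2, a, bb))
        if mode == "parametric":
            g_old = gamma_hat[:, b].copy()
            d_old = delta_hat[:, b].copy()
            Zb = Z[:, codes == b]
            for _ in range(100):
                g_new = (t2 * n_b[b] * gamma_hat[:, b] + d_old * gbar) / (t2 * n_b[b] + d_old)
                d_new = (0.5 * ((Zb - g_new[:, None]) ** 2).sum(axis=1) + bb) / (
                    n_b[b] / 2 + a - 1)
                change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                             np.max(np.abs(d_new - d_old) / np.abs(d_old)))
                g_old, d_old = g_new, d_new
                if change <= 1e-4:
                    break
            gamma_star[:, b], delta_star[:, b] = g_old, d_old
        else:
            Zb = Z[:, codes == b]
            for i in range(G):
                num_g = num_d = den = 0.0
                for j in range(G):
                    if j == i:
                        continue
                    lik = np.prod(
                        np.exp(-((Zb[i] - gamma_hat[j, b]) ** 2) / (2 * delta_hat[j, b]))
                        / np.sqrt(2 * np.pi * delta_hat[j, b]))
                    num_g += lik * gamma_hat[j, b]
                    num_d += lik * delta_hat[j, b]
                    den += lik
                gamma_star[i, b] = num_g / den
                delta_star[i, b] = num_d / den
    adjusted = np.empty_like(values)
    for i, c in enumerate(codes):
        adjusted[:, i] = ((Z[:, i] - gamma_star[:, c]) / np.sqrt(delta_star[:, c])
                          * np.sqrt(var_pooled) + grand)
    return dict(grand=grand, var_pooled=var_pooled, Z=Z, gamma_hat=gamma_hat,
                delta_hat=delta_hat, gamma_star=gamma_star, delta_star=delta_star,
                hyper=hyper, corrected=adjusted)


FIXED_5x12 = np.array([
    [6.1, 6.9, 7.3, 6.4, 7.8, 6.6, 8.9, 9.4, 8.7, 9.9, 8.2, 9.0],
    [5.2, 5.8, 5.5, 6.1, 5.0, 5.6, 5.9, 6.3, 5.4, 6.0, 5.7, 6.2],
    [8.0, 7.1, 7.7, 8.4, 7.5, 7.9, 6.2, 6.8, 6.0, 6.5, 7.0, 6.4],
    [4.4, 5.1, 4.9, 4.2, 5.3, 4.6, 4.8, 5.5, 4.3, 5.0, 5.2, 4.7],
    [9.3, 8.8, 9.6, 9.1, 8.5, 9.0, 10.4, 10.9, 10.1, 10.6, 11.0, 10.2],
])
CODES_5x12 = np.array([0] * 6 + [1] * 6)


class TestCombat:
    @pytest.mark.parametrize("mode", ["parametric", "nonparametric"])
    def test_matches_step_by_step_oracle(self, mode):
        meta = make_meta(FIXED_5x12, ["A"] * 6 + ["B"] * 6)
        fit = fit_combat(meta, mode=mode, preserve_bio=False)
        oracle = combat_oracle(FIXED_5x12, CODES_5x12, mode=mode)
        np.testing.assert_allclose(fit.grand_mean, oracle["grand"], atol=1e-6)
        np.testing.assert_allclose(fit.var_pooled, oracle["var_pooled"], atol=1e-6)
        np.testing.assert_allclose(fit.gamma_hat, oracle["gamma_hat"], atol=1e-6)
        np.testing.assert_allclose(fit.delta_hat, oracle["delta_hat"], atol=1e-6)
        for b in range(2):
            gbar, t2, a, bb = oracle["hyper"][b]
            assert abs(fit.gamma_bar[b] - gbar) < 1e-6
            assert abs(fit.t2[b] - t2) < 1e-6
            assert abs(fit.a_prior[b] - a) < 1e-6
            assert abs(fit.b_prior[b] - bb) < 1e-6
        np.testing.assert_allclose(fit.gamma_star, oracle["gamma_star"], atol=1e-6)
        np.testing.assert_allclose(fit.delta_star, oracle["delta_star"], atol=1e-6)
        out = apply_combat(meta, fit)
        np.testing.assert_allclose(out.matrix.to_numpy(), oracle["corrected"], atol=1e-6)

    def test_no_batch_effect_data_little_changed(self):
        rng = np.random.default_rng(5)
        values = rng.normal(7.0, 1.0, size=(50, 200))
        meta = make_meta(values, ["A"] * 100 + ["B"] * 100)
        out = correct_combat(meta, mode="parametric", preserve_bio=False)
        mean_abs_change = np.abs(out.matrix.to_numpy() - values).mean(axis=1)
        assert mean_abs_change.mean() < 0.05

    def test_constant_location_shift_removed_on_average(self):
        # a +2 shift common to all genes: EB shrinkage pulls every gene to the
        # common batch mean, leaving only diluted sampling noise
        rng = np.random.default_rng(6)
        values = rng.normal(7.0, 1.0, size=(50, 800))
        values[:, 400:] += 2.0
        meta = make_meta(values, ["A"] * 400 + ["B"] * 400)
        out = correct_combat(meta, mode="parametric", preserve_bio=False)
        corrected = out.matrix.to_numpy()
        diff = corrected[:, :400].mean(axis=1) - corrected[:, 400:].mean(axis=1)
        assert np.abs(diff).mean() < 0.05

    def test_model_generated_location_shifts_removed(self):
        # per-gene batch offsets drawn from the location/scale model: the EB
        # posterior tracks each gene, residual batch mean differences vanish
        cfg = SimConfig(n_genes=200, seed=3, batch_scale_sd=0.0,
                        batches=[{"id": "A", "n_samples": 100},
                                 {"id": "B", "n_samples": 100}])
        exps, _ = simulate_microarray_meta(cfg)
        meta = merge_experiments(exps, "disease")
        out = correct_combat(meta, mode="parametric")
        corrected = out.matrix.to_numpy()
        a = (meta.batch == "A").to_numpy()
        diff = corrected[:, a].mean(axis=1) - corrected[:, ~a].mean(axis=1)
        assert np.abs(diff).max() < 0.05

    def test_zero_variance_batch_floored_with_warning(self):
        values = np.array([[1.0, 1.0, 1.0, 2.0, 3.0, 2.5],
                           [2.0, 3.0, 4.0, 3.0, 2.0, 4.0]])
        meta = make_meta(values, ["A"] * 3 + ["B"] * 3)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_combat(meta, mode="parametric", preserve_bio=False)
        assert np.isfinite(fit.delta_star).all() and (fit.delta_star > 0).all()


class TestQCombat:
    def test_equals_manual_composition(self):
        meta = make_meta(FIXED_5x12, ["A"] * 6 + ["B"] * 6)
        out = correct_q_combat(meta, preserve_bio=False)
        qn = quantile_normalize(meta.matrix)
        manual = correct_combat(meta, mode="parametric", preserve_bio=False, matrix=qn)
        np.testing.assert_array_equal(out.matrix.to_numpy(), manual.matrix.to_numpy())

    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 3.0, 8.0])
        values = np.tile(col[:, None], (1, 6))
        meta = make_meta(values, ["A"] * 3 + ["B"] * 3)
        out = correct_q_combat(meta, preserve_bio=False)
        np.testing.assert_allclose(out.matrix.to_numpy(), values, atol=1e-6)

    def test_residual_batch_difference_small_on_shifted_data(self):
        cfg = SimConfig(n_genes=200, seed=3, batch_scale_sd=0.0,
                        batches=[{"id": "A", "n_samples": 100},
                                 {"id": "B", "n_samples": 100}])
        exps, _ = simulate_microarray_meta(cfg)
        meta = merge_experiments(exps, "disease")
        out = correct_q_combat(meta)
        corrected = out.matrix.to_numpy()
        a = meta.batch.to_numpy() == "A"
        diff = corrected[:, a].mean(axis=1) - corrected[:, ~a].mean(axis=1)
        assert np.abs(diff).mean() < 0.05


class TestNaiveRuv:
    def test_huge_ridge_is_identity(self, rng):
        values = rng.normal(0, 1, size=(120, 10))
        meta = make_meta(values, ["A"] * 5 + ["B"] * 5)
        out = correct_naive_ruv(meta, controls="empirical", k=2, nu=1e12)
        assert np.abs(out.matrix.to_numpy() - values).max() < 1e-6

    def test_matches_svd_ridge_oracle(self, rng):
        values = rng.normal(0, 1, size=(120, 16))
        meta = make_meta(values, ["A"] * 8 + ["B"] * 8)
        out = correct_naive_ruv(meta, controls="empirical", k=2, nu=1.0)
        ctrl = out.params["n_controls"]
        fit = out._fit
        Yt = values.T
        idx = meta.matrix.index.get_indexer(fit.controls)
        U, s, _ = np.linalg.svd(Yt[:, idx], full_matrices=False)
        W = U[:, :2] * s[:2]
        alpha = np.linalg.solve(W.T @ W + np.eye(2), W.T @ Yt)
        np.testing.assert_allclose(out.matrix.to_numpy(), (Yt - W @ alpha).T, atol=1e-10)

    def test_housekeeping_mode_uses_packaged_list(self, rng):
        hk = load_housekeeping_genes()
        assert "ACTB" in hk and len(hk) >= 50
        genes = hk[:30] + [f"g{i}" for i in range(90)]
        values = rng.normal(7, 1, size=(120, 8))
        matrix = pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(8)])
        meta = make_meta(values, ["A"] * 4 + ["B"] * 4)
        meta.matrix.index = pd.Index(genes)
        out = correct_naive_ruv(meta, controls="housekeeping", k=2)
        assert out.params["n_controls"] == 30

    def test_empty_housekeeping_intersection_suggests_empirical(self, micro_sim):
        _, _, meta = micro_sim
        with pytest.raises(ValueError, match="empirical"):
            correct_naive_ruv(meta, controls="housekeeping", k=2)

    def test_k_out_of_bounds_rejected(self, micro_sim):
        _, _, meta = micro_sim
        with pytest.raises(ValueError, match="k="):
            correct_naive_ruv(meta, controls="empirical", k=100)


class TestInvariants:
    def test_corrections_preserve_shape_labels_finite(self, micro_sim):
        _, _, meta = micro_sim
        for result in [
            correct_limma(meta),
            correct_combat(meta, mode="parametric"),
            correct_combat(meta, mode="nonparametric"),
            correct_q_combat(meta),
            correct_naive_ruv(meta, controls="empirical"),
        ]:
            result.check_against(meta)  # raises on misalignment / non-finite
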