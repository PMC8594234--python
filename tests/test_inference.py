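import numpy as np
import pandas as pd
import pytest

import gutnet as gn
from gutnet.errors import UsageError
from gutnet.inference import (
    _fit_cov,
    cclasso_fit,
    clr_transform,
    permutation_edge_pvalues,
)


class TestClrTransform:
    def test_equal_parts_give_zero(self):
        table = pd.DataFrame([[1, 2], [1, 2], [1, 2], [1, 2]],
                             index=list("abcd"), columns=["s1", "s2"])
        clr = clr_transform(gn.CountMatrix(table), pseudocount=0.5)
        assert np.allclose(clr.values.to_numpy(), 0.0)

    def test_hand_computed_column(self):
        table = pd.DataFrame([[1, 1], [3, 1]], index=["a", "b"],
                             columns=["s1", "s2"])
        clr = clr_transform(gn.CountMatrix(table), pseudocount=0.5)
        col = clr.values["s1"].to_numpy()
        expected = 0.5 * (np.log(3.5) - np.log(1.5))
        assert col == pytest.approx([-expected, expected])
        assert expected == pytest.approx(0.4236, abs=1e-4)

    def test_columns_sum_to_zero(self):
        cm = gn.generate_null_counts(30, 12, depth=5000, seed=1)
        clr = clr_transform(cm)
        assert np.allclose(clr.values.to_numpy().sum(axis=0), 0.0, atol=1e-9)

    def test_pseudocount_validation(self, small_counts):
        with pytest.raises(UsageError):
            clr_transform(small_counts, pseudocount=0.0)


class TestCclassoFit:
    def test_large_lambda_kills_all_edges(self):
        cm = gn.generate_null_counts(50, 6, depth=10000, seed=3)
        fit = cclasso_fit(clr_transform(cm), lam=100.0)
        off = fit.corr.to_numpy() - np.eye(6)
        assert np.all(off == 0.0)

    def test_null_data_off_diagonals_small(self):
        cm = gn.generate_null_counts(500, 6, depth=10000, seed=3)
        fit = cclasso_fit(clr_transform(cm), lam=0.05)
        off = np.abs(fit.corr.to_numpy() - np.eye(6))
        assert off.max() < 0.1

    def test_planted_pair_recovered_and_dominant(self):
        p = 10
        corr = np.eye(p)
        corr[0, 1] = corr[1, 0] = 0.9
        cm = gn.generate_correlated_counts(300, p, corr, 10000, seed=5)
        fit = cclasso_fit(clr_transform(cm), lam="cv", seed=0)
        m = fit.corr.to_numpy()
        assert m[0, 1] > 0.5
        assert m[0, 1] == np.max(np.abs(m[0, np.arange(p) != 0]))

    def test_output_is_correlation_matrix(self):
        cm = gn.generate_null_counts(40, 8, depth=8000, seed=9)
        fit = cclasso_fit(clr_transform(cm), lam=0.02)
        m = fit.corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.abs(m).max() <= 1.0
        assert np.linalg.eigvalsh(m).min() > -1e-8

    def test_matches_general_purpose_solver_on_toy(self):
        # p=3 problems against SLSQP with an explicit PSD constraint
        from scipy.optimize import minimize

        p = 3
        g = np.eye(p) - np.ones((p, p)) / p
        for seed, lam in [(1, 0.02), (3, 0.05), (4, 0.2)]:
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((p, 200))
            z[1] += 1.5 * z[0]
            z[2] -= 0.7 * z[0]
            x = z - z.mean(axis=0, keepdims=True)
            s = np.cov(x, ddof=1)

            def unpack(v):
                m = np.zeros((p, p))
                m[np.triu_indices(p)] = v
                return m + np.triu(m, 1).T

            def objective(v):
                m = unpack(v)
                r = s - g @ m @ g
                return 0.5 * np.sum(r * r) + lam * np.sum(
                    np.abs(m[np.triu_indices(p, 1)])
                )

            res = minimize(
                objective,
                s[np.triu_indices(p)],
                constraints=[{"type": "ineq",
                              "fun": lambda v: np.linalg.eigvalsh(unpack(v)).min()}],
                method="SLSQP",
                options={"maxiter": 2000, "ftol": 1e-15},
            )
            sigma, _, _ = _fit_cov(s, lam, tol=1e-12, max_iter=100000)
            assert np.abs(unpack(res.x) - sigma).max() < 1e-4

    def test_invariant_to_sample_order_and_taxon_relabeling(self):
        cm = gn.generate_null_counts(40, 6, depth=8000, seed=12)
        clr = clr_transform(cm)
        fit = cclasso_fit(clr, lam=0.03)
        # permute samples
        perm_cols = list(np.random.default_rng(0).permutation(clr.values.columns))
        clr_s = gn.ClrMatrix(clr.values[perm_cols], clr.pseudocount)
        fit_s = cclasso_fit(clr_s, lam=0.03)
        assert np.allclose(fit.corr.to_numpy(), fit_s.corr.to_numpy(), atol=1e-8)
        # permute taxa
        perm_rows = list(np.random.default_rng(1).permutation(clr.values.index))
        clr_t = gn.ClrMatrix(clr.values.loc[perm_rows], clr.pseudocount)
        fit_t = cclasso_fit(clr_t, lam=0.03)
        assert np.allclose(
            fit_t.corr.loc[clr.taxon_ids, clr.taxon_ids].to_numpy(),
            fit.corr.to_numpy(),
            atol=1e-8,
        )

    def test_argument_validation(self):
        cm = gn.generate_null_counts(40, 6, depth=8000, seed=1)
        clr = clr_transform(cm)
        with pytest.raises(UsageError):
            cclasso_fit(clr, lam=-1.0)
        with pytest.raises(UsageError):
            cclasso_fit(clr, lam="aic")


class TestPermutationPvalues:
    def test_add_one_minimum(self):
        p_min = 1.0 / 201.0
        assert p_min == pytest.approx(0.004975, abs=1e-6)
        assert p_min < 0.005  # the only attainable value below the threshold

    def test_pvalue_range_and_symmetry(self):
        cm = gn.generate_null_counts(60, 8, depth=8000, seed=21)
        clr = clr_transform(cm)
        pv, corr = permutation_edge_pvalues(clr, fit_lambda=0.02, n_perm=50,
                                            seed=0)
        m = pv.to_numpy()
        assert np.allclose(m, m.T)
        off = m[np.triu_indices(8, 1)]
        assert off.min() >= 1.0 / 51.0 - 1e-12
        assert off.max() <= 1.0

    def test_zero_observed_correlation_has_large_pvalue(self):
        # entries shrunk to exactly 0 can never beat a permutation
        cm = gn.generate_null_counts(60, 8, depth=8000, seed=22)
        clr = clr_transform(cm)
        pv, corr = permutation_edge_pvalues(clr, fit_lambda=0.5, n_perm=30,
                                            seed=1)
        zero_mask = (corr.to_numpy() == 0.0) & ~np.eye(8, dtype=bool)
        assert zero_mask.any()
        assert (pv.to_numpy()[zero_mask] == 1.0).all()

    def test_deterministic_under_seed(self):
        cm = gn.generate_null_counts(40, 6, depth=8000, seed=23)
        clr = clr_transform(cm)
        pv1, _ = permutation_edge_pvalues(clr, 0.02, n_perm=20, seed=5)
        pv2, _ = permutation_edge_pvalues(clr, 0.02, n_perm=20, seed=5)
        assert pv1.equals(pv2)


class TestBuildNetwork:
    def test_planted_pair_recovered_with_sign(self):
        hits = 0
        sign_ok = 0
        for s in range(5):
            corr = np.eye(6)
            corr[0, 1] = corr[1, 0] = 0.9
            cm = gn.generate_correlated_counts(60, 6, corr, 10000, seed=100 + s)
            net = gn.build_network(cm, lam="cv", n_perm=200, seed=s)
            if ("T0001", "T0002") in net.edge_keys():
                hits += 1
                sign_ok += net.edge_signs()[("T0001", "T0002")] == "co-occurrence"
        assert hits >= 4
        assert sign_ok == hits

    def test_negative_pair_labeled_co_exclusion(self):
        corr = np.eye(6)
        corr[0, 1] = corr[1, 0] = -0.9
        cm = gn.generate_correlated_counts(80, 6, corr, 10000, seed=55)
        net = gn.build_network(cm, lam="cv", n_perm=200, seed=3)
        assert net.edge_signs().get(("T0001", "T0002")) == "co-exclusion"

    def test_retained_edges_beat_all_permutations(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.9
        cm = gn.generate_correlated_counts(60, 5, corr, 10000, seed=77)
        net = gn.build_network(cm, lam=0.02, n_perm=200, seed=2)
        # p < 0.005 with 200 permutations is only possible at p = 1/201
        assert np.allclose(net.edges["p_value"], 1.0 / 201.0)

    def test_subset_selection_and_provenance(self):
        design = gn.generate_design(4)
        counts, _ = gn.generate_counts(design, seed=9)
        net = gn.build_network(
            counts, design, subset=("diet", "Ulva"), lam=0.1, n_perm=20, seed=0
        )
        assert net.provenance == "diet=Ulva"
        assert net.params["n_perm"] == 20

    def test_subset_too_small(self):
        design = gn.generate_design(4)
        counts, _ = gn.generate_counts(design, seed=9)
        with pytest.raises(UsageError, match="at least 3"):
            gn.build_network(counts, design, subset=("diet", "nope"))
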