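import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircoex import da
from mircoex.preprocessing import NormalizationFactors
from oracles import bh_oracle, exact_test_oracle, nb_loglik


def _unit_nf(columns, libsize=1_000_000):
    lib = pd.Series([libsize] * len(columns), index=columns)
    return NormalizationFactors(
        library_sizes=lib,
        tmm_factors=pd.Series(1.0, index=columns),
        reference_sample=columns[0],
    )


def _two_group_frame(rng, n_a, n_b, n_features, mean_a, mean_b, phi):
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    mu = np.concatenate([np.full(n_a, mean_a), np.full(n_b, mean_b)])
    counts = rng.poisson(rng.gamma(1 / phi, phi * mu, size=(n_features, n_a + n_b)))
    cm = pd.DataFrame(counts, columns=cols, index=[f"f{i}" for i in range(n_features)])
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
    return cm, groups


class TestDispersions:
    def test_poisson_data_low_estimate(self):
        rng = np.random.default_rng(0)
        cols = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
        cm = pd.DataFrame(rng.poisson(200.0, size=(300, 40)), columns=cols)
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=cols)
        disp = da.estimate_dispersions(cm, groups, shrinkage_weight=0.0)
        assert np.median(disp.phi) < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        cm, groups = _two_group_frame(rng, 20, 20, 400, 200.0, 200.0, phi=0.4)
        disp = da.estimate_dispersions(cm, groups, shrinkage_weight=0.0)
        assert np.median(disp.phi) == pytest.approx(0.4, rel=0.25)

    def test_constant_feature_gets_common(self):
        rng = np.random.default_rng(2)
        cm, groups = _two_group_frame(rng, 4, 4, 50, 100.0, 100.0, phi=0.2)
        cm.iloc[0] = 0
        nf = _unit_nf(list(cm.columns))
        disp = da.estimate_dispersions(cm, groups, nf=nf)
        assert disp.phi.iloc[0] == pytest.approx(disp.phi_common)

    def test_requires_two_per_group(self):
        cm = pd.DataFrame({"a0": [1], "b0": [2]})
        groups = pd.Series(["A", "B"], index=["a0", "b0"])
        with pytest.raises(ValueError):
            da.estimate_dispersions(cm, groups)


class TestExactTest:
    def _run(self, counts_a, counts_b, phi):
        n_a, n_b = len(counts_a), len(counts_b)
        cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        cm = pd.DataFrame([list(counts_a) + list(counts_b)], columns=cols, index=["f0"])
        groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
        nf = _unit_nf(cols)
        disp = da.DispersionEstimates(
            phi=pd.Series([phi], index=["f0"]), phi_common=phi, shrinkage_weight=0.0)
        return da.test_exact(cm, groups, nf, disp).iloc[0]

    def test_symmetric_totals_p_one(self):
        assert self._run([5, 5, 5], [5, 5, 5], phi=0.1) == pytest.approx(1.0)

    def test_all_zero_p_one(self):
        assert self._run([0, 0, 0], [0, 0, 0], phi=0.1) == 1.0

    @pytest.mark.parametrize("sa,sb", [(2, 20), (0, 12), (9, 9), (30, 3)])
    def test_matches_enumeration_oracle(self, sa, sb):
        # equal library sizes -> pseudo-counts equal raw counts
        p_pkg = self._run([sa, 0, 0], [sb, 0, 0], phi=0.1)
        p_oracle = exact_test_oracle(sa, sb, 3, 3, 0.1)
        assert p_pkg == pytest.approx(p_oracle, rel=1e-9)


class TestWaldTest:
    def test_equal_means_p_near_one(self):
        rng = np.random.default_rng(3)
        cm, groups = _two_group_frame(rng, 10, 10, 100, 300.0, 300.0, phi=0.05)
        nf = _unit_nf(list(cm.columns))
        disp = da.estimate_dispersions(cm, groups, nf=nf)
        res = da.test_wald(cm, groups, nf, disp)
        assert np.median(res["p_wald"]) > 0.3
        assert np.median(np.abs(res["log2fc"])) < 0.2

    def test_sign_recovery(self):
        rng = np.random.default_rng(4)
        cm, groups = _two_group_frame(rng, 7, 5, 200, 800.0, 200.0, phi=0.1)
        nf = _unit_nf(list(cm.columns))
        disp = da.estimate_dispersions(cm, groups, nf=nf)
        res = da.test_wald(cm, groups, nf, disp)
        assert (res["log2fc"] > 0).mean() >= 0.95

    def test_agrees_with_lrt_oracle_order_of_magnitude(self):
        from scipy.optimize import minimize_scalar
        from scipy.stats import chi2
        rng = np.random.default_rng(5)
        cm, groups = _two_group_frame(rng, 7, 7, 20, 400.0, 200.0, phi=0.1)
        nf = _unit_nf(list(cm.columns))
        disp = da.estimate_dispersions(cm, groups, nf=nf)
        # the LRT oracle is asymptotic, so compare the asymptotic Wald p
        res = da.test_wald(cm, groups, nf, disp, reference="normal")
        ga = (groups == "A").to_numpy()
        for i in range(10):
            y = cm.iloc[i].to_numpy(float)
            phi = disp.phi.iloc[i]

            def fit(mask):
                def nll(logmu):
                    return -nb_loglik(y[mask], np.exp(logmu), phi)
                r = minimize_scalar(nll, bounds=(-5, 15), method="bounded")
                return -r.fun

            ll_alt = fit(ga) + fit(~ga)
            ll_null = fit(np.ones_like(ga, dtype=bool))
            p_lrt = chi2.sf(2 * (ll_alt - ll_null), df=1)
            p_wald = res["p_wald"].iloc[i]
            if p_lrt < 1e-300 or p_wald < 1e-300:
                continue
            # order-of-magnitude agreement, with slack deep in the tail
            tol = max(1.0, 0.3 * abs(np.log10(p_lrt)))
            assert abs(np.log10(p_wald) - np.log10(p_lrt)) < tol


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(da.bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(da.bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_one(self):
        np.testing.assert_allclose(da.bh_fdr([1.0]), [1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            da.bh_fdr([0.1, float("nan")])

    def test_matches_oracle_random(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(da.bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, pvals):
        adj = da.bh_fdr(pvals)
        assert (adj <= 1.0).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestConsensus:
    def _call(self, pe, pw, alpha=0.05):
        idx = pd.Index([f"f{i}" for i in range(len(pe))])
        return da.consensus_calls(
            pd.Series(pe, index=idx), pd.Series(pw, index=idx),
            pd.Series(np.ones(len(pe)), index=idx), alpha=alpha)

    def test_conjunction_required(self):
        res = self._call([0.01], [0.20])
        assert not res["consensus_de"].iloc[0]

    def test_both_below(self):
        res = self._call([0.01], [0.04])
        assert res["consensus_de"].iloc[0]
        assert res["direction"].iloc[0] == 1

    def test_strict_boundary(self):
        res = self._call([0.05], [0.01])
        assert not res["consensus_de"].iloc[0]
        assert res["direction"].iloc[0] == 0

    def test_misaligned_error(self):
        a = pd.Series([0.1], index=["x"])
        b = pd.Series([0.1], index=["y"])
        with pytest.raises(ValueError):
            da.consensus_calls(a, b, a)

    def test_zero_p_floored(self):
        res = self._call([0.0], [0.0])
        assert res["p_exact"].iloc[0] > 0


class TestNullCalibration:
    def test_consensus_no_less_conservative_than_single_tests(self):
        from mircoex.synthetic import SyntheticConfig, generate_dataset
        from mircoex.preprocessing import filter_low_counts, tmm_factors
        fp_cons = fp_exact = fp_wald = 0
        n_feat = 0
        for seed in range(3):
            cfg = SyntheticConfig(n_samples_per_group={"A": 7, "B": 5}, n_mirna=400,
                                  n_mrna=5, n_de=0, feature_log_sd=0.3, seed=seed)
            ds = generate_dataset(cfg)
            cm = filter_low_counts(ds.mirna_counts)
            nf = tmm_factors(cm)
            res = da.run_contrast(cm, ds.sample_sheet, "A", "B", nf)
            fp_cons += int(res["consensus_de"].sum())
            fp_exact += int((res["fdr_exact"] < 0.05).sum())
            fp_wald += int((res["fdr_wald"] < 0.05).sum())
            n_feat += len(res)
        assert fp_cons <= fp_exact
        assert fp_cons <= fp_wald
        assert fp_cons / n_feat <= 0.02  # nominal FDR control on a complete null
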