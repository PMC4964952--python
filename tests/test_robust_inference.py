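import numpy as np
import pytest
from scipy import special, stats

from cengrm.design_matrix import DesignMatrix
from cengrm.robust_inference import (
    adjusted_lr_test,
    sandwich_covariance,
    term_deletion_table,
)
from cengrm.weibull_grm import fit_design, score_matrix


class FakeDS:
    """Minimal response carrier for array-level inference tests."""

    def __init__(self, t, delta):
        self._t, self._d = np.asarray(t, float), np.asarray(delta, int)

    @property
    def response(self):
        return self._t, self._d, None


def clustered_weibull(rng, n_clu=50, m=30, sigma_b=0.5, beta1=0.4,
                      alpha=1.3, censor_q=0.3):
    """Cluster frailty on the log scale; covariate with equal cluster- and
    site-level components."""
    n = n_clu * m
    cid = np.repeat(np.arange(n_clu), m)
    x = 0.7 * rng.normal(size=n_clu)[cid] + 0.7 * rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    b = rng.normal(0, sigma_b, n_clu)[cid]
    lam = np.exp(1.0 + beta1 * x + b) / special.gamma(1 + 1 / alpha)
    y = lam * rng.weibull(alpha, n)
    dl = np.quantile(y, censor_q)
    delta = (y >= dl).astype(int)
    t = np.where(delta == 1, y, dl)
    return X, t, delta, cid


def named_design(X, names):
    return DesignMatrix(X, names, {n: [j] for j, n in enumerate(names)}, None)


class TestSandwich:
    def test_total_score_vanishes_at_mle(self, rng):
        X, t, delta, cid = clustered_weibull(rng, n_clu=30, m=20)
        fit = fit_design(X, t, delta)
        total = score_matrix(fit.theta, X, t, delta).sum(axis=0)
        assert np.max(np.abs(total)) < 1e-4

    def test_iid_singletons_robust_close_to_naive(self, rng):
        # with one site per subset and a correct model, V converges to
        # H^-1; check the Frobenius error averaged over replicates
        rels = []
        for _ in range(3):
            X, t, delta, _ = clustered_weibull(rng, n_clu=2000, m=1,
                                               sigma_b=0.0)
            fit = fit_design(X, t, delta)
            sw = sandwich_covariance(fit, FakeDS(t, delta), np.arange(2000),
                                     small_sample="none")
            ratio = sw.robust_se[:2] / fit.se()
            assert np.all(ratio > 0.9) and np.all(ratio < 1.1)
            Hinv = np.linalg.inv(sw.H)
            rels.append(np.linalg.norm(sw.V - Hinv) / np.linalg.norm(Hinv))
        assert np.mean(rels) < 0.10

    def test_frailty_inflates_intercept_se(self, rng):
        X, t, delta, cid = clustered_weibull(rng, sigma_b=0.5)
        fit = fit_design(X, t, delta)
        sw = sandwich_covariance(fit, FakeDS(t, delta), cid)
        assert sw.robust_se[0] > fit.se()[0]

    def test_missing_labels_rejected(self, small_dataset):
        from cengrm import ModelSpec, fit_weibull_grm
        from cengrm.spatial_blocks import ClusterAssignment
        import pandas as pd

        fit = fit_weibull_grm(ModelSpec(continuous_terms=("tssc",)),
                              small_dataset)
        ca = ClusterAssignment(labels=pd.Series(
            [1], index=pd.Index(["W000"], name="site_id")))
        with pytest.raises(ValueError, match="without subset label"):
            sandwich_covariance(fit, small_dataset, ca)


class TestAdjustedLR:
    def _fits(self, rng, beta1, sigma_b=0.5):
        X, t, delta, cid = clustered_weibull(rng, beta1=beta1,
                                             sigma_b=sigma_b)
        full = fit_design(X, t, delta,
                          design=named_design(X, ["intercept", "x"]))
        red = fit_design(X[:, [0]], t, delta,
                         design=named_design(X[:, [0]], ["intercept"]))
        sw = sandwich_covariance(full, FakeDS(t, delta), cid)
        return full, red, sw, t, delta

    def test_identical_models_give_zero(self, rng):
        full, red, sw, t, delta = self._fits(rng, beta1=0.3)
        res = adjusted_lr_test(full, full, sw, [], t=t, delta=delta)
        assert res.adjusted_lr == 0.0
        assert res.p_value == 1.0

    def test_adjusted_equals_raw_when_v_is_naive(self, rng):
        # forcing V := H^-1 makes the curvature transformation the identity
        full, red, sw, t, delta = self._fits(rng, beta1=0.3, sigma_b=0.0)
        sw.V = np.linalg.inv(sw.H)
        res = adjusted_lr_test(full, red, sw, [1], t=t, delta=delta)
        assert res.adjusted_lr == pytest.approx(res.raw_lr, rel=1e-4)

    def test_independent_singletons_ratio_near_one(self, rng):
        X, t, delta, _ = clustered_weibull(rng, n_clu=2000, m=1,
                                           sigma_b=0.0, beta1=0.3)
        full = fit_design(X, t, delta,
                          design=named_design(X, ["intercept", "x"]))
        red = fit_design(X[:, [0]], t, delta,
                         design=named_design(X[:, [0]], ["intercept"]))
        sw = sandwich_covariance(full, FakeDS(t, delta), np.arange(2000))
        res = adjusted_lr_test(full, red, sw, [1], t=t, delta=delta)
        assert 0.8 < res.adjusted_lr / res.raw_lr < 1.2

    def test_detects_strong_true_effect(self, rng):
        full, red, sw, t, delta = self._fits(rng, beta1=0.8)
        res = adjusted_lr_test(full, red, sw, [1], t=t, delta=delta)
        assert res.p_value < 1e-6
        assert res.formatted_p() == "0"

    def test_non_nested_rejected(self, rng):
        full, red, sw, t, delta = self._fits(rng, beta1=0.3)
        with pytest.raises(ValueError, match="minus the tested"):
            adjusted_lr_test(full, full, sw, [1], t=t, delta=delta)

    def test_null_pvalues_roughly_uniform(self, rng):
        # under a truly null tested coefficient the adjusted p-values
        # should look uniform across replicates
        pvals = []
        for _ in range(80):
            full, red, sw, t, delta = self._fits(rng, beta1=0.0)
            res = adjusted_lr_test(full, red, sw, [1], t=t, delta=delta)
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTermDeletionTable:
    def test_table_on_synthetic_survey(self):
        from cengrm import (
            ModelSpec,
            bangladesh_like,
            generate_synthetic_survey,
        )
        from cengrm.spatial_blocks import decluster_sites

        ds, _ = generate_synthetic_survey(
            bangladesh_like(seed=21, n_sites=500, n_clusters=60,
                            geology_levels=4, cluster_scatter_km=8.0))
        spec = ModelSpec(continuous_terms=("depth", "tssc", "k_h"),
                         categorical_terms=("geology",),
                         interactions=(("geology", "depth"),
                                       ("geology", "tssc")))
        sv = ds.survey
        ca = decluster_sites(sv["site_id"], sv["lon"], sv["lat"])
        retained = sv["site_id"].isin(ca.labels.index).to_numpy()
        cal = ds.subset(retained)
        table = term_deletion_table(spec, cal, ca)
        assert set(table["factor"]) == {
            "geology and all interactions", "depth and interaction",
            "tssc and interaction", "k_h"}
        geo = table[table["factor"] == "geology and all interactions"]
        assert geo["df"].iloc[0] == 3 + 2 * 3  # (K-1) + 2 interactions
        assert (table.loc[table["status"] == "ok", "p_adjusted"]
                .between(0, 1).all())
        # geology carries real signal in the generator
        assert geo["p_adjusted"].iloc[0] < 0.01
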