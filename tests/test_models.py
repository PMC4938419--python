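import numpy as np
import pandas as pd
import pytest

import hiergst as hg
from hiergst.models import inv_logit
from hiergst.popdata import ValidationError


def synthetic_gst(hier, L, mu_g, mu_c, mu_s, mu_e, theta, noise_sd, rng):
    """Build a GstMatrix whose logit values follow the partitioning model."""
    design = hg.build_design(hier)
    P = len(design)
    theta = np.asarray(theta, dtype=float)
    mean = (
        mu_g
        + design["k_clus"].to_numpy() * mu_c
        + design["k_subclus"].to_numpy() * mu_s
        + design["k_elev"].to_numpy()[None, :] * (mu_e + theta[:, None])
    )
    y = mean + rng.normal(0, noise_sd, size=(L, P))
    rows = []
    for j, (_, pr) in enumerate(design.iterrows()):
        for m in range(L):
            rows.append((f"L{m:03d}", pr["pop_i"], pr["pop_j"], inv_logit(y[m, j]), 1))
    return hg.GstMatrix(pd.DataFrame(rows, columns=hg.GstMatrix.COLUMNS))


def ols_fit(gst, hier):
    """Independent least-squares oracle with sum-to-zero theta contrasts."""
    model = hg.HierarchicalGstModel(gst, hier)
    y = model.y
    L, P = y.shape
    kC, kS, kE = model.k_clus, model.k_subclus, model.k_elev
    cols = [np.ones(P), kC, kS, kE]
    X = np.stack([np.repeat(c[None, :], L, axis=0).ravel() for c in cols], axis=1)
    # sum-to-zero coding: theta_m for m < L-1, theta_{L-1} = -sum(others)
    T = np.zeros((L * P, L - 1))
    for m in range(L - 1):
        T[m * P: (m + 1) * P, m] = kE
    T[(L - 1) * P:, :] -= kE[:, None]
    beta, *_ = np.linalg.lstsq(np.hstack([X, T]), y.ravel(), rcond=None)
    theta = np.append(beta[4:], -beta[4:].sum())
    return beta[:4], theta


class TestBuildDesign:
    def test_pair_encodings(self, hierarchy16):
        d = hg.build_design(hierarchy16).set_index(["pop_i", "pop_j"])
        # same site, different elevation
        row = d.loc[("c1_s1_t1_low", "c1_s1_t1_high")]
        assert tuple(row[["k_clus", "k_subclus", "k_elev"]]) == (0, 0, 1)
        # different clusters, same elevation
        row = d.loc[("c1_s1_t1_low", "c2_s1_t1_low")]
        assert tuple(row[["k_clus", "k_subclus", "k_elev"]]) == (1, 0, 0)
        # same cluster, different sub-clusters, different elevations
        row = d.loc[("c1_s1_t1_low", "c1_s2_t1_high")]
        assert tuple(row[["k_clus", "k_subclus", "k_elev"]]) == (0, 1, 1)

    def test_pair_count_and_exclusivity(self, hierarchy16):
        d = hg.build_design(hierarchy16)
        P = len(hierarchy16.populations)
        assert len(d) == P * (P - 1) // 2
        assert not ((d["k_clus"] == 1) & (d["k_subclus"] == 1)).any()


class TestLogitTransform:
    def test_midpoint(self):
        assert hg.logit_transform(0.5)[0] == pytest.approx(0.0)

    def test_boundary_clamped(self):
        val, n = hg.logit_transform(0.0, eps=1e-6)
        assert val == pytest.approx(np.log(1e-6 / (1 - 1e-6)))
        assert val == pytest.approx(-13.8155, abs=1e-3)
        assert n == 1

    def test_inverse_pair(self):
        g = np.array([0.01, 0.3, 0.77])
        y, n = hg.logit_transform(g)
        assert n == 0
        assert np.allclose(inv_logit(y), g, atol=1e-12)


class TestHbm:
    def test_no_signal_theta_near_zero(self, hierarchy16):
        rng = np.random.default_rng(0)
        gst = synthetic_gst(hierarchy16, 12, -4.0, 0, 0, 0, np.zeros(12), 0.05, rng)
        fit = hg.HierarchicalGstModel(gst, hierarchy16).fit(
            n_iter=1500, n_burnin=500, seed=1
        )
        assert np.all(np.abs(fit.theta.to_numpy()) < 0.02)

    def test_sum_to_zero_every_retained_sample(self, hierarchy16):
        rng = np.random.default_rng(1)
        theta = rng.normal(0, 0.5, 20)
        theta -= theta.mean()
        gst = synthetic_gst(hierarchy16, 20, -4.0, 1.0, 0.5, 0.2, theta, 0.3, rng)
        fit = hg.HierarchicalGstModel(gst, hierarchy16).fit(
            n_iter=600, n_burnin=200, seed=2
        )
        sums = fit.samples["theta"].sum(axis=2)
        assert np.max(np.abs(sums)) < 1e-10

    def test_posterior_matches_ols_oracle(self, hierarchy16):
        """Posterior means agree elementwise with the least-squares fit
        under these effectively vague priors."""
        rng = np.random.default_rng(2)
        theta = rng.normal(0, 0.6, 25)
        theta -= theta.mean()
        gst = synthetic_gst(hierarchy16, 25, -4.0, 1.3, 1.1, 0.0, theta, 0.3, rng)
        fit = hg.HierarchicalGstModel(gst, hierarchy16).fit(
            n_iter=3000, n_burnin=1000, seed=3
        )
        beta, theta_ols = ols_fit(gst, hierarchy16)
        post_means = [fit._flat(n).mean() for n in
                      ("mu_g", "mu_clus", "mu_subclus", "mu_elev")]
        assert np.allclose(post_means, beta, atol=0.05)
        assert np.allclose(fit._flat("theta").mean(axis=0), theta_ols, atol=0.05)

    def test_parameter_recovery_coverage(self, hierarchy16):
        """95% credible intervals cover the generating genome-wide effects
        in at least 90% of 20 replicates."""
        true = {"mu_g": -4.0, "mu_clus": 1.3, "mu_subclus": 1.1, "mu_elev": 0.0}
        hits = {k: 0 for k in true}
        master = np.random.default_rng(42)
        for rep in range(20):
            rng = np.random.default_rng(master.integers(2**31))
            gst = synthetic_gst(hierarchy16, 15, true["mu_g"], true["mu_clus"],
                                true["mu_subclus"], true["mu_elev"],
                                np.zeros(15), 0.3, rng)
            fit = hg.HierarchicalGstModel(gst, hierarchy16).fit(
                n_iter=1200, n_burnin=400, seed=rep
            )
            ci = fit.conf_int()
            for k, v in true.items():
                if ci.loc[k, "lower"] <= v <= ci.loc[k, "upper"]:
                    hits[k] += 1
        for k, h in hits.items():
            assert h >= 18, (k, h)

    def test_locus_permutation_equivariance(self, hierarchy16):
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.5, 10)
        theta -= theta.mean()
        gst = synthetic_gst(hierarchy16, 10, -4.0, 1.0, 0.8, 0.1, theta, 0.2, rng)
        perm = list(rng.permutation(10))
        t2 = gst.table.copy()
        loci = [f"L{m:03d}" for m in range(10)]
        t2["locus"] = t2["locus"].map({loci[i]: loci[j] for i, j in enumerate(perm)})
        fit1 = hg.HierarchicalGstModel(gst, hierarchy16).fit(n_iter=2000, n_burnin=1000, seed=4)
        fit2 = hg.HierarchicalGstModel(hg.GstMatrix(t2), hierarchy16).fit(
            n_iter=2000, n_burnin=1000, seed=4
        )
        th1 = fit1.theta
        th2 = fit2.theta
        for i, j in enumerate(perm):
            assert th1[loci[i]] == pytest.approx(th2[loci[j]], abs=0.05)

    def test_chains_from_different_seeds_agree(self, hierarchy16):
        rng = np.random.default_rng(4)
        gst = synthetic_gst(hierarchy16, 15, -4.0, 1.0, 0.8, 0.1,
                            np.zeros(15), 0.3, rng)
        model = hg.HierarchicalGstModel(gst, hierarchy16)
        fits = [model.fit(n_iter=4000, n_burnin=1000, seed=s) for s in (10, 20)]
        for name in ("mu_g", "mu_clus", "mu_subclus", "mu_elev"):
            a, b = (f._flat(name) for f in fits)
            mcse = 2 * max(a.std(), b.std()) / np.sqrt(len(a) / 10)  # crude ESS
            assert abs(np.median(a) - np.median(b)) < 2 * mcse + 1e-3

    def test_neutral_simulation_hierarchy_ordering(self, neutral_sim):
        """On neutral data with m1 < m2 < m3, genome-wide effects decrease
        from broad to local scale and the elevation effect is small."""
        ds, _ = hg.filter_monomorphic(neutral_sim.dataset)
        gst = hg.gst_median_matrix(ds, n_samples=800, seed=9)
        fit = hg.HierarchicalGstModel(gst, neutral_sim.hierarchy).fit(
            n_iter=2000, n_burnin=1000, seed=10
        )
        p = fit.params
        assert p["mu_clus"] > p["mu_subclus"] > 0
        assert abs(p["mu_elev"]) < 0.4

    def test_dimension_mismatch_rejected(self, hierarchy16, neutral_sim):
        ds, _ = hg.filter_monomorphic(neutral_sim.dataset)
        gst = hg.gst_median_matrix(ds.subset(populations=ds.populations[:4]),
                                   n_samples=50, seed=1)
        with pytest.raises(ValidationError):
            hg.HierarchicalGstModel(gst, hierarchy16)

    def test_summary_layout(self, hierarchy16):
        rng = np.random.default_rng(5)
        gst = synthetic_gst(hierarchy16, 5, -4, 1, 1, 0, np.zeros(5), 0.2, rng)
        fit = hg.HierarchicalGstModel(gst, hierarchy16).fit(n_iter=400, n_burnin=100, seed=6)
        s = fit.summary()
        assert list(s.columns) == ["parameter", "median", "ci2.5", "ci97.5", "rhat"]
        assert len(s) == 8 + 5
        assert (s["ci2.5"] <= s["median"]).all() and (s["median"] <= s["ci97.5"]).all()


class TestSbm:
    def test_no_signal(self):
        # the single-site model is saturated (one observation per locus),
        # so theta medians carry some Monte-Carlo noise; run the longer
        # real-data chain length
        g = pd.Series(0.02, index=[f"L{i}" for i in range(30)])
        fit = hg.SingleSiteGstModel(g).fit(n_iter=10000, n_burnin=5000, seed=1)
        assert np.all(np.abs(fit.theta.to_numpy()) < 0.05)
        assert fit.params["mu_g"] == pytest.approx(np.log(0.02 / 0.98), abs=0.05)

    def test_single_high_locus_has_max_theta(self):
        vals = [0.01] * 99 + [0.5]
        g = pd.Series(vals, index=[f"L{i}" for i in range(100)])
        fit = hg.SingleSiteGstModel(g).fit(n_iter=1500, n_burnin=500, seed=2)
        assert fit.theta.idxmax() == "L99"

    def test_theta_matches_centered_residual_oracle(self):
        """Posterior medians of theta track the centred logit values (the
        least-squares solution of the saturated single-pair model)."""
        rng = np.random.default_rng(7)
        y = rng.normal(-4, 0.8, 50)
        g = pd.Series(inv_logit(y), index=[f"L{i}" for i in range(50)])
        fit = hg.SingleSiteGstModel(g).fit(n_iter=10000, n_burnin=5000, seed=3)
        oracle = y - y.mean()
        assert np.allclose(fit.theta.to_numpy(), oracle, atol=0.05)

    def test_sum_to_zero(self):
        g = pd.Series(np.random.default_rng(8).uniform(0.005, 0.2, 20),
                      index=[f"L{i}" for i in range(20)])
        fit = hg.SingleSiteGstModel(g).fit(n_iter=400, n_burnin=100, seed=4)
        assert np.max(np.abs(fit.samples["theta"].sum(axis=2))) < 1e-10

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValidationError):
            hg.SingleSiteGstModel(pd.Series([0.1, 0.2], index=["a", "b"]))


class TestMcmcConfig:
    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            hg.McmcConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValidationError):
            hg.McmcConfig(thin=0)
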