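"""Mixed-model fits: ML oracle agreement, calibration, recovery, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metgxe import kernels, models, simdata


# ---------------------------------------------------------------------------
# helpers: simulate from the crossed iid random-effects model directly
# ---------------------------------------------------------------------------

EQ4_FRACTIONS = {"year": 0.20, "location": 0.17, "year_location": 0.20,
                 "hybrid": 0.08, "hybrid_location": 0.04, "error": 0.51}


def _layout(n_hyb=40, n_year=4, n_loc=3, reps=2):
    rows = []
    for h in range(n_hyb):
        for y in range(n_year):
            for l in range(n_loc):
                for r in range(reps):
                    rows.append((f"H{h:03d}", 2014 + y,
                                 f"L{l}", "north" if l % 2 == 0 else "south",
                                 r + 1, f"{2014+y}:L{l}"))
    return pd.DataFrame(rows, columns=["hybrid", "year", "location", "region",
                                       "replicate", "year_location"])


def _draw_effect(levels, var, rng):
    """iid level effects with the raw second moment pinned to the variance
    parameter (the model's estimand; no centering, matching the iid prior)."""
    z = rng.normal(size=len(levels))
    ms = np.mean(z * z)
    if var == 0 or ms == 0:
        return dict(zip(levels, np.zeros(len(levels))))
    return dict(zip(levels, z * np.sqrt(var / ms)))


def _simulate_eq4(rec, fractions, rng, mu=0.0):
    y = np.full(len(rec), mu)
    maps = {
        "hybrid": rec["hybrid"], "year": rec["year"].astype(str),
        "location": rec["location"], "year_location": rec["year_location"],
        "hybrid_location": rec["hybrid"] + "|" + rec["location"],
    }
    for term, labels in maps.items():
        eff = _draw_effect(sorted(labels.unique()), fractions[term], rng)
        y = y + labels.map(eff).to_numpy()
    eps = rng.normal(size=len(rec))
    eps *= np.sqrt(fractions["error"] / np.mean(eps * eps))
    return y + eps


# ---------------------------------------------------------------------------
# ML fitter
# ---------------------------------------------------------------------------

def _dense_loglik(rec, y, mu, varcomp):
    """Brute-force marginal likelihood with the explicit dense covariance."""
    V = varcomp["error"] * np.eye(len(y))
    maps = {
        "hybrid": rec["hybrid"], "year": rec["year"].astype(str),
        "location": rec["location"], "year_location": rec["year_location"],
        "hybrid_location": rec["hybrid"] + "|" + rec["location"],
    }
    for term, labels in maps.items():
        Z = kernels.incidence(labels, pd.unique(labels))
        V += varcomp[term] * (Z @ Z.T)
    return stats.multivariate_normal.logpdf(y, mean=np.full(len(y), mu), cov=V)


class TestMLFitter:
    def test_loglik_matches_dense_oracle(self):
        rec = _layout(n_hyb=12, n_year=3, n_loc=2, reps=2)  # 144 records
        rng = np.random.default_rng(0)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
        fit = models.fit_random_effects(rec, "y", standardize=False,
                                        compute_se=False)
        oracle = _dense_loglik(rec, rec["y"].to_numpy(), fit.mu,
                               fit.varcomp.values)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_parameter_recovery(self):
        """Planted variance fractions recovered within +-0.05 on average over
        20 replicates at 200 hybrids x 24 year-locations x 2 replicates."""
        rec = _layout(n_hyb=200, n_year=6, n_loc=4, reps=2)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
            fit = models.fit_random_effects(rec, "y", standardize=False,
                                            compute_se=False)
            errs.append([fit.varcomp[k] - EQ4_FRACTIONS[k] for k in EQ4_FRACTIONS])
        mean_err = np.abs(np.mean(errs, axis=0))
        assert mean_err.max() < 0.05

    def test_pure_noise_gives_null_components(self):
        rec = _layout(n_hyb=50, n_year=4, n_loc=3, reps=2)
        rng = np.random.default_rng(1)
        rec["y"] = rng.normal(size=len(rec))
        fit = models.fit_random_effects(rec, "y", compute_se=False)
        for term in models.RANDOM_TERMS:
            assert fit.varcomp[term] < 0.03
        assert fit.varcomp["error"] == pytest.approx(1.0, abs=0.05)

    def test_blups_center_to_zero(self):
        rec = _layout(n_hyb=30, n_year=3, n_loc=3)
        rng = np.random.default_rng(2)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
        fit = models.fit_random_effects(rec, "y", compute_se=False)
        for term, blup in fit.blups.items():
            assert abs(blup.sum()) < 1e-6 * max(1, len(blup))

    def test_confounded_layout_raises(self):
        rec = _layout(n_hyb=10, n_year=1, n_loc=1)
        rec["y"] = 1.0
        with pytest.raises(ValueError, match="confounded"):
            models.fit_random_effects(rec, "y")

    def test_varcomp_ses_reported(self):
        rec = _layout(n_hyb=40, n_year=4, n_loc=3)
        rng = np.random.default_rng(3)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
        fit = models.fit_random_effects(rec, "y")
        assert set(fit.varcomp.se) == set(fit.varcomp.values)
        assert all(v > 0 for v in fit.varcomp.se.values())


class TestECAssociation:
    def _ec(self, rec, rng, beta=0.0):
        yls = sorted(rec["year_location"].unique())
        ec = pd.Series(rng.normal(size=len(yls)), index=yls)
        ec = (ec - ec.mean()) / ec.std()
        return ec, beta * rec["year_location"].map(ec).to_numpy()

    def test_zero_ec_reduces_to_null(self):
        rec = _layout(n_hyb=20, n_year=3, n_loc=2)
        rng = np.random.default_rng(4)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
        ec = pd.Series(0.0, index=sorted(rec["year_location"].unique()))
        fit, lam, p = models.fit_ec_association(rec, "y", ec)
        assert lam == 0.0 and p == 1.0

    def test_constant_nonzero_ec_raises(self):
        rec = _layout(n_hyb=20, n_year=3, n_loc=2)
        rec["y"] = 1.0
        ec = pd.Series(5.0, index=sorted(rec["year_location"].unique()))
        with pytest.raises(ValueError, match="zero variance"):
            models.fit_ec_association(rec, "y", ec)

    def test_planted_slope_within_two_se(self):
        """A planted EC effect of 0.3 SD is covered by +-2 SE in nearly all
        replicates."""
        rec = _layout(n_hyb=30, n_year=4, n_loc=3, reps=2)
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            ec, shift = self._ec(rec, rng, beta=0.3)
            rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng) + shift
            fit, _, _ = models.fit_ec_association(rec, "y", ec,
                                                  standardize=False)
            est = fit.fixed_effects.set_index("name").loc["ec"]
            hits += abs(est["estimate"] - 0.3) <= 2 * est["se"]
        assert hits >= n_rep - 2


class TestStressContrast:
    def _stress(self, rec, rng):
        yls = sorted(rec["year_location"].unique())
        flags = rng.random(len(yls)) < 0.4
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        return pd.Series(flags.astype(float), index=yls)

    def test_contrast_difference_equals_slope(self):
        rec = _layout(n_hyb=25, n_year=3, n_loc=3)
        rng = np.random.default_rng(5)
        stress = self._stress(rec, rng)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng) \
            - 0.5 * rec["year_location"].map(stress).to_numpy()
        fit, lam, p = models.fit_stress_contrast(rec, "y", stress,
                                                 standardize=False)
        c = fit.extra["contrasts"].set_index("contrast")
        diff = c.loc["stress", "estimate"] - c.loc["no_stress", "estimate"]
        assert diff == pytest.approx(fit.extra["slope"], abs=1e-12)

    def test_planted_effect_recovered(self):
        # enough year-locations that the ML-based slope SE is well calibrated
        rec = _layout(n_hyb=30, n_year=8, n_loc=4, reps=2)
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(200 + seed)
            stress = self._stress(rec, rng)
            rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng) \
                - 0.5 * rec["year_location"].map(stress).to_numpy()
            fit, _, _ = models.fit_stress_contrast(rec, "y", stress,
                                                   standardize=False)
            est = fit.fixed_effects.set_index("name").loc["ec"]
            hits += abs(est["estimate"] - (-0.5)) <= 2 * est["se"]
        assert hits >= n_rep - 1

    def test_constant_dummy_raises(self):
        rec = _layout(n_hyb=10, n_year=2, n_loc=2)
        rec["y"] = 1.0
        stress = pd.Series(1.0, index=sorted(rec["year_location"].unique()))
        with pytest.raises(ValueError, match="constant"):
            models.fit_stress_contrast(rec, "y", stress)


class TestPCModel:
    def _pcs(self, rec, rng, zero=False):
        hybs = sorted(rec["hybrid"].unique())
        yls = sorted(rec["year_location"].unique())
        mk = (np.zeros if zero else rng.normal)
        snp_pcs = pd.DataFrame(
            np.zeros((len(hybs), 10)) if zero else rng.normal(size=(len(hybs), 10)),
            index=hybs)
        ec_pcs = pd.DataFrame(
            np.zeros((len(yls), 5)) if zero else rng.normal(size=(len(yls), 5)),
            index=yls)
        return snp_pcs, ec_pcs

    def test_zero_pcs_reduce_to_baseline(self):
        rec = _layout(n_hyb=20, n_year=3, n_loc=2)
        rng = np.random.default_rng(6)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng)
        snp_pcs, ec_pcs = self._pcs(rec, rng, zero=True)
        with pytest.warns(UserWarning, match="collinear"):
            full = models.fit_pc_model(rec, "y", snp_pcs, ec_pcs)
        base = models.fit_random_effects(rec, "y", compute_se=False)
        assert full.loglik == pytest.approx(base.loglik, abs=1e-4)

    def test_nested_likelihood_ordering_and_pc1_recovery(self):
        rec = _layout(n_hyb=30, n_year=3, n_loc=3)
        rng = np.random.default_rng(7)
        snp_pcs, ec_pcs = self._pcs(rec, rng)
        rec["y"] = _simulate_eq4(rec, EQ4_FRACTIONS, rng) \
            + 0.4 * snp_pcs.loc[rec["hybrid"], 0].to_numpy()
        full = models.fit_pc_model(rec, "y", snp_pcs, ec_pcs,
                                   standardize=False, compute_se=True)
        base = models.fit_random_effects(rec, "y", standardize=False,
                                         compute_se=False)
        assert full.loglik >= base.loglik - 1e-6
        est = full.fixed_effects.set_index("name").loc["snp_pc1"]
        assert abs(est["estimate"] - 0.4) <= 2 * est["se"]


class TestEffectiveTests:
    def test_orthonormal_columns_give_column_count(self):
        rng = np.random.default_rng(8)
        W = rng.normal(size=(500, 12))  # nearly independent columns
        m = models.effective_tests(W, method="liji")
        assert abs(m - 12) < 0.7

    def test_duplicated_columns_do_not_inflate_gao(self):
        rng = np.random.default_rng(9)
        W = rng.normal(size=(60, 8)) @ rng.normal(size=(8, 8))  # correlated
        m1 = models.effective_tests(W, method="gao")
        m2 = models.effective_tests(np.hstack([W, W]), method="gao")
        assert m1 == m2

    def test_threshold_monotone_in_m_eff(self):
        ths = [models.bonferroni_threshold(0.05, m) for m in (10, 41, 100)]
        assert ths[0] > ths[1] > ths[2]

    def test_single_column(self):
        assert models.effective_tests(np.ones((10, 1))) == 1.0


class TestEnrichment:
    def test_exact_tail_probability(self):
        # group of 2, both significant, 10 of 189 significant overall:
        # p = C(10,2)/C(189,2) = 45/17766
        sig = pd.Series([True] * 10 + [False] * 179)
        groups = pd.Series(["g1"] * 2 + ["rest"] * 187)
        out = models.enrichment_test(sig, groups).set_index("group")
        assert out.loc["g1", "p"] == pytest.approx(45 / 17766, rel=1e-12)

    def test_zero_and_saturated_cases(self):
        sig = pd.Series([True] * 5 + [False] * 15)
        groups = pd.Series(["a"] * 4 + ["b"] * 16)
        out = models.enrichment_test(pd.Series([False] * 20), groups)
        assert (out["p"] == 1.0).all()
        out2 = models.enrichment_test(pd.Series([True] * 20), groups)
        assert (out2["p"] == 1.0).all()

    def test_singleton_group_skipped(self):
        sig = pd.Series([True, False, False])
        groups = pd.Series(["solo", "pair", "pair"])
        out = models.enrichment_test(sig, groups).set_index("group")
        assert np.isnan(out.loc["solo", "p"])
        assert "skipped" in out.loc["solo", "note"]


# ---------------------------------------------------------------------------
# reaction norm (Gibbs)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rn_instance():
    cfg = simdata.SimConfig(n_hybrids=80, n_snps=400, n_years=3,
                            n_locations_north=3, n_locations_south=2,
                            n_replicates=2, seed=21)
    d = simdata.make_trial_design(cfg)
    g = simdata.simulate_genotypes(cfg)
    _, ec = simdata.simulate_environment(d, cfg)
    rec = simdata.simulate_phenotypes(d, g, ec, cfg)
    ks = kernels.build_kernel_set(rec, g.dosages, ec)
    return cfg, rec, ks


class TestReactionNorm:
    def test_two_path_equivalence(self, rn_instance):
        """Crossed Kronecker path, general SVD path, and dense-K features give
        the same posterior summaries within Monte-Carlo error."""
        _, rec, ks = rn_instance
        fits = [
            models.fit_reaction_norm(rec, ks, n_iter=2500, burn_in=800,
                                     thin=2, seed=1),
            models.fit_reaction_norm(rec, ks, n_iter=2500, burn_in=800,
                                     thin=2, seed=1, force_general=True),
            models.fit_reaction_norm(rec, ks, n_iter=2500, burn_in=800,
                                     thin=2, seed=1, force_general=True,
                                     interaction_features="dense"),
        ]
        assert fits[0].extra["crossed_path"]
        assert not fits[1].extra["crossed_path"]
        for k in ("ec", "snp", "snp_ec", "error"):
            vals = [f.varcomp[k] for f in fits]
            assert max(vals) - min(vals) < 0.01

    def test_null_trait_loads_on_error(self, rn_instance):
        _, rec, ks = rn_instance
        rec2 = rec.copy()
        rng = np.random.default_rng(3)
        rec2["yield"] = rng.normal(size=len(rec2))
        fit = models.fit_reaction_norm(rec2, ks, n_iter=2000, burn_in=600,
                                       thin=2, seed=2)
        assert fit.varcomp["error"] > 0.85
        # scaled-inverse-chi-square priors keep the genetic terms slightly
        # above zero; together they stay a small share
        assert fit.varcomp["snp"] + fit.varcomp["snp_ec"] < 0.15

    def test_agrees_with_closed_form_blup(self, rn_instance):
        """Posterior-mean genetic effects track the closed-form single-kernel
        BLUP computed at the true variance ratio."""
        cfg, rec, ks = rn_instance
        fit = models.fit_reaction_norm(rec, ks, n_iter=2500, burn_in=800,
                                       thin=2, seed=4)
        y = rec["yield"].to_numpy()
        y = (y - y.mean()) / y.std()
        H = len(ks.hybrids)
        Gs = ks.G * H  # mean-diagonal ~1 scaling used by the sampler
        fr = cfg.variance_fractions
        Kg = ks.Z1 @ Gs @ ks.Z1.T
        V = (fr["snp"] * Kg
             + fr["ec"] * len(ks.year_locations) * ks.Z2 @ ks.omega @ ks.Z2.T
             + fr["snp_ec"] * ks.dense_k() / ks.dense_k().diagonal().mean()
             + fr["error"] * np.eye(len(y)))
        blup_g = fr["snp"] * Kg @ np.linalg.solve(V, y - y.mean())
        r = np.corrcoef(blup_g, fit.extra["effects"]["snp"].to_numpy())[0, 1]
        assert r > 0.98

    def test_chain_validation(self, rn_instance):
        _, rec, ks = rn_instance
        with pytest.raises(ValueError, match="burn-in"):
            models.fit_reaction_norm(rec, ks, n_iter=100, burn_in=200)

    def test_eq4_eq5_consistency(self, rn_instance):
        """On kernel-faithful synthetic data the SNP variance matches the
        hybrid variance of the plain random-effects fit and the EC variance
        matches the combined year/location/year-location variance."""
        _, rec, ks = rn_instance
        rn = models.fit_reaction_norm(rec, ks, n_iter=2500, burn_in=800,
                                      thin=2, seed=5)
        re = models.fit_random_effects(rec, "yield", compute_se=False)
        assert abs(rn.varcomp["snp"] - re.varcomp["hybrid"]) < 0.06
        yl_total = (re.varcomp["year"] + re.varcomp["location"]
                    + re.varcomp["year_location"])
        assert abs(rn.varcomp["ec"] - yl_total) < 0.12


class TestTwoTrait:
    def test_identical_traits_pin_genetic_correlation(self, rn_instance):
        _, rec, ks = rn_instance
        rec2 = rec.copy()
        rec2["y2"] = rec2["yield"]
        with pytest.warns(UserWarning, match="identical"):
            out = models.fit_two_trait(rec2, ("yield", "y2"), ks,
                                       n_iter=1500, burn_in=500, seed=1)
        assert out["snp"]["mean"] > 0.95

    def test_independent_traits_near_zero(self, rn_instance):
        cfg, rec, ks = rn_instance
        rec2 = rec.copy()
        other = simdata.simulate_phenotypes(
            simdata.make_trial_design(cfg), simdata.simulate_genotypes(cfg),
            None, cfg) if False else None
        rng = np.random.default_rng(11)
        # an independent trait with its own genetic signal
        g_eff = dict(zip(ks.hybrids, rng.normal(0, 0.3, len(ks.hybrids))))
        rec2["y2"] = rec2["hybrid"].map(g_eff).to_numpy() + rng.normal(size=len(rec2))
        out = models.fit_two_trait(rec2, ("yield", "y2"), ks,
                                   n_iter=2000, burn_in=700, seed=2)
        assert abs(out["snp"]["mean"]) < 0.35   # weakly identified, near zero
        assert abs(out["error"]["mean"]) < 0.1

    def test_planted_genetic_correlation_recovered(self, rn_instance):
        cfg, rec, ks = rn_instance
        rho = 0.6
        ests = []
        for seed in range(3):
            rng = np.random.default_rng(300 + seed)
            lam, U = ks.eigen_g()
            keep = lam > lam.max() * 1e-10
            A = U[:, keep] * np.sqrt(lam[keep])
            A /= np.sqrt(np.mean(np.sum(A ** 2, axis=1)))
            z1 = rng.normal(size=keep.sum())
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=keep.sum())
            g1, g2 = A @ z1 * 0.6, A @ z2 * 0.6
            h_idx = np.argmax(ks.Z1, axis=1)
            rec2 = rec.copy()
            rec2["t1"] = g1[h_idx] + 0.8 * rng.normal(size=len(rec2))
            rec2["t2"] = g2[h_idx] + 0.8 * rng.normal(size=len(rec2))
            out = models.fit_two_trait(rec2, ("t1", "t2"), ks,
                                       n_iter=2000, burn_in=700, seed=seed)
            ests.append(out["snp"]["mean"])
        assert abs(np.mean(ests) - rho) < 0.1


class TestPhenotypicCorrelations:
    def test_se_formula(self):
        assert models.correlation_se(0.6, 27) == pytest.approx(0.16)

    def test_identical_traits_give_unit_correlations(self, rn_instance):
        _, rec, _ = rn_instance
        rec2 = rec.copy()
        rec2["y2"] = rec2["yield"]
        out = models.phenotypic_correlations(rec2, "yield", "y2")
        assert out["across"] == pytest.approx(1.0)
        assert out["within"] == pytest.approx(1.0)
        assert out["between"] == pytest.approx(1.0)

    def test_constructed_within_and_between(self):
        """Planted within-YL correlation ~0.4 with independent YL means gives
        within ~0.4 and between ~0."""
        rng = np.random.default_rng(12)
        n_yl, n_per = 40, 50
        rows = []
        for j in range(n_yl):
            mu1, mu2 = rng.normal(0, 2, 2)  # independent YL means
            z1 = rng.normal(size=n_per)
            z2 = 0.4 * z1 + np.sqrt(1 - 0.16) * rng.normal(size=n_per)
            for i in range(n_per):
                rows.append((f"H{i}", 2014 + j % 4, f"L{j // 4}", "north", 1,
                             f"{2014 + j % 4}:L{j // 4}",
                             mu1 + z1[i], mu2 + z2[i]))
        rec = pd.DataFrame(rows, columns=["hybrid", "year", "location", "region",
                                          "replicate", "year_location", "t1", "t2"])
        out = models.phenotypic_correlations(rec, "t1", "t2")
        assert abs(out["within"] - 0.4) < 0.05
        assert abs(out["between"]) < 0.25

    def test_small_groups_excluded(self, rn_instance):
        _, rec, _ = rn_instance
        rec2 = rec.copy()
        rng = np.random.default_rng(13)
        rec2["y2"] = rng.normal(size=len(rec2))
        yl0 = rec2["year_location"].iloc[0]
        keep = (rec2["year_location"] != yl0) | (rec2.index < rec2.index[2])
        rec2 = rec2[keep]
        out = models.phenotypic_correlations(rec2, "yield", "y2")
        assert yl0 in out["excluded_year_locations"]
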