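"""Mixed models for multi-environment trial analysis.

Two model families are implemented:

* **Crossed iid random-effects models** (baseline, EC association, stress
  contrast, and PC-augmented variants) fitted by maximum likelihood so that
  likelihood-ratio tests between nested fits are valid.  The marginal
  likelihood is profiled analytically over the fixed effects and the error
  variance, leaving a low-dimensional optimization over variance ratios;
  all linear algebra runs on cached cross-products via the Woodbury
  identity, so fits cost O(q^3) per evaluation in the number of
  random-effect levels q, independent of the record count.

* **The reaction-norm model** ``y = mu + g + E + gE + eps`` with
  ``g ~ MVN(0, s2_snp G)``, ``E ~ MVN(0, s2_ec Omega)`` and
  ``gE ~ MVN(0, s2_snpxec K)``, ``K = (Z1 G Z1') o (Z2 Omega Z2')``,
  fitted by Gibbs sampling with scaled-inverse-chi-square priors.  The
  sampler works on an eigen-rotated representation in which every term has
  orthogonal columns, so all conditional updates are closed-form and
  element-wise.  Fully crossed balanced designs take a Kronecker fast path
  (all projections are small matrix products); arbitrary designs take a
  general path on cell-collapsed sufficient statistics.

Multiple-testing support: an effective number of independent tests from the
EC eigenvalue spectrum (Li & Ji by default, Gao's cumulative-variance rule as
an alternative), the Bonferroni threshold ``alpha / M_eff``, and one-sided
hypergeometric enrichment of EC groups among significant associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceComponents", "FitResult", "fit_random_effects", "fit_ec_association",
    "fit_stress_contrast", "fit_pc_model", "fit_reaction_norm", "fit_two_trait",
    "effective_tests", "bonferroni_threshold", "enrichment_test",
    "phenotypic_correlations", "location_share_of_yl", "within_trial_repeatability",
    "RANDOM_TERMS",
]

#: random terms of the baseline crossed model, in fitting order
RANDOM_TERMS = ["hybrid", "year", "location", "year_location", "hybrid_location"]


@dataclass
class VarianceComponents:
    """Named variance components with optional uncertainty per component."""

    values: dict
    se: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def proportions(self) -> dict:
        tot = sum(self.values.values())
        return {k: v / tot for k, v in self.values.items()}

    def total_yl(self) -> float:
        """Aggregate year + location + year-location share (reporting aid).

        A separately estimated ``total_yl`` entry (posterior of the sum, as
        variance-partition tables often print it) takes precedence over the
        sum of the individual components.
        """
        if "total_yl" in self.values:
            return self.values["total_yl"]
        return sum(self.values.get(k, 0.0) for k in ("year", "location", "year_location"))


def location_share_of_yl(vc: VarianceComponents) -> float:
    """Location variance as a share of the combined Y+L+YL variance."""
    return vc["location"] / vc.total_yl()


def within_trial_repeatability(vc: VarianceComponents) -> float:
    """Hybrid variance relative to hybrid plus plot-error variance."""
    key = "hybrid" if "hybrid" in vc.values else "snp"
    return vc[key] / (vc[key] + vc["error"])


@dataclass
class FitResult:
    """Estimates from one model fit (ML or posterior summaries)."""

    varcomp: VarianceComponents
    fixed_effects: pd.DataFrame  # name, estimate, se
    blups: dict                  # term -> pd.Series of level predictions
    loglik: float | None
    n: int
    extra: dict = field(default_factory=dict)

    @property
    def mu(self) -> float:
        return float(self.fixed_effects.set_index("name").loc["intercept", "estimate"])


# --------------------------------------------------------------------------
# ML fitter for crossed iid random effects
# --------------------------------------------------------------------------

class _CrossedML:
    """Profile-ML machinery for y = X b + sum_t Z_t u_t + e with iid u_t.

    Caches all cross-products once; every likelihood evaluation needs only a
    Cholesky of the q x q matrix ``I + S Z'Z S`` (Woodbury), where S holds
    sqrt variance ratios per column.
    """

    def __init__(self, y, X, factors: dict):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n = len(self.y)
        self.term_names = list(factors)
        self.levels = {}
        codes_all, sizes = [], []
        for name, labels in factors.items():
            codes, levels = pd.factorize(np.asarray(labels))
            self.levels[name] = list(levels)
            codes_all.append(codes)
            sizes.append(len(levels))
        self.sizes = sizes
        offs = np.concatenate([[0], np.cumsum(sizes)])
        self.offsets = offs
        self.q = offs[-1]
        # column index of each record in the stacked random-effect design
        self.col_idx = [codes_all[t] + offs[t] for t in range(len(sizes))]
        q, n, p = self.q, self.n, self.X.shape[1]
        all_idx = np.concatenate(self.col_idx)
        ZtZ = np.zeros((q, q))
        for a in range(len(sizes)):
            for b in range(len(sizes)):
                np.add.at(ZtZ, (self.col_idx[a], self.col_idx[b]), 1.0)
        self.ZtZ = ZtZ
        self.Zty = np.zeros(q)
        np.add.at(self.Zty, all_idx, np.tile(self.y, len(sizes)))
        self.ZtX = np.zeros((q, p))
        for j in range(p):
            col = np.zeros(q)
            np.add.at(col, all_idx, np.tile(self.X[:, j], len(sizes)))
            self.ZtX[:, j] = col
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        # Schur-complement split: the largest term's own Gram block is
        # diagonal (single-factor incidence), so it can be eliminated cheaply
        self.big = int(np.argmax(sizes))
        self.idx1 = np.arange(self.offsets[self.big], self.offsets[self.big + 1])
        self.idx0 = np.concatenate([
            np.arange(self.offsets[t], self.offsets[t + 1])
            for t in range(len(sizes)) if t != self.big
        ])
        self.Z00 = ZtZ[np.ix_(self.idx0, self.idx0)]
        self.Z01 = ZtZ[np.ix_(self.idx0, self.idx1)]
        self.diag1 = np.diag(ZtZ)[self.idx1].copy()

    def _expand(self, lam: np.ndarray) -> np.ndarray:
        s = np.empty(self.q)
        for t, l in enumerate(lam):
            s[self.offsets[t]:self.offsets[t + 1]] = l
        return s

    def _solver(self, lam):
        """Block solver for M = I + S Z'Z S via the Schur complement on the
        (diagonal) block of the largest term; returns (solve, logdet, s)."""
        s = np.sqrt(self._expand(lam))
        s0, s1 = s[self.idx0], s[self.idx1]
        M00 = (self.Z00 * s0[None, :]) * s0[:, None]
        M00[np.diag_indices_from(M00)] += 1.0
        B = (self.Z01 * s1[None, :]) * s0[:, None]
        d = 1.0 + s1 * s1 * self.diag1
        Bd = B / d[None, :]
        Sc = M00 - Bd @ B.T
        cf = cho_factor(Sc, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0]))) + float(np.sum(np.log(d)))

        def solve(R):
            R0, R1 = R[self.idx0], R[self.idx1]
            x0 = cho_solve(cf, R0 - Bd @ R1, check_finite=False)
            x1 = (R1 - B.T @ x0) / (d[:, None] if R1.ndim == 2 else d)
            out = np.empty_like(R)
            out[self.idx0], out[self.idx1] = x0, x1
            return out

        return solve, logdet, s

    def _pieces(self, lam):
        """M-solver plus the V0^{-1}-weighted cross-products of [X, y]."""
        solve, logdet, s = self._solver(lam)
        SZtA = s[:, None] * np.column_stack([self.ZtX, self.Zty])
        W = solve(SZtA)
        p = self.X.shape[1]
        AtA = np.empty((p + 1, p + 1))
        AtA[:p, :p] = self.XtX
        AtA[:p, p] = AtA[p, :p] = self.Xty
        AtA[p, p] = self.yty
        AtVA = AtA - SZtA.T @ W
        return solve, s, logdet, AtVA

    def nll(self, lam):
        _, _, logdet, AtVA = self._pieces(lam)
        p = self.X.shape[1]
        XtVX, XtVy, ytVy = AtVA[:p, :p], AtVA[:p, p], AtVA[p, p]
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf
        quad = ytVy - beta @ XtVy
        if quad <= 0:
            return np.inf
        sig2 = quad / self.n
        return 0.5 * (self.n * np.log(2 * np.pi * sig2) + logdet + self.n)

    def fit(self, lam0=None, maxiter=400):
        T = len(self.sizes)
        x0 = np.log(np.full(T, 0.1) if lam0 is None else np.asarray(lam0))
        res = optimize.minimize(lambda th: self.nll(np.exp(th)), x0,
                                method="L-BFGS-B",
                                bounds=[(-18.0, 8.0)] * T,
                                options={"maxiter": maxiter})
        lam = np.exp(res.x)
        solve, s, logdet, AtVA = self._pieces(lam)
        p = self.X.shape[1]
        XtVX, XtVy, ytVy = AtVA[:p, :p], AtVA[:p, p], AtVA[p, p]
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - beta @ XtVy
        sig2 = quad / self.n
        loglik = -0.5 * (self.n * np.log(2 * np.pi * sig2) + logdet + self.n)
        beta_cov = sig2 * np.linalg.inv(XtVX)
        # BLUPs: u_t = lam_t * Z' V0^{-1} (y - X beta)
        Ztr = self.Zty - self.ZtX @ beta
        w = Ztr - (self.ZtZ * s[None, :]) @ solve(s * Ztr)
        blups = {}
        for t, name in enumerate(self.term_names):
            sl = slice(self.offsets[t], self.offsets[t + 1])
            blups[name] = pd.Series(lam[t] * w[sl], index=self.levels[name])
        return {
            "lam": lam, "sig2e": sig2, "beta": beta, "beta_cov": beta_cov,
            "loglik": loglik, "blups": blups, "converged": bool(res.success),
            "theta": res.x,
        }

    def varcomp_ses(self, lam, sig2e, eps=1e-4):
        """Asymptotic SEs of (sigma2_t, sigma2_e) via the observed information
        of the full ML log-likelihood in log parameters (delta method)."""
        T = len(lam)

        def full_nll(par):
            l, s2 = np.exp(par[:T]), np.exp(par[T])
            _, _, logdet, AtVA = self._pieces(l)
            p = self.X.shape[1]
            XtVX, XtVy, ytVy = AtVA[:p, :p], AtVA[:p, p], AtVA[p, p]
            beta = np.linalg.solve(XtVX, XtVy)
            quad = ytVy - beta @ XtVy
            return 0.5 * (self.n * np.log(2 * np.pi * s2) + logdet + quad / s2)

        x = np.log(np.concatenate([np.maximum(lam, 1e-10), [sig2e]]))
        m = T + 1
        H = np.zeros((m, m))
        f0 = full_nll(x)
        for i in range(m):
            for j in range(i, m):
                xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
                xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
                xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
                xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
                H[i, j] = H[j, i] = (full_nll(xpp) - full_nll(xpm)
                                     - full_nll(xmp) + full_nll(xmm)) / (4 * eps * eps)
        try:
            cov_log = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        var_log = np.clip(np.diag(cov_log), 0, None)
        sig2 = np.concatenate([lam * sig2e, [sig2e]])
        # sigma2_t = exp(log lam_t + log s2e): delta method on the sum
        ses = np.empty(m)
        for t in range(T):
            v = (cov_log[t, t] + cov_log[m - 1, m - 1] + 2 * cov_log[t, m - 1])
            ses[t] = sig2[t] * np.sqrt(max(v, 0.0))
        ses[m - 1] = sig2[m - 1] * np.sqrt(var_log[m - 1])
        return ses


def _prepare(records: pd.DataFrame, trait, standardize: bool):
    if isinstance(trait, str):
        y = records[trait].to_numpy(dtype=float)
    else:
        y = np.asarray(trait, float)
    if standardize:
        sd = y.std()
        if sd == 0:
            raise ValueError("trait has zero variance")
        y = (y - y.mean()) / sd
    return y


def _check_layout(records: pd.DataFrame):
    if records["year"].nunique() == 1 and records["location"].nunique() == 1:
        raise ValueError("single year and single location: year, location and "
                         "year-location effects are confounded with the intercept")
    if records["hybrid"].nunique() < 2 or records["year_location"].nunique() < 2:
        raise ValueError("need at least 2 hybrids and 2 year-locations")


def _ml_fit(records, y, X, fixed_names, lam0=None, compute_se=True):
    factors = {name: records[name if name != "hybrid_location"
                             else "hybrid"].astype(str)
               for name in RANDOM_TERMS}
    factors["hybrid_location"] = (records["hybrid"].astype(str) + "|"
                                  + records["location"].astype(str))
    ml = _CrossedML(y, X, factors)
    out = ml.fit(lam0=lam0)
    sig2 = {name: out["lam"][t] * out["sig2e"] for t, name in enumerate(RANDOM_TERMS)}
    sig2["error"] = out["sig2e"]
    ses = {}
    if compute_se:
        se_arr = ml.varcomp_ses(out["lam"], out["sig2e"])
        if se_arr is not None:
            ses = {name: se_arr[t] for t, name in enumerate(RANDOM_TERMS)}
            ses["error"] = se_arr[-1]
    fixed = pd.DataFrame({
        "name": fixed_names,
        "estimate": out["beta"],
        "se": np.sqrt(np.diag(out["beta_cov"])),
    })
    return FitResult(
        varcomp=VarianceComponents(sig2, ses),
        fixed_effects=fixed,
        blups=out["blups"],
        loglik=out["loglik"],
        n=ml.n,
        extra={"beta_cov": out["beta_cov"], "converged": out["converged"],
               "lam": out["lam"], "theta": out["theta"]},
    )


def fit_random_effects(records: pd.DataFrame, trait="yield",
                       standardize: bool = True, compute_se: bool = True,
                       lam0=None) -> FitResult:
    """Baseline crossed random-effects model (no SNP or EC information).

    ``y = mu + hybrid + year + location + year-location + hybrid-by-location
    + error`` with iid Gaussian effects, fitted by ML.  The trait is
    standardized to unit variance by default so components read as shares.
    """
    _check_layout(records)
    y = _prepare(records, trait, standardize)
    X = np.ones((len(y), 1))
    return _ml_fit(records, y, X, ["intercept"], lam0=lam0, compute_se=compute_se)


def _lrt(full: FitResult, null: FitResult):
    lam = 2.0 * (full.loglik - null.loglik)
    if lam < 0:
        warnings.warn(f"negative LRT statistic {lam:.3g} clipped to 0")
        lam = 0.0
    return lam, float(stats.chi2.sf(lam, df=1))


def fit_ec_association(records: pd.DataFrame, trait, ec, standardize: bool = True,
                       null_fit: FitResult | None = None, compute_se: bool = False):
    """EC association model: baseline random effects plus a fixed EC regression.

    ``ec`` is a Series indexed by year-location (the covariate is defined at
    that level) or a per-record vector constant within year-location.
    Returns ``(FitResult, lrt_statistic, p_value)`` from the one-sided
    chi-square(1) likelihood-ratio test against the baseline model.

    An EC that is identically zero contributes nothing and reduces to the
    null (LRT 0, p 1); a non-zero constant EC is collinear with the intercept
    and raises ``ValueError``.
    """
    _check_layout(records)
    y = _prepare(records, trait, standardize)
    if isinstance(ec, pd.Series):
        ec_vec = records["year_location"].map(ec).to_numpy(dtype=float)
    else:
        ec_vec = np.asarray(ec, float)
    if null_fit is None:
        null_fit = _ml_fit(records, y, np.ones((len(y), 1)), ["intercept"],
                           compute_se=False)
    if np.all(ec_vec == 0):
        return null_fit, 0.0, 1.0
    if np.std(ec_vec) == 0:
        raise ValueError("EC has zero variance (collinear with the intercept)")
    X = np.column_stack([np.ones(len(y)), ec_vec])
    full = _ml_fit(records, y, X, ["intercept", "ec"],
                   lam0=null_fit.extra["lam"], compute_se=compute_se)
    lam, p = _lrt(full, null_fit)
    full.extra["lrt"] = lam
    full.extra["p_value"] = p
    return full, lam, p


def fit_stress_contrast(records: pd.DataFrame, trait, stress, standardize: bool = True,
                        null_fit: FitResult | None = None, compute_se: bool = True):
    """Stress-dummy model: baseline random effects plus a 0/1 stress indicator.

    ``stress`` is a boolean/0-1 Series indexed by year-location (or a
    per-record vector).  The fit's ``extra['contrasts']`` table holds the
    no-stress mean (intercept), the stress mean (intercept + slope) and their
    SEs; the contrast difference equals the dummy slope identically.
    Returns ``(FitResult, lrt_statistic, p_value)``.
    """
    if isinstance(stress, pd.Series):
        dummy = records["year_location"].map(stress).to_numpy(dtype=float)
    else:
        dummy = np.asarray(stress, float)
    if np.std(dummy) == 0:
        raise ValueError("stress dummy is constant across year-locations")
    fit, lam, p = fit_ec_association(records, trait, dummy, standardize=standardize,
                                     null_fit=null_fit, compute_se=compute_se)
    beta = fit.fixed_effects["estimate"].to_numpy()
    cov = fit.extra["beta_cov"]
    fit.extra["contrasts"] = pd.DataFrame({
        "contrast": ["no_stress", "stress"],
        "estimate": [beta[0], beta[0] + beta[1]],
        "se": [np.sqrt(cov[0, 0]), np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])],
    })
    fit.extra["slope"] = beta[1]
    return fit, lam, p


def fit_pc_model(records: pd.DataFrame, trait, snp_pcs: pd.DataFrame,
                 ec_pcs: pd.DataFrame, standardize: bool = True,
                 compute_se: bool = False) -> FitResult:
    """Baseline random effects plus fixed top SNP- and EC-derived PC scores.

    ``snp_pcs`` is indexed by hybrid (typically 10 columns) and ``ec_pcs`` by
    year-location (typically 5 columns); scores are mapped onto records.
    Collinear or constant PC columns are dropped with a warning.
    """
    _check_layout(records)
    y = _prepare(records, trait, standardize)
    Xh = snp_pcs.loc[records["hybrid"]].to_numpy(dtype=float)
    Xe = ec_pcs.loc[records["year_location"]].to_numpy(dtype=float)
    names = (["intercept"]
             + [f"snp_pc{j + 1}" for j in range(Xh.shape[1])]
             + [f"ec_pc{j + 1}" for j in range(Xe.shape[1])])
    X = np.column_stack([np.ones(len(y)), Xh, Xe])
    # drop collinear columns by inspecting the QR diagonal
    Q, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping collinear PC column(s): {dropped}")
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    return _ml_fit(records, y, X, names, compute_se=compute_se)


# --------------------------------------------------------------------------
# Multiple testing and enrichment
# --------------------------------------------------------------------------

def effective_tests(W, method: str = "liji") -> float:
    """Effective number of independent tests from the EC eigenvalue spectrum.

    ``liji`` (default): Li & Ji's estimator,
    ``M_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]`` over the
    eigenvalues of the column correlation matrix.  ``gao``: the smallest
    number of top eigenvalues explaining 99.5% of the total variance (exactly
    invariant to duplicating columns).  Fewer than 2 columns returns the
    column count.
    """
    W = W.to_numpy(dtype=float) if isinstance(W, pd.DataFrame) else np.asarray(W, float)
    p = W.shape[1]
    if p < 2:
        return float(p)
    Ws = (W - W.mean(axis=0)) / W.std(axis=0)
    corr = Ws.T @ Ws / W.shape[0]
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)[::-1]
    if method == "liji":
        return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    if method == "gao":
        frac = np.cumsum(lam) / lam.sum()
        return float(np.searchsorted(frac, 0.995) + 1)
    raise ValueError(f"unknown M_eff method {method!r}")


def bonferroni_threshold(alpha: float, m_eff: float) -> float:
    """Significance threshold ``alpha / M_eff``."""
    return alpha / m_eff


def enrichment_test(significant, groups) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of EC groups among significant ECs.

    ``significant`` is a boolean Series over all tested ECs and ``groups``
    maps each EC to its covariate group.  For every group with at least two
    members, ``p = P(X >= observed)`` drawing ``group size`` from the
    population of all ECs with ``total significant`` successes.  Groups of
    size <= 1 are skipped with a note in the output.
    """
    significant = pd.Series(significant).astype(bool)
    groups = pd.Series(groups)
    M = len(significant)
    K = int(significant.sum())
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        size = len(idx)
        if size <= 1:
            rows.append((g, size, np.nan, np.nan, "skipped: group size <= 1"))
            continue
        k = int(significant.loc[idx].sum())
        p = float(stats.hypergeom.sf(k - 1, M, K, size))
        rows.append((g, size, k, p, ""))
    return pd.DataFrame(rows, columns=["group", "size", "n_significant", "p", "note"])


# --------------------------------------------------------------------------
# Gibbs sampler for the reaction-norm model
# --------------------------------------------------------------------------

class _Block:
    """One random term with orthogonal design columns in (weighted) cell space."""

    def __init__(self, name, A, B, flat_prior=False):
        # design column (i, j) = sqrt(m) * (A[:, i] (x) B[:, j]); A, B have
        # mutually orthogonal (not necessarily unit) columns
        self.name = name
        self.A, self.B = A, B
        self.flat = flat_prior
        self.shape = (A.shape[1], B.shape[1])
        na = (A * A).sum(axis=0)
        nb = (B * B).sum(axis=0)
        self.colnorm2 = np.outer(na, nb)
        self.gamma = np.zeros(self.shape)

    def project(self, E):
        return self.A.T @ E @ self.B

    def expand(self):
        return self.A @ self.gamma @ self.B.T


class _FlatBlock:
    """General-path term: precomputed orthogonal design Q diag(s)."""

    def __init__(self, name, Q, s, flat_prior=False):
        self.name = name
        self.Q, self.s = Q, s
        self.flat = flat_prior
        self.colnorm2 = s * s
        self.gamma = np.zeros(len(s))

    def project(self, e):
        return self.s * (self.Q.T @ e)

    def expand(self):
        return self.Q @ (self.s * self.gamma)


def _sample_block(block, e, sig2, sig2e, rng):
    """Conjugate update of one term's coefficients; returns updated residual."""
    e = e + block.expand()
    z = block.project(e)
    prior_prec = 0.0 if block.flat else 1.0 / sig2
    prec = block.colnorm2 / sig2e + prior_prec
    var = 1.0 / prec
    mean = var * z / sig2e
    block.gamma = mean + np.sqrt(var) * rng.standard_normal(np.shape(z))
    return e - block.expand()


def _scaled_inv_chi2(rng, df, scale_sum):
    return scale_sum / rng.chisquare(df)


def fit_reaction_norm(records: pd.DataFrame, ks, trait="yield",
                      standardize: bool = True, n_iter: int = 15000,
                      burn_in: int = 5000, thin: int = 5, seed: int = 0,
                      prior_df: float = 5.0, retain_rel: float = 1e-10,
                      max_interaction_rank: int | None = None,
                      interaction_features: str = "factored",
                      force_general: bool = False) -> FitResult:
    """Bayesian fit of the reaction-norm model via Gibbs sampling.

    Kernels come from a :class:`~metgxe.kernels.KernelSet` aligned to
    ``records``; each kernel is rescaled so its record-level mean diagonal is
    1, making the variance components directly comparable to phenotypic
    shares.  Priors are scaled-inverse-chi-square with ``prior_df`` degrees
    of freedom and scales set so each prior mode equals an equal share of the
    phenotypic variance.

    Fully crossed balanced designs (every hybrid in every year-location with
    a constant replicate count) are detected and run on a Kronecker fast
    path; other designs use cell-collapsed sufficient statistics with
    per-term SVD orthogonalization.  ``interaction_features='dense'`` builds
    the interaction term from an eigendecomposition of the explicitly formed
    K instead of the factored basis (same model, used for cross-checking).

    Returns a :class:`FitResult` with posterior means/SDs of
    ``{'ec', 'snp', 'snp_ec', 'error'}``, record-level posterior-mean effects
    in ``extra['effects']``, the retained samples in ``extra['samples']`` and
    prediction operators in ``extra['predictors']``.
    """
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    y = _prepare(records, trait, standardize)
    n = len(y)
    rng = np.random.default_rng(seed)

    h_idx = np.argmax(ks.Z1, axis=1)
    e_idx = np.argmax(ks.Z2, axis=1)
    H, L = ks.Z1.shape[1], ks.Z2.shape[1]

    lamG, U = ks.eigen_g()
    lamO, V = ks.eigen_omega()
    kg = lamG > retain_rel * lamG.max()
    ko = lamO > retain_rel * lamO.max()
    lamG, U = lamG[kg], U[:, kg]
    lamO, V = lamO[ko], V[:, ko]
    # rescale kernels to record-level mean diagonal 1
    dG = np.einsum("ij,j,ij->i", U, lamG, U)
    dO = np.einsum("ij,j,ij->i", V, lamO, V)
    cg = dG[h_idx].mean()
    co = dO[e_idx].mean()
    ck = (dG[h_idx] * dO[e_idx]).mean()
    A_g = U * np.sqrt(lamG / cg)           # H x rG, effect_h = A_g[h] @ alpha
    B_e = V * np.sqrt(lamO / co)           # L x rOm
    A_k = U * np.sqrt(lamG)
    B_k = V * np.sqrt(lamO / (ck / 1.0))   # product scaling folded into B

    # cells and sufficient statistics
    cell_key = h_idx.astype(np.int64) * L + e_idx
    uniq, cell_of = np.unique(cell_key, return_inverse=True)
    n_cells = len(uniq)
    m = np.bincount(cell_of).astype(float)
    ysum = np.bincount(cell_of, weights=y)
    ybar = ysum / m
    ss_within = float(y @ y - ybar @ ysum)
    ch = (uniq // L).astype(int)
    ce = (uniq % L).astype(int)

    crossed = (not force_general) and n_cells == H * L and np.all(m == m[0]) \
        and interaction_features == "factored"
    var_y = y.var()
    n_terms = 3
    s0 = var_y / (n_terms + 1) * (prior_df + 2) / prior_df

    if crossed:
        mm = m[0]
        Ybar = np.zeros((H, L))
        Ybar[ch, ce] = ybar
        sqm = np.sqrt(mm)
        Uw = sqm * A_g
        Vw = sqm * B_e
        ones_h = np.full((H, 1), sqm)
        ones_l = np.ones((L, 1))
        blocks = [
            _Block("mu", ones_h, ones_l, flat_prior=True),
            _Block("snp", Uw, ones_l),
            _Block("ec", ones_h * 0 + 1.0, Vw),  # A=1_H, B = sqrt(m) V sqrt(lam)
            _Block("snp_ec", sqm * A_k, B_k),
        ]
        # weighted response as H x L matrix (sqrt(m) * ybar)
        e = sqm * Ybar
        project_cells = lambda Emat: Emat[ch, ce]  # noqa: E731
    else:
        sqm = np.sqrt(m)
        u_resp = sqm * ybar

        def _orth(F):
            Q, s, Pt = np.linalg.svd(F, full_matrices=False)
            keep = s > s[0] * 1e-12 if len(s) else np.zeros(0, bool)
            return Q[:, keep], s[keep], Pt[keep].T

        feats = {}
        F_g = sqm[:, None] * A_g[ch]
        F_e = sqm[:, None] * B_e[ce]
        if interaction_features == "dense":
            Kd = ks.dense_k()
            # collapse to one representative record per cell
            rep = np.zeros(n_cells, dtype=int)
            rep[cell_of] = np.arange(n)
            Kc = Kd[np.ix_(rep, rep)] / ck
            lamK, UK = np.linalg.eigh(Kc)
            ordk = np.argsort(lamK)[::-1]
            lamK, UK = np.clip(lamK[ordk], 0, None), UK[:, ordk]
            keepk = lamK > lamK.max() * 1e-12
            F_k = sqm[:, None] * (UK[:, keepk] * np.sqrt(lamK[keepk]))
            feats["snp_ec_pairs"] = None
        else:
            prod = np.outer(lamG, lamO).ravel()
            order = np.argsort(prod)[::-1]
            rmax = max_interaction_rank or len(prod)
            sel = order[:rmax]
            ii, jj = np.unravel_index(sel, (len(lamG), len(lamO)))
            F_k = sqm[:, None] * (A_k[ch][:, ii] * B_k[ce][:, jj])
            feats["snp_ec_pairs"] = (ii, jj)
        Qg, sg, Pg = _orth(F_g)
        Qe, se_, Pe = _orth(F_e)
        Qk, sk, Pk = _orth(F_k)
        feats.update({"Pg": Pg, "Pe": Pe, "Pk": Pk})
        blocks = [
            _FlatBlock("mu", (sqm / np.linalg.norm(sqm))[:, None],
                       np.array([np.linalg.norm(sqm)]), flat_prior=True),
            _FlatBlock("snp", Qg, sg),
            _FlatBlock("ec", Qe, se_),
            _FlatBlock("snp_ec", Qk, sk),
        ]
        e = u_resp.copy()
        project_cells = lambda evec: evec  # noqa: E731

    sig2 = {"snp": var_y / 4, "ec": var_y / 4, "snp_ec": var_y / 4}
    sig2e = var_y / 4
    n_saved = 0
    sums = {k: 0.0 for k in ("snp", "ec", "snp_ec", "error", "mu")}
    sums2 = {k: 0.0 for k in sums}
    samples = {k: [] for k in sums}
    eff_sum = {"snp": 0.0, "ec": 0.0, "snp_ec": 0.0}
    coef_sum = {b.name: np.zeros_like(b.gamma) for b in blocks}

    for it in range(n_iter):
        for b in blocks:
            e = _sample_block(b, e, sig2.get(b.name), sig2e, rng)
            if not b.flat:
                gsum = float(np.sum(b.gamma ** 2))
                p_b = b.gamma.size
                sig2[b.name] = _scaled_inv_chi2(rng, prior_df + p_b,
                                                prior_df * s0 + gsum)
        ss = ss_within + float(np.sum(e ** 2))
        sig2e = _scaled_inv_chi2(rng, prior_df + n, prior_df * s0 + ss)
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
            vals = {"snp": sig2["snp"], "ec": sig2["ec"],
                    "snp_ec": sig2["snp_ec"], "error": sig2e}
            # both paths place the intercept on a sqrt(m)-weighted ones column,
            # so the unweighted intercept is the raw coefficient itself
            vals["mu"] = float(np.ravel(blocks[0].gamma)[0])
            for k, v in vals.items():
                sums[k] += v
                sums2[k] += v * v
                samples[k].append(v)
            for b in blocks:
                coef_sum[b.name] += b.gamma
            for b in blocks[1:]:
                cell_fit = b.expand()
                eff_sum[b.name] += project_cells(cell_fit)

    post_mean = {k: sums[k] / n_saved for k in sums}
    post_sd = {k: np.sqrt(max(sums2[k] / n_saved - post_mean[k] ** 2, 0.0))
               for k in sums}
    vc = VarianceComponents(
        {k: post_mean[k] for k in ("ec", "snp", "snp_ec", "error")},
        {k: post_sd[k] for k in ("ec", "snp", "snp_ec", "error")},
    )
    # record-level posterior-mean effects (unweight the sqrt(m) cell scaling)
    inv_sqm = 1.0 / (np.sqrt(m[0]) if crossed else sqm)
    effects = {}
    for name in ("snp", "ec", "snp_ec"):
        cell_eff = eff_sum[name] / n_saved * inv_sqm
        effects[name] = pd.Series(cell_eff[cell_of], index=records.index)

    coef_mean = {k: v / n_saved for k, v in coef_sum.items()}
    if crossed:
        predictors = {
            "mu": post_mean["mu"],
            "snp": (A_g, coef_mean["snp"].ravel()),
            "ec": (B_e, coef_mean["ec"].ravel()),
            "snp_ec": (A_k, coef_mean["snp_ec"], B_k),
        }
    else:
        alpha_g = feats["Pg"] @ coef_mean["snp"]
        alpha_e = feats["Pe"] @ coef_mean["ec"]
        predictors = {"mu": post_mean["mu"], "snp": (A_g, alpha_g),
                      "ec": (B_e, alpha_e)}
        if feats.get("snp_ec_pairs") is not None:
            ii, jj = feats["snp_ec_pairs"]
            alpha_k = feats["Pk"] @ coef_mean["snp_ec"]
            Mk = np.zeros((A_k.shape[1], B_k.shape[1]))
            Mk[ii, jj] = alpha_k
            predictors["snp_ec"] = (A_k, Mk, B_k)
        else:
            predictors["snp_ec"] = None

    fixed = pd.DataFrame({"name": ["intercept"], "estimate": [post_mean["mu"]],
                          "se": [post_sd["mu"]]})
    return FitResult(
        varcomp=vc, fixed_effects=fixed, blups={}, loglik=None, n=n,
        extra={
            "effects": effects, "samples": {k: np.array(v) for k, v in samples.items()},
            "n_saved": n_saved, "crossed_path": crossed, "predictors": predictors,
            "diagnostics": {
                "n_iter": n_iter, "burn_in": burn_in, "thin": thin,
                "posterior_sd": post_sd,
            },
        },
    )


def predict_reaction_norm(fit: FitResult, h_idx, e_idx) -> np.ndarray:
    """Posterior-mean prediction ``mu + g + E + gE`` for (hybrid, YL) indices.

    Indices refer to the kernel row order used at fit time; unseen levels are
    handled through the kernel extension implicit in the eigen-features.
    """
    P = fit.extra["predictors"]
    if P.get("snp_ec") is None and P.get("snp") is None:
        raise ValueError("fit carries no prediction operators")
    A_g, a_g = P["snp"]
    B_e, a_e = P["ec"]
    out = P["mu"] + A_g[h_idx] @ a_g + B_e[e_idx] @ a_e
    if P.get("snp_ec") is not None:
        A_k, Mk, B_k = P["snp_ec"]
        out = out + np.einsum("ri,ij,rj->r", A_k[h_idx], Mk, B_k[e_idx])
    return out


# --------------------------------------------------------------------------
# Two-trait reaction norm
# --------------------------------------------------------------------------

def fit_two_trait(records: pd.DataFrame, traits, ks, standardize: bool = True,
                  include_interaction: bool = False, n_iter: int = 6000,
                  burn_in: int = 2000, thin: int = 2, seed: int = 0,
                  prior_df: float = 4.0) -> dict:
    """Bivariate reaction-norm fit with unstructured 2x2 covariances.

    Gibbs sampler over SNP, EC (and optionally SNP x EC) coefficient matrices
    with inverse-Wishart updates for each term's 2x2 covariance and the error
    covariance.  Records missing either trait are dropped.  Returns posterior
    means/SDs of the genetic, EC-level, and residual correlations plus the
    raw correlation samples.
    """
    t1, t2 = traits
    sub = records.dropna(subset=[t1, t2])
    Y = np.column_stack([
        _prepare(sub, t1, standardize), _prepare(sub, t2, standardize)
    ])
    if np.allclose(Y[:, 0], Y[:, 1]):
        warnings.warn("the two traits are identical; correlations are pinned near 1")
    n = len(sub)
    rng = np.random.default_rng(seed)

    pos = sub.index
    h_idx = np.argmax(ks.Z1, axis=1)[records.index.get_indexer(pos)]
    e_idx = np.argmax(ks.Z2, axis=1)[records.index.get_indexer(pos)]
    lamG, U = ks.eigen_g()
    lamO, V = ks.eigen_omega()
    kg = lamG > lamG.max() * 1e-10
    ko = lamO > lamO.max() * 1e-10
    A_g = (U[:, kg] * np.sqrt(lamG[kg]))[h_idx]
    B_e = (V[:, ko] * np.sqrt(lamO[ko]))[e_idx]
    A_g /= np.sqrt(np.mean(np.sum(A_g ** 2, axis=1)))  # mean diag 1
    B_e /= np.sqrt(np.mean(np.sum(B_e ** 2, axis=1)))
    term_feats = {"snp": A_g, "ec": B_e}
    if include_interaction:
        F_k = A_g[:, :, None] * B_e[:, None, :]
        term_feats["snp_ec"] = F_k.reshape(n, -1)

    blocks = {}
    for name, F in term_feats.items():
        Q, s, Pt = np.linalg.svd(F, full_matrices=False)
        keep = s > s[0] * 1e-10
        blocks[name] = {"Q": Q[:, keep], "s": s[keep],
                        "G": np.zeros((int(keep.sum()), 2))}

    n_terms = len(blocks) + 1
    share = np.trace(np.cov(Y.T)) / 2 / n_terms
    # weakly informative scale: a strong prior scale would pull correlations
    # toward zero whenever a term's coefficient norm is modest
    Psi0 = 0.1 * share * np.eye(2)
    Sig = {name: share * np.eye(2) for name in blocks}
    SigE = share * np.eye(2)
    mu = Y.mean(axis=0)
    E = Y - mu
    for b in blocks.values():
        E -= b["Q"] @ (b["s"][:, None] * b["G"])

    def _inv2(Mx):
        det = Mx[0, 0] * Mx[1, 1] - Mx[0, 1] * Mx[1, 0]
        return np.array([[Mx[1, 1], -Mx[0, 1]], [-Mx[1, 0], Mx[0, 0]]]) / det

    corr_samples = {name: [] for name in list(blocks) + ["error"]}
    for it in range(n_iter):
        iSigE = _inv2(SigE)
        for name, b in blocks.items():
            Q, s, G = b["Q"], b["s"], b["G"]
            E += Q @ (s[:, None] * G)
            Z = s[:, None] * (Q.T @ E)          # r x 2
            iSig = _inv2(Sig[name])
            s2 = s * s
            # vectorized 2x2 posterior: P = s2*iSigE + iSig
            P11 = s2 * iSigE[0, 0] + iSig[0, 0]
            P12 = s2 * iSigE[0, 1] + iSig[0, 1]
            P22 = s2 * iSigE[1, 1] + iSig[1, 1]
            det = P11 * P22 - P12 * P12
            V11, V12, V22 = P22 / det, -P12 / det, P11 / det
            rhs1 = iSigE[0, 0] * Z[:, 0] + iSigE[0, 1] * Z[:, 1]
            rhs2 = iSigE[1, 0] * Z[:, 0] + iSigE[1, 1] * Z[:, 1]
            m1 = V11 * rhs1 + V12 * rhs2
            m2 = V12 * rhs1 + V22 * rhs2
            # Cholesky of the 2x2 posterior covariance, vectorized
            l11 = np.sqrt(V11)
            l21 = V12 / l11
            l22 = np.sqrt(np.maximum(V22 - l21 * l21, 1e-300))
            z1 = rng.standard_normal(len(s))
            z2 = rng.standard_normal(len(s))
            G[:, 0] = m1 + l11 * z1
            G[:, 1] = m2 + l21 * z1 + l22 * z2
            E -= Q @ (s[:, None] * G)
            Sig[name] = stats.invwishart.rvs(df=prior_df + len(s),
                                             scale=Psi0 + G.T @ G, random_state=rng)
        # intercepts (flat prior)
        E += mu
        mu = E.mean(axis=0) + stats.multivariate_normal.rvs(
            mean=np.zeros(2), cov=SigE / n, random_state=rng)
        E -= mu
        SigE = stats.invwishart.rvs(df=prior_df + n, scale=Psi0 + E.T @ E,
                                    random_state=rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for name in blocks:
                S = Sig[name]
                corr_samples[name].append(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))
            corr_samples["error"].append(SigE[0, 1] / np.sqrt(SigE[0, 0] * SigE[1, 1]))

    out = {}
    for name, vals in corr_samples.items():
        arr = np.asarray(vals)
        out[name] = {"mean": float(arr.mean()), "sd": float(arr.std()),
                     "samples": arr}
    return out


# --------------------------------------------------------------------------
# Phenotypic correlations
# --------------------------------------------------------------------------

def correlation_se(r: float, n: int) -> float:
    """SE of a Pearson correlation, ``sqrt((1 - r^2) / (n - 2))``."""
    return float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))


def phenotypic_correlations(records: pd.DataFrame, trait_x: str, trait_y: str,
                            min_n: int = 3, weights: str = "inv_se2",
                            fits: tuple | None = None) -> dict:
    """Across-, within-, and between-year-location trait correlations.

    * across: pooled Pearson correlation over all complete records;
    * within: per-year-location Pearson correlations combined by
      inverse-squared-SE weights (``SE(r_i) = sqrt((1-r_i^2)/(n_i-2))``), or
      by record counts with ``weights='count'``; year-locations with fewer
      than ``min_n`` records are excluded and listed;
    * between: Pearson correlation of the model-estimated year-location means
      of the two traits (baseline random-effects fits, computed here unless
      passed via ``fits``).
    """
    sub = records.dropna(subset=[trait_x, trait_y])
    x, y = sub[trait_x].to_numpy(float), sub[trait_y].to_numpy(float)
    across = float(np.corrcoef(x, y)[0, 1])

    rows, excluded = [], []
    for yl, g in sub.groupby("year_location", sort=False):
        if len(g) < min_n:
            excluded.append(yl)
            continue
        gx, gy = g[trait_x].to_numpy(float), g[trait_y].to_numpy(float)
        if gx.std() == 0 or gy.std() == 0:
            excluded.append(yl)
            continue
        r = float(np.corrcoef(gx, gy)[0, 1])
        rows.append((yl, r, len(g)))
    per_yl = pd.DataFrame(rows, columns=["year_location", "r", "n"])
    if len(per_yl):
        if weights == "inv_se2":
            se = np.array([correlation_se(r, n) for r, n in zip(per_yl.r, per_yl.n)])
            w = 1.0 / np.maximum(se, 1e-8) ** 2
        elif weights == "count":
            w = per_yl.n.to_numpy(float)
        else:
            raise ValueError(f"unknown weighting {weights!r}")
        within = float(np.average(per_yl.r, weights=w))
        within_se = float(1.0 / np.sqrt(w.sum())) if weights == "inv_se2" else np.nan
    else:
        within, within_se = np.nan, np.nan

    if fits is None:
        fx = fit_random_effects(sub, trait_x, compute_se=False)
        fy = fit_random_effects(sub, trait_y, compute_se=False)
    else:
        fx, fy = fits

    def _yl_means(fit):
        yls = sorted(sub["year_location"].unique())
        vals = []
        for yl in yls:
            g = sub[sub["year_location"] == yl].iloc[0]
            v = fit.mu
            v += fit.blups["year"].get(str(g["year"]), 0.0)
            v += fit.blups["location"].get(str(g["location"]), 0.0)
            v += fit.blups["year_location"].get(str(yl), 0.0)
            vals.append(v)
        return np.array(vals)

    mx, my = _yl_means(fx), _yl_means(fy)
    between = float(np.corrcoef(mx, my)[0, 1])
    return {
        "across": across, "within": within, "within_se": within_se,
        "between": between, "per_year_location": per_yl,
        "excluded_year_locations": excluded,
    }
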