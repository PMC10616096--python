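"""Cross-validation benchmarking of the prediction models.

Two schemes mirror the questions breeders ask of multi-environment data:

* ``10F_hybrid`` (CV1): whole hybrids are held out in 10 folds, mimicking the
  prediction of untested hybrids.  A model without marker data cannot
  transfer hybrid information into the test fold, so its within-trial
  accuracy hovers around zero; a SNP + EC reaction norm learns hybrid effects
  through genomic relationships.
* ``leave_year_out`` (LYO): all records of one year form the test set,
  mimicking prediction of a future season.

Accuracy is summarized as the within-year-location Pearson correlation
between predicted and observed phenotypes, aggregated across year-locations
by inverse-squared-SE weights (``SE(r) = sqrt((1-r^2)/(n-2))``).

All preprocessing that involves the response or environment summaries (EC
standardization for Omega, PC score computation) is fitted on training rows
only; an audit log records exactly which rows each preprocessing step
touched so leakage is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels as _kernels
from . import models as _models

__all__ = ["CVPlan", "CVResult", "AuditLog", "make_folds", "make_lyo_splits",
           "run_cv", "summarize_benchmark", "weighted_mean_correlation"]


@dataclass
class CVPlan:
    scheme: str                  # '10F_hybrid' or 'leave_year_out'
    assignment: pd.Series        # hybrid -> fold, or year -> split id
    seed: int | None = None

    def splits(self, records: pd.DataFrame):
        """Yield (split_label, train_index, test_index) over record rows."""
        if self.scheme == "10F_hybrid":
            fold_of = records["hybrid"].map(self.assignment)
        elif self.scheme == "leave_year_out":
            fold_of = records["year"].map(self.assignment)
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for k in sorted(self.assignment.unique()):
            test = records.index[fold_of == k]
            train = records.index[fold_of != k]
            yield k, train, test


@dataclass
class AuditLog:
    """Records which rows each preprocessing step touched (leakage audit)."""

    entries: list = field(default_factory=list)

    def record(self, step: str, rows):
        self.entries.append((step, frozenset(rows)))

    def rows_touched(self, step_prefix: str = ""):
        out = set()
        for step, rows in self.entries:
            if step.startswith(step_prefix):
                out |= rows
        return out


@dataclass
class CVResult:
    scheme: str
    model: str
    trait: str
    predictions: pd.DataFrame    # record index, observed, predicted, split
    per_yl: pd.DataFrame         # year_location, r, n, se
    aggregate_r: float
    aggregate_se: float
    audit: AuditLog = None


def make_folds(hybrids, k: int = 10, seed: int = 0) -> CVPlan:
    """Randomly assign hybrids to ``k`` non-overlapping folds of near-equal size."""
    hybrids = pd.Index(pd.unique(pd.Series(list(hybrids))))
    if k > len(hybrids):
        raise ValueError(f"cannot make {k} folds from {len(hybrids)} hybrids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(hybrids))
    folds = np.empty(len(hybrids), dtype=int)
    folds[perm] = np.arange(len(hybrids)) % k
    return CVPlan(scheme="10F_hybrid",
                  assignment=pd.Series(folds, index=hybrids), seed=seed)


def make_lyo_splits(years) -> CVPlan:
    """One split per distinct year; the year's records form the test set."""
    years = sorted(pd.unique(pd.Series(list(years))))
    if len(years) < 2:
        raise ValueError("leave-one-year-out needs at least two years")
    return CVPlan(scheme="leave_year_out",
                  assignment=pd.Series(range(len(years)), index=years))


def weighted_mean_correlation(per_yl: pd.DataFrame, weights: str = "inv_se2"):
    """Aggregate per-year-location correlations; returns ``(mean, se)``."""
    if len(per_yl) == 0:
        return np.nan, np.nan
    r = per_yl["r"].to_numpy(float)
    n = per_yl["n"].to_numpy(float)
    if weights == "inv_se2":
        se = np.sqrt(np.clip(1 - r * r, 1e-8, None) / (n - 2))
        w = 1.0 / se**2
    elif weights == "count":
        w = n
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    mean = float(np.average(r, weights=w))
    # SE of the weighted mean from the weighted dispersion of the r_i
    resid = r - mean
    se_mean = float(np.sqrt(np.sum(w**2 * resid**2)) / w.sum())
    return mean, se_mean


def _per_yl_correlations(pred: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    rows = []
    for yl, g in pred.groupby("year_location", sort=False):
        if len(g) < min_n or g["observed"].std() == 0 or g["predicted"].std() == 0:
            continue
        r = float(np.corrcoef(g["observed"], g["predicted"])[0, 1])
        rows.append((yl, r, len(g), _models.correlation_se(r, len(g))))
    return pd.DataFrame(rows, columns=["year_location", "r", "n", "se"])


def _predict_re(fit, test: pd.DataFrame, pc_X: np.ndarray | None = None):
    """mu + BLUPs for seen levels (+ fixed PC effects); unseen levels -> 0."""
    pred = np.full(len(test), fit.mu)
    blups = fit.blups
    keys = {
        "hybrid": test["hybrid"].astype(str),
        "year": test["year"].astype(str),
        "location": test["location"].astype(str),
        "year_location": test["year_location"].astype(str),
        "hybrid_location": test["hybrid"].astype(str) + "|" + test["location"].astype(str),
    }
    for term, labels in keys.items():
        pred += labels.map(blups[term]).fillna(0.0).to_numpy()
    if pc_X is not None:
        beta = fit.fixed_effects["estimate"].to_numpy()[1:]
        pred += pc_X @ beta
    return pred


def run_cv(plan: CVPlan, model: str, records: pd.DataFrame, dosages: pd.DataFrame,
           ec_raw: pd.DataFrame, trait: str = "yield", seed: int = 0,
           sampler: dict | None = None, n_snp_pcs: int = 10, n_ec_pcs: int = 5,
           standardize_omega_on: str = "train") -> CVResult:
    """Run one cross-validation scheme for one model and trait.

    ``model`` is ``'re'`` (baseline random effects), ``'snp_ec'`` (reaction
    norm on G, Omega, K), or ``'re_pc'`` (random effects plus top SNP/EC PC
    fixed effects).  ``ec_raw`` is the unstandardized year-location x EC
    matrix: EC standardization (and EC/SNP PC computation for ``re_pc``) is
    redone inside every training split; ``standardize_omega_on='full'``
    reuses full-data standardization instead (flagged in the audit log).

    The trait is standardized once on its global mean/sd purely to put
    models on a common scale; correlations are invariant to that scaling.
    """
    sampler = dict(n_iter=2000, burn_in=500, thin=2) | (sampler or {})
    audit = AuditLog()
    rec = records.copy()
    y_all = rec[trait].to_numpy(float)
    y_std = (y_all - y_all.mean()) / y_all.std()
    rec["_y"] = y_std

    hybrids = list(dosages.index)
    G = _kernels.genomic_relationship(dosages)
    preds = []
    lam0 = None
    if model == "re":  # warm-start fold fits from the full-data optimum
        lam0 = _models.fit_random_effects(rec, "_y", standardize=False,
                                          compute_se=False).extra["lam"]

    for split, train_idx, test_idx in plan.splits(rec):
        train, test = rec.loc[train_idx], rec.loc[test_idx]
        if model == "re":
            fit = _models.fit_random_effects(train, "_y", standardize=False,
                                             compute_se=False, lam0=lam0)
            p = _predict_re(fit, test)
        elif model == "re_pc":
            p = _run_pc_split(train, test, G, hybrids, ec_raw, audit, split,
                              n_snp_pcs, n_ec_pcs)
        elif model == "snp_ec":
            p = _run_rn_split(train, test, G, hybrids, ec_raw, audit, split,
                              sampler, seed, standardize_omega_on)
        else:
            raise ValueError(f"unknown model {model!r}")
        preds.append(pd.DataFrame({
            "record": test.index, "year_location": test["year_location"].to_numpy(),
            "observed": test["_y"].to_numpy(), "predicted": p, "split": split,
        }))

    pred = pd.concat(preds, ignore_index=True)
    assert pred["record"].is_unique, "a test record was predicted twice"
    per_yl = _per_yl_correlations(pred)
    agg, agg_se = weighted_mean_correlation(per_yl)
    return CVResult(scheme=plan.scheme, model=model, trait=trait,
                    predictions=pred, per_yl=per_yl,
                    aggregate_r=agg, aggregate_se=agg_se, audit=audit)


def _train_omega(ec_raw, train_yls, audit, split, train_rows, mode):
    """Standardize EC columns on training year-locations, extend to all."""
    if mode == "train":
        stats_src = ec_raw.loc[[yl for yl in ec_raw.index if yl in train_yls]]
        audit.record(f"split{split}:omega_standardization", train_rows)
    else:  # full-data standardization, explicitly flagged
        stats_src = ec_raw
        audit.record(f"split{split}:omega_standardization_FULL", ec_raw.index)
    mu = stats_src.mean(axis=0)
    sd = stats_src.std(axis=0, ddof=0)
    keep = sd > 0
    W = (ec_raw.loc[:, keep] - mu[keep]) / sd[keep]
    WW = W.to_numpy() @ W.to_numpy().T
    Om = WW / np.trace(WW)
    return (Om + Om.T) / 2.0


def _run_pc_split(train, test, G, hybrids, ec_raw, audit, split,
                  n_snp_pcs, n_ec_pcs):
    train_hyb = sorted(set(train["hybrid"]))
    hi = pd.Index(hybrids)
    tr_pos = hi.get_indexer(train_hyb)
    G_tr = G[np.ix_(tr_pos, tr_pos)]
    pc_g = _kernels.pca(G_tr)
    audit.record(f"split{split}:snp_pc", train.index)
    k_g = min(n_snp_pcs, int(np.sum(pc_g.eigenvalues > 1e-12)))
    scores_tr = pc_g.scores[:, :k_g]
    # out-of-sample hybrids projected through cross-kernel rows
    all_pos = hi.get_indexer(hi)
    cross = G[np.ix_(all_pos, tr_pos)]
    scores_all = pc_g.project(cross, k_g)
    snp_pcs = pd.DataFrame(scores_all, index=hi)
    snp_pcs.iloc[tr_pos] = scores_tr

    train_yls = set(train["year_location"])
    yl_index = list(ec_raw.index)
    Om = _train_omega(ec_raw, train_yls, audit, split, train.index, "train")
    tr_yl_pos = [i for i, yl in enumerate(yl_index) if yl in train_yls]
    pc_e = _kernels.pca(Om[np.ix_(tr_yl_pos, tr_yl_pos)])
    audit.record(f"split{split}:ec_pc", train.index)
    k_e = min(n_ec_pcs, int(np.sum(pc_e.eigenvalues > 1e-12)))
    cross_e = Om[:, tr_yl_pos]
    ec_scores = pc_e.project(cross_e, k_e)
    ec_scores[tr_yl_pos] = pc_e.scores[:, :k_e]
    ec_pcs = pd.DataFrame(ec_scores, index=yl_index)

    fit = _models.fit_pc_model(train, "_y", snp_pcs, ec_pcs, standardize=False)
    names = list(fit.fixed_effects["name"])[1:]
    Xh = snp_pcs.loc[test["hybrid"]].to_numpy()
    Xe = ec_pcs.loc[test["year_location"]].to_numpy()
    X_full = np.column_stack([Xh, Xe])
    full_names = ([f"snp_pc{j+1}" for j in range(Xh.shape[1])]
                  + [f"ec_pc{j+1}" for j in range(Xe.shape[1])])
    keep = [full_names.index(nm) for nm in names]
    return _predict_re(fit, test, pc_X=X_full[:, keep])


def _kernel_extension(K_full, train_pos):
    """Conditional-mean operator ``K[., train] K[train, train]^+`` (BLUP
    extension of a random effect to levels absent from training)."""
    Kt = K_full[np.ix_(train_pos, train_pos)]
    lam, U = np.linalg.eigh(Kt)
    keep = lam > lam.max() * 1e-10
    pinv = (U[:, keep] / lam[keep]) @ U[:, keep].T
    return K_full[:, train_pos] @ pinv


def _run_rn_split(train, test, G, hybrids, ec_raw, audit, split, sampler,
                  seed, omega_mode):
    """Fit the reaction norm on the training split and predict test records.

    When the training design is fully crossed (every training hybrid in every
    training year-location, constant replication) the fit runs on kernels
    restricted to the training levels via the Kronecker fast path, and
    test-level effects are obtained by kernel extension
    ``E[u_test | u_train] = K[test,train] K[train,train]^+ u_train``.
    Otherwise the general sampler runs on features built from the full-design
    kernels, which realizes the same extension implicitly.
    """
    train_yls = set(train["year_location"])
    Om = _train_omega(ec_raw, train_yls, audit, split, train.index, omega_mode)
    yls = list(ec_raw.index)
    hi, yi = pd.Index(hybrids), pd.Index(yls)

    tr_h = sorted(set(train["hybrid"]))
    tr_e = sorted(train_yls)
    h_pos = hi.get_indexer(tr_h)
    e_pos = yi.get_indexer(tr_e)
    cells = train.groupby(["hybrid", "year_location"]).size()
    crossed = (len(cells) == len(tr_h) * len(tr_e)) and cells.nunique() == 1

    if crossed:
        G_tr = G[np.ix_(h_pos, h_pos)]
        Om_tr = Om[np.ix_(e_pos, e_pos)]
        Z1 = _kernels.incidence(train["hybrid"], tr_h)
        Z2 = _kernels.incidence(train["year_location"], tr_e)
        ks = _kernels.KernelSet(G=G_tr, omega=Om_tr, Z1=Z1, Z2=Z2,
                                hybrids=tr_h, year_locations=tr_e)
        fit = _models.fit_reaction_norm(
            train, ks, trait="_y", standardize=False, seed=seed,
            n_iter=sampler["n_iter"], burn_in=sampler["burn_in"], thin=sampler["thin"],
        )
        P = fit.extra["predictors"]
        A_g, a_g = P["snp"]
        B_e, a_e = P["ec"]
        A_k, Mk, B_k = P["snp_ec"]
        g_tr = A_g @ a_g                      # training-hybrid effects
        E_tr = B_e @ a_e                      # training-YL effects
        W_tr = A_k @ Mk @ B_k.T               # training (hybrid x YL) interaction
        Tg = _kernel_extension(G, h_pos)      # all hybrids x train hybrids
        Te = _kernel_extension(Om, e_pos)
        g_all, E_all = Tg @ g_tr, Te @ E_tr
        W_all = Tg @ W_tr @ Te.T
        th = hi.get_indexer(test["hybrid"])
        te = yi.get_indexer(test["year_location"])
        return P["mu"] + g_all[th] + E_all[te] + W_all[th, te]

    Z1 = _kernels.incidence(train["hybrid"], hybrids)
    Z2 = _kernels.incidence(train["year_location"], yls)
    ks = _kernels.KernelSet(G=G, omega=Om, Z1=Z1, Z2=Z2,
                            hybrids=hybrids, year_locations=yls)
    fit = _models.fit_reaction_norm(
        train, ks, trait="_y", standardize=False, seed=seed,
        force_general=True, max_interaction_rank=sampler.get("max_interaction_rank", 400),
        n_iter=sampler["n_iter"], burn_in=sampler["burn_in"], thin=sampler["thin"],
    )
    h_idx = hi.get_indexer(test["hybrid"])
    e_idx = yi.get_indexer(test["year_location"])
    return _models.predict_reaction_norm(fit, h_idx, e_idx)


def summarize_benchmark(results: list) -> pd.DataFrame:
    """Comparison table of CV results sharing one plan.

    One row per (model, trait, scheme) with the aggregate correlation and its
    SE, plus paired per-year-location sign-test p-values against the first
    result in the list.  Results with mismatched schemes raise ``ValueError``.
    """
    from scipy.stats import binomtest

    schemes = {r.scheme for r in results}
    if len(schemes) != 1:
        raise ValueError("results come from different CV schemes")
    base = results[0]
    rows = []
    for r in results:
        merged = base.per_yl.merge(r.per_yl, on="year_location", suffixes=("_base", ""))
        diff = merged["r"] - merged["r_base"]
        nz = diff[diff != 0]
        p = binomtest(int((nz > 0).sum()), len(nz), 0.5).pvalue if len(nz) else 1.0
        rows.append((r.model, r.trait, r.scheme, r.aggregate_r, r.aggregate_se,
                     float(diff.mean()), float(p)))
    return pd.DataFrame(rows, columns=["model", "trait", "scheme", "aggregate_r",
                                       "se", "mean_diff_vs_first", "sign_test_p"])
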