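"""Quality control for plot phenotypes and SNP genotypes.

Phenotype rules, applied in a fixed, logged order:

1. drop records missing any of planting, harvesting, anthesis, or silking date;
2. drop records with anthesis-silking interval (ASI) above 15 days (strict);
3. within each year-location, drop yield records outside
   ``[Q25 - 2.5 IQR, Q75 + 2.5 IQR]`` (linear-interpolation quantiles; the
   rule is skipped, and logged, for groups with fewer than 4 records).

Genotype rules: keep bi-allelic SNPs with minor allele frequency strictly
above 3% and missing rate strictly below 10%, then mean-impute survivors.
LD pruning links SNPs with squared dosage correlation above 0.85 within 1 Mbp
on the same chromosome and keeps one representative per connected set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["filter_phenotypes", "filter_genotypes", "ld_prune", "compute_gdd_traits"]

_DATE_COLS = ["planting_date", "harvesting_date", "anthesis_date", "silking_date"]


def filter_phenotypes(records: pd.DataFrame, asi_max: float = 15.0,
                      iqr_mult: float = 2.5, min_group: int = 4):
    """Apply the phenotype QC rules; returns ``(kept, rejection_log)``.

    The rejection log has one row per dropped record with the first rule that
    fired (``missing_dates``, ``asi``, or ``yield_outlier``) and a detail
    string; skipped outlier groups are logged with rule ``outlier_skipped``.
    """
    rec = records.copy()
    log_rows = []

    missing = rec[_DATE_COLS].isna().any(axis=1)
    for idx in rec.index[missing]:
        bad = [c for c in _DATE_COLS if pd.isna(rec.at[idx, c])]
        log_rows.append((idx, "missing_dates", ",".join(bad)))
    rec = rec[~missing]

    high_asi = rec["asi_days"] > asi_max
    for idx in rec.index[high_asi]:
        log_rows.append((idx, "asi", f"asi_days={rec.at[idx, 'asi_days']}"))
    rec = rec[~high_asi]

    drop = []
    for yl, sub in rec.groupby("year_location", sort=False):
        if len(sub) < min_group:
            log_rows.append((-1, "outlier_skipped", f"{yl}: n={len(sub)} < {min_group}"))
            continue
        q25, q75 = np.percentile(sub["yield"], [25, 75])  # linear interpolation
        iqr = q75 - q25
        lo, hi = q25 - iqr_mult * iqr, q75 + iqr_mult * iqr
        out = sub.index[(sub["yield"] > hi) | (sub["yield"] < lo)]
        for idx in out:
            log_rows.append((idx, "yield_outlier",
                             f"yield={sub.at[idx, 'yield']:.3f} outside [{lo:.3f},{hi:.3f}]"))
        drop.extend(out)
    rec = rec.drop(index=drop)

    log = pd.DataFrame(log_rows, columns=["record", "rule", "detail"])
    return rec, log


def filter_genotypes(dosages: pd.DataFrame, maf_min: float = 0.03,
                     missing_max: float = 0.10) -> pd.DataFrame:
    """Drop SNPs failing MAF/missingness rules, mean-impute the rest.

    MAF must be strictly greater than ``maf_min`` and the missing fraction
    strictly smaller than ``missing_max``; all-missing SNPs are dropped with a
    warning.  Surviving columns are imputed with their observed mean, so the
    column mean is preserved.
    """
    X = dosages.to_numpy(dtype=float)
    n = X.shape[0]
    n_miss = np.isnan(X).sum(axis=0)
    all_missing = n_miss == n
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} SNP(s) with all values missing")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = (~all_missing) & (maf > maf_min) & (n_miss / n < missing_max)
    X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    ix = np.where(np.isnan(X))
    X[ix] = col_mean[ix[1]]
    return pd.DataFrame(X, index=dosages.index, columns=dosages.columns[keep])


def ld_prune(dosages: pd.DataFrame, snp_map: pd.DataFrame,
             r2_threshold: float = 0.85, max_dist_bp: int = 1_000_000):
    """LD pruning by connected components of the R^2 > threshold graph.

    Within each chromosome, SNP pairs with squared Pearson correlation of
    dosages strictly above ``r2_threshold`` and positions at most
    ``max_dist_bp`` apart are linked; connected components form LD sets and
    the most representative SNP of each set is retained — the member with the
    highest mean R^2 to the other members, ties broken by lowest bp position.
    Unlinked SNPs are all retained; zero-variance SNPs are excluded from the
    correlation, retained trivially, and logged with a warning.

    Returns the retained SNP ids in map order.
    """
    m = snp_map.set_index("snp")
    X = dosages.to_numpy(dtype=float)
    snps = list(dosages.columns)
    sd = X.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{zero_var.sum()} zero-variance SNP(s) excluded from LD "
                      "correlation and retained")
    retained = set(np.asarray(snps)[zero_var])

    for chrom, chrom_map in m.groupby("chrom", sort=False):
        ids = [s for s in chrom_map.index if s in dosages.columns]
        cols = [snps.index(s) for s in ids if not zero_var[snps.index(s)]]
        if not cols:
            continue
        names = [snps[c] for c in cols]
        bp = m.loc[names, "bp"].to_numpy()
        sub = X[:, cols]
        sub = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        r2 = (sub.T @ sub / sub.shape[0]) ** 2
        close = np.abs(bp[:, None] - bp[None, :]) <= max_dist_bp
        adj = (r2 > r2_threshold) & close
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            members = np.flatnonzero(labels == comp)
            if len(members) == 1:
                retained.add(names[members[0]])
                continue
            block = r2[np.ix_(members, members)]
            mean_r2 = (block.sum(axis=1) - 1.0) / (len(members) - 1)
            order = sorted(range(len(members)),
                           key=lambda k: (-round(mean_r2[k], 12), bp[members[k]]))
            retained.add(names[members[order[0]]])
    return [s for s in m.index if s in retained]


def compute_gdd_traits(records: pd.DataFrame, series_by_yl: dict,
                       base_c: float = 10.0, cap_c: float = 30.0) -> pd.DataFrame:
    """Accumulate growing degree days from planting to each flowering date.

    Daily GDD = ``max(0, (min(tmax, cap) + max(tmin, base)) / 2 - base)``;
    defaults 10/30 degC follow the maize convention.  Records whose flowering
    day lies beyond the daily series are flagged (``gdd_flag``) with GDD left
    missing.
    """
    rec = records.copy()
    rec["anthesis_gdd"] = np.nan
    rec["silking_gdd"] = np.nan
    rec["gdd_flag"] = False
    for yl, sub in rec.groupby("year_location", sort=False):
        s = series_by_yl.get(yl)
        if s is None:
            rec.loc[sub.index, "gdd_flag"] = True
            continue
        daily = np.maximum(
            0.0, (np.minimum(s.tmax, cap_c) + np.maximum(s.tmin, base_c)) / 2.0 - base_c
        )
        cum = np.concatenate([[0.0], np.cumsum(daily)])
        n_days = len(daily)
        for trait, col in (("anthesis_days", "anthesis_gdd"), ("silking_days", "silking_gdd")):
            d = sub[trait].to_numpy()
            ok = d <= n_days
            rec.loc[sub.index[~ok], "gdd_flag"] = True
            rec.loc[sub.index[ok], col] = cum[d[ok].astype(int)]
    return rec
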