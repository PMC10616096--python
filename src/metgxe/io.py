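"""CSV readers/writers for the pipeline's tabular interchange formats.

All formats are plain text so that simulated data sets round-trip through the
curation and kernel builders: a plot-level phenotype table, a hybrid x SNP
dosage matrix with a genomic map, a year-location x covariate (EC) matrix, a
long-format daily environment table, and labeled square kernel matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: columns of the plot-level phenotype table, in canonical order
PHENOTYPE_COLUMNS = [
    "hybrid", "year", "location", "region", "replicate", "year_location",
    "planting_date", "harvesting_date", "anthesis_date", "silking_date",
    "yield", "anthesis_days", "silking_days", "asi_days",
]

DATE_COLUMNS = ["planting_date", "harvesting_date", "anthesis_date", "silking_date"]


def year_location_key(year, location) -> str:
    """Canonical ``"<year>:<location>"`` key for one trial environment."""
    return f"{year}:{location}"


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in DATE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_dosages(dosages: pd.DataFrame, snp_map: pd.DataFrame, dosage_path, map_path) -> None:
    """Write a hybrids x SNPs dosage matrix and its (snp, chrom, bp) map."""
    dosages.to_csv(dosage_path, index_label="hybrid")
    snp_map.to_csv(map_path, index=False)


def read_dosages(dosage_path, map_path):
    dosages = pd.read_csv(dosage_path, index_col="hybrid")
    snp_map = pd.read_csv(map_path)
    return dosages, snp_map


def write_ec_matrix(ec: pd.DataFrame, path) -> None:
    ec.to_csv(path, index_label="year_location")


def read_ec_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="year_location")


def write_kernel(kernel: pd.DataFrame | np.ndarray, path, labels=None) -> None:
    if not isinstance(kernel, pd.DataFrame):
        kernel = pd.DataFrame(kernel, index=labels, columns=labels)
    kernel.to_csv(path, index_label="id")


def read_kernel(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


def write_daily_long(series_by_yl: dict, path) -> None:
    """Long format: year_location, day, variable, layer, value.

    Scalar daily variables get layer = -1; per-soil-layer variables carry the
    layer index.  Stage boundaries are emitted as variable ``stage_bound``
    with the boundary index in ``day`` and the day value in ``value``.
    """
    rows = []
    for yl, s in series_by_yl.items():
        for name in ("tmax", "tmin", "eo", "cover_green", "supply"):
            vals = getattr(s, name)
            for d, v in enumerate(vals):
                rows.append((yl, d, name, -1, v))
        for layer in range(s.soil_water.shape[0]):
            for d in range(s.soil_water.shape[1]):
                rows.append((yl, d, "soil_water", layer, s.soil_water[layer, d]))
                rows.append((yl, d, "soil_access", layer, s.soil_access[layer, d]))
        for i, b in enumerate(s.stage_bounds):
            rows.append((yl, i, "stage_bound", -1, b))
    pd.DataFrame(rows, columns=["year_location", "day", "variable", "layer", "value"]).to_csv(
        path, index=False
    )


def read_daily_long(path) -> dict:
    from .simdata import DailyEnvSeries  # local import avoids a cycle

    df = pd.read_csv(path)
    out = {}
    for yl, sub in df.groupby("year_location", sort=False):
        def _scalar(name):
            v = sub[sub.variable == name].sort_values("day")
            return v.value.to_numpy()

        bounds = _scalar("stage_bound").astype(int)
        n_days = len(sub[sub.variable == "tmax"])
        n_layers = int(sub[sub.variable == "soil_water"].layer.max()) + 1
        soil_water = np.empty((n_layers, n_days))
        soil_access = np.empty((n_layers, n_days))
        for layer in range(n_layers):
            for nm, arr in (("soil_water", soil_water), ("soil_access", soil_access)):
                v = sub[(sub.variable == nm) & (sub.layer == layer)].sort_values("day")
                arr[layer] = v.value.to_numpy()
        out[yl] = DailyEnvSeries(
            year_location=yl,
            tmax=_scalar("tmax"), tmin=_scalar("tmin"), eo=_scalar("eo"),
            cover_green=_scalar("cover_green"), supply=_scalar("supply"),
            soil_water=soil_water, soil_access=soil_access,
            stage_bounds=bounds,
        )
    return out


def read_vcf_dosages(path):
    """Read dosages (count of ALT allele) from a minimal bi-allelic VCF.

    Ignores phasing; ``./.`` becomes missing (NaN).  Multi-allelic or symbolic
    records are skipped.  Requires the optional ``cyvcf2`` dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("VCF support requires the optional 'cyvcf2' dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, chroms, positions, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0].startswith("<"):
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        names.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dose)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=names)
    dosages.index.name = "hybrid"
    snp_map = pd.DataFrame({"snp": names, "chrom": chroms, "bp": positions})
    return dosages, snp_map
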