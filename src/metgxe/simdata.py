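"""Synthetic multi-environment maize trial generator.

Emulates the statistical structure the downstream analyses assume, so every
stage of the pipeline is testable without any external download:

* tester-group population structure among hybrids (Balding-Nichols group
  allele frequencies around a common ancestral frequency);
* a north/south regional network of trial locations with a latitude split;
* environmental covariates whose variance partitions into region, location,
  and year-location shares (the study system attributes roughly 60% of EC
  variability to years and year-location interactions);
* daily environment series (temperature, potential evapotranspiration, green
  canopy cover, crop water supply, layered soil water) consistent with the
  stage-averaged EC summaries;
* phenotypes generated from the reaction-norm model
  ``y = mu + g + E + gE + eps`` with components drawn from the corresponding
  multivariate normals and rescaled so each realized component variance
  equals its configured fraction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import year_location_key
from . import kernels as _kernels

__all__ = [
    "SimConfig", "TrialDesign", "DailyEnvSeries", "make_trial_design",
    "simulate_genotypes", "simulate_environment", "simulate_phenotypes",
    "GenotypeMatrix", "EC_TYPE_NAMES",
]

#: the 21 daily environmental-covariate types tracked by the generator,
#: mirroring crop-model outputs (thermal time, evapotranspiration, canopy,
#: biomass, and soil-water variables)
EC_TYPE_NAMES = [
    "TT", "CumTT", "Radn", "Eo", "Eos", "Es", "LAI", "CoverGreen", "CoverTotal",
    "Biomass", "Yield", "SW", "ESW", "Supply", "Demand", "Flow", "Flux",
    "TimeEvap2", "PotRunoff", "PotInfiltr", "FlowNo3",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs for the synthetic trial generator.

    ``variance_fractions`` are the reaction-norm shares of a unit-variance
    phenotype (EC main effect, SNP main effect, SNP x EC interaction, plot
    error); defaults follow the grain-yield column of the study's
    variance-partition table.  ``ec_variance_shares`` partition each EC
    column into region / location / year-location components.
    """

    n_hybrids: int = 300
    n_groups: int = 3
    n_snps: int = 2000
    n_chromosomes: int = 10
    maf_range: tuple = (0.1, 0.5)
    fst: float = 0.25
    missing_rate: float = 0.0
    n_years: int = 4
    n_locations_north: int = 4
    n_locations_south: int = 3
    n_replicates: int = 2
    prop_yls_per_hybrid: float = 1.0
    season_days: int = 150
    n_stages: int = 9
    ec_variance_shares: dict = field(
        default_factory=lambda: {"region": 0.2, "location": 0.2, "year_location": 0.6}
    )
    variance_fractions: dict = field(
        default_factory=lambda: {"ec": 0.485, "snp": 0.067, "snp_ec": 0.091, "error": 0.380}
    )
    mean_yield: float = 9.5
    sd_yield: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_hybrids", "n_groups", "n_snps", "n_years",
                     "n_locations_north", "n_locations_south", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        vf = self.variance_fractions
        if any(v < 0 for v in vf.values()):
            raise ConfigurationError("variance fractions must be non-negative")
        # printed variance-partition tables can sum slightly off 1 after
        # rounding, so allow a small deviation; the phenotype variance then
        # equals the sum of the fractions
        if abs(sum(vf.values()) - 1.0) > 0.05:
            raise ConfigurationError("variance fractions must sum to ~1")
        if any(v < 0 for v in self.ec_variance_shares.values()):
            raise ConfigurationError("EC variance shares must be non-negative")
        if sum(self.ec_variance_shares.values()) > 1.0 + 1e-8:
            raise ConfigurationError("EC variance shares must not sum above 1")
        if not 0.0 < self.prop_yls_per_hybrid <= 1.0:
            raise ConfigurationError("prop_yls_per_hybrid must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a configuration from a YAML key-value file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data = {k: tuple(v) if k == "maf_range" else v for k, v in data.items()}
        return cls(**data)

    def to_file(self, path) -> None:
        import dataclasses

        import yaml

        data = dataclasses.asdict(self)
        data["maf_range"] = list(data["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TrialDesign:
    """Years, locations (with region and coordinates), and the plot layout."""

    years: list
    locations: pd.DataFrame  # columns: location, region, longitude, latitude
    year_locations: list     # list of "<year>:<loc>" keys
    plots: pd.DataFrame      # columns: hybrid, year, location, replicate, year_location

    def __post_init__(self):
        yl = set(self.year_locations)
        if not set(self.plots["year_location"]).issubset(yl):
            raise ConfigurationError("plot (year, location) missing from year_locations")
        for region in ("north", "south"):
            if (self.locations["region"] == region).sum() < 1:
                raise ConfigurationError(f"region {region!r} has no locations")


@dataclass
class GenotypeMatrix:
    """Hybrid x SNP dosages (0/1/2, NaN for missing) plus the genomic map."""

    dosages: pd.DataFrame
    snp_map: pd.DataFrame
    groups: pd.Series = None  # true tester-group labels, for validation


@dataclass
class DailyEnvSeries:
    """Daily environment of one year-location over the growing season.

    Day 0 is planting.  ``stage_bounds`` holds 10 increasing day indices
    delimiting 9 contiguous phenological stages (half-open intervals, last
    stage closed at harvest).  The reproductive window (flag-leaf appearance
    through end of grain fill) spans stages 6-8.
    """

    year_location: str
    tmax: np.ndarray
    tmin: np.ndarray
    eo: np.ndarray
    cover_green: np.ndarray
    supply: np.ndarray
    soil_water: np.ndarray   # layers x days
    soil_access: np.ndarray  # layers x days, crop accessibility weights
    stage_bounds: np.ndarray
    daily_types: pd.DataFrame = None  # days x 21 EC-type series

    @property
    def window(self) -> tuple:
        """(start, stop) day indices of the reproductive window (half-open)."""
        return int(self.stage_bounds[5]), int(self.stage_bounds[9])


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def make_trial_design(config: SimConfig, rng: np.random.Generator | None = None) -> TrialDesign:
    """Partially replicated multi-year, multi-location trial layout.

    Each hybrid is tested in a random subset of year-locations
    (``prop_yls_per_hybrid``) with ``n_replicates`` plots per cell; sampling
    is stratified by year so hybrids appear in at least two years whenever
    more than one year exists.
    """
    rng = rng or _rng(config, 1)
    years = [2014 + i for i in range(config.n_years)]
    rows = []
    for i in range(config.n_locations_north):
        rows.append((f"N{i+1:02d}", "north",
                     rng.uniform(-104, -75), rng.uniform(38.0, 46.0)))
    for i in range(config.n_locations_south):
        rows.append((f"S{i+1:02d}", "south",
                     rng.uniform(-102, -78), rng.uniform(30.0, 36.5)))
    locations = pd.DataFrame(rows, columns=["location", "region", "longitude", "latitude"])
    yls = [year_location_key(y, loc) for y in years for loc in locations["location"]]

    hybrids = [f"H{i+1:04d}" for i in range(config.n_hybrids)]
    plot_rows = []
    n_yl = len(yls)
    n_pick = max(1, int(round(config.prop_yls_per_hybrid * n_yl)))
    for h in hybrids:
        if n_pick >= n_yl:
            chosen = yls
        else:
            chosen = list(rng.choice(yls, size=n_pick, replace=False))
            if config.n_years > 1:  # guarantee presence in >=2 years
                got_years = {c.split(":")[0] for c in chosen}
                if len(got_years) < 2:
                    other = [yl for yl in yls if yl.split(":")[0] not in got_years]
                    chosen[0] = rng.choice(other)
        for yl in chosen:
            y, loc = yl.split(":")
            for rep in range(1, config.n_replicates + 1):
                plot_rows.append((h, int(y), loc, rep, yl))
    plots = pd.DataFrame(plot_rows, columns=["hybrid", "year", "location", "replicate",
                                             "year_location"])
    return TrialDesign(years=years, locations=locations, year_locations=yls, plots=plots)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Structured SNP dosages via Balding-Nichols group allele frequencies.

    An ancestral frequency is drawn per SNP from ``maf_range``; each tester
    group gets its own frequency from a Beta distribution with differentiation
    ``fst``, inducing the group clustering visible on the top genomic PCs.
    """
    rng = rng or _rng(config, 2)
    H, S, Gk = config.n_hybrids, config.n_snps, config.n_groups
    p_anc = rng.uniform(*config.maf_range, size=S)
    if Gk == 1 or config.fst <= 0:
        p_group = np.tile(p_anc, (Gk, 1))
    else:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_group = rng.beta(np.tile(a, (Gk, 1)), np.tile(b, (Gk, 1)))
        p_group = np.clip(p_group, 0.01, 0.99)
    groups = np.arange(H) % Gk
    dose = rng.binomial(2, p_group[groups, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dose.shape) < config.missing_rate
        dose[mask] = np.nan

    chrom = 1 + (np.arange(S) * config.n_chromosomes) // S
    bp = np.empty(S, dtype=int)
    for c in range(1, config.n_chromosomes + 1):
        idx = np.flatnonzero(chrom == c)
        gaps = rng.integers(1_000, 200_000, size=len(idx))
        bp[idx] = 10_000 + np.cumsum(gaps)
    hybrids = [f"H{i+1:04d}" for i in range(H)]
    snps = [f"S{c}_{p}" for c, p in zip(chrom, bp)]
    dosages = pd.DataFrame(dose, index=pd.Index(hybrids, name="hybrid"), columns=snps)
    snp_map = pd.DataFrame({"snp": snps, "chrom": chrom, "bp": bp})
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map,
                          groups=pd.Series(groups, index=hybrids, name="group"))


def _center_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    for g in np.unique(groups):
        m = groups == g
        out[m] -= out[m].mean()
    return out


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    v = np.var(x)
    if target_var == 0 or v == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_environment(design: TrialDesign, config: SimConfig,
                         rng: np.random.Generator | None = None):
    """Daily environment series per year-location plus the EC matrix.

    Each EC column (21 types x 9 stages) is generated hierarchically as
    region effect + location effect (centered within region) + year-location
    noise (centered within location), with every piece rescaled so the
    realized sequential sums-of-squares match ``ec_variance_shares`` exactly
    on balanced designs.  The region effect is tied to latitude (north/south),
    so it correlates with latitude by construction.  Daily EC-type series are
    then built around the EC entries so stage means reproduce them exactly.
    """
    rng = rng or _rng(config, 3)
    if len(design.year_locations) == 0:
        raise ConfigurationError("empty trial design")
    yls = design.year_locations
    n_yl = len(yls)
    loc_of = np.array([yl.split(":")[1] for yl in yls])
    region_of_loc = dict(zip(design.locations["location"], design.locations["region"]))
    region_of = np.array([region_of_loc[l] for l in loc_of])
    region_code = np.where(region_of == "north", 1.0, -1.0)

    shares = config.ec_variance_shares
    n_types, n_stages = len(EC_TYPE_NAMES), config.n_stages
    cols, data = [], []
    for t in EC_TYPE_NAMES:
        for s in range(1, n_stages + 1):
            cols.append(f"{t}_{s}")
    loc_codes = pd.factorize(loc_of)[0]
    for _ in cols:
        sign = rng.choice([-1.0, 1.0])
        reg = _scale_to_var(sign * (region_code - region_code.mean()), shares["region"])
        loc_eff = rng.normal(size=design.locations.shape[0])[loc_codes]
        loc_eff = _center_within(loc_eff, pd.factorize(region_of)[0])
        loc_eff = _scale_to_var(loc_eff, shares["location"])
        yl_eff = _center_within(rng.normal(size=n_yl), loc_codes)
        yl_eff = _scale_to_var(yl_eff, shares["year_location"])
        data.append(reg + loc_eff + yl_eff)
    ec = pd.DataFrame(np.array(data).T, index=pd.Index(yls, name="year_location"),
                      columns=cols)

    # stage boundaries: 9 contiguous stages over the season, jittered per YL
    base = np.linspace(0, config.season_days, n_stages + 1).round().astype(int)
    series = {}
    lat_of_loc = dict(zip(design.locations["location"], design.locations["latitude"]))
    days = np.arange(config.season_days)
    for yl_idx, yl in enumerate(yls):
        bounds = base.copy()
        jitter = rng.integers(-3, 4, size=n_stages - 1)
        bounds[1:-1] = np.clip(base[1:-1] + jitter, 1, config.season_days - 1)
        bounds = np.maximum.accumulate(bounds)
        for k in range(1, len(bounds)):  # enforce strictly increasing
            if bounds[k] <= bounds[k - 1]:
                bounds[k] = bounds[k - 1] + 1
        bounds[-1] = config.season_days

        lat = lat_of_loc[loc_of[yl_idx]]
        warm = (45.0 - lat) * 0.45  # southern sites run hotter
        seasonal = 24.0 + 8.0 * np.sin(np.pi * days / config.season_days)
        tmax = seasonal + warm + rng.normal(0, 2.5, config.season_days) \
            + rng.normal(0, 1.5)
        tmin = tmax - 11.0 + rng.normal(0, 1.5, config.season_days)
        eo = np.clip(1.5 + 0.18 * (tmax - 15.0) + rng.normal(0, 0.4, config.season_days),
                     0.2, None)
        grow = 1.0 / (1.0 + np.exp(-(days - 35) / 8.0))
        senesce = 1.0 / (1.0 + np.exp((days - 130) / 6.0))
        cover = np.clip(grow * senesce + rng.normal(0, 0.01, config.season_days), 0.0, 1.0)
        supply_level = np.clip(rng.normal(2.2, 0.9), 0.3, None)
        supply = np.clip(supply_level * (1.1 - 0.4 * days / config.season_days)
                         + rng.normal(0, 0.25, config.season_days), 0.05, None)
        soil_water = np.clip(
            rng.normal(25, 4, size=(10, 1))
            + rng.normal(0, 1.5, size=(10, config.season_days)), 2, None)
        root_depth = np.clip((days + 5) / 12.0, 0.5, 10.0)  # layers reached over time
        layer_idx = np.arange(10)[:, None]
        soil_access = np.clip(root_depth[None, :] - layer_idx, 0.0, 1.0)

        daily_types = np.empty((config.season_days, n_types))
        noise = rng.normal(0, 0.3, size=(config.season_days, n_types))
        for s in range(n_stages):
            lo, hi = bounds[s], bounds[s + 1]
            block = noise[lo:hi]
            block = block - block.mean(axis=0, keepdims=True)
            ec_vals = ec.iloc[yl_idx, s::n_stages].to_numpy()  # one value per type
            daily_types[lo:hi] = ec_vals[None, :] + block
        series[yl] = DailyEnvSeries(
            year_location=yl, tmax=tmax, tmin=tmin, eo=eo, cover_green=cover,
            supply=supply, soil_water=soil_water, soil_access=soil_access,
            stage_bounds=bounds,
            daily_types=pd.DataFrame(daily_types, columns=EC_TYPE_NAMES),
        )
    return series, ec


def simulate_phenotypes(design: TrialDesign, genotypes: GenotypeMatrix,
                        ec: pd.DataFrame, config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plot records from the reaction-norm model ``y = mu + g + E + gE + eps``.

    ``g ~ MVN(0, f_snp G)``, ``E ~ MVN(0, f_ec Omega)``,
    ``gE ~ MVN(0, f_snpxec K)`` and iid plot error; each realized record-level
    component is rescaled so its empirical variance equals the configured
    fraction exactly, making the standardized phenotype variance ~1.
    Flowering traits (anthesis/silking days, with ASI = silking - anthesis
    identically) and the calendar dates the curation filters expect are also
    emitted.
    """
    rng = rng or _rng(config, 4)
    plots = design.plots
    hybrids = list(genotypes.dosages.index)
    yls = list(ec.index)
    if not set(plots["hybrid"]).issubset(hybrids):
        raise KeyError("plot hybrids missing from genotype matrix")
    if not set(plots["year_location"]).issubset(yls):
        raise KeyError("plot year-locations missing from EC matrix")

    dos = genotypes.dosages
    if dos.isna().any().any():
        dos = dos.fillna(dos.mean())
    G = _kernels.genomic_relationship(dos)
    Om = _kernels.environmental_relationship(ec)
    lamG, U = np.linalg.eigh(G)
    lamO, V = np.linalg.eigh(Om)
    kg = lamG > lamG.max() * 1e-10
    ko = lamO > lamO.max() * 1e-10
    lamG, U = lamG[kg], U[:, kg]
    lamO, V = lamO[ko], V[:, ko]

    h_idx = pd.Index(hybrids).get_indexer(plots["hybrid"])
    e_idx = pd.Index(yls).get_indexer(plots["year_location"])
    n = len(plots)
    fr = config.variance_fractions

    # rescale kernels to record-level mean diagonal 1 (as the fitter does) and
    # pin each component's variance *parameter* exactly: the coefficient
    # vector in the kernel eigenbasis is renormalized so its mean square
    # equals the configured fraction
    dG = np.einsum("ij,j,ij->i", U, lamG, U)
    dO = np.einsum("ij,j,ij->i", V, lamO, V)
    cg, co = dG[h_idx].mean(), dO[e_idx].mean()
    ck = (dG[h_idx] * dO[e_idx]).mean()

    def _coef(size, frac):
        z = rng.normal(size=size)
        ms = np.mean(z * z)
        return z * np.sqrt(frac / ms) if frac > 0 and ms > 0 else np.zeros(size)

    g_h = (U * np.sqrt(lamG / cg)) @ _coef(len(lamG), fr["snp"])
    E_e = (V * np.sqrt(lamO / co)) @ _coef(len(lamO), fr["ec"])
    # interaction draw via the Kronecker structure of G (x) Omega
    Zm = _coef((len(lamG), len(lamO)), fr["snp_ec"])
    W = (U * np.sqrt(lamG)) @ Zm @ (np.sqrt(lamO)[:, None] * V.T) / np.sqrt(ck)
    g = g_h[h_idx]
    E = E_e[e_idx]
    gE = W[h_idx, e_idx]
    eps = _scale_to_var(rng.normal(size=n), fr["error"])
    y = g + E + gE + eps

    rec = plots.copy()
    region_of = dict(zip(design.locations["location"], design.locations["region"]))
    rec["region"] = rec["location"].map(region_of)
    rec["yield"] = config.mean_yield + config.sd_yield * y

    # flowering traits: hybrid maturity requirement + environment + plot noise
    anth_h = rng.normal(0, 2.5, size=len(hybrids))
    anth_e = rng.normal(0, 3.0, size=len(yls))
    anthesis = np.round(66 + anth_h[h_idx] + anth_e[e_idx]
                        + rng.normal(0, 1.2, n)).astype(int)
    asi = np.clip(np.round(rng.normal(2.0, 1.5, n)), 0, None).astype(int)
    silking = anthesis + asi
    rec["anthesis_days"] = anthesis
    rec["silking_days"] = silking
    rec["asi_days"] = silking - anthesis  # identically ASI

    planting = pd.to_datetime(rec["year"].astype(str) + "-05-01") \
        + pd.to_timedelta((e_idx % 10) - 5, unit="D")
    rec["planting_date"] = planting
    rec["harvesting_date"] = planting + pd.Timedelta(days=150)
    rec["anthesis_date"] = planting + pd.to_timedelta(rec["anthesis_days"], unit="D")
    rec["silking_date"] = planting + pd.to_timedelta(rec["silking_days"], unit="D")
    cols = ["hybrid", "year", "location", "region", "replicate", "year_location",
            "planting_date", "harvesting_date", "anthesis_date", "silking_date",
            "yield", "anthesis_days", "silking_days", "asi_days"]
    return rec[cols]
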