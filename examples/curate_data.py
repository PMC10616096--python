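"""Phenotype and genotype quality control on a simulated trial.

Shows the three phenotype rules (missing key dates, ASI > 15 d, yield
outliers beyond 2.5 IQR within trial), the SNP filters (MAF > 3%, missing
< 10%, mean imputation) and LD pruning (R^2 > 0.85 within 1 Mbp).
"""

import numpy as np
import pandas as pd

from metgxe import curation, simdata

cfg = simdata.SimConfig(n_hybrids=80, n_snps=500, n_years=3,
                        n_locations_north=2, n_locations_south=2,
                        missing_rate=0.03, seed=2)
design = simdata.make_trial_design(cfg)
geno = simdata.simulate_genotypes(cfg)
_, ec = simdata.simulate_environment(design, cfg)
records = simdata.simulate_phenotypes(design, geno, ec, cfg)

# plant some dirty records
records.loc[records.index[0], "silking_date"] = pd.NaT
records.loc[records.index[1], "asi_days"] = 20
records.loc[records.index[2], "yield"] = 40.0  # far outside its trial's spread

kept, log = curation.filter_phenotypes(records)
print(f"phenotypes: kept {len(kept)} of {len(records)}")
print(log[log.record >= 0].to_string(index=False))

filtered = curation.filter_genotypes(geno.dosages)
print(f"\ngenotypes: {geno.dosages.shape[1]} -> {filtered.shape[1]} SNPs "
      f"after MAF/missingness filters; any missing left: "
      f"{bool(np.isnan(filtered.to_numpy()).any())}")

retained = curation.ld_prune(filtered, geno.snp_map)
print(f"LD pruning retained {len(retained)} of {filtered.shape[1]} SNPs")
# Each dropped phenotype record carries exactly one logged rule; the LD sets
# keep their most representative member (highest mean R^2 to the set).
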