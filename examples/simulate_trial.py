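"""Generate a synthetic multi-environment maize trial and inspect it.

Builds a small trial network (hybrids structured into tester groups, north
and south locations, several years), daily environments, stage-averaged
environmental covariates (ECs), and reaction-norm phenotypes.
"""

from metgxe import simdata

cfg = simdata.SimConfig(n_hybrids=120, n_snps=800, n_years=4,
                        n_locations_north=3, n_locations_south=2,
                        n_replicates=2, seed=1)
design = simdata.make_trial_design(cfg)
geno = simdata.simulate_genotypes(cfg)
series, ec = simdata.simulate_environment(design, cfg)
records = simdata.simulate_phenotypes(design, geno, ec, cfg)

print(f"{len(design.year_locations)} year-locations over {len(design.years)} years")
print(f"{geno.dosages.shape[0]} hybrids x {geno.dosages.shape[1]} SNPs")
print(f"EC matrix: {ec.shape[0]} year-locations x {ec.shape[1]} covariates")
print(f"{len(records)} plot records; yield sd = {records['yield'].std():.2f} t/ha")
print(records.head(3).to_string())
# The EC matrix has 21 covariate types x 9 phenological stages = 189 columns;
# phenotypes follow y = mu + g + E + gE + error with the configured variance
# fractions (defaults mirror a grain-yield variance partition).
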