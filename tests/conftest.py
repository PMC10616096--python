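import numpy as np
import pandas as pd
import pytest

from metgxe import simdata, kernels


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimConfig(
        n_hybrids=60, n_snps=300, n_years=3, n_locations_north=3,
        n_locations_south=2, n_replicates=2, seed=7,
    )


@pytest.fixture(scope="session")
def small_design(small_cfg):
    return simdata.make_trial_design(small_cfg)


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return simdata.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_env(small_design, small_cfg):
    return simdata.simulate_environment(small_design, small_cfg)


@pytest.fixture(scope="session")
def small_records(small_design, small_geno, small_env, small_cfg):
    series, ec = small_env
    return simdata.simulate_phenotypes(small_design, small_geno, ec, small_cfg)


@pytest.fixture(scope="session")
def small_kernelset(small_records, small_geno, small_env):
    _, ec = small_env
    return kernels.build_kernel_set(small_records, small_geno.dosages, ec)


@pytest.fixture(scope="session")
def yl_meta(small_design, small_env):
    _, ec = small_env
    loc = pd.Series({yl: yl.split(":")[1] for yl in ec.index}, name="location")
    region_of = dict(zip(small_design.locations["location"],
                         small_design.locations["region"]))
    return pd.DataFrame({"location": loc, "region": loc.map(region_of)})
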