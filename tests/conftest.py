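import numpy as np
import pandas as pd
import pytest

import hydroxymut as hm
from hydroxymut.io_formats import merge_intervals


@pytest.fixture(scope="session")
def default_cohort():
    """The package's default synthetic cohort (~1e5 CpGs, 100 WGS patients,
    methylated sites about twice as mutable as hydroxymethylated)."""
    return hm.simulate_cohort()


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Classification + mutation join for the default cohort."""
    cohort = default_cohort
    labels = hm.classify_sites(cohort.sites)
    joins = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs,
                                       ("C>T", "C>A", "C>G"))
    return cohort, labels, joins


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for module-level tests."""
    cfg = hm.CohortSimConfig(seed=7, n_chromosomes=1, chrom_length_bp=500_000,
                             n_patients=30, baseline_mut_prob=2e-3)
    return hm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    cohort = small_cohort
    labels = hm.classify_sites(cohort.sites)
    joins = hm.join_mutations_to_sites(cohort.sites, cohort.catalogs, ("C>T",))
    return cohort, labels, joins


@pytest.fixture(scope="session")
def merged_exons(small_cohort):
    return merge_intervals(small_cohort.exons)


def toy_sites(rows):
    """Build a minimal site table from (chrom, pos, strand, mod, hmc_rel)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mod_level", "hmc_rel"])
    df["context"] = "CG"
    df["hmc_level"] = df["hmc_rel"].fillna(0) * df["mod_level"]
    df["mc_level"] = df["mod_level"] - df["hmc_level"]
    return df


def toy_joins(entries):
    """Build a join table from (site_index, sample_id, mut_type)."""
    return pd.DataFrame(entries, columns=["site_index", "sample_id", "mut_type"])
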