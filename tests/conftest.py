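"""Shared fixtures: tiny CSV tables and a mid-sized simulated site with
known pedigree, reused across the parentage/dispersal/reproduction tests."""

import io

import numpy as np
import pytest

from kinflow.core import load_individuals
from kinflow.simulate import (
    Kernel,
    SimulationParams,
    mate_and_disperse,
    simulate_adults,
    _concat_tables,
)


def make_csv(rows, header):
    return io.StringIO("\n".join([header] + rows) + "\n")


@pytest.fixture
def tiny_table():
    """3 individuals, 2 loci, one missing genotype, out-of-order alleles."""
    header = "id,site,x,y,dbh,hap,loc1_a,loc1_b,loc2_a,loc2_b"
    rows = [
        "i1,s,0,0,45,H1,102,101,200,200",
        "i2,s,3,4,12,H2,101,101,NA,NA",
        "i3,s,10,0,30,H1,102,102,201,200",
    ]
    return load_individuals(make_csv(rows, header))


@pytest.fixture(scope="session")
def sim_site():
    """One simulated site: adults + offspring cohort + truth pedigree.

    Short kernels, mild selfing, complete sampling; genotypes informative
    enough that parentage is essentially exact at epsilon = 0.
    """
    params = SimulationParams(
        plot_width=300.0,
        plot_height=300.0,
        adult_density=15.0,
        n_loci=30,
        target_he=0.5,
        n_plastid_haplotypes=8,
        seed_kernel=Kernel(scale=30.0),
        pollen_kernel=Kernel(scale=80.0),
        selfing_rate=0.02,
        n_generations_burnin=1,
        n_offspring=150,
        site_name="simsite",
    )
    adults, state = simulate_adults(params, seed=11)
    offspring, truth = mate_and_disperse(adults, params, 150, state=state)
    merged = _concat_tables(adults, offspring)
    return {
        "params": params,
        "adults": adults,
        "offspring": offspring,
        "truth": truth.table,
        "merged": merged,
    }
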