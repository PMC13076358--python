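"""Reproductive skew: who actually parents the next generation?

Tallies offspring per adult from concordant parentage assignments,
quantifies inequality with the Gini index, and compares two sites with
contrasting fecundity dispersion using a pooled-reassignment permutation
test.
"""

import numpy as np

from kinflow import (
    GenotypingErrorModel,
    Kernel,
    SimulationParams,
    assign_exclusion,
    assign_likelihood,
    concordant,
    gini,
    gini_permutation_test,
    mate_and_disperse,
    simulate_adults,
    sibship_clusters,
    tally_success,
)
from kinflow.diversity import allele_frequencies
from kinflow.reproduction import cluster_summary

counts = {}
for name, disp in (("even_site", 0.0), ("skewed_site", 3.0)):
    params = SimulationParams(
        plot_width=300.0, plot_height=300.0, adult_density=12.0, n_loci=35,
        fecundity_dispersion=disp, seed_kernel=Kernel(30.0),
        pollen_kernel=Kernel(90.0), n_generations_burnin=1, site_name=name,
    )
    adults, state = simulate_adults(params, seed=3)
    offspring, _ = mate_and_disperse(adults, params, 200, state=state)
    freqs = allele_frequencies(adults)
    merged = concordant(
        assign_likelihood(offspring, adults, freqs, error_model=GenotypingErrorModel(0.0)),
        assign_exclusion(offspring, adults, max_mismatch=0),
    )
    success = tally_success(adults, merged)
    counts[name] = success["total"].to_numpy()
    cs = cluster_summary(sibship_clusters(merged))
    print(
        f"{name:12s} adults={adults.n:3d}  G={gini(counts[name]):.3f}  "
        f"families={cs.attrs['n_clusters']}  top-family share={cs.attrs['max_cluster_share']:.2f}"
    )

p = gini_permutation_test(counts, n_perm=10_000, seed=4)
print(f"\npermutation p (Gini difference): {p.loc['even_site', 'skewed_site']:.4f}")
print()
print("G above ~0.45 is conventionally read as substantial reproductive")
print("skew; the permutation test pools the two sites' per-adult outputs")
print("and reassigns them at the original sample sizes.")
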