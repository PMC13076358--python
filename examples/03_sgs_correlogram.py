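"""Fine-scale spatial genetic structure: kinship correlogram and Sp.

Computes pairwise Loiselle kinship within a simulated stand, bins it
into distance classes, tests it against a null that permutes individual
locations, and summarizes structure with F_1 (first-class kinship),
b_log (kinship-on-ln(distance) slope), Sp = -b_log/(1-F_1), and Wright's
neighbourhood size NS = 1/Sp.  Also writes a correlogram figure.
"""

from kinflow import (
    Kernel,
    SimulationParams,
    autocorrelogram,
    loiselle_kinship,
    pairwise_distances,
    simulate_adults,
)
from kinflow.sgs import plot_correlogram

params = SimulationParams(
    plot_width=400.0, plot_height=400.0, adult_density=15.0, n_loci=30,
    n_plastid_haplotypes=10, n_generations_burnin=8,
    seed_kernel=Kernel(20.0), pollen_kernel=Kernel(70.0), site_name="demo",
)
adults, _ = simulate_adults(params, seed=5)
dist = pairwise_distances(adults)
classes = [30, 60, 90, 130, 170, 220, 300, 560]

for label, mode in (("nuclear", "diploid"), ("plastid", "haploid")):
    kin = loiselle_kinship(adults, mode=mode)
    res = autocorrelogram(kin, dist, spec=classes, n_perm=999, seed=3)
    print(
        f"{label:8s} F_1={res.f1:+.4f}  b_log={res.b_log:+.5f}  "
        f"Sp={res.sp:.4f} ({res.tier})  NS={res.ns:.0f}"
    )
    if label == "nuclear":
        plot_correlogram(res, "correlogram_demo.png")

print()
print("Positive F_1 with a significantly negative slope is the isolation-by-")
print("distance signature of restricted dispersal; the haploid (maternally")
print("inherited) marker shows stronger structure because it moves only by")
print("seed.  Figure written to correlogram_demo.png.")
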