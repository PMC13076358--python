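# Methods

This note documents the statistical models implemented in kinflow, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions a user should know before trusting
a number.

## Data model and conventions

Individuals carry an ID, site, coordinates (planar meters, or lon/lat
projected to a local tangent plane about the centroid when planar
analyses are requested), DBH in cm, diploid genotypes at a shared locus
panel, and one plastid haplotype.  Allele pairs are stored
order-normalized; a locus with any missing allele is treated as wholly
missing for that individual (half-called SSR genotypes are not trusted).
Size classes split at DBH 30 cm with the boundary value assigned to
adults ("≥ 30 cm" defines the potentially reproductive class).  Geodesic
distances use the haversine formula with Earth radius 6 371 008.8 m.
Whether within-plot distances are planar or geodesic is a user choice
recorded in the pipeline manifest; at plot scales (< 1 km) the two agree
to ~0.1%.

## Diversity statistics

* Allelic richness is rarefied to k gene copies (default 50) with the
  hypergeometric closed form `A_R = Σ_a [1 − C(n_l − n_a, k)/C(n_l, k)]`,
  computed in log-gamma space; loci with fewer than k typed copies are
  dropped from A_R only.
* H_E uses the small-sample correction `n/(n−1)(1 − Σp²)`; H_O is a
  simple proportion.  Multilocus F_IS = 1 − (Σ_l H_O,l)/(Σ_l H_E,l).
* The F_IS permutation test shuffles gene copies among individuals
  within each locus.  Gene diversity is invariant under that shuffle, so
  only H_O is recomputed per permutation; p-values are two-sided
  (doubled smaller tail) with the add-one convention.  Measured type-I
  error at α = 0.05 is ~4% over 200 null replicates — slightly
  conservative, as expected for a doubled discrete p.
* Pairwise F_ST is the Weir–Cockerham (1984) multilocus θ (ratio of
  summed variance components), with significance by permuting
  individuals between the two sites.
* Selfing: (a) the equilibrium transform s = 2F_IS/(1+F_IS), clipped to
  [0, 1]; (b) the identity-disequilibrium route.  g2 is the
  moment estimator `(N−1) Σ_{k≠l} m_kl / Σ_{k≠l}(H_k H_l − m_kl) − 1`
  on heterozygosity indicators; the conversion to s inverts the
  equilibrium relation g2(s) = (2−s)²/((4−s)(1−s)) − 1, derived from the
  geometric selfing-class distribution with per-class heterozygosity
  ∝ 2^−n (so g2 ≈ s/4 at small s).  Because published work rarely
  restates this conversion, it is validated here only by parameter
  recovery: the estimator matches the relation on an idealized
  mixed-mating model and recovers s = 0.3 within ±0.05 on forward
  simulations.  Significance is a one-sided z-test of g2 > 0 with a
  jackknife-over-loci standard error.

## Spatial genetic structure

The Loiselle kinship estimator is, summed over loci and alleles,

    F_ij = Σ_l Σ_a [(p_ila − p̄_la)(p_jla − p̄_la) + p̄_la(1−p̄_la)/(m_l − 1)]
           / Σ_l Σ_a p̄_la(1 − p̄_la)

with p_ila ∈ {0, ½, 1} (diploid) or {0, 1} (haploid) and m_l the number
of typed **gene copies** (2n_l diploid, n_l haploid).  The m_l − 1
denominator of the bias term is chosen so that E[F_ij] = 0 for unrelated
pairs relative to the sample frequencies; with "individuals − 1" the
estimator is visibly off-center on panmictic data.  Reference
frequencies are recomputed within each analyzed group (site × size class
× marker), mirroring how per-group SGS is conventionally run.  Pairs
sharing fewer than 20 nuclear loci (1 plastid) are dropped.

b_log is fit on **pairwise** points (not class means); class means exist
for the correlogram display and envelopes.  Zero-distance pairs are
excluded from the log regression and counted.  The permutation null
shuffles individual locations (an index permutation of the distance
matrix) with kinship held fixed, recomputing class means and the slope
each round; envelopes are the 2.5/97.5 percentiles and the Sp
significance is two-sided on the null slope.  Sp = −b_log/(1 − F_1);
NS = 1/Sp (reported as infinite when Sp = 0).  Significance tiers are
***/**/* /ns at 0.001/0.01/0.05.

Distance classes default to upper bounds 30, 60, 90, 130, 170, 220,
300, 600 m (half-open (lower, upper]); the class grid is fully
configurable and is set to shorter grids for small simulated plots.

## Historical dispersal

Effective density D_e = fraction × census adult density (default 0.25,
reflecting that only part of the standing adults reproduce in a given
season); a maternal-only variant (D_e/2) is available for sensitivity
analysis of the plastid inversion.  σ is obtained by inverting
Sp = 1/(4πD_eσ_g²) (nuclear) or 1/(2πD_eσ_s²) (plastid) — all σ axial —
then iterating: refit b_log over (σ, 20σ], recompute Sp and σ, stop at
< 1% relative change (max 20 iterations; the range multiplier 20 is
configurable).  The upper bound is clipped to the largest pairwise
distance; non-convergence is declared (and the last σ reported censored,
with a flag) when the lower bound exceeds the plot, Sp turns
non-positive, fewer than 10 pairs remain in range, or the iteration cap
is hit.  Declaring failure whenever 20σ exceeds the plot would censor
essentially every realistic estimate, so only the lower bound is treated
as "leaving the plot".  σ_p = sqrt(2(σ_g² − σ_s²)) — the factor 2
because pollen moves a haploid genome per diploid seed — with an
explanatory flag instead of a number when σ_s > σ_g (estimator noise can
produce this).  On forward simulations at drift–dispersal equilibrium
(40 burn-in generations, ~450 adults, correctly specified D_e) the
plastid inversion recovers the realized axial seed dispersal within
±30% (mean ratio ≈ 1.03 over 20 replicates).  "Realized" truth is
computed from the simulator's pedigree and therefore includes plot-edge
truncation of the kernel.

## Parentage

The trio LOD is `Σ_loci ln[P(offspring | mother, father, Mendel + ε) /
P(offspring | HWE draw)]`; the error model replaces each recorded
offspring allele with a random frequency-weighted allele with
probability ε (default 0.01), folded into the transmission probability
as T(a) = (1−ε)·Mendel + ε·p_a — the standard first-order formulation at
low error rates.  Candidates missing a locus contribute the population
distribution (uninformative).  Pair search shortlists the top-m
(default 20) candidates by single-parent LOD, then scores all pairs
(including the selfed diagonal) among them; with ≥ 30 informative loci
the true parents dominate the dyad ranking, and recovery against the
simulator's pedigree is 100% at full sampling.  The confidence gap Δ
(best minus second-best pair LOD) is capped at 100 log-units because an
exactly-excluded runner-up makes it unbounded.  Exact ties give tier
"none" — never an arbitrary choice.

Threshold calibration simulates offspring from HWE parents at the
supplied frequencies (defaults: 10 000 offspring, 500 candidates, 25%
parent sampling, polygamy implicit), hides each true parent with
probability 1 − prop_sampled, scores all candidates, and sets the
strict/relaxed thresholds as the smallest Δ at which the accepted set is
≥ 95% / ≥ 80% correct.

The second, independent method is exclusion: per-dyad and per-trio
Mendelian mismatch counting, accepting only the unique pair within the
mismatch budget (default 1 locus).  At ε = 0 "LOD = −∞" and "≥ 1 trio
mismatch" coincide exactly (property-tested).  Full-likelihood sibship
reconstruction in the style of COLONY is deliberately not
re-implemented; sibships are connected components of offspring sharing
an inferred parent from the concordant set, with full-sib subfamilies
keyed by identical parent pairs.  Only assignments identical between the
two methods ("concordant") feed downstream analyses.

## Contemporary dispersal

Maternity: within a concordant pair, the parent sharing the offspring's
plastid haplotype is the mother **provided** the other parent's
haplotype differs; double matches are excluded as unresolved, zero
matches flagged as conflicts and excluded (conservative — the data are
silent on this case) but logged.  Seed distance is mother→offspring;
pollen distance is father→mother (the mating event), with
father→offspring also emitted since either convention appears in the
literature.  CIs are percentile bootstrap (default 10 000 resamples) of
the mean, reported as half-widths; measured coverage on a normal toy is
~93.5% (the usual slight undercoverage of the percentile method at
n = 100).  Dispersal histograms use 10 m bins.

## Reproductive success

"Total" success counts each concordant offspring once per parental slot
(a selfed offspring gives its parent +1 mother-count, +1 father-count,
+2 total).  Zero-count adults are included in the Gini — skew among
*potential* breeders is the quantity of interest, and dropping zeros
deflates G arbitrarily; an exclusive variant is a one-line filter away.
G = Σ|x_i − x_j| / (2n²x̄) without small-sample correction (O(n log n)
sorted form, property-tested against the double loop).  The pairwise
between-site test pools two sites' per-adult outputs and reassigns them
at the original sizes (10 000 permutations, add-one p); no multiplicity
correction by default, with Holm available.  The conventional 0.45
"substantial skew" threshold is an annotation, never a decision rule.
DBH effects are OLS of total count on DBH; mother-vs-father balance is a
paired Wilcoxon signed-rank with zero differences dropped (p = 1 and a
flag when all differences are zero).

## Simulator

Adults: Thomas cluster process (parent intensity in clusters/ha,
Gaussian scatter σ) conditioned on a Poisson(density × area) count;
cluster parents are laid in a buffered window capped at the plot scale,
and scatter ≥ 3× the plot size short-circuits to exact uniform sampling
(the CSR limit).  Founder genotypes are HWE draws from per-locus
symmetric-Dirichlet frequencies with concentration solved from the
target H_E; haplotypes from a Dirichlet(1) frequency vector.  Mating:
mothers ∝ Gamma(1/d, d) relative fecundity (dispersion d = 0 means
equal); selfing with probability s; otherwise fathers ∝ fecundity ×
exponential-power kernel weight of the father–mother distance (mother
excluded); immigrant fathers (probability `immigration_rate`) carry
genotypes from the current background frequencies.  Offspring positions
are mother + 2-D kernel displacement (distance via the Gamma(2/b)
transform, uniform direction), rejection-resampled to stay inside the
closed plot.  Plastid inheritance is strictly maternal; there is no
mutation and no age structure beyond replacement burn-in.  All
randomness flows from one seeded generator per call; fixtures are
byte-reproducible.

The four-site study preset emulates the target study system: 17–38 ha
plots, adult densities 2.6–7.9/ha, aggregated distributions, realized
nuclear H_E ≈ 0.48–0.55 (the low-density, high-skew site gets a raised
*founder* target because drift during burn-in removes ~0.01 He per
generation there), ~5–8 plastid haplotypes per site, selfing 0.01, seed
kernels with medians ~20–75 m and pollen kernels ~130–290 m, and
site-contrasted fecundity skew.  What the simulator does **not**
emulate: genotyping error in emitted fixtures (ε enters only the
likelihood model), null alleles, masting schedules, seed/pollen
immigration structure beyond a flat rate, overlapping generations, and
mutation.  Passing parameter-recovery tests therefore demonstrates
estimator correctness under the model's assumptions, not robustness to
marker artefacts in real data.

## Problem sizes and numerical choices

Test and validation runs use deliberately moderate sizes chosen as this
package's own desk-scale defaults: e.g. σ_s recovery uses 20 replicates
of ~450 adults with 40 burn-in generations; parentage recovery uses 66
loci × 200 offspring; permutation counts in unit tests are 100–2000
(the analysis defaults remain 10 000).  Monte-Carlo assertions use
seeded generators and 3–4 SE bands.  Degenerate inputs are errors with
messages naming the offending row/locus/individual wherever possible;
estimators that can fail (negative Sp, σ_s > σ_g, empty first distance
class, all-zero counts) return flags or raise rather than silently
dropping groups.

## Known limitations

* The drift–dispersal inversion assumes equilibrium; recently disturbed
  stands violate it and σ estimates then reflect a mixture of past
  regimes.
* D_e is a stipulated fraction of census density, not an estimate; σ
  scales as D_e^(−1/2), so a factor-2 error in D_e shifts σ by √2.
* The likelihood parentage search is shortlist-based; with very few,
  weakly informative loci (< ~10 at H_E ≈ 0.5) the true pair can fall
  outside the dyad shortlist and `top_m` should be raised.
* The exclusion route treats the mismatch budget as per-trio and
  per-dyad jointly; it does not model error likelihood and is therefore
  conservative with noisy genotypes.
* g2-based selfing assumes inbreeding equilibrium and no null alleles;
  null alleles inflate g2 and hence s.
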