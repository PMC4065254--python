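# Methods

## The screening problem

A dominant modifier of the *Apc^Min^* phenotype changes a carrier's
expected tumor multiplicity by a multiplicative fold. Because the
phenotype is strongly overdispersed, no single animal is informative: a
kindred — the cluster of Min/+ progeny of one first-generation (G1) son
of a mutagenized male — is the unit of detection, and the modifier, if
present, is heterozygous in the founder and segregates to each progeny
with probability ½. The package implements the statistical machinery of
that strategy: the phenotype model, the mixture over kindreds, per-
kindred power, whole-screen sizing, and the construction of an isogenic
SNV mapping panel for locating a discovered modifier.

## Phenotype model

Tumor counts in the unmodified reference colony follow a negative
binomial `NB(μ, k)` with mean `μ = 99.8` and shape `k = 9.8`
(variance `μ + μ²/k ≈ 1116`), the values estimated from the closed
C57BL/6JD-*Apc^Min^* colony. A modifier of fold `f` multiplies the mean
(`NB(fμ, k)`) and leaves the shape untouched.

Lifespan enters through a survival link:
`log L = a − b·log(Y + 1) + ε`, `ε ~ N(0, σ)`, defaults
`a = 7.5, b = 0.5, σ = 0.2`, chosen so an animal with ~100 tumors lives
~180 days with ~20% coefficient of variation — a realistic scale for
Min mice. Only the *sign* of the lifespan–burden association is asserted
by the data this emulates; the log-log-normal form is a package choice,
and any analysis that depends on the lifespan channel's exact shape
should treat it as illustrative. The mixture machinery accepts either
channel through one density interface (`NegativeBinomialPhenotype` for
counts, `GaussianLogPhenotype` for log-lifespans).

## The segregating three-component mixture

Kindred `k` draws a latent class `c ∈ {unaffected, suppressor,
enhancer}` with weights `(π₀, π_s, π_e)`; a modifier kindred draws one
fold `f ~ G_c` and the kindred likelihood mixes carrier and non-carrier
densities animal by animal:

    L_k(c) = E_{f~G_c} ∏_j [ s·p(y_j | f) + (1−s)·p₀(y_j) ],   s = ½.

The default effect family is log-normal on the fold, truncated to
(0, 1−δ] for suppressors and [1+δ, ∞) for enhancers. Simulation
defaults are the estimated screen conditions: weights (0.39, 0.41,
0.20), suppressor median fold 0.6, enhancer median 1.8, log-SD 0.2.
This likelihood is a reconstruction of the screening model from its
published summary statistics; the original analysis's exact effect
family is not public, so a point-mass and a discrete-grid alternative
are provided alongside the log-normal.

**Fitting.** `fit_mixture` runs ECM: the E-step computes kindred class
responsibilities; the weights update in closed form; each effect
component's (location, log-scale) is improved by a short Nelder–Mead
conditional step accepted only when it increases the expected complete
log-likelihood, so the observed log-likelihood path is non-decreasing
by construction. The expectation over `f` uses Gauss–Legendre quadrature
in the quantile space of `G_c` (12 nodes; accurate for the default
log-SDs). Initialisation is method-of-moments on the trimmed tails of
the kindred means; restarts (default 5) perturb it randomly, are
screened at a relative tolerance of 1e-6 (≤ 400 iterations), and the
best is polished at 1e-8 (≤ 2000 iterations). Non-convergence is
flagged, not raised.

**Identifiability.** Truncation pins the labels (suppressor folds < 1 <
enhancer folds), so components cannot swap. The margin `δ = 0.1`
(configurable `effect_margin`) is the smallest effect the fit treats as
a modifier: a fold of exactly 1 is indistinguishable from no modifier,
and without the margin the class weights are unidentifiable on
modifier-free data (effect mass piles up at 1 and the weights go
wherever the start put them). Even with the margin, mixture weights for
absent components retain a small positive bias in finite samples —
noticeable for shallow clusters (~7% spurious weight at 8 progeny per
kindred in a 500-kindred null cohort, < 1% at 15 progeny).

## Extreme-kindred enrichment

Selecting kindreds whose initial clusters contain `≥ m` of `c` animals
in a baseline tail of mass `q` (default 5th/95th percentile) enriches
for large effects. With per-animal extreme probability
`p(f) = s·P(Y_f ∈ tail) + (1−s)·P(Y₀ ∈ tail)` the selection event is a
binomial tail, and

    enrichment = P(effect beyond threshold | selected) / P(effect beyond threshold)

is evaluated by quadrature over the class/effect mixture. For discrete
counts the tail is inclusive below (`Y ≤ q_q`) and exclusive above
(`Y > q_{1−q}`); the exact NB tail mass is used rather than the nominal
`q`, so quantile discreteness is respected. `m = 0` encodes the vacuous
rule (select everything, enrichment exactly 1). Note that selection at
the baseline *median* is still mildly informative under segregation —
a fold-2 carrier exceeds the median more often than chance — so
enrichment approaches 1 only as the rule, not the quantile, becomes
vacuous.

## Power and screen design

The per-kindred test refers the kindred mean to its null normal
approximation `N(μ, (μ + μ²/k)/n)`, two-sided at α = 0.05 by default
(one-sided variants for direction-committed screens). Under the
alternative the marginal moments include the between-genotype variance
contributed by segregation itself:

    E[Ȳ] = μ(1 − s + sf),
    Var[Ȳ] = [ s(fμ + (fμ)²/k) + (1−s)(μ + μ²/k) + s(1−s)μ²(f−1)² ] / n.

Power is evaluated by conditioning on the binomial carrier count and
applying the normal approximation within each stratum; the single
marginal normal (also available, `method='marginal'`) is visibly off for
clusters of ~5 animals, where the mean's distribution is a clearly
non-normal mixture. The stratified evaluation agrees with exact
NB-plus-segregation simulation to < 0.01 across folds 0.25–4 and
clusters of 5–30.

**Screen sizing.** A screen of `N` kindreds × `n` progeny yields
per-kindred p-values (null normal approximation), a Benjamini–Hochberg
list at `q = 0.05`, and a *discovery* when the list contains a kindred
truly carrying an effect beyond a fold threshold. The design criterion
asks for the smallest `N` with discovery probability ≥ 0.95, evaluated
by Monte Carlo over whole screens (default 2000 replicates) with common
random numbers across candidate `N` (so the estimated curve is monotone)
and doubling-plus-bisection search. Preselection conditions the mixture
on the selection event — class weights reweighted by per-class selection
probability, effect distributions tilted to discrete grids — and runs
the same search on the enriched mixture. Designs produced here are
functions of the *assumed* effect distribution; published screen sizes
for any particular fitted distribution are not reproduced, because that
distribution is not public — the machinery, not those numbers, is the
deliverable.

## Inbreeding

`H_t = H_{t−1}/2 + H_{t−2}/4`, `H₀ = H₁ = 1`, gives the fraction of
initially heterozygous loci still segregating after `t` generations of
full-sib mating; `1 − H_t` is the classical inbreeding coefficient
series, and `H_{t+1}/H_t → (1+√5)/4 ≈ 0.809`. `t` counts generations
with F10 ↦ `t = 10` (14.06% ≈ 14%); the 11% figure corresponds to the
adjacent index `t = 11`. The two published anchors sit at adjacent
indices of the same recurrence under inconsistent generation labels;
the package documents the indexing rather than adjudicating it.

## Variant panel

Site identity across lines is keyed on (chrom, pos, alt); zygosity is
ignored for specificity classing. Depth filtering keeps
`3 ≤ depth ≤ 2.5 × line mean coverage`. Partitioning sends each site to
exactly one of: a line's exclusive set, the related pair's shared set
(B6.SNVg/h share a founder; their shared variants are early-origin ENU
mutations), or the remainder. Candidate markers require the maximum
Phred genotyping quality (99) and a flank free of significant repeats —
operationalised as no homopolymer run ≥ 8 nt and no ≥ 4 tandem
dinucleotide units within ±50 bp (the criterion is configurable;
"significant" has no published definition). Ranking prefers
related-pair-shared sites, then A>T/T>A transversions, then A>G/T>C,
then G>A/C>T transitions; remaining types are admitted at the bottom of
the order so sparse regions can still be served (`relax_types=False`
drops them instead). Each autosome is split into three equal physical
thirds — a pragmatic stand-in for centromere/middle/telomere on the
acrocentric mouse karyotype — and the best-ranked candidate per bin is
chosen, ties going to the candidate nearer the bin midpoint, then the
lower position. Gap detection reports 0-based half-open marker-free
intervals ≥ 30 Mbp including chromosome ends; the gap between 1-based
sites `p < q` is `[p, q−1)`.

## Genotyping validation

Five mutually exclusive outcomes, applied in order: all samples no-call
→ assay failure; any alt allele in the reference colony → reference
divergence (colony drift from the canonical reference or an error in
it — one label deliberately covers both, as the assay cannot
distinguish them); SNV-line samples all ref/ref → call error; SNV-line
genotypes mixed → residual heterozygosity (requires at least one alt
and at least one non-fixed sample — heterozygosity is not obligatory,
homozygotes segregate too); otherwise validated homozygous. Partial
no-calls classify on the called subset.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis
assumes: NB counts with the stated moments, Mendelian carrier
segregation, multiplicative effects, Poisson variant placement uniform
along chromosomes with the published substitution spectrum, a related
line pair sharing the published fraction of variants, and
heterozygosity flags at the residual-inbreeding rate. They do not
emulate mutational hotspots, linkage or recombination, raw reads, or
real lifespan distributions — so passing tests demonstrate internal
consistency of the method under its own model, not robustness to the
ways real colonies violate it (drifting colony means, litter effects,
non-multiplicative modifiers). One master seed spawns a named substream
per generator, so outputs are bit-reproducible and decoupled.

## Problem sizes and numerical defaults

Simulation-based checks use: 1e5 animals for distributional
goodness-of-fit; 1e5 replicate kindreds per cell for power and test
size; 1e5 kindreds for enrichment cross-checks; 2000–4000 replicate
screens for design Monte Carlo; 2000 kindreds × 10 progeny with 3–10
restarts for mixture recovery. These sizes put Monte-Carlo error well
inside each assertion's tolerance while keeping the full suite around a
minute. Quadrature uses 12 nodes (24 for enrichment); EM tolerances as
above; effect scale is bounded to [1e-3, 2] on the log-fold scale.

## Known limitations

* The mixture fit assumes the baseline NB parameters are known (supplied
  from the control colony), not jointly estimated; colony drift is not
  modelled.
* Mixture weights of absent components are positively biased in shallow
  cohorts (see Identifiability); interpret small fitted weights with the
  cluster depth in mind.
* The screen-design Monte Carlo samples kindred means from the normal
  approximation, consistent with the power model; an exact-NB p-value
  mode exists for validation but is slower.
* Marker-panel bin boundaries are physical thirds, not cytogenetic
  assignments, and the repeat screen is a heuristic.
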