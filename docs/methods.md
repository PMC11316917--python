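# Methods

This note documents the statistical machinery implemented in
`sizestab`, the assumptions behind it, the synthetic data generator's
planted structure, and the numerical choices that affect results.

## Data model and normalization

The exchange object is a samples × taxa abundance matrix
(`CommunityTable`) in `counts` or `relative` mode. Because 16S and 18S
libraries are sequenced separately, proportions are only comparable
within a marker: the pipeline renormalizes taxon proportions within each
domain (bacteria; fungi; protists) before aggregating taxa into organism
groups (`to_domain_relative`, then `aggregate_groups`). The
within-domain proportions are divided by the number of represented
domains so each row remains a unit simplex; this global constant cancels
in every downstream statistic (resistance is scale-invariant, Spearman
and OLS are monotone-invariant, diversity and breadth are computed on
counts). Plain member-proportion sums without the domain renormalization
remain available and conserve mass exactly.

No rarefaction is performed by default; relative abundance is the
normalization. An opt-in seeded `rarefy` (multivariate hypergeometric
subsampling) is provided for users who want incidence-based metrics on
even depth.

Group selection uses a coverage filter: per domain, the mean relative
abundance captured by the configured groups divided by the domain total
must reach a threshold (default 0.6). Taxa outside every group count
toward the denominator only.

## Resistance and stability

Resistance of a group's (domain-relative) abundance in a field pair is
the bounded Orwin–Wardle index

    RS = 1 − 2|D0| / (C0 + |D0|),   D0 = C0 − P0,

with C0 the control and P0 the disturbed value. RS = 1 iff P0 = C0,
0 when the response is completely lost, and → −1 as P0 grows far beyond
C0. It is invariant to common rescaling of the pair and undefined when
C0 = 0 (such pairs are skipped and logged; records with fewer than
three valid pairs carry a `low_n` flag). The response variable is
group-level relative abundance — robust at moderate depth — rather than
per-taxon averages or a pairwise-similarity variant.

Tolerance width is the abundance-weighted standard deviation of an
environmental covariate, W = √(Σaⱼ(eⱼ−ē)²/Σaⱼ): zero iff all abundance
mass sits at one covariate value, insensitive to abundance rescaling.
With several covariates a width is reported per covariate, never
combined.

Nonsynchronization is 1 − φ with the variance-ratio synchrony
φ = Var(Σᵢxᵢ)/(ΣᵢSD(xᵢ))² over member taxa (rows) across the ordered
disturbance conditions within a field, averaged over fields. φ uses
population (ddof = 0) moments; two proportional series give φ = 1
(result 0), mean-centered mirror series give 1. Ties in condition order
follow the configured treatment order.

## Diversity, niche breadth, generalists

Shannon diversity H = −Σ p ln p is computed per sample over a group's
member taxa and averaged over samples. Levins breadth B = 1/ΣⱼP²ᵢⱼ uses
Pᵢⱼ = the fraction of taxon i's total counts in habitat j, where a
habitat is a sample within a crop (configurable to treatment level);
B ranges from 1 to the number of habitats. The group-level value is the
abundance-weighted mean of member breadths, weights proportional to
taxon totals.

Generalist/specialist calls compare each taxon's observed B with a
permutation null that redistributes the taxon's total count across
samples by a multinomial draw with probabilities proportional to sample
depths — preserving sequencing effort, the dominant artifact in breadth
estimates. With n_perm = 999 draws (default) and a two-sided empirical
95% interval, a taxon above the upper quantile is a generalist (more
even than sampling noise allows), below the lower one a specialist.
Taxa with fewer than 20 total counts are labelled neutral with a
low-power flag and excluded from group proportions. On data generated
from this null the non-neutral rate matches the nominal 5% level within
binomial error (checked in the acceptance suite with n_perm = 499,
400 taxa).

## Assembly models

**Neutral fit.** The Sloan neutral model predicts occurrence frequency
from metacommunity mean relative abundance p with one parameter Nm. The
classic curve, F̂(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)) with detection
limit d = 1/mean depth, is implemented (`sloan_frequency`), but the
default fitting curve is the sampling-aware occurrence
P(detect in N reads) = 1 − B(a, b+N)/B(a, b) (the zero class of a
beta-binomial). The distinction matters: on data simulated by the
birth–death scheme below, the continuous-threshold curve overestimates
Nm by ≈30% (verified against the exact Dirichlet-multinomial occurrence
curve), while the beta-binomial form recovers the planted migration rate
within ≈10%; the classic form remains available via
`occurrence_model="threshold"`. Nm is estimated by nonlinear least
squares of occurrence on the curve over taxa with interior occurrence
(0 < F < 1; at least 10 required), using a fixed 60-point log-spaced
initialization grid followed by bounded scalar refinement — fits are
deterministic to ~1e−10. r² = 1 − SSE/SST; the 95% band uses Wilson
binomial intervals around the fitted frequencies; m = Nm/mean depth.

**Neutral simulator.** `simulate_neutral` implements the birth–death
scheme: per step one random individual dies and is replaced by an
immigrant from the fixed source pool with probability m, else by a copy
of a random resident. Communities are initialized from the chain's
approximate stationary law (multinomial from Dirichlet(θp) proportions,
θ = (N−1)m/(1−m)) so the default 50·N update steps refine rather than
burn in; a plain multinomial start needs far longer than 50 turnovers to
decorrelate and leaves the fitted m biased upward.

**Normalized stochasticity ratio.** For each sample pair,
D = observed dissimilarity (Bray–Curtis on within-subset relative
abundance, or Jaccard on incidence) and Ē = its mean over n_null
randomizations (default 200; at least 30). The bounded ratio form

    ST = D/Ē        if D ≤ Ē
       = (1−D)/(1−Ē) otherwise

is averaged over pairs; pairs with Ē ∈ {0, 1} are excluded. The default
null model preserves each sample's richness and depth exactly: taxa are
drawn without replacement proportional to occupancy frequency, each
selected taxon receives one count, and the remaining depth is allocated
multinomially proportional to regional mean relative abundance.
Identical samples give NST = 0; data drawn from the null itself give
NST ≈ 0.8–0.9 rather than exactly 1, because any finite draw deviates
from the null mean and the ratio normalization is concave, so every
deviation pushes ST below 1. Increasing environmental-filtering
strength decreases NST monotonically (checked over three levels at
fixed seeds). NST is computed per group within each treatment, crops
pooled.

## Function linkage

Multifunctionality is the averaging index: z-score each measured
function across samples, take the per-sample mean; constant functions
are dropped with a warning. The R value of a group in a crop × treatment
stratum is the Spearman correlation (mid-ranks; exact permutation
p-value for n ≤ 9, t approximation otherwise) between the group's
abundance and multifunctionality over the stratum's samples; per-single-
function correlations are emitted alongside, so either reading of
"correlation with each functional factor" is available, with the
multifunctionality version as the headline. The D value is R under a
disturbance treatment minus R in the control stratum of the same crop.
Per-function correlation matrices are reported unadjusted (the heat map
is descriptive); a Benjamini–Hochberg helper is provided.

All body-size regressions are ordinary least squares on log₁₀ size
(any other base rescales the slope by a constant), with the two-sided
slope p-value from the t distribution on n − 2 df. Headline regressions
average per-group metrics over crops (and over disturbance treatments
for resistance and D) before regressing. A metric that is constant
across groups is reported as slope 0, r² 0, p 1.

## Synthetic generator: what is planted and what is not

Defaults emulate a paired incubation design: 2 crops × 25 fields ×
4 treatments (control, warming, N, P; unit doses) = 200 samples,
24 organism groups, Poisson-distributed depth with mean 10 000 reads per
marker per sample, and 11 function variables. All draws derive from one
seed via three named streams (structure, sampling, functions), so
community structure can be held fixed across sampling-noise replicates.

Planted structure, per group g with body size s_g (µm):

* **Richness ramp** — taxa per group decline linearly in size rank from
  80 (smallest) to 20 (largest): more, smaller taxa. Drives the
  Shannon–size trend.
* **Disturbance sensitivity** — in a disturbed sample every member
  taxon's expected proportion is multiplied by exp(−σ·log₁₀(s_g)·dose + ε)
  (sensitivity slope σ = 0.4 by default, clipped at 0). The noise ε
  (SD 0.15) is drawn once per group × sample, not per taxon: with
  per-taxon noise, taxon-rich (small-bodied) groups average it away and
  the resulting richness-dependent RS bias masquerades as a body-size
  effect even when σ = 0. With group-level noise the no-effect control
  is clean (20/20 non-significant regressions at σ = 0).
* **Environmental niches** — each field carries a standard-normal
  gradient value; each taxon responds through a Gaussian kernel whose
  width shrinks with size (w_g = 5·s_g^−0.6 in gradient SD units, i.e.
  bacteria are effectively indifferent, protists occupy narrow slices).
  Drives the breadth–size and generalist–size trends and, because
  narrow-niche taxa are patchy, the stochasticity contrast.
* **Function links** — within each crop × treatment stratum, each
  function is a noisy weighted sum of z-scored group abundances: a
  strong weight from its assigned group plus a weak spillover from all
  groups, scaled by a link strength that increases with log size in the
  control stratum (0.15 → 0.8) and decreases with size under treatment
  (0.8 → 0.15). This plants the positive control R–size slope and the
  negative D–size slope; a single strength per group cannot produce
  both, which is why the configuration takes a (function, control
  strength, treated strength) triple per group.
* About 15% of each domain's taxa are left outside every group, so the
  coverage filter does nontrivial work.

The ground truth (sensitivities, widths, link strengths, baseline
proportions) is recorded before sampling noise and serialized with the
bundle.

Not emulated: sequencing error, chimeras, compositional extraction bias,
copy-number variation, temporal dynamics within the incubation, or
calibrated dose units (doses are abstract). Passing tests therefore
demonstrate that the statistics recover planted effects through
multinomial sampling and compositional constraints — not robustness to
amplicon artifacts, and body sizes in the bundled 24-group lookup are
synthetic fixture values on a literature-plausible scale, not curated
measurements.

## Numerical choices and scale

* All randomness flows through `numpy.random.Generator` objects seeded
  from named `SeedSequence` streams; pipeline reruns with the same
  config and seed are byte-identical, and the manifest records the
  config hash plus a sha256 per output so external tooling can skip
  unchanged stages (an in-process cache would cost more than any stage
  at these scales).
* `null_randomize` forces C-contiguous input before computing null
  weights: summation order otherwise depends on how the caller's
  DataFrame was constructed, and 1-ulp weight differences change
  multinomial draws, breaking exact relabeling invariance.
* Degenerate inputs fail loudly: zero-total samples, all-zero abundance
  vectors, single-sample breadth, constant rank vectors and zero
  size variance all raise with the offending record named; zero-control
  resistance pairs and Ē ∈ {0,1} NST pairs are skipped and logged.
* Test and validation problem sizes are chosen desk-scale: neutral
  recovery uses S = 200, N = 1000, 60 samples, 5 replicates; NST
  calibration 20 samples at n_null = 200; the planted-pattern check one
  default 200-sample bundle; the no-effect control 20 replicate bundles.
  The full validation script completes in about a minute on one CPU;
  published analyses would typically raise n_null to 1000 and n_perm to
  999+ per crop.

## Known limitations

* The ratio-form NST is one of several published normalizations; it is
  bounded and symmetric about the null but saturates near 1 slowly, and
  its self-null expectation is below 1 (see above). Alternative ST
  formulas can be swapped in behind the same interface.
* Generalist calls are conservative on overdispersed data: any
  biological variability beyond multinomial noise pushes breadth below
  the null, so generalist proportions are small and the specialist side
  carries most of the signal.
* Per-group neutral fits inherit the usual caveats of fitting a
  one-parameter curve to occurrence data: Nm is identified mostly by
  mid-occupancy taxa, and groups with few interior taxa are reported as
  missing rather than fitted.
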