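# Methods

## Model

### Poisson random field likelihood

The unit of inference is a `SpectrumSet`: unfolded (or folded)
synonymous and nonsynonymous site frequency spectra for a sample of
`n` chromosomes, site opportunities `Ls`/`Ln`, and divergence counts
`Ds`/`Dn` against a single outgroup.  Under the Poisson random field
approximation with per-site mutation rate θ = 4Nₑu, the expected number
of polymorphic sites at derived-allele count `i` is

    E[s_i] = r_i θ Ls / i
    E[x_i] = r_i θ Ln ∫ f(S) G(S, i, n) dS

where `f` is the density of the scaled selection coefficient S = 4Nₑs
of new nonsynonymous mutations and

    G(S, i, n) = ∫₀¹ C(n,i) xⁱ (1−x)^(n−i) h(x; S) dx,
    h(x; S)    = (1 − e^{−S(1−x)}) / ((1 − e^{−S}) x (1−x)),

the standard diffusion sojourn density (h(x;0) = 1/x).  The likelihood
is the product of independent Poisson terms over the synonymous and
nonsynonymous classes 1..n−1.  Divergence counts are excluded from the
likelihood and enter only through the observed ω (see *Decomposition*).

Optional components, both off by default:

- nuisance multipliers `r_i` (r₁ ≡ 1) shared between the synonymous and
  nonsynonymous spectra, absorbing demographic/ascertainment distortion;
  they are profiled analytically per frequency class;
- an ancestral-misidentification probability ε ∈ [0, 0.5] that mixes
  class `i` with class `n−i` symmetrically in both spectra.

### DFE families

- **Neutral** — point mass at S = 0.  One free parameter (θ).
- **Gamma** — deleterious effects: −S ~ Gamma(shape β, mean S̄_d).
  Three free parameters.
- **GammaExpo** — a fraction `p_b` of new mutations is beneficial with
  S ~ Exponential(S̄_b); the rest follow the Gamma.  Five free
  parameters.

Families are compared by AIC = 2k − 2 log L (ties broken toward fewer
parameters).  The Gamma–Exponential family nests Gamma (p_b = 0), which
nests Neutral in the weak-selection limit; maximized likelihoods are
monotone across the nesting, a property the tests assert.

### Decomposition into ω_na and ω_a

With the relative fixation probability Q(S) = S / (1 − e^{−S}), the
fitted DFE yields the expected non-adaptive dN/dS

    ω_na = (1 − p_b) ∫ f_del(S) Q(S) dS  +  p_b ∫_{0}^{S_min} f_ben(S) Q(S) dS

and the observed ω = (Dn/Ln)/(Ds/Ls) gives ω_a = ω − ω_na and
α = ω_a/ω.

The second term implements a deliberate design choice: **fixations of
beneficial mutations with S below S_min = 1 are counted as
non-adaptive.**  The SFS alone cannot distinguish a large `p_b` of
effectively neutral "beneficial" mutations (S̄_b → 0) from neutral mass
inside the Gamma — the likelihood surface has a ridge along this
trade-off, and on some data realizations the ridge's far end is the
global maximum.  Under the alternative convention (every
exponential-component fixation is adaptive) ω_a is unidentifiable along
the ridge: a fit with p_b ≈ 0.09, S̄_b ≈ 0.01 claims ω_na ≈ 0.018
where the truth is 0.084.  Counting sub-threshold fixations as
non-adaptive makes the decomposition ridge-invariant (the same fit then
reports ω_na ≈ 0.109), at the cost of classifying genuinely weak
positive selection (0 < S < 1, fixation advantage below 1.6× neutral)
as non-adaptive.  The synthetic-truth manifests use the identical
convention, so recovery is measured consistently.

## Numerics

- `x`-integration: 128-node Gauss–Legendre on (0, 1); agrees with a
  10⁵-interval midpoint rule to better than 10⁻⁴ relative error over
  S ∈ [−100, 100] (asserted in tests, near machine precision in
  practice).
- `S`-integration: each DFE component is discretized into 400 bins,
  geometrically spaced over |S| ∈ [10⁻⁴, 10⁵], with bin masses taken as
  CDF differences (exactly mass-conserving) and the integrand evaluated
  at geometric bin midpoints.  Mass below 10⁻⁴ is treated as neutral
  (G = 1/i, Q = 1); deleterious mass above 10⁵ neither segregates nor
  fixes; beneficial tail mass above 10⁵ is negligible within the
  optimization bounds.
- `h(x; S)` and `Q(S)` use `expm1`-based branch-separated forms, stable
  to |S| = 10⁴ and beyond.
- Optimization: θ (and `r_i`) profiled analytically; the remaining
  parameters are optimized by L-BFGS-B in log space (p_b and ε on their
  natural scale) with bounds β ∈ [0.01, 10], S̄_d ∈ [10⁻², 10⁶],
  p_b ∈ [0, 0.5], S̄_b ∈ [10⁻², 10³]; five deterministic seeded starts
  by default.  Bootstrap replicate fits are warm-started at the
  category's full-data fit with a single start and a looser `ftol`
  (10⁻⁷): optimizer error far below the bootstrap noise floor is wasted
  work.
- The Neutral family (without nuisances) has a closed-form MLE and
  skips the optimizer.

## SFS building rules

Codon columns are classified one at a time:

- Codons containing gaps, N, or stop codons (in any ingroup sequence or
  the outgroup), columns segregating at more than one nucleotide
  position, positions with more than two alleles, and columns whose
  outgroup allele matches neither ingroup allele (polarization failure)
  are excluded with a reason code.  A missing outgroup codon is missing
  data.  Alignments with a premature ingroup stop codon are rejected.
- Opportunities use Nei–Gojobori fractional counting averaged over the
  ingroup codons of the column; single-base changes to stop codons
  count toward neither class, so a codon's opportunities sum to 3 minus
  its stop-reachable fraction.
- A column that is both polymorphic and divergent counts as polymorphic
  only (no double counting).  Divergent columns differing from the
  outgroup at ≥2 positions are excluded (pathway ambiguity).
- Polymorphic sites are down-sampled to the common sample size by
  hypergeometric projection — either the exact expected mass over
  classes (deterministic) or a seeded single draw; projected counts of
  0 or n leave the polymorphic spectrum.
- Coordinates are 0-based throughout; `codon_index * 3 +
  position_in_codon` is the nucleotide offset.

## Covariate machinery

- RSA = solvent-accessible area / residue maximum accessible area
  (shipped per-residue table of theoretical maxima; configurable),
  clamped to [0, 1].  Buried means RSA < 0.05, exposed RSA ≥ 0.05.
- Disorder: a residue is "disordered" if its value exceeds the 75th
  percentile (linear interpolation) of all residue values — strictly
  above, so uniform inputs flag nothing; per-gene `prop_disordered` is
  the flagged fraction.
- Equal-count binning: quantile bins over the units; ties share the
  lower-quantile bin; with `zero_special` the units at exactly 0 form
  their own first category and the remainder is split into k−1 bins
  (the RSA layout).  Ties that prevent k nonempty bins reduce k with a
  warning.
- Grantham classes: a change is radical iff the absolute difference of
  the volume or polarity index exceeds its cutoff; default cutoffs are
  each index's range midpoint (the source analysis does not publish its
  cutoffs, so they are explicit, configurable parameters here).
- Structure-to-sequence transfer walks a pairwise alignment and copies
  features only at matched, ungapped columns.

## Bootstrap and tests

- Per category, units (genes, or gene-level contributions to a site
  category) are resampled with replacement to the original count,
  pooled, and refitted; B = 100 replicates by default; deterministic
  given the seed.
- Trimming drops failed replicates and any replicate whose fitted DFE
  mean or shape lies strictly outside the [1%, 99%] percentile band of
  its category (union over the two parameters) — at B = 100 with
  all-distinct values this removes at most 4 replicates.
- Summaries are the replicate mean and percentile [2.5%, 97.5%]
  interval.
- Trend: Kendall's τ between category rank and the replicate-mean
  estimate; two-sided P (exact for small numbers of categories).
- Pairwise: replicates of two categories are paired by a seeded random
  permutation (index pairing available for regression tests), the
  shorter list padded by seeded resampling; differences are counted by
  sign, zeros split evenly; k = min(#neg, #pos) and P = (2k+1)/(N+1).
  Families of pairwise comparisons are BH-FDR adjusted.  Because the
  two replicate sets are conditionally independent given their data,
  the sign count is Binomial(N, ½) under the null and the test is
  conservative (empirical false-positive rate ≈ 0 at nominal 5%).
- ANCOVA: OLS of ω_a (or ω_na) on RSA, disorder, and their interaction
  with type-I (sequential) sums of squares, RSA entered first —
  matching the "% of variation explained by RSA" reading; term order is
  a parameter.

## Synthetic data

`simulate_features` emulates the study's data products: log-normal gene
lengths; log-normal expression rank-correlated −0.4 with length;
zero-inflated Beta RSA (12% of residues at exactly 0, emulating totally
buried residues) with a negative length–RSA gene-level correlation
(longer proteins have proportionally smaller surfaces); persistent
3-state secondary structure segments; disorder rank-correlated with RSA
and elevated in loops; plus intron counts, recombination rates, PPI
degrees, chaperone binding, localization and functional classes.

`simulate_spectra` draws SFS counts independently per class from the
analytic expectation of a per-category DFE (count-noise model) and
divergence counts with E[Dn] = dS · Ln · ω_true, so each category's
true ω, ω_na, ω_a, α are analytic and recorded in a `TruthManifest`.
The count-noise model matches the fitted likelihood's assumptions —
deliberately, so that parameter recovery is a well-posed test of the
estimator.  It does **not** emulate linkage, demography, coalescent
noise, GC-biased gene conversion, or mutation-rate heterogeneity;
passing recovery tests therefore validates the inference machinery, not
robustness to those real-data violations.

Default study conditions (used by the tests and the acceptance script):
n = 20 chromosomes (desk-scale stand-in for the ~105–110 the full
studies down-sample to), θ = 0.01/site, dS = 0.15, and a fly-like
Gamma–Exponential truth (β = 0.3, S̄_d = 2000, p_b = 0.009, S̄_b = 10),
which gives ω ≈ 0.18, ω_na ≈ 0.084, ω_a ≈ 0.091, α ≈ 0.52.  The
planted solvent-exposure effect ramps p_b geometrically 10-fold from
the most buried to the most exposed of 19 RSA categories — the
magnitude the full-genome analyses report for the exposed/buried
ω_a contrast.  Problem sizes in the test-suite recovery runs (G = 2000
genes, 20 seeds, B = 100 bootstrap replicates) were chosen so the whole
statistical battery runs on a laptop-class single core in minutes.

## Known limitations

- ω_a at a single category can be slightly negative by sampling noise;
  it is reported as estimated, not truncated.
- p_b and S̄_b are individually weakly identified from the SFS (their
  product region is what the data constrain); only the decomposition is
  made ridge-invariant, not the parameters themselves.  CIs on p_b/S̄_b
  should not be over-interpreted.
- The pairwise bootstrap test is conservative by construction; with B
  replicates its smallest attainable P is 1/(B+1), so B = 100 cannot
  reach below P ≈ 0.0099.
- Site-category bootstraps resample gene-level contributions to a
  category rather than individual sites; this preserves within-gene
  correlation and is the scale at which the generator plants effects.
- The folded-spectrum path supports Gamma/Neutral fits well; the
  beneficial component of GammaExpo is barely identifiable from a
  folded SFS, as expected.
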