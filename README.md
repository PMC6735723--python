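# dfescan

Estimation of the adaptive and non-adaptive rates of protein evolution
from population genomic data, with the categorization, bootstrap and
significance-testing machinery needed to scan structural and functional
correlates of adaptation — solvent exposure, secondary structure,
intrinsic disorder, expression, gene architecture — across a genome.

## The problem

The dN/dS ratio ω averages positive and negative selection over sites.
McDonald–Kreitman-style methods disentangle the two by contrasting
polymorphism and divergence at synonymous and nonsynonymous sites: after
fitting a distribution of fitness effects (DFE) to the site frequency
spectrum (SFS), the expected rate of fixation of neutral and deleterious
mutations gives the *non-adaptive* rate

&emsp; ω<sub>na</sub> = dN<sub>na</sub>/dS,

and the remainder of the observed ω is attributed to adaptation:

&emsp; ω<sub>a</sub> = ω − ω<sub>na</sub>, &emsp; α = ω<sub>a</sub>/ω.

`dfescan` implements this estimator end to end:

- **SFS building** from per-gene codon alignments (ingroup chromosomes
  plus one outgroup): Nei–Gojobori fractional site counting, outgroup
  polarization, hypergeometric down-sampling to a common sample size,
  folded or unfolded spectra, divergence counts.
- **DFE fitting** by Poisson maximum likelihood on the SFS under the
  Neutral, Gamma, and Gamma–Exponential families (deleterious Gamma plus
  an exponential tail of beneficial effects), with optional per-class
  nuisance multipliers r<sub>i</sub> and ancestral-misidentification
  ε; model choice by AIC.
- **Covariate machinery**: relative solvent accessibility (RSA = SA /
  max accessible area; buried < 0.05 ≤ exposed), top-quartile disorder
  flagging, equal-count binning with a dedicated RSA = 0 category,
  structure-to-sequence mapping, Grantham conservative/radical classes.
- **Statistics**: per-category bootstrap (resampling genes or sites)
  with 1% trimming on the DFE mean and shape, percentile 95% CIs,
  Kendall trend tests over ordered categories, a pairwise bootstrap
  statistic k with P = (2k + 1)/(N + 1), Benjamini–Hochberg FDR, and a
  sequential ANCOVA partitioning ω<sub>a</sub>/ω<sub>na</sub> variance
  between RSA, disorder, and their interaction.
- **A synthetic-data generator** producing covariate tables with
  realistic correlation structure and spectra drawn from known DFEs, so
  every stage can be validated against analytic ground truth.

## Worked example

Fit the three DFE families to a genome-scale spectrum (20 chromosomes,
2M synonymous / 6M nonsynonymous sites) simulated from the generator's
default fly-like Gamma–Exponential DFE:

```python
import numpy as np
from dfescan import DFEParams, compare_models, SpectrumSet
from dfescan.dfe import _nonsyn_integral, omega_expected

truth = DFEParams("GammaExpo", shape=0.3, mean_del=2000.0, p_b=0.009, mean_ben=10.0)
n, Ls, Ln, theta, ds = 20, 2e6, 6e6, 0.01, 0.15
rng = np.random.default_rng(42)
i = np.arange(1, n)
obs = SpectrumSet(
    n=n, Ls=Ls, Ln=Ln,
    sfs_syn=rng.poisson(theta * Ls / i),
    sfs_nonsyn=rng.poisson(theta * Ln * _nonsyn_integral(truth, n)),
    Ds=float(rng.poisson(ds * Ls)),
    Dn=float(rng.poisson(ds * Ln * omega_expected(truth))),
)
for fit in compare_models(obs, seed=0):
    p = fit.params
    print(f"{p.family:<10} AIC={fit.aic:10.1f}  omega={fit.omega:.3f}  "
          f"omega_na={fit.omega_na:.3f}  omega_a={fit.omega_a:.3f}  alpha={fit.alpha:.3f}")
```

```
GammaExpo  AIC=     387.7  omega=0.176  omega_na=0.082  omega_a=0.094  alpha=0.533
Gamma      AIC=     465.8  omega=0.176  omega_na=0.101  omega_a=0.074  alpha=0.424
Neutral    AIC=   85190.7  omega=0.176  omega_na=1.000  omega_a=-0.824  alpha=-4.693
```

AIC selects the generating Gamma–Exponential family; its decomposition
recovers the simulated truth (ω<sub>a</sub> = 0.091, α = 0.52) within
sampling noise.  The Gamma family, lacking a beneficial component,
absorbs part of the adaptive signal into ω<sub>na</sub>; the Neutral
family attributes all constraint to ω<sub>na</sub> = 1 and is rejected
outright.

The same machinery runs from the shell: `dfescan simulate` writes
covariate tables, `dfescan build-sfs` turns FASTA codon alignments into
SFS files (TSV and a one-line DoFE-style dialect), `dfescan fit` fits
and ranks DFE families, and `dfescan scan` runs the full synthetic
pipeline below.

## Scanning covariates

`dfescan scan` (or `dfescan.pipeline.scan_synthetic`) runs the whole
design: simulate covariates for G genes, bin residues into 19 ordered
RSA categories (totally buried RSA = 0 residues form their own
category), draw per-category spectra from a DFE map whose beneficial
fraction p_b rises 10-fold with solvent exposure, bootstrap each
category (B = 100 replicates, trimmed), refit the Gamma–Exponential
model on every replicate, and test the ω<sub>a</sub> trend (Kendall τ)
and the buried-vs-exposed contrast (pairwise bootstrap k with FDR).
It prints Table-style TSVs: per-category estimates with 95% CIs, trend
taus with significance codes, and pairwise differences.

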