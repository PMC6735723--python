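"""Bootstrap resampling, replicate trimming, and the analysis statistics.

Per category, units (genes or sites) are resampled with replacement, the
pooled spectrum is refitted, and the replicate estimates of omega,
omega_na and omega_a feed:

* percentile confidence intervals (mean and 95% CI of the replicates);
* Kendall trend tests of category means against the category order;
* a pairwise bootstrap statistic k — replicates of two categories are
  paired at random, differences counted by sign, ``k = min(#neg, #pos)``
  and ``P = (2k + 1) / (N + 1)``;
* Benjamini-Hochberg FDR correction over families of pairwise tests;
* a sequential (type-I) ANCOVA partitioning variance in omega_a/omega_na
  between RSA, disorder and their interaction.

Replicates whose DFE mean or shape fall outside the [1%, 99%] percentile
band of their category are trimmed before any summary or test, as are
replicates whose fit failed outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from . import dfe
from .spectra import SpectrumSet

__all__ = [
    "BootstrapResult",
    "TestOutcome",
    "bootstrap_categories",
    "trim_replicates",
    "summarize",
    "kendall_trend",
    "pairwise_bootstrap_test",
    "fdr_adjust",
    "ancova_partition",
    "significance_code",
]


@dataclass
class TestOutcome:
    """One statistical comparison: a statistic, its P value, optional FDR."""

    comparison: str
    statistic: float
    p_value: float
    p_adjusted: Optional[float] = None

    def code(self) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return significance_code(p)


def significance_code(p: float) -> str:
    """Table-style significance annotation: ***, **, *, '.' or ''."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


@dataclass
class BootstrapResult:
    """Per-category bootstrap replicates of DFE fits.

    ``replicates[label]`` holds up to B :class:`~dfescan.dfe.FitResult`
    entries (None marks a failed replicate before trimming); ``point``
    holds the full-data fit per category.
    """

    scheme_name: str
    labels: list[str]
    replicates: dict[str, list]
    point: dict[str, object]
    B: int
    retained: dict[str, int] = field(default_factory=dict)
    trimmed: bool = False

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = {
                lab: sum(r is not None for r in reps)
                for lab, reps in self.replicates.items()
            }

    def values(self, label: str, metric: str = "omega_a") -> np.ndarray:
        return np.array(
            [getattr(r, metric) for r in self.replicates[label] if r is not None]
        )


class _StackedUnits:
    """Column-stacked per-unit spectra enabling O(U) bootstrap aggregation."""

    def __init__(self, spectra: Sequence[SpectrumSet]):
        first = spectra[0]
        self.n = first.n
        self.folded = first.folded
        self.syn = np.stack([s.sfs_syn for s in spectra])
        self.nonsyn = np.stack([s.sfs_nonsyn for s in spectra])
        self.scalars = np.array(
            [[s.Ls, s.Ln, s.Ds, s.Dn] for s in spectra]
        )

    def resample(self, rng: np.random.Generator) -> SpectrumSet:
        U = self.syn.shape[0]
        idx = rng.integers(0, U, size=U)
        return self.pool(idx)

    def pool(self, idx=None) -> SpectrumSet:
        if idx is None:
            syn, nonsyn = self.syn.sum(0), self.nonsyn.sum(0)
            Ls, Ln, Ds, Dn = self.scalars.sum(0)
        else:
            syn, nonsyn = self.syn[idx].sum(0), self.nonsyn[idx].sum(0)
            Ls, Ln, Ds, Dn = self.scalars[idx].sum(0)
        return SpectrumSet(n=self.n, Ls=Ls, Ln=Ln, sfs_syn=syn,
                           sfs_nonsyn=nonsyn, Ds=Ds, Dn=Dn, folded=self.folded)


def _omega_only_estimate(spec: SpectrumSet) -> dfe.FitResult:
    """Closed-form count-based estimate (no DFE fit): omega and the
    neutral-expectation alpha.  Used by fast calibration checks."""
    omega = (spec.Dn / spec.Ln) / (spec.Ds / spec.Ls)
    return dfe.FitResult(
        params=None, loglik=np.nan, n_params=0, aic=np.nan,
        omega=omega, omega_na=1.0, omega_a=omega - 1.0,
        alpha=1.0 - 1.0 / omega if omega > 0 else np.nan,
        name=spec.name,
    )


def bootstrap_categories(
    units_by_label: Mapping[str, Sequence],
    spectra: Mapping,
    B: int = 100,
    seed: int = 0,
    family: str = "GammaExpo",
    estimator: str = "dfe",
    n_starts: int = 1,
    point_n_starts: int = 5,
    identity: bool = False,
    scheme_name: str = "scheme",
    fit_kwargs: Optional[dict] = None,
    replicate_ftol: float = 1e-7,
    replicate_maxiter: int = 60,
) -> BootstrapResult:
    """Bootstrap each category by resampling its units with replacement.

    Each replicate pools a resample of the category's unit spectra and
    refits the chosen DFE family, warm-started from the category's
    full-data fit (``n_starts`` extra optimizer starts per replicate; the
    point fit itself uses ``point_n_starts``).  Failed fits are recorded
    as None.  ``identity=True`` disables resampling (every replicate
    equals the point estimate, for regression tests).  Replicate fits
    run at a looser optimizer tolerance (``replicate_ftol``) than the
    point fit: optimization error far below the bootstrap noise floor
    is wasted work.
    ``estimator='omega'`` replaces the DFE fit by the closed-form
    count-based omega (fast; used for calibration checks).

    Deterministic given ``seed``.
    """
    fit_kwargs = dict(fit_kwargs or {})
    labels = list(units_by_label.keys())
    replicates: dict[str, list] = {}
    point: dict[str, object] = {}
    master = np.random.SeedSequence(seed)
    label_seeds = master.spawn(len(labels))
    for lab, lab_seed in zip(labels, label_seeds):
        units = list(units_by_label[lab])
        if len(units) < 2:
            raise ValueError(f"category {lab!r} has fewer than 2 units")
        stack = _StackedUnits([spectra[u] for u in units])
        pooled = stack.pool()
        pooled.name = lab
        if estimator == "omega":
            pt = _omega_only_estimate(pooled)
        else:
            pt = dfe.fit_model(pooled, family=family, n_starts=point_n_starts,
                               seed=seed, **fit_kwargs)
        point[lab] = pt
        rng = np.random.default_rng(lab_seed)
        reps: list = []
        for b in range(B):
            spec = pooled if identity else stack.resample(rng)
            spec.name = f"{lab}_rep{b}"
            try:
                if estimator == "omega":
                    fit = _omega_only_estimate(spec)
                else:
                    fit = dfe.fit_model(
                        spec, family=family, n_starts=n_starts, seed=b,
                        start=pt.params, ftol=replicate_ftol,
                        maxiter=replicate_maxiter, **fit_kwargs,
                    )
                bad = not np.isfinite(fit.omega_a) or not np.isfinite(fit.loglik)
                if estimator == "omega":
                    bad = not np.isfinite(fit.omega_a)
                reps.append(None if bad else fit)
            except (RuntimeError, ValueError):
                reps.append(None)
        replicates[lab] = reps
    return BootstrapResult(
        scheme_name=scheme_name, labels=labels, replicates=replicates,
        point=point, B=B,
    )


def trim_replicates(result: BootstrapResult) -> BootstrapResult:
    """Drop failed replicates and DFE-parameter outliers per category.

    A replicate is trimmed when its fitted DFE mean or shape falls
    strictly above the 99th or strictly below the 1st percentile of the
    category's replicate values (union over the two parameters) — the 1%
    tail rule guarding against unconverged fits.  Categories retaining
    fewer than half their replicates are flagged with a warning.
    """
    new_reps: dict[str, list] = {}
    retained: dict[str, int] = {}
    for lab, reps in result.replicates.items():
        good = [r for r in reps if r is not None]
        if len(good) < 10:
            warnings.warn(
                f"{result.scheme_name}/{lab}: only {len(good)} replicates; "
                "percentile trimming skipped"
            )
            kept = good
        else:
            kept = good
            for attr in ("mean_del", "shape"):
                vals = np.array(
                    [getattr(r.params, attr) if r.params is not None else np.nan
                     for r in good],
                    dtype=float,
                )
                if np.all(np.isnan(vals)):
                    continue  # parameter-free estimator: nothing to trim on
                lo, hi = np.nanpercentile(vals, [1.0, 99.0])
                kept = [
                    r for r in kept
                    if lo <= getattr(r.params, attr) <= hi
                ]
        if len(kept) < 0.5 * result.B:
            warnings.warn(
                f"{result.scheme_name}/{lab}: fewer than 50% of replicates "
                f"retained ({len(kept)}/{result.B})"
            )
        new_reps[lab] = kept
        retained[lab] = len(kept)
    return BootstrapResult(
        scheme_name=result.scheme_name, labels=result.labels,
        replicates=new_reps, point=result.point, B=result.B,
        retained=retained, trimmed=True,
    )


def summarize(
    result: BootstrapResult,
    metrics: Sequence[str] = ("omega", "omega_na", "omega_a"),
) -> pd.DataFrame:
    """Mean and percentile 95% CI of the retained replicates, per category.

    Categories with fewer than 3 retained replicates are omitted with a
    warning.
    """
    rows = []
    for lab in result.labels:
        vals_by_metric = {m: result.values(lab, m) for m in metrics}
        n_reps = len(result.replicates[lab]) - sum(
            r is None for r in result.replicates[lab]
        )
        if n_reps < 3:
            warnings.warn(f"{result.scheme_name}/{lab}: <3 replicates, omitted")
            continue
        for m, v in vals_by_metric.items():
            rows.append({
                "label": lab, "rank": result.labels.index(lab), "metric": m,
                "mean": float(np.mean(v)),
                "ci_low": float(np.percentile(v, 2.5)),
                "ci_high": float(np.percentile(v, 97.5)),
                "n_replicates": n_reps,
            })
    return pd.DataFrame(rows)


def kendall_trend(
    means: Sequence[float],
    comparison: str = "trend",
) -> TestOutcome:
    """Kendall's tau between category rank and category mean estimate.

    Two-sided P value (exact for small category counts without ties,
    normal approximation otherwise, as provided by scipy).  Zero
    variance in the means leaves tau undefined.
    """
    means = np.asarray(means, dtype=float)
    if len(means) < 3:
        raise ValueError("trend test needs at least 3 categories")
    if np.ptp(means) == 0.0:
        return TestOutcome(comparison=f"{comparison} (undefined: zero variance)",
                           statistic=np.nan, p_value=np.nan)
    tau, p = sps.kendalltau(np.arange(len(means)), means)
    return TestOutcome(comparison=comparison, statistic=float(tau),
                       p_value=float(p))


def pairwise_bootstrap_test(
    reps_a: Sequence[float],
    reps_b: Sequence[float],
    seed: int = 0,
    pairing: str = "random",
    comparison: str = "A-B",
) -> TestOutcome:
    """Bootstrap-overlap test for a difference between two categories.

    Replicates are paired (randomly permuted, or by index for regression
    tests), differences ``d = A - B`` are counted by sign, zeros split
    evenly, and ``k = min(#neg, #pos)`` gives the two-tailed
    ``P = (2k + 1) / (N + 1)``.  The shorter replicate list is padded by
    seeded resampling.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if min(len(a), len(b)) < 10:
        raise ValueError("pairwise test needs at least 10 replicates per side")
    rng = np.random.default_rng(seed)
    N = max(len(a), len(b))
    if len(a) < N:
        a = np.concatenate([a, rng.choice(a, N - len(a))])
    if len(b) < N:
        b = np.concatenate([b, rng.choice(b, N - len(b))])
    if pairing == "random":
        a = a[rng.permutation(N)]
    elif pairing != "index":
        raise ValueError(f"unknown pairing {pairing!r}")
    d = a - b
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    n_zero = N - n_pos - n_neg
    k = min(n_pos, n_neg) + n_zero / 2.0
    p = (2.0 * k + 1.0) / (N + 1.0)
    return TestOutcome(comparison=comparison, statistic=float(k),
                       p_value=float(min(p, 1.0)))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ancova_partition(
    data: pd.DataFrame,
    response: str = "omega_a",
    rsa_col: str = "rsa",
    disorder_col: str = "disorder",
) -> pd.DataFrame:
    """Sequential ANCOVA of omega_a (or omega_na) on RSA x disorder.

    Ordinary least squares with RSA entered first, then disorder, then
    the interaction; type-I (entry-order) sums of squares are converted
    to fractions of the total, which reproduces the '% of variation
    explained by RSA' reading.  Fractions sum to 1.
    """
    df = pd.DataFrame({
        "y": data[response].astype(float),
        "rsa": data[rsa_col].astype(float),
        "disorder": data[disorder_col].astype(float),
    }).dropna()
    if len(df) < 8:
        raise ValueError("ANCOVA needs at least 8 observations")
    for col in ("rsa", "disorder"):
        if df[col].std() == 0:
            raise ValueError(f"covariate {col!r} is constant")
    corr = df["rsa"].corr(df["disorder"])
    if abs(corr) > 0.999:
        raise ValueError(
            f"covariates rsa and disorder are collinear (r={corr:.4f})"
        )
    model = ols("y ~ rsa + disorder + rsa:disorder", data=df).fit()
    aov = anova_lm(model, typ=1)
    total_ss = float(aov["sum_sq"].sum())
    out = aov.rename(index={"rsa:disorder": "interaction", "Residual": "residual"})
    out = out.assign(fraction=out["sum_sq"] / total_ss)
    return out[["df", "sum_sq", "fraction", "F", "PR(>F)"]]
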