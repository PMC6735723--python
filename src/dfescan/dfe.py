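"""Distribution-of-fitness-effects inference from site frequency spectra.

Fits DFE models to a :class:`~dfescan.spectra.SpectrumSet` by Poisson
maximum likelihood on the SFS, compares families by AIC, and decomposes
the observed dN/dS ratio (omega) into a non-adaptive expectation
(omega_na, the rate at which deleterious and neutral mutations fix) and
the adaptive remainder (omega_a = omega - omega_na; alpha = omega_a/omega).

Model
-----
Under the Poisson random field approximation, the expected number of
polymorphic sites with ``i`` of ``n`` sampled chromosomes carrying the
derived allele is

    E[s_i] = r_i * theta * Ls / i                        (synonymous)
    E[x_i] = r_i * theta * Ln * Int f(S) G(S, i, n) dS   (nonsynonymous)

where ``theta = 4 Ne u`` per site, ``f`` is the density of the scaled
selection coefficient ``S = 4 Ne s`` of new nonsynonymous mutations, and

    G(S, i, n) = Int_0^1 C(n,i) x^i (1-x)^(n-i) h(x; S) dx

with the diffusion sojourn density ``h(x; S) =
(1 - exp(-S(1-x))) / ((1 - exp(-S)) x (1-x))`` (``1/x`` at S=0).
Optional nuisance multipliers ``r_i`` (r_1 = 1) absorb demographic or
ascertainment distortions shared by the two classes, and an optional
ancestral-misidentification probability ``eps`` mixes class ``i`` with
class ``n - i``.

Families: ``Neutral`` (point mass at S=0), ``Gamma`` (deleterious
effects, -S ~ Gamma(shape, mean)), ``GammaExpo`` (a fraction ``p_b`` of
mutations is beneficial with S ~ Exponential(mean_ben)).

The relative fixation probability ``Q(S) = S / (1 - exp(-S))`` converts
the fitted deleterious DFE into the expected non-adaptive dN/dS:
``omega_na = (1 - p_b) * Int f_del(S) Q(S) dS``.  Divergence counts enter
only through the observed omega; the likelihood uses the SFS alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .spectra import SpectrumSet

__all__ = [
    "DFEParams",
    "FitResult",
    "FAMILIES",
    "sojourn_weight",
    "fixation_ratio",
    "sfs_weight",
    "expected_spectrum",
    "poisson_loglik",
    "fit_model",
    "alpha_decompose",
    "compare_models",
    "omega_na_expected",
    "omega_expected",
]

FAMILIES = ("Neutral", "Gamma", "GammaExpo")

# Fixed quadrature configuration: 128-node Gauss-Legendre on allele
# frequency x; 400 log-spaced mass bins per DFE component on |S| in
# [1e-4, 1e5].  Mass below the grid is treated as effectively neutral
# (G = 1/i, Q = 1); deleterious mass above it never segregates or fixes.
N_X_NODES = 128
S_GRID_SIZE = 400
S_MIN = 1e-4
S_MAX = 1e5

_S_EDGES = np.geomspace(S_MIN, S_MAX, S_GRID_SIZE + 1)
_S_NODES = np.sqrt(_S_EDGES[:-1] * _S_EDGES[1:])

_x_leg, _w_leg = np.polynomial.legendre.leggauss(N_X_NODES)
_X_NODES = 0.5 * (_x_leg + 1.0)
_X_WEIGHTS = 0.5 * _w_leg


@dataclass
class DFEParams:
    """Parameters of a fitted (or generating) DFE.

    ``shape``/``mean_del`` parameterize the Gamma distribution of the
    magnitude of deleterious scaled coefficients; ``p_b``/``mean_ben``
    the exponential beneficial tail; ``r`` the per-class nuisance
    multipliers (r_1 fixed to 1); ``eps`` the ancestral
    misidentification probability.
    """

    family: str
    theta: float = np.nan
    shape: Optional[float] = None
    mean_del: Optional[float] = None
    p_b: float = 0.0
    mean_ben: Optional[float] = None
    r: Optional[np.ndarray] = None
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown DFE family {self.family!r}")
        if self.family == "Neutral":
            self.shape = self.mean_del = self.mean_ben = None
            self.p_b = 0.0
        if self.family == "Gamma":
            self.p_b = 0.0
            self.mean_ben = None
        if self.family in ("Gamma", "GammaExpo"):
            if self.shape is not None and self.shape <= 0:
                raise ValueError("Gamma shape must be > 0")
            if self.mean_del is not None and self.mean_del <= 0:
                raise ValueError("mean deleterious effect must be > 0")
        if not 0.0 <= self.p_b <= 1.0:
            raise ValueError("p_b must lie in [0, 1]")
        if not 0.0 <= self.eps <= 0.5:
            raise ValueError("eps must lie in [0, 0.5]")


@dataclass
class FitResult:
    """A DFE fit: parameters, likelihood, AIC, and the omega decomposition."""

    params: DFEParams
    loglik: float
    n_params: int
    aic: float
    omega: float = np.nan
    omega_na: float = np.nan
    omega_a: float = np.nan
    alpha: float = np.nan
    converged: bool = True
    message: str = ""
    name: str = ""


# ---------------------------------------------------------------------------
# Diffusion weights
# ---------------------------------------------------------------------------

def sojourn_weight(x, S: float):
    """Sojourn density ``h(x; S)`` of a mutation with scaled effect S.

    Stable for |S| up to ~1e4; ``h(x; 0) = 1/x`` by the analytic limit.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("frequency x must lie strictly inside (0, 1)")
    S = float(S)
    if S == 0.0:
        out = 1.0 / x
    elif S > 0.0:
        out = (-np.expm1(-S * (1.0 - x))) / (-np.expm1(-S)) / (x * (1.0 - x))
    else:
        T = -S
        out = (
            np.exp(-T * x)
            * (-np.expm1(-T * (1.0 - x)))
            / (-np.expm1(-T))
            / (x * (1.0 - x))
        )
    return out if out.shape else float(out)


def fixation_ratio(S):
    """Relative fixation probability ``Q(S) = S / (1 - e^{-S})``; Q(0)=1."""
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    pos = S > 0
    neg = S < 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = S[pos] / (-np.expm1(-S[pos]))
        # S<0: S/(1-e^{-S}) = -|S| e^{-|S|} / (1 - e^{-|S|})
        T = -S[neg]
        out[neg] = T * np.exp(-T) / (-np.expm1(-T))
    return out if out.shape else float(out)


def _binom_pmf_matrix(i: np.ndarray, n: int, x: np.ndarray) -> np.ndarray:
    """C(n,i) x^i (1-x)^(n-i) as an (len(i), len(x)) matrix, in log space."""
    i = i[:, None]
    logc = (
        special.gammaln(n + 1)
        - special.gammaln(i + 1)
        - special.gammaln(n - i + 1)
    )
    return np.exp(logc + i * np.log(x) + (n - i) * np.log1p(-x))


def sfs_weight(S: float, i, n: int) -> np.ndarray | float:
    """Expected relative contribution ``G(S, i, n)`` of an S-mutation to
    SFS class ``i`` in a sample of ``n`` chromosomes.

    ``G(0, i, n) = 1/i`` exactly (neutral closed form via the Beta
    integral); other values by 128-node Gauss-Legendre quadrature.
    """
    i_arr = np.atleast_1d(np.asarray(i, dtype=int))
    if np.any(i_arr < 1) or np.any(i_arr > n - 1):
        raise ValueError("class index i must satisfy 1 <= i <= n-1")
    if float(S) == 0.0:
        out = 1.0 / i_arr.astype(float)
    else:
        h = sojourn_weight(_X_NODES, S)
        B = _binom_pmf_matrix(i_arr, n, _X_NODES)
        out = B @ (h * _X_WEIGHTS)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite sfs_weight for S={S}, n={n}")
    return out if np.ndim(i) else float(out[0])


_G_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _g_matrices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed G(S, i, n) on the signed S grid: (del, ben, ben-boundary)."""
    if n not in _G_CACHE:
        i = np.arange(1, n)
        B = _binom_pmf_matrix(i, n, _X_NODES)  # (n-1, K)
        hw_del = np.empty((S_GRID_SIZE, N_X_NODES))
        hw_ben = np.empty((S_GRID_SIZE, N_X_NODES))
        for j, s in enumerate(_S_NODES):
            hw_del[j] = sojourn_weight(_X_NODES, -s) * _X_WEIGHTS
            hw_ben[j] = sojourn_weight(_X_NODES, s) * _X_WEIGHTS
        g_del = hw_del @ B.T  # (S_GRID_SIZE, n-1)
        g_ben = hw_ben @ B.T
        g_ben_top = B @ (sojourn_weight(_X_NODES, S_MAX) * _X_WEIGHTS)
        _G_CACHE[n] = (g_del, g_ben, g_ben_top)
    return _G_CACHE[n]


def _gamma_masses(shape: float, mean: float):
    """Bin masses of Gamma(shape, mean) on the |S| grid via CDF differences."""
    scale = mean / shape
    cdf = special.gammainc(shape, _S_EDGES / scale)
    return cdf[0], np.diff(cdf), 1.0 - cdf[-1]

def _expon_masses(mean: float):
    cdf = -np.expm1(-_S_EDGES / mean)
    return cdf[0], np.diff(cdf), 1.0 - cdf[-1]


def _nonsyn_integral(params: DFEParams, n: int) -> np.ndarray:
    """``Int f(S) G(S, i, n) dS`` for i = 1..n-1 under ``params``."""
    inv_i = 1.0 / np.arange(1, n)
    if params.family == "Neutral":
        return inv_i
    g_del, g_ben, g_ben_top = _g_matrices(n)
    m0, m, _ = _gamma_masses(params.shape, params.mean_del)
    I = m0 * inv_i + m @ g_del  # mass above S_MAX contributes 0
    if params.family == "GammaExpo" and params.p_b > 0.0:
        b0, bm, btail = _expon_masses(params.mean_ben)
        I_ben = b0 * inv_i + bm @ g_ben + btail * g_ben_top
        I = (1.0 - params.p_b) * I + params.p_b * I_ben
    return I


# Fixations with scaled effect below this threshold are counted as
# non-adaptive even when they come from the beneficial mixture component.
# Without it, omega_a is unidentifiable along the mean_ben -> 0 likelihood
# ridge, where a large p_b of effectively neutral "beneficial" mutations
# (indistinguishable from neutral mass in the SFS, but with Q ~ 1) can
# masquerade as adaptive fixations.
S_ADAPTIVE_MIN = 1.0


def omega_na_expected(params: DFEParams,
                      s_adaptive_min: float = S_ADAPTIVE_MIN) -> float:
    """Expected non-adaptive dN/dS under the fitted DFE.

    ``(1 - p_b) * Int f_del(S) Q(S) dS`` plus the fixation rate of
    beneficial mutations with ``S < s_adaptive_min``, which are
    effectively neutral and counted as non-adaptive.  The Neutral family
    fixes every mutation at the neutral rate, giving 1.
    """
    if params.family == "Neutral":
        return 1.0
    m0, m, _ = _gamma_masses(params.shape, params.mean_del)
    q = fixation_ratio(-_S_NODES)
    w = float((1.0 - params.p_b) * (m0 + m @ q))
    if params.family == "GammaExpo" and params.p_b > 0.0 and s_adaptive_min > 0:
        b0, bm, _ = _expon_masses(params.mean_ben)
        weak = _S_NODES < s_adaptive_min
        w += params.p_b * float(
            b0 + bm[weak] @ fixation_ratio(_S_NODES[weak])
        )
    return w


def omega_expected(params: DFEParams) -> float:
    """Expected total dN/dS under the full DFE: ``Int f(S) Q(S) dS``.

    Used by the synthetic-data generator, where it defines the true
    omega; ``omega_a_true = omega_expected - omega_na_expected``.
    """
    w = omega_na_expected(params)
    if params.family == "GammaExpo" and params.p_b > 0.0:
        b0, bm, btail = _expon_masses(params.mean_ben)
        q = fixation_ratio(_S_NODES)
        w += params.p_b * float(b0 + bm @ q + btail * fixation_ratio(S_MAX))
    return w


# ---------------------------------------------------------------------------
# Expected spectra and likelihood
# ---------------------------------------------------------------------------

def _fold_vector(v: np.ndarray, n: int) -> np.ndarray:
    f = np.zeros_like(v)
    for i in range(1, n):
        j = min(i, n - i)
        f[j - 1] += v[i - 1]
    return f


def _class_mask(n: int, folded: bool) -> np.ndarray:
    i = np.arange(1, n)
    return i <= n // 2 if folded else np.ones(n - 1, dtype=bool)


def _expected_per_theta(
    params: DFEParams, n: int, Ls: float, Ln: float, folded: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Expected SFS divided by theta (and by r, which multiplies later)."""
    inv_i = 1.0 / np.arange(1, n)
    e_syn = Ls * inv_i
    e_nonsyn = Ln * _nonsyn_integral(params, n)
    if params.eps > 0.0:
        e_syn = (1.0 - params.eps) * e_syn + params.eps * e_syn[::-1]
        e_nonsyn = (1.0 - params.eps) * e_nonsyn + params.eps * e_nonsyn[::-1]
    if folded:
        e_syn = _fold_vector(e_syn, n)
        e_nonsyn = _fold_vector(e_nonsyn, n)
    return e_syn, e_nonsyn


def expected_spectrum(
    params: DFEParams, n: int, Ls: float, Ln: float, folded: bool = False
) -> SpectrumSet:
    """Expected SFS under ``params`` (divergence fields left at zero)."""
    e_syn, e_nonsyn = _expected_per_theta(params, n, Ls, Ln, folded)
    r = np.ones(n - 1) if params.r is None else np.asarray(params.r, dtype=float)
    if r.shape != (n - 1,):
        raise ValueError(f"r must have length n-1={n - 1}")
    return SpectrumSet(
        n=n, Ls=Ls, Ln=Ln,
        sfs_syn=params.theta * r * e_syn,
        sfs_nonsyn=params.theta * r * e_nonsyn,
        folded=folded, name=f"expected_{params.family}",
    )


def poisson_loglik(params: DFEParams, observed: SpectrumSet) -> float:
    """Full Poisson log likelihood of the observed SFS under ``params``.

    Divergence counts are excluded.  A class with zero expectation but
    positive observation yields ``-inf`` (reported, not raised).
    """
    exp = expected_spectrum(params, observed.n, observed.Ls, observed.Ln,
                            observed.folded)
    mask = _class_mask(observed.n, observed.folded)
    total = 0.0
    for o, e in (
        (observed.sfs_syn[mask], exp.sfs_syn[mask]),
        (observed.sfs_nonsyn[mask], exp.sfs_nonsyn[mask]),
    ):
        bad = (e <= 0.0) & (o > 0.0)
        if np.any(bad):
            return -np.inf
        ok = e > 0.0
        total += float(
            np.sum(o[ok] * np.log(e[ok]) - e[ok] - special.gammaln(o[ok] + 1.0))
        )
    return total


# ---------------------------------------------------------------------------
# Maximum likelihood fitting
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "shape": (0.01, 10.0),
    "mean_del": (1e-2, 1e6),
    "p_b": (0.0, 0.5),
    "mean_ben": (1e-2, 1e3),
    "eps": (0.0, 0.5),
}

_N_FREE = {"Neutral": 1, "Gamma": 3, "GammaExpo": 5}


class _Objective:
    """Profiled negative log likelihood over the free DFE parameters.

    theta (and the nuisance r_i when enabled) enter the Poisson mean
    linearly, so their MLEs are available in closed form given the shape
    of the expected spectrum; only the DFE shape parameters are left to
    the numerical optimizer.
    """

    def __init__(self, observed: SpectrumSet, family: str,
                 use_r: bool, use_eps: bool):
        self.obs = observed
        self.family = family
        self.use_r = use_r
        self.use_eps = use_eps
        self.n = observed.n
        self.mask = _class_mask(self.n, observed.folded)
        self.o_syn = observed.sfs_syn[self.mask]
        self.o_nonsyn = observed.sfs_nonsyn[self.mask]
        self.inv_i = 1.0 / np.arange(1, self.n)

    def params_from_vector(self, u: np.ndarray) -> DFEParams:
        eps = float(u[-1]) if self.use_eps else 0.0
        if self.family == "Neutral":
            return DFEParams("Neutral", eps=eps)
        if self.family == "Gamma":
            return DFEParams("Gamma", shape=np.exp(u[0]), mean_del=np.exp(u[1]),
                             eps=eps)
        return DFEParams(
            "GammaExpo", shape=np.exp(u[0]), mean_del=np.exp(u[1]),
            p_b=float(u[2]), mean_ben=np.exp(u[3]), eps=eps,
        )

    def profile(self, params: DFEParams):
        """MLE of theta (and r) given the remaining parameters.

        Returns ``(theta, r, kernel)`` where kernel is the log likelihood
        without the factorial terms.
        """
        e_syn, e_nonsyn = _expected_per_theta(
            params, self.n, self.obs.Ls, self.obs.Ln, self.obs.folded
        )
        ms = e_syn[self.mask]
        mn = e_nonsyn[self.mask]
        o = self.o_syn + self.o_nonsyn
        m = ms + mn
        if np.any((m <= 0.0) & (o > 0.0)):
            return np.nan, None, -np.inf
        if self.use_r:
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.where(m > 0.0, o / m, 0.0)
            theta = c[0]
            if theta <= 0.0:
                return np.nan, None, -np.inf
            r_masked = c / theta
        else:
            theta = o.sum() / m.sum()
            c = np.full_like(m, theta)
            r_masked = None
        lam_s = c * ms
        lam_n = c * mn
        kernel = 0.0
        for ob, lam in ((self.o_syn, lam_s), (self.o_nonsyn, lam_n)):
            if np.any((lam <= 0.0) & (ob > 0.0)):
                return np.nan, None, -np.inf
            pos = lam > 0.0
            kernel += float(np.sum(ob[pos] * np.log(lam[pos]) - lam[pos]))
        r = None
        if self.use_r:
            r = np.ones(self.n - 1)
            r[self.mask] = r_masked
        return float(theta), r, kernel

    def __call__(self, u: np.ndarray) -> float:
        try:
            params = self.params_from_vector(u)
        except ValueError:
            return np.inf
        _, _, kernel = self.profile(params)
        return np.inf if not np.isfinite(kernel) else -kernel


def _start_vectors(family: str, n_starts: int, seed: int,
                   start: Optional[DFEParams], use_eps: bool,
                   bounds: list[tuple[float, float]]) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    defaults = {"shape": 0.3, "mean_del": 1e3, "p_b": 0.02, "mean_ben": 10.0}
    if start is not None:
        defaults = {
            "shape": start.shape or defaults["shape"],
            "mean_del": start.mean_del or defaults["mean_del"],
            "p_b": start.p_b if start.p_b > 0 else defaults["p_b"],
            "mean_ben": start.mean_ben or defaults["mean_ben"],
        }
    if family == "Gamma":
        base = [np.log(defaults["shape"]), np.log(defaults["mean_del"])]
    else:
        base = [np.log(defaults["shape"]), np.log(defaults["mean_del"]),
                defaults["p_b"], np.log(defaults["mean_ben"])]
    if use_eps:
        base = base + [0.01]
    starts = [np.array(base)]
    for _ in range(n_starts - 1):
        u = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        starts.append(u)
    return starts


def fit_model(
    observed: SpectrumSet,
    family: str = "GammaExpo",
    n_starts: int = 5,
    seed: int = 0,
    use_r: bool = False,
    use_eps: bool = False,
    start: Optional[DFEParams] = None,
    bounds: Optional[dict] = None,
    maxiter: int = 200,
    ftol: float = 1e-9,
) -> FitResult:
    """Fit a DFE family to an observed spectrum by Poisson ML.

    Multi-start bounded optimization in log-parameter space (``p_b`` and
    ``eps`` on their natural scale), deterministic given ``seed``.  theta
    and the nuisance ``r_i`` (if enabled) are profiled analytically.
    The returned :class:`FitResult` carries omega, omega_na, omega_a and
    alpha when the observed spectrum has divergence data (``Ds > 0``).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if observed.sfs_syn.sum() <= 0 or observed.sfs_nonsyn.sum() <= 0:
        raise ValueError(
            "observed spectrum needs at least one polymorphic site in each "
            "of the synonymous and nonsynonymous classes"
        )
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    obj = _Objective(observed, family, use_r, use_eps)

    if family == "Neutral" and not use_eps:
        params = DFEParams("Neutral")
        theta, r, _ = obj.profile(params)
        params = replace(params, theta=theta, r=r)
        best_msg, converged = "closed form", True
    else:
        if family == "Neutral":
            opt_bounds = [b["eps"]]
        elif family == "Gamma":
            opt_bounds = [tuple(np.log(b["shape"])), tuple(np.log(b["mean_del"]))]
        else:
            opt_bounds = [
                tuple(np.log(b["shape"])), tuple(np.log(b["mean_del"])),
                b["p_b"], tuple(np.log(b["mean_ben"])),
            ]
        if use_eps and family != "Neutral":
            opt_bounds.append(b["eps"])
        starts = _start_vectors(family, n_starts, seed, start, use_eps, opt_bounds)
        best = None
        for u0 in starts:
            res = optimize.minimize(
                obj, u0, method="L-BFGS-B", bounds=opt_bounds,
                options={"maxiter": maxiter, "ftol": ftol},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"all {n_starts} starts failed to converge for family "
                f"{family}; best objective: "
                f"{best.fun if best is not None else 'none'}"
            )
        params = obj.params_from_vector(best.x)
        theta, r, _ = obj.profile(params)
        params = replace(params, theta=theta, r=r)
        best_msg, converged = str(best.message), bool(best.success)

    loglik = poisson_loglik(params, observed)
    k = _N_FREE[family]
    if use_r:
        k += int(obj.mask.sum()) - 1  # r_1 fixed to 1
    if use_eps:
        k += 1
    fit = FitResult(
        params=params, loglik=loglik, n_params=k, aic=2 * k - 2 * loglik,
        converged=converged, message=best_msg, name=observed.name,
    )
    if observed.Ds > 0:
        fit.omega, fit.omega_na, fit.omega_a, fit.alpha = alpha_decompose(
            params, observed
        )
    return fit


def alpha_decompose(
    params: DFEParams, observed: SpectrumSet
) -> tuple[float, float, float, float]:
    """Split observed omega into non-adaptive and adaptive components.

    ``omega = (Dn/Ln) / (Ds/Ls)``; ``omega_na`` is the expectation under
    the fitted deleterious DFE; ``omega_a = omega - omega_na`` and
    ``alpha = omega_a / omega``.
    """
    if observed.Ds <= 0:
        raise ValueError("omega undefined: no synonymous substitutions (Ds=0)")
    if observed.Ln <= 0 or observed.Ls <= 0:
        raise ValueError("omega undefined: zero site opportunities")
    omega = (observed.Dn / observed.Ln) / (observed.Ds / observed.Ls)
    w_na = omega_na_expected(params)
    return omega, w_na, omega - w_na, (omega - w_na) / omega


def compare_models(
    observed: SpectrumSet,
    families: Sequence[str] = FAMILIES,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit several families and rank them by AIC (ties: fewer parameters)."""
    if len(families) < 2:
        raise ValueError("model comparison needs at least two families")
    fits = [fit_model(observed, family=f, **fit_kwargs) for f in families]
    fits.sort(key=lambda f: (f.aic, f.n_params))
    return fits
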