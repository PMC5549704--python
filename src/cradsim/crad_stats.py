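"""CRAD curves and heavy-tailed distribution fitting.

The cumulative relative abundance distribution (CRAD) of a community maps
each relative abundance x to the fraction of species whose abundance is at
least x (the survival function across species); on log-log axes a power-law
community appears as a straight line of slope −β.  This module computes
CRAD curves, rarefies count vectors, estimates β by maximum likelihood on
the 0.8-40 % abundance window, runs a semi-parametric Kolmogorov-Smirnov
bootstrap goodness-of-fit test, and fits log-normal / stretched-exponential
alternatives on the same window so the families are directly comparable.

Two power-law likelihood conventions are provided:

* ``method="truncated"`` — the exact MLE of the doubly truncated Pareto
  with density f(x) = β x^(−β−1) / (L^(−β) − U^(−β)) on [L, U], solved by
  root-finding on the score function.
* ``method="untruncated"`` — the closed form β̂ = n / Σ ln(xᵢ/L), i.e. the
  continuous power-law MLE that ignores the upper bound (the window's
  upper end only selects which points enter).  This is the convention the
  simulation ensembles use (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitWindow",
    "FitOptions",
    "CRADCurve",
    "PowerLawFit",
    "AltFit",
    "MedianCRAD",
    "compute_crad",
    "rarefy",
    "fit_powerlaw_mle",
    "gof_pvalue",
    "fit_alternative",
    "compare_families",
    "median_crad",
    "sample_truncated_powerlaw",
]

PowerLawMethod = Literal["truncated", "untruncated"]
AltFamily = Literal["lognormal", "stretched_exponential", "exponential"]

#: Exclusion threshold of the goodness-of-fit test: a fitted distribution
#: is considered plausible when the bootstrap KS p-value is >= 0.1.
GOF_THRESHOLD = 0.1


@dataclass(frozen=True)
class FitWindow:
    """Relative-abundance window for exponent estimation (0.8 % to 40 %).

    ``upper`` may exceed 1 to approximate an unbounded tail (the truncated
    likelihood then converges to the untruncated one); abundances
    themselves never exceed 1, so such a window simply stops truncating.
    """

    lower: float = 0.008
    upper: float = 0.40

    def __post_init__(self):
        if not (0.0 < self.lower < self.upper) or not np.isfinite(self.upper):
            raise ValueError(
                f"invalid fit window [{self.lower}, {self.upper}]: "
                "need 0 < lower < upper < inf"
            )

    def restrict(self, x: np.ndarray) -> np.ndarray:
        """The window-interior points (endpoints inclusive)."""
        x = np.asarray(x, dtype=float)
        return x[(x >= self.lower) & (x <= self.upper)]


@dataclass
class FitOptions:
    """How ensemble replicates fit β (see :func:`simulate_ensemble`)."""

    window: FitWindow = field(default_factory=FitWindow)
    method: PowerLawMethod = "untruncated"
    gof: bool = True
    n_boot: int = 200
    fit_beta: bool = True


@dataclass
class CRADCurve:
    """A CRAD: per-species relative abundances (ascending) and, for each,
    the fraction of species with abundance at least that large.

    Equivalent to the rank-abundance curve: a species' descending rank is
    ``n_species * survival`` at its abundance (ties share the larger rank).
    """

    abundances: np.ndarray
    survival: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.abundances)

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if len(self.abundances) != len(self.survival):
            raise ValueError("abundances and survival must have equal length")


def _as_count_vector(sample) -> np.ndarray:
    """Accept a ReadSample, a mapping id->count, or a plain count vector."""
    if hasattr(sample, "counts"):
        counts = np.asarray(sample.counts)
    elif isinstance(sample, dict):
        counts = np.asarray(list(sample.values()))
    else:
        counts = np.asarray(sample)
    return counts


def compute_crad(sample) -> CRADCurve:
    """Compute the CRAD of one sample.

    Relative abundance per species is count / total; survival(x) is the
    fraction of species with abundance >= x.
    """
    counts = _as_count_vector(sample)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    counts = counts[counts > 0]
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute a CRAD from all-zero counts")
    x = np.sort(counts / total)
    n = len(x)
    # fraction of species with abundance >= x_i; ties get the same value
    # (the count of >= is taken against the whole sorted vector)
    geq = n - np.searchsorted(x, x, side="left")
    return CRADCurve(abundances=x, survival=geq / n)


def rarefy(
    counts: Sequence[int] | np.ndarray,
    depth: int = 2500,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Rarefaction makes richness comparable across samples of unequal
    sequencing depth; the draw is multivariate hypergeometric.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total < depth:
        name = f" {sample_id!r}" if sample_id else ""
        raise ValueError(
            f"sample{name} has {total} reads, fewer than rarefaction depth {depth}"
        )
    if total == depth:
        return counts.copy()
    if rng is None:
        rng = np.random.default_rng()
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


# ---------------------------------------------------------------------------
# truncated power law

def _trunc_pl_loglik(x: np.ndarray, beta: float, window: FitWindow) -> float:
    """Log-likelihood of the power law truncated to the window,
    f(x) = β x^(−β−1) / (L^(−β) − U^(−β))."""
    L, U = window.lower, window.upper
    n = len(x)
    norm = L ** (-beta) - U ** (-beta)
    return float(n * np.log(beta) - (beta + 1) * np.log(x).sum() - n * np.log(norm))


def _trunc_pl_score(x: np.ndarray, beta: float, window: FitWindow) -> float:
    L, U = window.lower, window.upper
    n = len(x)
    La, Ua = L ** (-beta), U ** (-beta)
    return float(
        n / beta
        - np.log(x).sum()
        + n * (La * np.log(L) - Ua * np.log(U)) / (La - Ua)
    )


_BETA_BRACKET = (1e-3, 50.0)


def _trunc_pl_mle(x: np.ndarray, window: FitWindow) -> float:
    lo, hi = _BETA_BRACKET
    s_lo = _trunc_pl_score(x, lo, window)
    s_hi = _trunc_pl_score(x, hi, window)
    if s_lo < 0:  # likelihood decreasing everywhere: boundary solution
        return lo
    if s_hi > 0:
        return hi
    return float(optimize.brentq(lambda b: _trunc_pl_score(x, b, window), lo, hi))


def _trunc_pl_cdf(x: np.ndarray, beta: float, window: FitWindow) -> np.ndarray:
    L, U = window.lower, window.upper
    La, Ua = L ** (-beta), U ** (-beta)
    return (La - np.asarray(x, dtype=float) ** (-beta)) / (La - Ua)


def sample_truncated_powerlaw(
    n: int,
    beta: float,
    rng: np.random.Generator,
    window: FitWindow = FitWindow(),
) -> np.ndarray:
    """Draw ``n`` i.i.d. values from the window-truncated power law by
    inverting the CDF."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    L, U = window.lower, window.upper
    La, Ua = L ** (-beta), U ** (-beta)
    u = rng.random(n)
    return (La - u * (La - Ua)) ** (-1.0 / beta)


@dataclass
class PowerLawFit:
    """Result of a power-law CRAD fit within the abundance window."""

    beta: float
    window: FitWindow
    n_in_window: int
    loglik: float
    ks_stat: float
    method: PowerLawMethod = "truncated"
    gof_p: float | None = None
    excluded: bool = False
    exclusion_reason: Literal["too_few_points", "gof_reject"] | None = None


def _ks_statistic(x_sorted: np.ndarray, cdf: np.ndarray) -> float:
    n = len(x_sorted)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(max(np.max(hi - cdf), np.max(cdf - lo)))


def fit_powerlaw_mle(
    abundances: Sequence[float] | np.ndarray,
    window: FitWindow = FitWindow(),
    method: PowerLawMethod = "truncated",
) -> PowerLawFit:
    """Fit the CRAD exponent β on the abundance window by maximum likelihood.

    Samples with fewer than two window points are flagged excluded
    (``too_few_points``); the goodness-of-fit exclusion is applied by
    :func:`gof_pvalue` once its p-value is computed.  The reported
    ``loglik`` is always evaluated under the window-truncated density so
    power-law fits are comparable with the alternative families.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("abundances must lie in (0, 1]")
    xw = np.sort(window.restrict(x))
    n = len(xw)
    if n < 2:
        return PowerLawFit(
            beta=float("nan"),
            window=window,
            n_in_window=n,
            loglik=float("nan"),
            ks_stat=float("nan"),
            method=method,
            excluded=True,
            exclusion_reason="too_few_points",
        )
    if method == "truncated":
        beta = _trunc_pl_mle(xw, window)
    elif method == "untruncated":
        beta = float(n / np.log(xw / window.lower).sum())
    else:
        raise ValueError(f"unknown power-law method {method!r}")
    return PowerLawFit(
        beta=beta,
        window=window,
        n_in_window=n,
        loglik=_trunc_pl_loglik(xw, beta, window),
        ks_stat=_ks_statistic(xw, _trunc_pl_cdf(xw, beta, window)),
        method=method,
    )


# ---------------------------------------------------------------------------
# alternative families (window-truncated)

@dataclass
class AltFit:
    """An alternative heavy-tailed family fitted on the same window."""

    family: AltFamily
    params: tuple[float, ...]
    window: FitWindow
    n_in_window: int
    loglik: float
    ks_stat: float = float("nan")
    gof_p: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    converged: bool = True


def _lognormal_nll(theta, lx, a, b):
    mu, log_sigma = theta
    sigma = np.exp(log_sigma)
    z = (lx - mu) / sigma
    denom = stats.norm.cdf((b - mu) / sigma) - stats.norm.cdf((a - mu) / sigma)
    if denom <= 0 or not np.isfinite(denom):
        return 1e12
    ll = (stats.norm.logpdf(z) - np.log(sigma) - lx - np.log(denom)).sum()
    return -ll


def _lognormal_cdf(x, params, window):
    mu, sigma = params
    a, b = np.log(window.lower), np.log(window.upper)
    lo = stats.norm.cdf((a - mu) / sigma)
    hi = stats.norm.cdf((b - mu) / sigma)
    return (stats.norm.cdf((np.log(x) - mu) / sigma) - lo) / (hi - lo)


def _lognormal_sample(n, params, window, rng):
    mu, sigma = params
    a, b = np.log(window.lower), np.log(window.upper)
    z = stats.truncnorm.rvs(
        (a - mu) / sigma, (b - mu) / sigma, loc=mu, scale=sigma,
        size=n, random_state=rng,
    )
    return np.exp(z)


def _stretched_surv(x, lam, c):
    return np.exp(-((x / lam) ** c))


def _stretched_nll(theta, x, a, b, fix_c=None):
    if fix_c is None:
        lam, c = np.exp(theta)
    else:
        lam, c = np.exp(theta[0]), fix_c
    sa, sb = _stretched_surv(a, lam, c), _stretched_surv(b, lam, c)
    denom = sa - sb
    if denom <= 0 or not np.isfinite(denom):
        return 1e12
    u = (x / lam) ** c
    ll = (np.log(c / lam) + (c - 1) * np.log(x / lam) - u - np.log(denom)).sum()
    return -ll


def _stretched_cdf(x, params, window):
    lam, c = params
    sa = _stretched_surv(window.lower, lam, c)
    sb = _stretched_surv(window.upper, lam, c)
    return (sa - _stretched_surv(np.asarray(x, dtype=float), lam, c)) / (sa - sb)


def _stretched_sample(n, params, window, rng):
    lam, c = params
    sa = _stretched_surv(window.lower, lam, c)
    sb = _stretched_surv(window.upper, lam, c)
    s = sa - rng.random(n) * (sa - sb)
    return lam * (-np.log(s)) ** (1.0 / c)


def fit_alternative(
    abundances: Sequence[float] | np.ndarray,
    family: AltFamily,
    window: FitWindow = FitWindow(),
) -> AltFit:
    """Fit a window-truncated alternative family by maximum likelihood.

    Families: ``lognormal`` (params: log-mean μ, log-sd σ),
    ``stretched_exponential`` (survival ∝ exp(−(x/λ)^c), params λ, c),
    and ``exponential`` (the stretched family with c fixed at 1, the
    natural one-parameter contrast to the one-parameter power law).
    Log-likelihoods are evaluated on the same window points as the
    power-law fit, so the families are directly comparable.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("abundances must lie in (0, 1]")
    xw = np.sort(window.restrict(x))
    n = len(xw)
    if n < 2:
        return AltFit(
            family=family, params=(), window=window, n_in_window=n,
            loglik=float("nan"), excluded=True, exclusion_reason="too_few_points",
        )
    if family == "lognormal":
        lx = np.log(xw)
        a, b = np.log(window.lower), np.log(window.upper)
        res = optimize.minimize(
            _lognormal_nll, x0=[lx.mean(), np.log(lx.std() + 1e-3)],
            args=(lx, a, b), method="Nelder-Mead",
        )
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        params = (float(mu), sigma)
        cdf = _lognormal_cdf(xw, params, window)
    elif family in ("stretched_exponential", "exponential"):
        fix_c = 1.0 if family == "exponential" else None
        a, b = window.lower, window.upper
        best = None
        for lam0 in (0.01, 0.05, 0.2):
            x0 = [np.log(lam0)] if fix_c else [np.log(lam0), 0.0]
            res = optimize.minimize(
                _stretched_nll, x0=x0, args=(xw, a, b, fix_c), method="Nelder-Mead"
            )
            if best is None or res.fun < best.fun:
                best = res
        res = best
        if fix_c:
            params = (float(np.exp(res.x[0])), 1.0)
        else:
            params = (float(np.exp(res.x[0])), float(np.exp(res.x[1])))
        cdf = _stretched_cdf(xw, params, window)
    else:
        raise ValueError(f"unknown alternative family {family!r}")
    loglik = -float(res.fun)
    converged = bool(res.success) and np.isfinite(loglik) and abs(res.fun) < 1e11
    return AltFit(
        family=family,
        params=params,
        window=window,
        n_in_window=n,
        loglik=loglik,
        ks_stat=_ks_statistic(xw, np.clip(cdf, 0.0, 1.0)),
        converged=converged,
    )


def compare_families(
    abundances: Sequence[float] | np.ndarray,
    families: Sequence[str] = ("powerlaw", "lognormal", "stretched_exponential"),
    window: FitWindow = FitWindow(),
    method: PowerLawMethod = "truncated",
) -> dict[str, "PowerLawFit | AltFit"]:
    """Fit several families on the same window points.

    Each returned fit carries an ``aic`` attribute (2k − 2·loglik); with
    the same data the family with the smallest AIC is preferred.  AIC
    rather than raw log-likelihood is used so the one-parameter power law
    is not penalised for its parsimony against the two-parameter
    alternatives.
    """
    fits: dict[str, PowerLawFit | AltFit] = {}
    for family in families:
        if family == "powerlaw":
            fit = fit_powerlaw_mle(abundances, window=window, method=method)
            k = 1
        else:
            fit = fit_alternative(abundances, family, window=window)
            k = 1 if family == "exponential" else 2
        fit.aic = float("inf") if fit.excluded else 2 * k - 2 * fit.loglik
        fits[family] = fit
    return fits


# ---------------------------------------------------------------------------
# goodness of fit

def _refit(fit, x):
    if isinstance(fit, PowerLawFit):
        return fit_powerlaw_mle(x, window=fit.window, method=fit.method)
    return fit_alternative(x, fit.family, window=fit.window)


def _fitted_sampler(fit):
    if isinstance(fit, PowerLawFit):
        return lambda n, rng: sample_truncated_powerlaw(
            n, fit.beta, rng, window=fit.window
        )
    if fit.family == "lognormal":
        return lambda n, rng: _lognormal_sample(n, fit.params, fit.window, rng)
    return lambda n, rng: _stretched_sample(n, fit.params, fit.window, rng)


def gof_pvalue(
    fit: PowerLawFit | AltFit,
    abundances: Sequence[float] | np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Semi-parametric bootstrap goodness-of-fit p-value.

    The KS distance between the empirical and fitted CDFs within the
    window is compared against ``n_boot`` replicates drawn from the fitted
    (window-truncated) distribution, each refitted before its KS distance
    is measured; p is the fraction of bootstrap distances at least as
    large as the observed one.  A power-law fit with p below 0.1 is marked
    excluded (``gof_reject``), following the convention that a family is
    plausible only when p >= 0.1.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if fit.excluded:
        raise ValueError("cannot test an excluded fit")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(abundances, dtype=float)
    xw = fit.window.restrict(x)
    n = len(xw)
    obs = fit.ks_stat
    sampler = _fitted_sampler(fit)
    n_ge = 0
    for _ in range(n_boot):
        xb = sampler(n, rng)
        refit = _refit(fit, xb)
        if refit.excluded or not np.isfinite(refit.ks_stat):
            n_ge += 1  # conservative: count degenerate replicates as extreme
            continue
        if refit.ks_stat >= obs:
            n_ge += 1
    p = n_ge / n_boot
    fit.gof_p = p
    if isinstance(fit, PowerLawFit) and p < GOF_THRESHOLD:
        fit.excluded = True
        fit.exclusion_reason = "gof_reject"
    return p


# ---------------------------------------------------------------------------
# median CRAD across samples

@dataclass
class MedianCRAD:
    """Median CRAD over samples: log-spaced abundance bins, and per
    non-empty bin the median of all survival values falling in it."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_medians: np.ndarray
    n_samples: int


def median_crad(
    curves: Iterable[CRADCurve], bins_per_decade: int = 10
) -> MedianCRAD:
    """Aggregate CRADs from multiple samples into one median curve.

    The pooled abundance range is split into logarithmic bins
    (``bins_per_decade`` per factor of 10); each non-empty bin is
    represented by the median of the survival values whose abundance
    falls inside it.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("median_crad needs at least one curve")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    x = np.concatenate([c.abundances for c in curves])
    y = np.concatenate([c.survival for c in curves])
    lo, hi = np.log10(x.min()), np.log10(x.max())
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, lo + n_bins / bins_per_decade, n_bins + 1)
    edges[-1] = max(edges[-1], x.max() * (1 + 1e-12))
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers, medians = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            centers.append(float(np.sqrt(edges[b] * edges[b + 1])))
            medians.append(float(np.median(y[m])))
    return MedianCRAD(
        bin_edges=edges,
        bin_centers=np.asarray(centers),
        bin_medians=np.asarray(medians),
        n_samples=len(curves),
    )
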