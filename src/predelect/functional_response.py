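"""Type-II functional-response modelling for non-replacement predation trials.

The random-predator model describes the number of prey eaten ``Ne`` out of
``N0`` offered over an exposure of ``T`` days, when eaten prey are not
replaced, in terms of the attack coefficient ``a`` (per day, per unit prey
density) and the handling time ``h`` (days per prey item):

    Ne = N0 * (1 - exp(a * (Ne * h - T)))

The equation is implicit in ``Ne``; its explicit solution uses the principal
branch of the Lambert W function:

    Ne = N0 - W(a h N0 exp(-a (T - N0 h))) / (a h)

Fitting maximizes a binomial likelihood around this mean, appropriate for
counts of prey eaten out of a known number offered.  ``1/(hT)`` is the
maximum feeding rate over the exposure (prey per day).

This module determines FR type by quasibinomial logistic regression of the
proportion eaten on density, fits the random-predator model by maximum
likelihood, bootstraps confidence bands for the fitted curve, and compares
parameters between predator groups with indicator variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import lambertw

from .trial_io import FRTrial, account_consumption

__all__ = [
    "FRFit",
    "FRTypeResult",
    "FRComparison",
    "BootstrapBand",
    "rogers_expected_consumption",
    "max_feeding_rate",
    "detect_fr_type",
    "fit_rogers",
    "bootstrap_fr",
    "compare_fr",
    "fr_difference",
]

_H_FLOOR = 1e-8  # lower bound on handling time in the optimizer (days/prey)
_AH_SWITCH = 1e-12  # below this a*h the depletion model is the h=0 closed form


# ---------------------------------------------------------------------------
# Model core


def _lambertw_exp(log_z: float) -> float:
    """W(exp(log_z)) on the principal branch, stable for huge arguments."""
    if log_z < 700.0:
        return float(lambertw(np.exp(log_z)).real)
    # solve w + log(w) = log_z by Newton; w0 from the asymptotic expansion
    w = log_z - np.log(log_z)
    for _ in range(50):
        step = (w + np.log(w) - log_z) / (1.0 + 1.0 / w)
        w -= step
        if abs(step) < 1e-12 * w:
            break
    return w


def rogers_expected_consumption(a: float, h: float, t_days: float, n0: float) -> float:
    """Expected number of prey eaten under the random-predator model.

    Handles the limits continuously: zero at ``n0 = 0`` or ``a = 0``, and the
    pure-exponential depletion ``n0 (1 - exp(-a T))`` when ``h = 0``.  The
    returned value always lies in ``[0, n0]``.
    """
    if a < 0 or h < 0 or n0 < 0 or t_days < 0:
        raise ValueError("a, h, t_days and n0 must be non-negative")
    if n0 == 0 or a == 0 or t_days == 0:
        return 0.0
    if a * h < _AH_SWITCH:
        return float(n0 * (1.0 - np.exp(-a * t_days)))
    log_z = np.log(a * h * n0) - a * (t_days - n0 * h)
    ne = n0 - _lambertw_exp(log_z) / (a * h)
    return float(min(max(ne, 0.0), n0))


def _expected_vector(a: float, h: float, t_days: float, n0: np.ndarray) -> np.ndarray:
    """Vectorized random-predator expectation over an array of densities."""
    n0 = np.asarray(n0, dtype=float)
    if a == 0 or t_days == 0:
        return np.zeros_like(n0)
    if a * h < _AH_SWITCH:
        return n0 * (1.0 - np.exp(-a * t_days))
    out = np.zeros_like(n0)
    pos = n0 > 0
    npos = n0[pos]
    log_z = np.log(a * h * npos) - a * (t_days - npos * h)
    w = np.empty_like(log_z)
    small = log_z < 700.0
    w[small] = lambertw(np.exp(log_z[small])).real
    if np.any(~small):
        w[~small] = [_lambertw_exp(lz) for lz in log_z[~small]]
    out[pos] = np.clip(npos - w / (a * h), 0.0, npos)
    return out


def max_feeding_rate(h: float, t_days: float) -> float:
    """Maximum feeding rate ``1 / (h * T)`` (prey per day): the asymptote of
    the type-II curve, where a predator spends all its time handling."""
    if h <= 0 or t_days <= 0:
        raise ValueError("h and t_days must be positive")
    return 1.0 / (h * t_days)


# ---------------------------------------------------------------------------
# FR type determination


@dataclass(frozen=True)
class FRTypeResult:
    """Outcome of the second-order quasibinomial logistic regression.

    ``type_call`` is "II" when the linear density coefficient is
    significantly negative, "III" when the linear coefficient is
    significantly positive with a significantly negative quadratic, and
    "I/indeterminate" otherwise.
    """

    linear_coef: float
    quadratic_coef: float
    se_linear: float
    se_quadratic: float
    dispersion: float
    p_linear: float
    p_quadratic: float
    type_call: str
    alpha: float = 0.05


def detect_fr_type(
    trials: list[FRTrial], alpha: float = 0.05, use_t: bool = False
) -> FRTypeResult:
    """Classify the FR type from proportional consumption against density.

    Fits ``logit(consumed / n0) ~ n0 + n0^2`` with a quasibinomial
    dispersion (Pearson X^2 / df) inflating the standard errors.  ``use_t``
    switches the coefficient tests from normal to Student-t reference.
    """
    n0 = np.array([t.n0 for t in trials], dtype=float)
    if len(np.unique(n0)) < 3:
        raise ValueError("need at least 3 distinct densities to determine FR type")
    consumed = np.array(
        [account_consumption(t).consumed_rounded for t in trials], dtype=float
    )
    endog = np.column_stack([consumed, n0 - consumed])
    exog = np.column_stack([np.ones_like(n0), n0, n0**2])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        df_resid = res.df_resid
        dispersion = float(res.pearson_chi2 / df_resid) if df_resid > 0 else np.nan
        se = np.asarray(res.bse) * np.sqrt(max(dispersion, np.finfo(float).tiny))
        coefs = np.asarray(res.params)
        degenerate = not (np.all(np.isfinite(se)) and np.all(np.isfinite(coefs)))
    except Exception:
        degenerate = True

    if degenerate:
        return FRTypeResult(
            linear_coef=np.nan,
            quadratic_coef=np.nan,
            se_linear=np.nan,
            se_quadratic=np.nan,
            dispersion=np.nan,
            p_linear=np.nan,
            p_quadratic=np.nan,
            type_call="I/indeterminate",
            alpha=alpha,
        )

    z = coefs / se
    if use_t:
        p = 2 * stats.t.sf(np.abs(z), df_resid)
    else:
        p = 2 * stats.norm.sf(np.abs(z))

    lin, quad = coefs[1], coefs[2]
    p_lin, p_quad = float(p[1]), float(p[2])
    if lin < 0 and p_lin < alpha:
        call = "II"
    elif lin > 0 and quad < 0 and p_lin < alpha and p_quad < alpha:
        call = "III"
    else:
        call = "I/indeterminate"
    return FRTypeResult(
        linear_coef=float(lin),
        quadratic_coef=float(quad),
        se_linear=float(se[1]),
        se_quadratic=float(se[2]),
        dispersion=dispersion,
        p_linear=p_lin,
        p_quadratic=p_quad,
        type_call=call,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


@dataclass(frozen=True)
class FRFit:
    """Fitted random-predator parameters with uncertainty.

    ``vcov`` is the 2x2 covariance of ``(a_hat, h_hat)`` from the inverse
    observed information; ``max_feed_rate`` is ``1 / (h_hat * t_days)``,
    the asymptotic number of prey a predator can process per day.
    """

    a_hat: float
    h_hat: float
    se_a: float
    se_h: float
    vcov: np.ndarray
    loglik: float
    t_days: float
    max_feed_rate: float
    n_trials: int
    h_at_bound: bool = False


def _counts(trials: list[FRTrial]) -> tuple[np.ndarray, np.ndarray]:
    n0 = np.array([t.n0 for t in trials], dtype=float)
    consumed = np.array(
        [account_consumption(t).consumed_rounded for t in trials], dtype=float
    )
    return n0, consumed


def _nll(theta: np.ndarray, n0: np.ndarray, consumed: np.ndarray, t_days: float) -> float:
    a, h = np.exp(theta)
    uniq, inv = np.unique(n0, return_inverse=True)
    p_uniq = np.clip(_expected_vector(a, h, t_days, uniq) / uniq, 1e-12, 1 - 1e-12)
    p = p_uniq[inv]
    # binomial log-likelihood; the combinatorial constant is kept so loglik
    # values are comparable across models
    from scipy.special import gammaln

    logpmf = (
        gammaln(n0 + 1)
        - gammaln(consumed + 1)
        - gammaln(n0 - consumed + 1)
        + consumed * np.log(p)
        + (n0 - consumed) * np.log1p(-p)
    )
    return float(-np.sum(logpmf))


def _hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(x)
    steps = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return hess


def _initial_guesses(
    n0: np.ndarray, consumed: np.ndarray, t_days: float
) -> list[np.ndarray]:
    # slope of consumption at the lowest density gives a first cut at a;
    # the reciprocal of the largest observed consumption rate bounds h
    low = n0 == n0.min()
    p_low = np.clip(consumed[low].mean() / n0[low].mean(), 1e-3, 1 - 1e-3)
    a0 = -np.log(1 - p_low) / t_days
    max_eaten = max(consumed.max(), 1.0)
    h0 = t_days / max_eaten
    starts = []
    for fa in (0.1, 1.0, 10.0):
        for fh in (0.5, 1.0, 2.0):
            starts.append(np.log([max(fa * a0, 1e-6), max(fh * h0, _H_FLOOR)]))
    return starts


def fit_rogers(
    trials: list[FRTrial], t_days: float | None = None, _starts: list | None = None
) -> FRFit:
    """Fit the random-predator model by binomial maximum likelihood.

    Optimization is over ``(log a, log h)`` with multiple starting points;
    standard errors come from the inverse observed information, mapped back
    to the natural scale by the delta method.

    Raises
    ------
    ValueError
        On fewer than two distinct densities, or when no prey were consumed
        in any trial (the attack coefficient has no finite MLE).
    """
    n0, consumed = _counts(trials)
    if len(np.unique(n0)) < 2:
        raise ValueError("need at least 2 distinct densities to fit")
    if consumed.sum() == 0:
        raise ValueError("no prey consumed in any trial: attack coefficient has no finite MLE")
    if t_days is None:
        t_set = {t.t_days for t in trials}
        if len(t_set) != 1:
            raise ValueError("trials mix exposure times; pass t_days explicitly")
        t_days = t_set.pop()

    starts = _starts if _starts is not None else _initial_guesses(n0, consumed, t_days)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll,
            x0,
            args=(n0, consumed, t_days),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    a_hat, h_hat = np.exp(theta)
    h_at_bound = h_hat <= _H_FLOOR * 10
    if h_at_bound:
        h_hat = max(h_hat, _H_FLOOR)

    hess = _hessian(lambda th: _nll(th, n0, consumed, t_days), theta)
    try:
        cov_theta = np.linalg.inv(hess)
        jac = np.diag([a_hat, h_hat])  # d(a,h)/d(log a, log h)
        vcov = jac @ cov_theta @ jac
        if not np.all(np.isfinite(vcov)) or vcov[0, 0] < 0 or vcov[1, 1] < 0:
            raise np.linalg.LinAlgError
        se_a, se_h = np.sqrt(np.diag(vcov))
    except np.linalg.LinAlgError:
        vcov = np.full((2, 2), np.nan)
        se_a = se_h = np.nan
    return FRFit(
        a_hat=float(a_hat),
        h_hat=float(h_hat),
        se_a=float(se_a),
        se_h=float(se_h),
        vcov=vcov,
        loglik=-float(best.fun),
        t_days=float(t_days),
        max_feed_rate=float(1.0 / (h_hat * t_days)),
        n_trials=len(trials),
        h_at_bound=h_at_bound,
    )


# ---------------------------------------------------------------------------
# Bootstrap confidence bands


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise percentile envelope of the fitted FR curve."""

    grid: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    draws_a: np.ndarray
    draws_h: np.ndarray
    n_failed: int
    warning: str | None = None


def bootstrap_fr(
    trials: list[FRTrial],
    t_days: float | None = None,
    n_boot: int = 1999,
    seed: int = 0,
    grid: np.ndarray | None = None,
    level: float = 0.95,
) -> BootstrapBand:
    """Nonparametric bootstrap band for the fitted FR curve.

    Trials are resampled with replacement within each density stratum,
    preserving the experimental design, and the model is refit to each
    resample (seeded from the full-data fit).  The band is the pointwise
    percentile envelope of the refitted curves on ``grid``.  Refits that
    fail are dropped and counted; more than 10 % failures attaches a
    warning.
    """
    fit = fit_rogers(trials, t_days)
    t_days = fit.t_days
    n0_all = np.array([t.n0 for t in trials])
    if grid is None:
        grid = np.linspace(max(n0_all.min(), 1), n0_all.max(), 50)
    grid = np.asarray(grid, dtype=float)
    point = _expected_vector(fit.a_hat, fit.h_hat, t_days, grid)

    rng = np.random.default_rng(seed)
    strata = {d: [t for t in trials if t.n0 == d] for d in np.unique(n0_all)}
    warm = [np.log([fit.a_hat, max(fit.h_hat, _H_FLOOR)])]

    curves, a_draws, h_draws = [], [], []
    n_failed = 0
    for _ in range(n_boot):
        sample: list[FRTrial] = []
        for d, members in strata.items():
            idx = rng.integers(0, len(members), size=len(members))
            sample.extend(members[i] for i in idx)
        try:
            bfit = fit_rogers(sample, t_days, _starts=warm)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        if not np.isfinite(bfit.a_hat) or not np.isfinite(bfit.h_hat):
            n_failed += 1
            continue
        a_draws.append(bfit.a_hat)
        h_draws.append(bfit.h_hat)
        curves.append(_expected_vector(bfit.a_hat, bfit.h_hat, t_days, grid))

    if curves:
        arr = np.array(curves)
        tail = (1 - level) / 2
        lower = np.quantile(arr, tail, axis=0)
        upper = np.quantile(arr, 1 - tail, axis=0)
    else:
        lower = point.copy()
        upper = point.copy()

    warning = None
    if n_boot > 0 and n_failed > 0.1 * n_boot:
        warning = f"{n_failed}/{n_boot} bootstrap refits failed"
    return BootstrapBand(
        grid=grid,
        point=point,
        lower=lower,
        upper=upper,
        draws_a=np.array(a_draws),
        draws_h=np.array(h_draws),
        n_failed=n_failed,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Indicator-variable comparison between groups


@dataclass(frozen=True)
class FRComparison:
    """Wald comparison of FR parameters between two predator groups.

    ``Da`` and ``Dh`` are the comparison-group minus base-group differences
    in attack coefficient and handling time under a full-interaction
    indicator-variable parameterization, so they equal the differences of
    the separate fits exactly.
    """

    base_group: str
    comparison_group: str
    Da: float
    Dh: float
    se_Da: float
    se_Dh: float
    z_a: float
    z_h: float
    p_a: float
    p_h: float
    fit_base: FRFit = field(repr=False, default=None)
    fit_comp: FRFit = field(repr=False, default=None)


def compare_fr(
    trials_base: list[FRTrial],
    trials_comp: list[FRTrial],
    t_days: float | None = None,
    base_label: str = "base",
    comp_label: str = "comparison",
) -> FRComparison:
    """Compare attack coefficient and handling time between two groups.

    The joint likelihood with indicator variables gives the comparison
    group parameters ``a + Da`` and ``h + Dh``; with a full interaction the
    joint MLE separates, so point estimates are differences of the separate
    fits and the difference variances are the sums of the groups' observed-
    information variances.  Two-sided p-values use the standard normal.
    """
    fit_b = fit_rogers(trials_base, t_days)
    fit_c = fit_rogers(trials_comp, t_days)
    return fr_difference(fit_b, fit_c, base_label=base_label, comp_label=comp_label)


def fr_difference(
    fit_b: FRFit,
    fit_c: FRFit,
    base_label: str = "base",
    comp_label: str = "comparison",
) -> FRComparison:
    """Indicator-variable parameter differences from two fitted groups.

    ``Da = a_comp - a_base`` and ``Dh = h_comp - h_base`` with standard
    errors combined across the independent groups.
    """
    if not np.isfinite(fit_b.se_a) or not np.isfinite(fit_c.se_a):
        raise ValueError("degenerate group fit: no finite standard errors")
    da = fit_c.a_hat - fit_b.a_hat
    dh = fit_c.h_hat - fit_b.h_hat
    se_da = float(np.sqrt(fit_b.se_a**2 + fit_c.se_a**2))
    se_dh = float(np.sqrt(fit_b.se_h**2 + fit_c.se_h**2))
    z_a = da / se_da
    z_h = dh / se_dh
    return FRComparison(
        base_group=base_label,
        comparison_group=comp_label,
        Da=float(da),
        Dh=float(dh),
        se_Da=se_da,
        se_Dh=se_dh,
        z_a=float(z_a),
        z_h=float(z_h),
        p_a=float(2 * stats.norm.sf(abs(z_a))),
        p_h=float(2 * stats.norm.sf(abs(z_h))),
        fit_base=fit_b,
        fit_comp=fit_c,
    )
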