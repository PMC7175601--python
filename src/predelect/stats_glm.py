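"""Binomial/quasibinomial GLM machinery for kill-incidence analyses.

Wraps logit-link GLM fitting (individual-level Bernoulli representation,
treatment coding), Wald contrasts between group coefficients, quasi-
likelihood dispersion with F tests for term deletion, backward model
simplification to a minimum adequate model (MAM), and the exact
small-sample utilities used alongside (Clopper-Pearson intervals, Fisher's
exact test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "IncidenceTable",
    "GLMFit",
    "fit_binomial_glm",
    "wald_contrast",
    "quasi_dispersion",
    "term_deletion_test",
    "simplify_to_mam",
    "clopper_pearson",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class IncidenceTable:
    """Per-group (events, totals) counts, e.g. predators that killed prey."""

    groups: tuple[str, ...]
    events: tuple[int, ...]
    totals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.events) == len(self.totals)):
            raise ValueError("groups, events and totals must have equal length")
        for g, k, n in zip(self.groups, self.events, self.totals):
            if n <= 0:
                raise ValueError(f"{g}: total must be positive")
            if not 0 <= k <= n:
                raise ValueError(f"{g}: events must lie in [0, total]")

    def proportions(self) -> np.ndarray:
        return np.array(self.events) / np.array(self.totals)


@dataclass(frozen=True)
class GLMFit:
    """A fitted logit-link binomial GLM of incidence on group.

    Coefficients use treatment coding with the first group in data order as
    reference.  Deviances are computed against the saturated model on the
    individual-level (Bernoulli) representation, so ``df_null = n - 1`` for
    n exposed individuals.
    """

    groups: tuple[str, ...]
    coefficients: np.ndarray
    se: np.ndarray
    cov: np.ndarray = field(repr=False)
    dispersion: float
    deviance: float
    null_deviance: float
    df_residual: int
    df_null: int
    separation_flags: tuple[bool, ...] = ()

    @property
    def deviance_explained(self) -> float:
        """Deviance difference between null and group models (the group-term
        deviance on ``df_null - df_residual`` degrees of freedom)."""
        return self.null_deviance - self.deviance


def _expand(table: IncidenceTable) -> pd.DataFrame:
    rows = []
    for g, k, n in zip(table.groups, table.events, table.totals):
        rows += [{"group": g, "y": 1}] * k + [{"group": g, "y": 0}] * (n - k)
    df = pd.DataFrame(rows)
    df["group"] = pd.Categorical(df["group"], categories=list(table.groups))
    return df


def fit_binomial_glm(table: IncidenceTable) -> GLMFit:
    """Fit incidence ~ group by logit-link binomial maximum likelihood.

    Groups with events equal to 0 or to the total have an infinite MLE on
    the logit scale; these are flagged in ``separation_flags`` rather than
    raising, since contrasts not involving them remain valid.
    """
    if len(table.groups) < 1:
        raise ValueError("need at least one group")
    df = _expand(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm("y ~ group", data=df, family=sm.families.Binomial()).fit()
        null = smf.glm("y ~ 1", data=df, family=sm.families.Binomial()).fit()
    phi = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    flags = tuple(k == 0 or k == n for k, n in zip(table.events, table.totals))
    return GLMFit(
        groups=table.groups,
        coefficients=np.asarray(res.params),
        se=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()),
        dispersion=phi,
        deviance=float(res.deviance),
        null_deviance=float(null.deviance),
        df_residual=int(res.df_resid),
        df_null=int(null.df_resid),
        separation_flags=flags,
    )


def wald_contrast(fit: GLMFit, group_i: str, group_j: str) -> tuple[float, float]:
    """Wald z and two-sided normal p for the logit difference of two groups.

    The contrast is computed from the coefficient covariance, so it is
    invariant to the coding.  For the saturated one-factor model it equals
    the classic log-odds-ratio statistic with standard error
    ``sqrt(1/k_i + 1/(n_i-k_i) + 1/k_j + 1/(n_j-k_j))``.
    """
    for g in (group_i, group_j):
        if g not in fit.groups:
            raise ValueError(f"group {g!r} not in fit (groups: {fit.groups})")
    c = np.zeros(len(fit.coefficients))
    # treatment coding: coefficient index of non-reference group g is its
    # position in the group ordering (intercept at 0)
    for g, sign in ((group_i, 1.0), (group_j, -1.0)):
        pos = fit.groups.index(g)
        if pos > 0:
            c[pos] += sign
    est = float(c @ fit.coefficients)
    se = float(np.sqrt(c @ fit.cov @ c))
    if se == 0:
        return 0.0, 1.0
    z = est / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def quasi_dispersion(fit: GLMFit) -> float:
    """Quasi-likelihood dispersion: Pearson X^2 over residual df."""
    if fit.df_residual <= 0:
        raise ValueError("no residual degrees of freedom")
    return fit.dispersion


def term_deletion_test(
    deviance_reduced: float,
    deviance_full: float,
    df_delta: int,
    df_residual_full: int,
    dispersion: float = 1.0,
    quasi: bool = False,
) -> tuple[float, float]:
    """Significance of a dropped term: chi-square for binomial, F for quasi.

    Returns ``(statistic, p)`` where the statistic is the deviance change
    (chi-square case) or the dispersion-scaled mean deviance change per df
    (F case, reference F(df_delta, df_residual_full))."""
    delta = deviance_reduced - deviance_full
    if quasi:
        f = (delta / df_delta) / dispersion
        return float(f), float(stats.f.sf(f, df_delta, df_residual_full))
    return float(delta), float(stats.chi2.sf(delta, df_delta))


def _term_factors(term: str) -> frozenset[str]:
    return frozenset(term.replace("*", ":").split(":"))


def _droppable(terms: list[str]) -> list[str]:
    """Terms whose factors are not a proper subset of another term's (marginality)."""
    out = []
    for t in terms:
        ft = _term_factors(t)
        if not any(ft < _term_factors(u) for u in terms if u != t):
            out.append(t)
    return out


def _fit_formula(response: str, terms: list[str], data: pd.DataFrame):
    rhs = " + ".join(terms) if terms else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.glm(f"{response} ~ {rhs}", data=data, family=sm.families.Binomial()).fit()


def simplify_to_mam(
    terms: list[str],
    data: pd.DataFrame,
    response: str = "y",
    alpha: float = 0.05,
    quasi: bool = False,
) -> list[str]:
    """Backward-eliminate terms to a minimum adequate model.

    Repeatedly refits without each droppable term (respecting marginality:
    a main effect is never dropped while its interaction remains) and
    removes the least significant one whose deletion test has ``p >=
    alpha``; chi-square deletion tests for binomial models, F tests scaled
    by the Pearson dispersion of the full model when ``quasi``.
    """
    terms = list(terms)
    while terms:
        full = _fit_formula(response, terms, data)
        phi = float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else 1.0
        candidates = []
        for t in _droppable(terms):
            reduced = _fit_formula(response, [u for u in terms if u != t], data)
            df_delta = int(reduced.df_resid - full.df_resid)
            if df_delta <= 0:
                continue
            _, p = term_deletion_test(
                reduced.deviance,
                full.deviance,
                df_delta,
                int(full.df_resid),
                dispersion=phi,
                quasi=quasi,
            )
            candidates.append((p, t))
        if not candidates:
            break
        p_worst, t_worst = max(candidates)
        if p_worst < alpha:
            break
        terms.remove(t_worst)
    return terms


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table, summing hypergeometric
    probabilities no larger than the observed table's."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
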