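"""Compositional diet-electivity analysis for multi-food feeding trials.

Electivity compares the relative representation of food types in a
consumer's diet with their relative availability.  Raw consumed masses are
first corrected for autogenic change measured in predator-free controls;
each individual's diet is then expressed as percentages of total adjusted
consumption and, after replacing structural zeros with a small constant,
mapped to log-ratios so that standard multivariate statistics apply.
Departure from random feeding is tested with Wilks' lambda against a
sign-flip randomization null, and foods are ranked by pairwise mean
log-ratio differences with randomization-based significance letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trial_io import FOOD_TYPES, ElectivityTrial

__all__ = [
    "AdjustedConsumption",
    "DietComposition",
    "CompositionalTestResult",
    "RankingResult",
    "adjust_autogenic",
    "build_compositions",
    "compositional_manova",
    "rank_electivity",
]

ZERO_REPLACEMENT_PCT = 0.01


@dataclass(frozen=True)
class AdjustedConsumption:
    """Autogenic-corrected consumed mass (mg) per food for one arena."""

    trial_id: str
    group: str
    consumed_mg: dict[str, float]


@dataclass(frozen=True)
class DietComposition:
    """Percentage diet use and availability for one individual.

    ``use_pct`` and ``avail_pct`` each sum to 100; entries flagged in
    ``zero_replaced`` equal the zero-replacement constant (0.01 %).
    """

    individual_id: str
    use_pct: dict[str, float]
    avail_pct: dict[str, float]
    zero_replaced: dict[str, bool]


@dataclass(frozen=True)
class CompositionalTestResult:
    """Wilks' lambda randomization test of use against availability."""

    wilks_lambda: float
    p_value: float
    n_randomizations: int
    seed: int


@dataclass(frozen=True)
class RankingResult:
    """Electivity ranking of food types.

    ``order`` lists foods from the largest to the smallest diet
    contribution relative to availability; ``mean_logratio_diff`` is the
    antisymmetric pairwise matrix of mean log-ratio differences (rows minus
    columns); foods share a significance letter iff their pairwise
    difference is not significant under sign-flip randomization.
    """

    foods: tuple[str, ...]
    order: tuple[str, ...]
    mean_logratio_diff: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    letters: dict[str, str]
    tie_broken: bool = False


# ---------------------------------------------------------------------------
# Autogenic adjustment


def adjust_autogenic(trials: list[ElectivityTrial]) -> list[AdjustedConsumption]:
    """Correct raw mass losses for autogenic change measured in controls.

    For each food, the signed mean control change ``mean(remaining -
    offered)`` is added to the raw consumption ``offered - remaining`` of
    every treatment arena (a food that decays in controls has part of its
    apparent consumption explained away; one that gains mass has its
    consumption topped up).  Results are floored at zero.
    """
    controls = [t for t in trials if t.is_control]
    if not controls:
        raise ValueError("autogenic adjustment requires at least one control arena")
    mean_change = {
        f: float(np.mean([t.remaining_mass_mg[f] - t.offered_mass_mg[f] for t in controls]))
        for f in FOOD_TYPES
    }
    out = []
    for t in trials:
        if t.is_control:
            continue
        consumed = {
            f: max(
                (t.offered_mass_mg[f] - t.remaining_mass_mg[f]) + mean_change[f], 0.0
            )
            for f in FOOD_TYPES
        }
        out.append(AdjustedConsumption(trial_id=t.trial_id, group=t.group, consumed_mg=consumed))
    return out


# ---------------------------------------------------------------------------
# Composition construction


def _offered_availability(trials: list[ElectivityTrial]) -> dict[str, float]:
    offered = {f: float(np.mean([t.offered_mass_mg[f] for t in trials])) for f in FOOD_TYPES}
    total = sum(offered.values())
    return {f: 100.0 * offered[f] / total for f in FOOD_TYPES}


def build_compositions(
    adjusted: list[AdjustedConsumption],
    zero_replacement: float = ZERO_REPLACEMENT_PCT,
    availability: str | dict[str, float] = "equal",
    trials: list[ElectivityTrial] | None = None,
) -> list[DietComposition]:
    """Express each individual's diet as percentages with zeros replaced.

    Zero use percentages are set to ``zero_replacement`` (in percent) and
    the remaining entries rescaled proportionally so each composition stays
    on the 100 % simplex.  ``availability`` is "equal" (every food 100/k),
    "offered" (percentage of mean offered mass; requires ``trials``), or an
    explicit mapping.  Individuals with zero total consumption carry no
    compositional information and are excluded with a warning.
    """
    k = len(FOOD_TYPES)
    if availability == "equal":
        avail = {f: 100.0 / k for f in FOOD_TYPES}
    elif availability == "offered":
        if trials is None:
            raise ValueError("availability='offered' requires the trials")
        avail = _offered_availability([t for t in trials if not t.is_control])
    else:
        total = sum(availability.values())
        avail = {f: 100.0 * availability[f] / total for f in FOOD_TYPES}

    out = []
    for rec in adjusted:
        total = sum(rec.consumed_mg.values())
        if total <= 0:
            warnings.warn(
                f"{rec.trial_id}: zero total consumption, excluded from compositions",
                stacklevel=2,
            )
            continue
        pct = {f: 100.0 * rec.consumed_mg[f] / total for f in FOOD_TYPES}
        zero = {f: pct[f] == 0.0 for f in FOOD_TYPES}
        n_zero = sum(zero.values())
        if n_zero:
            scale = (100.0 - n_zero * zero_replacement) / 100.0
            pct = {
                f: zero_replacement if zero[f] else pct[f] * scale for f in FOOD_TYPES
            }
        out.append(
            DietComposition(
                individual_id=rec.trial_id,
                use_pct=pct,
                avail_pct=dict(avail),
                zero_replaced=zero,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Compositional MANOVA (Wilks' lambda with sign-flip randomization)


def _logratio_differences(
    compositions: list[DietComposition], reference: str | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-individual (use - availability) log-ratio vectors, k-1 coords."""
    foods = sorted(FOOD_TYPES)
    if reference is None:
        reference = foods[-1]  # last food alphabetically
    others = [f for f in foods if f != reference]
    rows = []
    for c in compositions:
        d = [
            np.log(c.use_pct[f] / c.use_pct[reference])
            - np.log(c.avail_pct[f] / c.avail_pct[reference])
            for f in others
        ]
        rows.append(d)
    return np.array(rows), others


def _wilks_lambda(d: np.ndarray) -> float:
    dbar = d.mean(axis=0)
    centered = d - dbar
    w = centered.T @ centered
    t = d.T @ d
    det_t = np.linalg.det(t)
    if det_t <= 0 or not np.isfinite(det_t):
        raise np.linalg.LinAlgError(
            "singular cross-product matrix; more individuals than foods are needed"
        )
    return float(np.linalg.det(w) / det_t)


def compositional_manova(
    compositions: list[DietComposition],
    n_rand: int = 1999,
    seed: int = 0,
    reference: str | None = None,
) -> CompositionalTestResult:
    """Test the null of random feeding (use equals availability).

    Wilks' lambda is ``det(W) / det(T)`` where ``W`` and ``T`` are the
    centred and uncentred cross-products of the per-individual log-ratio
    difference vectors; lambda near 1 means no systematic departure.  The
    null distribution is generated by independent +-1 sign flips of each
    individual's difference vector (the exact null when use is
    exchangeable with availability), and the p-value counts randomized
    lambdas no larger than the observed one, including the observed
    statistic itself.
    """
    k = len(FOOD_TYPES)
    if len(compositions) < k:
        raise ValueError(f"need at least {k} individuals for {k} foods")
    d, _ = _logratio_differences(compositions, reference)
    if np.max(np.abs(d)) < 1e-12:
        # use identical to availability for everyone: no departure at all
        return CompositionalTestResult(1.0, 1.0, n_rand, seed)
    lam_obs = _wilks_lambda(d)
    if n_rand == 0:
        return CompositionalTestResult(lam_obs, 1.0, 0, seed)
    rng = np.random.default_rng(seed)
    n = len(d)
    # det(T - n m m') = det(T) (1 - n m' T^-1 m): lambda depends on the sign
    # flips only through the flipped mean m, so randomization vectorizes
    t = d.T @ d
    t_inv = np.linalg.inv(t)
    signs = rng.choice([-1.0, 1.0], size=(n_rand, n))
    means = (signs @ d) / n
    lam_rand = 1.0 - n * np.einsum("ri,ij,rj->r", means, t_inv, means)
    count = int(np.sum(lam_rand <= lam_obs + 1e-12))
    p = (1 + count) / (n_rand + 1)
    return CompositionalTestResult(lam_obs, float(p), n_rand, seed)


# ---------------------------------------------------------------------------
# Electivity ranking


def _assign_letters(order: tuple[str, ...], significant: np.ndarray, foods: tuple[str, ...]) -> dict[str, str]:
    """Compact letter display: foods share a letter iff not significantly
    different (letters follow maximal cliques of the non-significance graph)."""
    idx = {f: i for i, f in enumerate(foods)}
    g = nx.Graph()
    g.add_nodes_from(order)
    for i, f in enumerate(order):
        for h in order[i + 1:]:
            if not significant[idx[f], idx[h]]:
                g.add_edge(f, h)
    cliques = list(nx.find_cliques(g))
    # order cliques by the best-ranked food they contain, for stable letters
    rank = {f: i for i, f in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[f] for f in c))
    letters: dict[str, list[str]] = {f: [] for f in order}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for f in clique:
            letters[f].append(letter)
    return {f: "".join(sorted(ls)) for f, ls in letters.items()}


def rank_electivity(
    compositions: list[DietComposition],
    n_rand: int = 1999,
    seed: int = 0,
    alpha: float = 0.05,
) -> RankingResult:
    """Rank foods by their contribution to diet relative to availability.

    The pairwise statistic for foods (f, g) is the across-individual mean
    of ``log(use_f / use_g) - log(avail_f / avail_g)``; the ranking sorts
    foods by the number of positive entries in their matrix row (ties
    broken by the row sum).  Pairwise significance comes from per-
    individual sign-flip randomization of the difference, two-sided.
    Meaningful after a significant compositional MANOVA; the function runs
    regardless.
    """
    foods = tuple(sorted(FOOD_TYPES))
    k = len(foods)
    n = len(compositions)
    if n < 2:
        raise ValueError("need at least two individuals to rank foods")
    # per-individual pairwise log-ratio differences, shape (n, k, k)
    lu = np.array([[np.log(c.use_pct[f]) for f in foods] for c in compositions])
    la = np.array([[np.log(c.avail_pct[f]) for f in foods] for c in compositions])
    e = (lu[:, :, None] - lu[:, None, :]) - (la[:, :, None] - la[:, None, :])
    mean_mat = e.mean(axis=0)

    rng = np.random.default_rng(seed)
    p_values = np.ones((k, k))
    if n_rand > 0:
        signs = rng.choice([-1.0, 1.0], size=(n_rand, n))
        for i in range(k):
            for j in range(i + 1, k):
                obs = abs(mean_mat[i, j])
                rand_means = np.abs(signs @ e[:, i, j]) / n
                count = int(np.sum(rand_means >= obs - 1e-12))
                p = (1 + count) / (n_rand + 1)
                p_values[i, j] = p_values[j, i] = p
    significant = p_values < alpha
    np.fill_diagonal(significant, False)

    pos_counts = (mean_mat > 0).sum(axis=1)
    row_sums = mean_mat.sum(axis=1)
    order_idx = sorted(range(k), key=lambda i: (-pos_counts[i], -row_sums[i], foods[i]))
    tie_broken = len(set(pos_counts)) < k
    order = tuple(foods[i] for i in order_idx)
    letters = _assign_letters(order, significant, foods)
    return RankingResult(
        foods=foods,
        order=order,
        mean_logratio_diff=mean_mat,
        p_values=p_values,
        significant=significant,
        letters=letters,
        tie_broken=tie_broken,
    )
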