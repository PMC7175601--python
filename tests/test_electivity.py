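"""Autogenic adjustment, composition construction, Wilks' lambda and ranking."""

import numpy as np
import pytest

from predelect import (
    FOOD_TYPES,
    ElectivitySimConfig,
    ElectivityTrial,
    adjust_autogenic,
    build_compositions,
    compositional_manova,
    rank_electivity,
    simulate_electivity,
)
from predelect.electivity import AdjustedConsumption, DietComposition, _logratio_differences


def make_arena(trial_id, group, offered, remaining):
    return ElectivityTrial(
        trial_id=trial_id,
        group=group,
        offered_mass_mg=dict(offered),
        remaining_mass_mg=dict(remaining),
        offered_count={f: 10 for f in FOOD_TYPES},
        remaining_count={f: 5 for f in FOOD_TYPES},
    )


def control_with_drift(trial_id, drift):
    offered = {f: 40.0 for f in FOOD_TYPES}
    remaining = {f: 40.0 + drift[f] for f in FOOD_TYPES}
    return make_arena(trial_id, "control", offered, remaining)


class TestAdjustAutogenic:
    # measured control drifts: eggs decay slightly, leaves leach mass,
    # the live plant gains, isopods occasionally die and fragment
    drift = {"fish": -0.3, "leaf": -1.8, "plant": 1.7, "invertebrate": -1.9}

    def test_signed_control_change_applied_per_food(self):
        ctrl = control_with_drift("c0", self.drift)
        offered = {f: 40.0 for f in FOOD_TYPES}
        remaining = {"fish": 35.0, "leaf": 40.0, "plant": 39.0, "invertebrate": 40.0}
        arena = make_arena("a0", "Dv_large", offered, remaining)
        (adj,) = adjust_autogenic([arena, ctrl])
        assert adj.consumed_mg["fish"] == pytest.approx(5.0 - 0.3)
        assert adj.consumed_mg["plant"] == pytest.approx(1.0 + 1.7)

    def test_zero_raw_consumption_with_negative_drift_floors_at_zero(self):
        ctrl = control_with_drift("c0", self.drift)
        offered = {f: 40.0 for f in FOOD_TYPES}
        arena = make_arena("a0", "G_pulex", offered, dict(offered))
        (adj,) = adjust_autogenic([arena, ctrl])
        assert adj.consumed_mg["fish"] == 0.0
        assert adj.consumed_mg["leaf"] == 0.0
        assert adj.consumed_mg["plant"] == pytest.approx(1.7)

    def test_requires_controls(self):
        offered = {f: 40.0 for f in FOOD_TYPES}
        arena = make_arena("a0", "G_pulex", offered, dict(offered))
        with pytest.raises(ValueError, match="control"):
            adjust_autogenic([arena])


def adjusted(trial_id, consumed):
    return AdjustedConsumption(trial_id=trial_id, group="g",
                               consumed_mg=dict(zip(sorted(FOOD_TYPES), consumed)))


class TestBuildCompositions:
    def test_equal_consumption_gives_equal_percentages(self):
        (comp,) = build_compositions([adjusted("i1", (10, 10, 10, 10))])
        assert list(comp.use_pct.values()) == pytest.approx([25, 25, 25, 25])
        assert sum(comp.avail_pct.values()) == pytest.approx(100)

    def test_zero_replacement_rescales_to_simplex(self):
        (comp,) = build_compositions([adjusted("i1", (30, 10, 0, 0))])
        foods = sorted(FOOD_TYPES)
        expected = dict(zip(foods, (74.985, 24.995, 0.01, 0.01)))
        for f in foods:
            assert comp.use_pct[f] == pytest.approx(expected[f], abs=1e-9)
        assert sum(comp.use_pct.values()) == pytest.approx(100, abs=1e-9)
        assert comp.zero_replaced[foods[2]] and comp.zero_replaced[foods[3]]

    def test_offered_availability_percentages(self):
        trial = make_arena("a0", "g", {f: 40.0 for f in FOOD_TYPES},
                           {f: 20.0 for f in FOOD_TYPES})
        (comp,) = build_compositions(
            [adjusted("i1", (1, 2, 3, 4))], availability="offered", trials=[trial]
        )
        assert list(comp.avail_pct.values()) == pytest.approx([25, 25, 25, 25])

    def test_invariant_to_uniform_mass_rescaling(self):
        (c1,) = build_compositions([adjusted("i1", (3, 1, 2, 4))])
        (c2,) = build_compositions([adjusted("i1", (30, 10, 20, 40))])
        for f in FOOD_TYPES:
            assert c1.use_pct[f] == pytest.approx(c2.use_pct[f])

    def test_zero_total_individual_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            comps = build_compositions(
                [adjusted("i1", (0, 0, 0, 0)), adjusted("i2", (1, 1, 1, 1))]
            )
        assert [c.individual_id for c in comps] == ["i2"]


def composition(ind, use, avail=None):
    foods = sorted(FOOD_TYPES)
    avail = avail or {f: 25.0 for f in foods}
    return DietComposition(
        individual_id=ind,
        use_pct=dict(zip(foods, use)),
        avail_pct=dict(avail),
        zero_replaced={f: False for f in foods},
    )


def simulated_compositions(weights, n=15, seed=0, drift_free=True):
    kw = {}
    if drift_free:
        zero = {f: 0.0 for f in FOOD_TYPES}
        kw = dict(autogenic_mean=zero, autogenic_sd=zero)
    cfg = ElectivitySimConfig(
        electivity_weights=weights,
        offered_masses={f: 40.0 for f in FOOD_TYPES},
        n_individuals=n, seed=seed, **kw,
    )
    trials = simulate_electivity(cfg)
    return build_compositions(adjust_autogenic(trials), availability="offered",
                              trials=trials)


class TestCompositionalManova:
    def test_use_equal_availability_gives_unit_lambda(self):
        comps = [composition(f"i{k}", (25, 25, 25, 25)) for k in range(6)]
        res = compositional_manova(comps, n_rand=199, seed=1)
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_strong_electivity_reaches_randomization_floor(self):
        weights = {"fish": 10.0, "leaf": 1.0, "plant": 1.0, "invertebrate": 1.0}
        comps = simulated_compositions(weights, n=15, seed=11)
        res = compositional_manova(comps, n_rand=1999, seed=7)
        assert res.p_value == pytest.approx(1 / 2000)
        assert res.wilks_lambda < 0.5

    def test_p_value_never_below_floor(self):
        weights = {"fish": 50.0, "leaf": 1.0, "plant": 1.0, "invertebrate": 1.0}
        comps = simulated_compositions(weights, n=10, seed=3)
        res = compositional_manova(comps, n_rand=99, seed=5)
        assert res.p_value >= 1 / 100

    def test_lambda_invariant_to_reference_food(self):
        weights = {"fish": 3.0, "leaf": 1.0, "plant": 0.5, "invertebrate": 1.5}
        comps = simulated_compositions(weights, n=12, seed=9)
        lams = {
            compositional_manova(comps, n_rand=0, seed=0, reference=f).wilks_lambda
            for f in FOOD_TYPES
        }
        assert max(lams) - min(lams) < 1e-9

    def test_too_few_individuals_rejected(self):
        comps = [composition("i0", (40, 30, 20, 10))]
        with pytest.raises(ValueError, match="individuals"):
            compositional_manova(comps)

    def test_null_rejection_rate_near_alpha(self):
        # scaled-down type-I check; the full calibration runs in acceptance
        weights = {f: 1.0 for f in FOOD_TYPES}
        hits = 0
        n_sim = 120
        for i in range(n_sim):
            comps = simulated_compositions(weights, n=12, seed=40_000 + i)
            if compositional_manova(comps, n_rand=199, seed=50_000 + i).p_value < 0.05:
                hits += 1
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, n_sim, 0.05)
        assert lo <= hits <= hi


class TestRanking:
    def test_matrix_antisymmetric(self):
        weights = {"fish": 4.0, "leaf": 2.0, "plant": 1.0, "invertebrate": 0.5}
        comps = simulated_compositions(weights, n=12, seed=13)
        res = rank_electivity(comps, n_rand=199, seed=1)
        assert np.allclose(res.mean_logratio_diff, -res.mean_logratio_diff.T)

    def test_dominant_food_ranks_first_with_distinct_letter(self):
        weights = {"fish": 10.0, "leaf": 1.0, "plant": 1.0, "invertebrate": 1.0}
        comps = simulated_compositions(weights, n=15, seed=17)
        res = rank_electivity(comps, n_rand=999, seed=2)
        assert res.order[0] == "fish"
        fish_letters = set(res.letters["fish"])
        for other in ("leaf", "plant", "invertebrate"):
            assert not fish_letters & set(res.letters[other])

    def test_leaf_dominated_diet_ranks_leaf_first(self):
        weights = {"fish": 1.0, "leaf": 8.0, "plant": 1.0, "invertebrate": 0.5}
        comps = simulated_compositions(weights, n=15, seed=19)
        res = rank_electivity(comps, n_rand=999, seed=3)
        assert res.order[0] == "leaf"

    def test_exchangeable_foods_share_a_letter(self):
        weights = {"fish": 1.0, "leaf": 1.0, "plant": 1.0, "invertebrate": 1.0}
        comps = simulated_compositions(weights, n=12, seed=23)
        res = rank_electivity(comps, n_rand=999, seed=4)
        # at least one pair of equally-weighted foods shares a letter
        shared = [
            (f, g)
            for i, f in enumerate(res.foods)
            for g in res.foods[i + 1:]
            if set(res.letters[f]) & set(res.letters[g])
        ]
        assert shared

    def test_order_invariant_to_logratio_reference(self):
        # log-ratio reference cancels in pairwise differences: the mean
        # matrix is built from pairwise ratios directly
        weights = {"fish": 5.0, "leaf": 2.5, "plant": 1.0, "invertebrate": 0.4}
        comps = simulated_compositions(weights, n=14, seed=29)
        d_default, _ = _logratio_differences(comps)
        d_other, _ = _logratio_differences(comps, reference="fish")
        res = rank_electivity(comps, n_rand=0, seed=0)
        assert res.order[0] == "fish"
        assert d_default.shape == d_other.shape
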