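"""Trial data types, CSV I/O, validation and consumption accounting.

A functional-response (FR) trial exposes one predator to ``n0`` prey in an
arena for ``t_days``; what is left at the end (whole prey, damaged prey with
an eyeballed flesh fraction remaining, dead-but-undamaged prey) is turned
into an analyzable consumption record here.  An electivity trial offers four
food types at once and records offered/remaining mass and count per food.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FOOD_TYPES",
    "EGG_PREY",
    "FRTrial",
    "ConsumptionRecord",
    "ElectivityTrial",
    "ValidationError",
    "read_fr_trials",
    "write_fr_trials",
    "read_electivity_trials",
    "write_electivity_trials",
    "account_consumption",
    "reconstruct_partials",
]

#: Fixed food-type set of the electivity design: the focal fish prey (eggs or
#: larvae), conditioned leaf discs, live aquatic plant, and a live isopod.
FOOD_TYPES: tuple[str, ...] = ("fish", "leaf", "plant", "invertebrate")

#: Prey labels for which partial consumption is not expected (eggs are
#: normally consumed whole; rare nibbling occurs, so it warns, not rejects).
EGG_PREY: frozenset[str] = frozenset({"carp_egg", "trout_egg"})

_FRACTION_TOL = 1e-9


class ValidationError(ValueError):
    """A trial record violated a structural invariant."""


@dataclass(frozen=True)
class FRTrial:
    """One predator-in-arena exposure of a functional-response experiment.

    Parameters
    ----------
    trial_id : str
        Unique arena identifier.
    group : str
        Predator group label (e.g. ``"G_pulex"``, ``"Dv_large"``).
    prey : str
        Prey type label (e.g. ``"carp_egg"``).
    n0 : int
        Number of prey supplied (initial density).
    t_days : float
        Exposure time in days.
    whole_remaining : int
        Intact, alive prey recovered.
    damaged_fractions : tuple of float
        Flesh fraction remaining for each damaged prey item, estimated to
        the nearest 10 % (multiples of 0.1 strictly between 0 and 1).
    dead_undamaged : int
        Prey found dead but undamaged; treated as background mortality.
    is_control : bool
        Predator-free control arena.
    """

    trial_id: str
    group: str
    prey: str
    n0: int
    t_days: float
    whole_remaining: int
    damaged_fractions: tuple[float, ...] = ()
    dead_undamaged: int = 0
    is_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "damaged_fractions", tuple(float(f) for f in self.damaged_fractions)
        )
        self.validate()

    def validate(self) -> None:
        if self.n0 <= 0:
            raise ValidationError(f"{self.trial_id}: n0 must be positive, got {self.n0}")
        if self.t_days <= 0:
            raise ValidationError(f"{self.trial_id}: t_days must be positive")
        if self.whole_remaining < 0 or self.dead_undamaged < 0:
            raise ValidationError(f"{self.trial_id}: negative remaining/dead counts")
        accounted = self.whole_remaining + len(self.damaged_fractions) + self.dead_undamaged
        if accounted > self.n0:
            raise ValidationError(
                f"{self.trial_id}: accounted prey ({accounted}) exceed n0 ({self.n0})"
            )
        for f in self.damaged_fractions:
            if not (0.0 < f < 1.0):
                raise ValidationError(
                    f"{self.trial_id}: damaged fraction {f} outside (0, 1)"
                )
            if abs(f * 10 - round(f * 10)) > _FRACTION_TOL:
                raise ValidationError(
                    f"{self.trial_id}: damaged fraction {f} is not a multiple of 0.1"
                )
        if self.is_control and self.damaged_fractions:
            raise ValidationError(
                f"{self.trial_id}: control arena cannot carry predator damage"
            )
        if self.prey in EGG_PREY and self.damaged_fractions:
            warnings.warn(
                f"{self.trial_id}: partial consumption recorded for egg prey "
                f"{self.prey!r}; eggs are normally consumed whole",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    """Per-trial consumption summary derived from arena remains.

    ``consumed_mass_equiv`` is in prey-equivalents (fractional, from summed
    remaining flesh fractions); ``consumed_rounded`` is the nearest whole
    prey; ``killed`` counts predation deaths (damaged prey count as killed,
    dead-but-undamaged prey do not).
    """

    consumed_mass_equiv: float
    consumed_rounded: int
    killed: int
    partially_consumed: int


@dataclass(frozen=True)
class ElectivityTrial:
    """One arena of an electivity experiment with four foods on offer."""

    trial_id: str
    group: str  # predator group label, or "control"
    offered_mass_mg: dict[str, float] = field(default_factory=dict)
    remaining_mass_mg: dict[str, float] = field(default_factory=dict)
    offered_count: dict[str, int] = field(default_factory=dict)
    remaining_count: dict[str, int] = field(default_factory=dict)

    @property
    def is_control(self) -> bool:
        return self.group == "control"

    def __post_init__(self) -> None:
        for mapping in (
            self.offered_mass_mg,
            self.remaining_mass_mg,
            self.offered_count,
            self.remaining_count,
        ):
            if set(mapping) != set(FOOD_TYPES):
                raise ValidationError(
                    f"{self.trial_id}: food set {sorted(mapping)} != {sorted(FOOD_TYPES)}"
                )
        for food in FOOD_TYPES:
            if self.offered_mass_mg[food] < 0 or self.remaining_mass_mg[food] < 0:
                raise ValidationError(f"{self.trial_id}: negative mass for {food}")
            if self.offered_count[food] <= 0:
                raise ValidationError(f"{self.trial_id}: offered count for {food} not positive")
            if not 0 <= self.remaining_count[food] <= self.offered_count[food]:
                raise ValidationError(
                    f"{self.trial_id}: remaining count for {food} outside [0, offered]"
                )


# ---------------------------------------------------------------------------
# Consumption accounting


def _round_half_up(x: float) -> int:
    # "rounded to the nearest whole prey"; ties (x.5) round up
    import math

    return int(math.floor(x + 0.5))


def account_consumption(trial: FRTrial) -> ConsumptionRecord:
    """Turn arena remains into consumed/killed counts.

    Consumption is prey supplied minus all remaining flesh, whole and
    damaged; prey found dead but undamaged are excluded from both consumed
    and killed as background mortality.

    Raises
    ------
    ValueError
        If the trial is a control, or the computed consumption is negative
        (an internally inconsistent record).
    """
    if trial.is_control:
        raise ValueError(f"{trial.trial_id}: controls carry no predator-attributed consumption")
    remaining_flesh = trial.whole_remaining + sum(trial.damaged_fractions)
    consumed = trial.n0 - remaining_flesh - trial.dead_undamaged
    if consumed < -_FRACTION_TOL:
        raise ValueError(
            f"{trial.trial_id}: negative computed consumption ({consumed:.3f}); "
            "record is inconsistent"
        )
    consumed = max(consumed, 0.0)
    killed = trial.n0 - trial.whole_remaining - trial.dead_undamaged
    return ConsumptionRecord(
        consumed_mass_equiv=consumed,
        consumed_rounded=min(_round_half_up(consumed), trial.n0),
        killed=killed,
        partially_consumed=len(trial.damaged_fractions),
    )


def reconstruct_partials(heads: int, tails: int, other_parts: int = 0) -> int:
    """Minimum number of individuals represented by recovered body parts.

    Pairs complementary parts whenever possible: a head and a tail are
    assumed to come from the same individual, so heads and tails contribute
    ``max(heads, tails)``.  Other unclassified parts are absorbed by the
    already-counted individuals where possible, each surplus part adding one.
    """
    if min(heads, tails, other_parts) < 0:
        raise ValueError("part counts must be non-negative")
    paired = max(heads, tails)
    return paired + max(0, other_parts - paired)


# ---------------------------------------------------------------------------
# CSV I/O (comma-separated, UTF-8, "." decimal, one row per arena)

_FR_FIELDS = [
    "trial_id",
    "group",
    "prey",
    "n0",
    "t_days",
    "whole_remaining",
    "damaged_fractions",
    "dead_undamaged",
    "is_control",
]


def _format_fractions(fractions: Sequence[float]) -> str:
    return ";".join(f"{f:g}" for f in fractions)


def _parse_fractions(text: str) -> tuple[float, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(float(tok) for tok in text.split(";"))


def read_fr_trials(path: str | Path) -> list[FRTrial]:
    """Read validated FR trial records from a CSV file, preserving row order."""
    trials: list[FRTrial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_FR_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                trials.append(
                    FRTrial(
                        trial_id=row["trial_id"],
                        group=row["group"],
                        prey=row["prey"],
                        n0=int(row["n0"]),
                        t_days=float(row["t_days"]),
                        whole_remaining=int(row["whole_remaining"]),
                        damaged_fractions=_parse_fractions(row["damaged_fractions"]),
                        dead_undamaged=int(row["dead_undamaged"]),
                        is_control=row["is_control"].strip().lower() in ("true", "1", "yes"),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return trials


def write_fr_trials(trials: Iterable[FRTrial], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FR_FIELDS)
        for t in trials:
            writer.writerow(
                [
                    t.trial_id,
                    t.group,
                    t.prey,
                    t.n0,
                    f"{t.t_days:g}",
                    t.whole_remaining,
                    _format_fractions(t.damaged_fractions),
                    t.dead_undamaged,
                    str(t.is_control).lower(),
                ]
            )


def _elect_fields() -> list[str]:
    cols = ["trial_id", "group"]
    for food in FOOD_TYPES:
        cols += [
            f"{food}_offered_mass_mg",
            f"{food}_remaining_mass_mg",
            f"{food}_offered_count",
            f"{food}_remaining_count",
        ]
    return cols


def read_electivity_trials(path: str | Path) -> list[ElectivityTrial]:
    """Read validated electivity trial records from a CSV file."""
    trials: list[ElectivityTrial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_elect_fields()) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                trials.append(
                    ElectivityTrial(
                        trial_id=row["trial_id"],
                        group=row["group"],
                        offered_mass_mg={
                            f: float(row[f"{f}_offered_mass_mg"]) for f in FOOD_TYPES
                        },
                        remaining_mass_mg={
                            f: float(row[f"{f}_remaining_mass_mg"]) for f in FOOD_TYPES
                        },
                        offered_count={
                            f: int(row[f"{f}_offered_count"]) for f in FOOD_TYPES
                        },
                        remaining_count={
                            f: int(row[f"{f}_remaining_count"]) for f in FOOD_TYPES
                        },
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return trials


def write_electivity_trials(trials: Iterable[ElectivityTrial], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_elect_fields())
        for t in trials:
            row: list[object] = [t.trial_id, t.group]
            for food in FOOD_TYPES:
                row += [
                    f"{t.offered_mass_mg[food]:g}",
                    f"{t.remaining_mass_mg[food]:g}",
                    t.offered_count[food],
                    t.remaining_count[food],
                ]
            writer.writerow(row)
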