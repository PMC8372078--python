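"""Parasitization performance indices from vial-level count data.

A standardized 4-hour assay exposes 25 host larvae to a single parasitoid
female.  Four indices summarise her performance, each corrected for the
baseline survival of unexposed larvae on the same testing day (the day
control mean, ``n_bar``, in flies per vial):

- attack rate      = 100 * (n_bar - w) / n_bar      (w = survivors without capsule)
- killing rate     = 100 * (n_bar - f) / n_bar      (f = flies emerged)
- lethal attack    = 100 * (n_bar - f) / (n_bar - w) (killed / attacked)
- successful parasitism = 100 * p / (n_bar - f)     (offspring / killed)

A negative killing rate (f > n_bar, i.e. more survivors than the day's
controls) is a sampling artifact and is floored at zero.  Attack and lethal
attack rates are clamped into [0, 100] and the clamping is flagged.  Lethal
attack rate and successful parasitism are *undefined* (not zero) when their
denominators are non-positive; undefined values are excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from waspqg.tables import CONTROLS_SCHEMA, TRIALS_SCHEMA, read_table


class MissingControlError(ValueError):
    """No control vials available for a requested testing day."""


class DegenerateControlError(ValueError):
    """Day control mean is non-positive; indices are not computable."""


class EmptyDatasetError(ValueError):
    """Quality control removed every block."""


@dataclass(frozen=True)
class ControlVial:
    """A vial of larvae never exposed to a wasp."""

    day_id: str
    n_larvae: int
    n_emerged: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_emerged <= self.n_larvae:
            raise ValueError(
                f"control vial on day {self.day_id}: need "
                f"0 <= n_emerged <= n_larvae, got {self.n_emerged}/{self.n_larvae}"
            )


@dataclass(frozen=True)
class DayControlSummary:
    """Mean emerged flies per control vial on one testing day (``n_bar``)."""

    day_id: str
    n_bar: float
    n_vials: int

    def __post_init__(self) -> None:
        if self.n_bar < 0 or self.n_vials < 1:
            raise ValueError("day control summary requires n_bar >= 0, n_vials >= 1")


@dataclass(frozen=True)
class ExposureTrial:
    """One female's assay: counts of larvae, survivors and wasp offspring.

    ``f`` flies emerged, of which ``e`` carried at least one encapsulated
    egg and ``w = f - e`` carried none; ``p`` adult wasps emerged.
    """

    female_id: str
    day_id: str
    n_larvae: int
    f: int
    e: int
    p: int
    line_id: str = "0"
    generation: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f <= self.n_larvae:
            raise ValueError(f"trial {self.female_id}: need 0 <= f <= n_larvae")
        if not 0 <= self.e <= self.f:
            raise ValueError(f"trial {self.female_id}: need 0 <= e <= f")
        if not 0 <= self.p <= self.n_larvae - self.f:
            raise ValueError(
                f"trial {self.female_id}: wasp offspring p must satisfy "
                f"0 <= p <= n_larvae - f"
            )

    @property
    def w(self) -> int:
        return self.f - self.e


@dataclass(frozen=True)
class PerformanceRecord:
    """The four indices for one female, with defined/clamped flags."""

    female_id: str
    attack_rate: float
    killing_rate: float
    lethal_attack_rate: float | None
    successful_parasitism: float | None
    attack_clamped: bool = False
    killing_clamped: bool = False
    lethal_clamped: bool = False


def summarize_day_controls(
    vials: list[ControlVial], day_id: str
) -> DayControlSummary:
    """Arithmetic mean of emerged flies over one day's control vials."""
    todays = [v for v in vials if v.day_id == day_id]
    if not todays:
        raise MissingControlError(f"no control vials for day {day_id!r}")
    n_bar = float(np.mean([v.n_emerged for v in todays]))
    return DayControlSummary(day_id=day_id, n_bar=n_bar, n_vials=len(todays))


def _require_positive_control(control: DayControlSummary) -> None:
    if control.n_bar <= 0:
        raise DegenerateControlError(
            f"day {control.day_id}: control mean {control.n_bar} is not positive"
        )


def attack_rate(trial: ExposureTrial, control: DayControlSummary) -> float:
    """Percent of hosts parasitized: killed plus encapsulated survivors."""
    _require_positive_control(control)
    raw = 100.0 * (control.n_bar - trial.w) / control.n_bar
    return min(max(raw, 0.0), 100.0)


def killing_rate(trial: ExposureTrial, control: DayControlSummary) -> float:
    """Percent of hosts killed in excess of same-day control mortality."""
    _require_positive_control(control)
    raw = 100.0 * (control.n_bar - trial.f) / control.n_bar
    return max(raw, 0.0)


def lethal_attack_rate(
    trial: ExposureTrial, control: DayControlSummary
) -> float | None:
    """Killed hosts as a percent of attacked hosts; None when none attacked."""
    _require_positive_control(control)
    attacked = control.n_bar - trial.w
    if attacked <= 0:
        return None
    raw = 100.0 * (control.n_bar - trial.f) / attacked
    return min(max(raw, 0.0), 100.0)


def successful_parasitism(
    trial: ExposureTrial, control: DayControlSummary
) -> float | None:
    """Wasp offspring as a percent of killed hosts; None when none killed."""
    _require_positive_control(control)
    killed = control.n_bar - trial.f
    if killed <= 0:
        return None
    return 100.0 * trial.p / killed


def performance_record(
    trial: ExposureTrial, control: DayControlSummary
) -> PerformanceRecord:
    """All four indices for one trial, with clamp flags."""
    _require_positive_control(control)
    raw_attack = 100.0 * (control.n_bar - trial.w) / control.n_bar
    raw_kill = 100.0 * (control.n_bar - trial.f) / control.n_bar
    lar = lethal_attack_rate(trial, control)
    attacked = control.n_bar - trial.w
    raw_lar = 100.0 * (control.n_bar - trial.f) / attacked if attacked > 0 else None
    return PerformanceRecord(
        female_id=trial.female_id,
        attack_rate=min(max(raw_attack, 0.0), 100.0),
        killing_rate=max(raw_kill, 0.0),
        lethal_attack_rate=lar,
        successful_parasitism=successful_parasitism(trial, control),
        attack_clamped=not 0.0 <= raw_attack <= 100.0,
        killing_clamped=raw_kill < 0.0,
        lethal_clamped=raw_lar is not None and not 0.0 <= raw_lar <= 100.0,
    )


def qc_filter_blocks(
    summaries: list[DayControlSummary], ratio_threshold: float = 0.6
) -> tuple[list[DayControlSummary], list[DayControlSummary]]:
    """Drop testing blocks whose control mean falls below a fraction of the
    median block mean (low-quality host batches).

    Returns ``(retained, excluded)``; order-independent and idempotent.
    """
    if len(summaries) < 2:
        raise ValueError("block quality control needs at least 2 blocks")
    med = float(np.median([s.n_bar for s in summaries]))
    retained = [s for s in summaries if s.n_bar >= ratio_threshold * med]
    excluded = [s for s in summaries if s.n_bar < ratio_threshold * med]
    if not retained:
        raise EmptyDatasetError("quality control excluded every block")
    return retained, excluded


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def standardized_counts(
    trial: ExposureTrial, control: DayControlSummary, index: str
) -> tuple[int, int] | None:
    """Integer (successes, failures) pair for model fitting, using the day's
    control mean (rounded half away from zero) as the trial total.

    ``index`` is one of ``"killing"``, ``"attack"``, ``"lethal"``,
    ``"parasitism"``.  Returns None where the index is undefined.
    """
    _require_positive_control(control)
    total = _round_half_away(control.n_bar)
    if index == "killing":
        successes = min(max(total - trial.f, 0), total)
        return successes, total - successes
    if index == "attack":
        successes = min(max(total - trial.w, 0), total)
        return successes, total - successes
    if index == "lethal":
        attacked = min(max(total - trial.w, 0), total)
        if attacked <= 0:
            return None
        successes = min(max(total - trial.f, 0), attacked)
        return successes, attacked - successes
    if index == "parasitism":
        killed = min(max(total - trial.f, 0), total)
        if killed <= 0:
            return None
        successes = min(trial.p, killed)
        return successes, killed - successes
    raise ValueError(f"unknown index {index!r}")


# ---------------------------------------------------------------------------
# Table-level pipeline


def controls_to_summaries(controls: pd.DataFrame) -> dict[str, DayControlSummary]:
    """Per-day control summaries from a validated controls table."""
    out: dict[str, DayControlSummary] = {}
    for day_id, grp in controls.groupby("day_id", sort=False):
        out[str(day_id)] = DayControlSummary(
            day_id=str(day_id),
            n_bar=float(grp["flies_emerged"].mean()),
            n_vials=len(grp),
        )
    return out


def trials_to_objects(trials: pd.DataFrame) -> list[ExposureTrial]:
    return [
        ExposureTrial(
            female_id=str(r.female_id),
            day_id=str(r.day_id),
            line_id=str(r.line_id),
            generation=int(r.generation),
            n_larvae=int(r.n_larvae),
            f=int(r.flies_emerged),
            e=int(r.flies_encapsulated),
            p=int(r.wasp_offspring),
        )
        for r in trials.itertuples(index=False)
    ]


def compute_performance_table(
    trials: pd.DataFrame,
    controls: pd.DataFrame,
    qc_threshold: float | None = 0.6,
) -> pd.DataFrame:
    """One row per female: the four indices plus defined/clamped flags.

    When ``qc_threshold`` is given, low-quality testing days are removed
    first (see :func:`qc_filter_blocks`).
    """
    summaries = controls_to_summaries(controls)
    if qc_threshold is not None and len(summaries) >= 2:
        retained, _ = qc_filter_blocks(list(summaries.values()), qc_threshold)
        summaries = {s.day_id: s for s in retained}
    rows = []
    for trial in trials_to_objects(trials):
        if trial.day_id not in summaries:
            continue
        rec = performance_record(trial, summaries[trial.day_id])
        rows.append(
            {
                "female_id": rec.female_id,
                "day_id": trial.day_id,
                "line_id": trial.line_id,
                "generation": trial.generation,
                "attack_rate": rec.attack_rate,
                "killing_rate": rec.killing_rate,
                "lethal_attack_rate": rec.lethal_attack_rate,
                "successful_parasitism": rec.successful_parasitism,
                "lethal_defined": rec.lethal_attack_rate is not None,
                "parasitism_defined": rec.successful_parasitism is not None,
                "attack_clamped": rec.attack_clamped,
                "killing_clamped": rec.killing_clamped,
                "lethal_clamped": rec.lethal_clamped,
            }
        )
    if not rows:
        raise EmptyDatasetError("no trials on retained testing days")
    return pd.DataFrame(rows)


def load_and_compute(
    trials_path, controls_path, qc_threshold: float | None = 0.6
) -> pd.DataFrame:
    trials = read_table(trials_path, TRIALS_SCHEMA)
    controls = read_table(controls_path, CONTROLS_SCHEMA)
    return compute_performance_table(trials, controls, qc_threshold)
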