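"""Synthetic longitudinal cohorts with known ground truth.

Generates the three cohort tables under a simple generative model: every
person is observed for a fixed span; each drug is dispensed independently
with a fixed probability, at a date drawn uniformly from the middle of the
observation period (leaving room for the pre-exposure control windows and the
post-exposure surveillance windows); each condition fires day-by-day as an
independent Bernoulli with a constant background daily rate. For injected
positive-control pairs the daily rate is multiplied by a rate ratio on days
inside the effect window after that person's exposure to that drug; all other
drug-condition pairs are negative controls whose event processes are
independent of exposure timing by construction.

At most one event per (person, condition, day) is ever generated, matching
the distinct-count semantics downstream. An analytic oracle
(:func:`expected_window_events`) gives the closed-form expected number of
event-days in any relative window, so count and rate checks can be exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .counts import DayWindow
from .errors import ConfigurationError
from .io import Cohort, validate_cohort

#: Calendar anchor of all simulated observation periods (days since epoch).
BASE_DAY = 14610  # 2010-01-01

DRUG_ID_BASE = 1
CONDITION_ID_BASE = 101


@dataclass(frozen=True)
class InjectedPair:
    """A positive-control pair: the condition's daily rate is multiplied by
    ``rate_ratio`` on day offsets in [effect_start, effect_end] after the
    person's exposure to the drug."""

    drug_id: int
    condition_id: int
    rate_ratio: float
    effect_start: int = 1
    effect_end: int = 30

    def __post_init__(self) -> None:
        if self.rate_ratio < 1:
            raise ConfigurationError("rate_ratio must be >= 1")
        if self.effect_start < 1:
            raise ConfigurationError("effect window must start at day offset >= 1")
        if self.effect_end < self.effect_start:
            raise ConfigurationError("empty effect window")


@dataclass(frozen=True)
class GroundTruth:
    """Known positive and negative drug-condition control pairs."""

    positive_pairs: frozenset[tuple[int, int]]
    negative_pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.positive_pairs & self.negative_pairs:
            raise ConfigurationError("positive and negative control sets overlap")

    def save(self, path: str) -> str:
        rows = [(d, c, "positive") for d, c in sorted(self.positive_pairs)]
        rows += [(d, c, "negative") for d, c in sorted(self.negative_pairs)]
        pd.DataFrame(rows, columns=["drug_id", "condition_id", "label"]).to_csv(
            path, index=False
        )
        return path

    @classmethod
    def load(cls, path: str) -> "GroundTruth":
        df = pd.read_csv(path)
        pos = frozenset(
            (int(r.drug_id), int(r.condition_id))
            for r in df[df.label == "positive"].itertuples()
        )
        neg = frozenset(
            (int(r.drug_id), int(r.condition_id))
            for r in df[df.label == "negative"].itertuples()
        )
        return cls(pos, neg)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``pre_margin_days``/``post_margin_days`` bound the exposure date away
    from the observation edges so that control windows spanning up to
    ``pre_margin_days`` before and surveillance windows up to
    ``post_margin_days`` after the index date always fit inside the
    observation period — keeping analytic oracles exact.
    ``trend_break`` optionally scales every condition's daily rate by a
    common factor from a given day (offset from observation start) onward,
    exercising the ICΔ calendar-time calibration.
    """

    n_persons: int = 2000
    observation_days: int = 720
    n_drugs: int = 10
    n_conditions: int = 20
    exposure_probability: float = 0.3
    baseline_daily_rate: float = 0.001
    injected_pairs: tuple[InjectedPair, ...] = ()
    seed: int = 0
    pre_margin_days: int = 180
    post_margin_days: int = 360
    trend_break: tuple[int, float] | None = None  # (day offset from obs start, factor)

    def __post_init__(self) -> None:
        if not 0 < self.baseline_daily_rate < 1:
            raise ConfigurationError("baseline_daily_rate must be in (0, 1)")
        if not 0 <= self.exposure_probability <= 1:
            raise ConfigurationError("exposure_probability must be in [0, 1]")
        if min(self.n_persons, self.n_drugs, self.n_conditions) < 1:
            raise ConfigurationError("cohort dimensions must be positive")
        last = self.observation_days - 1 - self.post_margin_days
        if last < self.pre_margin_days:
            raise ConfigurationError(
                f"observation_days={self.observation_days} too small for margins "
                f"{self.pre_margin_days}+{self.post_margin_days}"
            )
        for pair in self.injected_pairs:
            rate = pair.rate_ratio * self.baseline_daily_rate
            if self.trend_break is not None:
                rate *= max(1.0, self.trend_break[1])
            if rate > 1:
                raise ConfigurationError(
                    f"rate_ratio {pair.rate_ratio} lifts the daily rate above 1"
                )
            if pair.drug_id not in self.drug_ids or pair.condition_id not in self.condition_ids:
                raise ConfigurationError(
                    f"injected pair ({pair.drug_id}, {pair.condition_id}) outside cohort"
                )

    @property
    def drug_ids(self) -> tuple[int, ...]:
        return tuple(range(DRUG_ID_BASE, DRUG_ID_BASE + self.n_drugs))

    @property
    def condition_ids(self) -> tuple[int, ...]:
        return tuple(range(CONDITION_ID_BASE, CONDITION_ID_BASE + self.n_conditions))

    def ground_truth(self) -> GroundTruth:
        pos = frozenset((p.drug_id, p.condition_id) for p in self.injected_pairs)
        neg = frozenset(
            (d, c) for d in self.drug_ids for c in self.condition_ids if (d, c) not in pos
        )
        return GroundTruth(pos, neg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["injected_pairs"] = [asdict(p) for p in self.injected_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["injected_pairs"] = tuple(
            InjectedPair(**p) for p in d.get("injected_pairs", ())
        )
        if d.get("trend_break") is not None:
            d["trend_break"] = tuple(d["trend_break"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the generative model; fully seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    days = config.observation_days
    person_ids = np.arange(1, n + 1)

    observation = pd.DataFrame(
        {
            "person_id": person_ids,
            "start_day": BASE_DAY,
            "end_day": BASE_DAY + days - 1,
        }
    )

    # Exposures: per drug, Bernoulli(p) per person; one exposure date drawn
    # uniformly from the feasible middle span of the observation period.
    lo = config.pre_margin_days
    hi = days - 1 - config.post_margin_days  # inclusive
    exp_rows = []
    exposure_offset: dict[int, np.ndarray] = {}  # drug -> per-person offset or -1
    for drug in config.drug_ids:
        exposed = rng.random(n) < config.exposure_probability
        offs = np.full(n, -1, dtype=np.int64)
        offs[exposed] = rng.integers(lo, hi + 1, size=int(exposed.sum()))
        exposure_offset[drug] = offs
        exp_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[exposed],
                    "drug_id": drug,
                    "day": BASE_DAY + offs[exposed],
                }
            )
        )
    exposures = (
        pd.concat(exp_rows, ignore_index=True)
        if exp_rows
        else pd.DataFrame(columns=["person_id", "drug_id", "day"])
    )

    # Daily rate profile per condition (constant unless trend_break set).
    base_profile = np.full(days, config.baseline_daily_rate)
    if config.trend_break is not None:
        break_day, factor = config.trend_break
        base_profile[int(break_day):] = np.minimum(
            1.0, config.baseline_daily_rate * factor
        )

    injected_by_condition: dict[int, list[InjectedPair]] = {}
    for pair in config.injected_pairs:
        injected_by_condition.setdefault(pair.condition_id, []).append(pair)

    cond_rows = []
    for condition in config.condition_ids:
        events = rng.random((n, days)) < base_profile[None, :]
        # Re-draw effect-window days at the elevated rate for exposed persons,
        # so the elevation is exact and stays a Bernoulli per day.
        for pair in injected_by_condition.get(condition, []):
            offs = exposure_offset[pair.drug_id]
            for p_idx in np.flatnonzero(offs >= 0):
                a = offs[p_idx] + pair.effect_start
                b = min(offs[p_idx] + pair.effect_end, days - 1)
                if a > b:
                    continue
                elevated = np.minimum(1.0, base_profile[a : b + 1] * pair.rate_ratio)
                events[p_idx, a : b + 1] = rng.random(b - a + 1) < elevated
        pidx, didx = np.nonzero(events)
        cond_rows.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[pidx],
                    "condition_id": condition,
                    "day": BASE_DAY + didx,
                }
            )
        )
    conditions = (
        pd.concat(cond_rows, ignore_index=True)
        if cond_rows
        else pd.DataFrame(columns=["person_id", "condition_id", "day"])
    )

    cohort = validate_cohort(exposures, conditions, observation)
    return cohort, config.ground_truth()


def expected_window_events(
    config: SimulationConfig, pair: tuple[int, int], window: DayWindow
) -> float:
    """Closed-form expected number of (person, day) events in a relative
    window for one drug-condition pair under the generative model.

    Sums the daily event probability over the window across the expected
    number of exposed persons, applying the injected rate ratio on days that
    overlap the pair's effect window. Only valid for windows that fit inside
    the configured margins (so every exposed person is fully observed over
    the window) and without a calendar trend break, whose interaction with
    the random exposure date has no simple closed form.
    """
    if config.trend_break is not None:
        raise ConfigurationError("analytic oracle unavailable with trend_break")
    if window.start_day >= 1 and window.end_day > config.post_margin_days:
        raise ConfigurationError(f"window {window} exceeds post_margin_days")
    if window.end_day <= -1 and window.start_day < -config.pre_margin_days:
        raise ConfigurationError(f"window {window} exceeds pre_margin_days")

    drug, condition = pair
    effect = {
        (p.drug_id, p.condition_id): p
        for p in config.injected_pairs
    }.get((drug, condition))
    n_exposed = config.n_persons * config.exposure_probability
    total = 0.0
    for day in range(window.start_day, window.end_day + 1):
        rate = config.baseline_daily_rate
        if effect is not None and effect.effect_start <= day <= effect.effect_end:
            rate = min(1.0, rate * effect.rate_ratio)
        total += rate
    return n_exposed * total


def save_config(config: SimulationConfig, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    return path
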