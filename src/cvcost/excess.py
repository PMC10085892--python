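"""Population-average excess annual costs via recycled prediction.

For each event and timing category, every member of a population is
predicted twice — once with the event state set to the given timing and
once with the event absent, all else equal — and the mean difference is
reported. For the linear primary-care model this difference is a fixed sum
of coefficients, independent of the population; for the two-part hospital
model it varies with population composition. Published summary values are
rounded to the nearest ten pounds.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .model_spec import (
    AnnualEventState,
    CancerDuration,
    CohortStratum,
    CoefficientSet,
    CovariateProfile,
    DiabetesDuration,
    EventDuration,
    Service,
)
from .predictor import (
    DesignRow,
    encode_design_row,
    extract_features,
    predict_hospital_cost,
    predict_primary_cost,
    term_value,
)

__all__ = [
    "EventKind", "ExcessCostEstimate", "set_event", "clear_event",
    "recycled_excess", "round_to_ten", "bootstrap_ci", "excess_table",
    "EVENT_TIMINGS",
]

Population = Sequence[tuple[CovariateProfile, AnnualEventState]]
ModelMap = Mapping[tuple[CohortStratum, Service], CoefficientSet]


class EventKind(str, enum.Enum):
    MI = "mi"
    STROKE = "stroke"
    CRV = "crv"
    VD = "vd"
    NVD = "nvd"
    DIABETES = "diabetes"
    CANCER = "cancer"


# Timing categories reported per event (same ordering as the published
# excess-cost table).
EVENT_TIMINGS: dict[EventKind, tuple[str, ...]] = {
    EventKind.MI: ("same_year", "one_year_ago", "two_years_ago",
                   "three_plus_years_ago"),
    EventKind.STROKE: ("same_year", "one_year_ago", "two_years_ago",
                       "three_plus_years_ago"),
    EventKind.CRV: ("same_year", "one_year_ago", "two_years_ago",
                    "three_plus_years_ago"),
    EventKind.VD: ("same_year",),
    EventKind.DIABETES: ("lt10y", "ge10y"),
    EventKind.CANCER: ("same_year", "one_year_ago", "two_years_ago",
                       "three_years_ago", "four_years_ago",
                       "five_to_ten_years_ago", "ge10y"),
    EventKind.NVD: ("same_year",),
}


@dataclass(frozen=True)
class ExcessCostEstimate:
    stratum: CohortStratum
    service: str  # "primary" | "hospital"
    event: EventKind
    timing: str
    mean_gbp: float
    ci_low_gbp: Optional[float] = None
    ci_high_gbp: Optional[float] = None
    rounded: bool = False
    n_population: int = 0
    n_bootstrap: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ci_low_gbp is not None and self.ci_high_gbp is not None:
            if not (self.ci_low_gbp <= self.mean_gbp <= self.ci_high_gbp):
                raise ValueError("CI does not bracket the mean")


def set_event(state: AnnualEventState, event: EventKind, timing: str
              ) -> AnnualEventState:
    """Counterfactual state with the event at the given timing category."""
    if timing not in EVENT_TIMINGS[event]:
        raise ValueError(f"timing {timing!r} invalid for {event.value}")
    if event in (EventKind.MI, EventKind.STROKE, EventKind.CRV):
        return replace(state, **{f"{event.value}_duration":
                                 EventDuration(timing)})
    if event is EventKind.DIABETES:
        return replace(state, diabetes_duration=DiabetesDuration(timing))
    if event is EventKind.CANCER:
        return replace(state, cancer_duration=CancerDuration(timing))
    if event is EventKind.VD:
        return replace(state, vd_this_year=True, nvd_this_year=False)
    return replace(state, nvd_this_year=True, vd_this_year=False)


def clear_event(state: AnnualEventState, event: EventKind
                ) -> AnnualEventState:
    if event in (EventKind.MI, EventKind.STROKE, EventKind.CRV):
        return replace(state, **{f"{event.value}_duration":
                                 EventDuration.NONE})
    if event is EventKind.DIABETES:
        return replace(state, diabetes_duration=DiabetesDuration.NONE)
    if event is EventKind.CANCER:
        return replace(state, cancer_duration=CancerDuration.NONE)
    if event is EventKind.VD:
        return replace(state, vd_this_year=False)
    return replace(state, nvd_this_year=False)


def _member_excess(models: ModelMap, stratum: CohortStratum,
                   profile: CovariateProfile, state: AnnualEventState,
                   event: EventKind, timing: str, service: str) -> float:
    on = set_event(state, event, timing)
    off = clear_event(state, event)
    if service == "primary":
        model = models[(stratum, Service.PRIMARY)]
        lp_on, _ = predict_primary_cost(
            encode_design_row(profile, on, model), model)
        lp_off, _ = predict_primary_cost(
            encode_design_row(profile, off, model), model)
        return lp_on - lp_off
    if service == "hospital":
        part1 = models[(stratum, Service.HOSPITAL_PART1)]
        part2 = models[(stratum, Service.HOSPITAL_PART2)]
        out = []
        for st in (on, off):
            feats = extract_features(profile, st)
            p1row = DesignRow({t.name: term_value(t, feats)
                               for t in part1.terms})
            p2row = DesignRow({t.name: term_value(t, feats)
                               for t in part2.terms})
            pred = predict_hospital_cost(p1row, p2row, part1, part2,
                                         features=feats)
            out.append(pred.hospital_gbp)
        return out[0] - out[1]
    raise ValueError(f"unknown service {service!r}")


def recycled_excess(models: ModelMap, population: Population,
                    event: EventKind, timing: str,
                    service: str = "primary",
                    stratum: CohortStratum = CohortStratum.WITHOUT_CVD
                    ) -> float:
    """Mean excess annual cost for an event at a timing category.

    The event is toggled on (at the given timing) and off for every
    population member with everything else held fixed; interactions fire
    only when their components hold, so the counterfactual with the event
    off also switches off any interaction involving it.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    total = 0.0
    for profile, state in population:
        total += _member_excess(models, stratum, profile, state, event,
                                timing, service)
    return total / len(population)


def round_to_ten(x: float) -> float:
    """Nearest multiple of 10, halves away from zero."""
    return math.copysign(math.floor(abs(x) / 10.0 + 0.5) * 10.0, x) \
        if x != 0 else 0.0


def bootstrap_ci(statistic: Callable[[Population], float],
                 population: Population, n_resamples: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap interval, resampling participants.

    The resampling unit is the population member (a participant with all
    their annual periods), drawn with replacement; deterministic for a
    given seed.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if len(population) == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    n = len(population)
    values = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        values[b] = statistic([population[i] for i in idx])
    low, high = np.quantile(values, [0.025, 0.975])
    if high == low:
        warnings.warn("degenerate statistic: bootstrap interval has zero "
                      "width", stacklevel=2)
    return float(low), float(high)


def excess_table(models: ModelMap, population: Population,
                 stratum: CohortStratum = CohortStratum.WITHOUT_CVD,
                 services: Sequence[str] = ("primary", "hospital"),
                 n_bootstrap: int = 0, seed: int = 0,
                 round_gbp: bool = True) -> list[ExcessCostEstimate]:
    """One excess-cost estimate per event x timing x service.

    Timing categories merged during selection simply inherit the preceding
    category's coefficient, so their excess equals the carried value.
    """
    rows: list[ExcessCostEstimate] = []
    for event, timings in EVENT_TIMINGS.items():
        for timing in timings:
            for service in services:
                mean = recycled_excess(models, population, event, timing,
                                       service, stratum)
                ci_low = ci_high = None
                if n_bootstrap >= 2:
                    stat = (lambda pop, e=event, t=timing, s=service:
                            recycled_excess(models, pop, e, t, s, stratum))
                    ci_low, ci_high = bootstrap_ci(stat, population,
                                                   n_bootstrap, seed)
                if round_gbp:
                    mean = round_to_ten(mean)
                    if ci_low is not None:
                        ci_low = min(round_to_ten(ci_low), mean)
                        ci_high = max(round_to_ten(ci_high), mean)
                rows.append(ExcessCostEstimate(
                    stratum=stratum, service=service, event=event,
                    timing=timing, mean_gbp=mean, ci_low_gbp=ci_low,
                    ci_high_gbp=ci_high, rounded=round_gbp,
                    n_population=len(population),
                    n_bootstrap=n_bootstrap if n_bootstrap >= 2 else None,
                    seed=seed if n_bootstrap >= 2 else None))
    return rows
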