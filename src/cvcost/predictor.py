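"""Design-row encoding and annual cost prediction.

Predictions follow the published formulas exactly: the primary-care and
hospital conditional-cost parts are additive linear predictors in pounds
(identity link), while the hospital part-1 probability is
``odds / (1 + odds)`` with ``odds = intercept_odds * prod(OR_i ** x_i)``,
computed internally as a log-odds sum. In annual periods with same-year
coronary revascularization the probability of incurring hospital cost is
overridden to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model_spec import (
    AnnualEventState,
    CancerDuration,
    CohortStratum,
    CoefficientSet,
    CovariateProfile,
    DiabetesDuration,
    EventDuration,
    ModelTerm,
    Service,
    validate_profile,
)

__all__ = [
    "DesignRow", "CostPrediction", "duration_category", "extract_features",
    "encode_design_row", "design_matrix", "predict_primary_cost",
    "predict_hospital_cost", "annual_states", "predict_trajectory",
]

FLAG_FLOORED = "negative_linear_predictor_floored"
FLAG_CRV_CERTAIN = "crv_certainty_rule_applied"


@dataclass(frozen=True)
class DesignRow:
    """Ordered term-name -> value map; the intercept entry is always 1."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass(frozen=True)
class CostPrediction:
    primary_gbp: float
    hospital_probability: float
    hospital_conditional_gbp: float
    hospital_gbp: float
    flags: tuple[str, ...] = ()


def duration_category(
    event_first_year: Optional[int],
    current_year: int,
    event_kind: str,
) -> Union[EventDuration, DiabetesDuration, CancerDuration]:
    """Time-since-first-occurrence category for an event.

    MI/stroke/CRV use the five-level scheme (none, same year, 1 year ago,
    2 years ago, >= 3 years ago); diabetes uses {none, < 10 years,
    >= 10 years}; cancer uses the eight-level scheme.
    """
    kind = event_kind.lower()
    if kind in ("mi", "stroke", "crv"):
        scheme = "cvd"
    elif kind == "diabetes":
        scheme = "diabetes"
    elif kind == "cancer":
        scheme = "cancer"
    else:
        raise ValueError(f"unknown event kind {event_kind!r}")

    if event_first_year is None:
        return {"cvd": EventDuration.NONE,
                "diabetes": DiabetesDuration.NONE,
                "cancer": CancerDuration.NONE}[scheme]
    delta = current_year - event_first_year
    if delta < 0:
        raise ValueError(
            f"event_first_year {event_first_year} after current year "
            f"{current_year}")
    if scheme == "cvd":
        return (EventDuration.SAME_YEAR, EventDuration.ONE_YEAR_AGO,
                EventDuration.TWO_YEARS_AGO)[delta] if delta <= 2 \
            else EventDuration.THREE_PLUS_YEARS_AGO
    if scheme == "diabetes":
        return DiabetesDuration.LT10Y if delta < 10 else DiabetesDuration.GE10Y
    if delta <= 4:
        return (CancerDuration.SAME_YEAR, CancerDuration.ONE_YEAR_AGO,
                CancerDuration.TWO_YEARS_AGO, CancerDuration.THREE_YEARS_AGO,
                CancerDuration.FOUR_YEARS_AGO)[delta]
    return (CancerDuration.FIVE_TO_TEN_YEARS_AGO if delta < 10
            else CancerDuration.GE10Y)


def extract_features(profile: CovariateProfile, state: AnnualEventState
                     ) -> dict[str, object]:
    """Flatten a (profile, state) pair into the shared feature namespace.

    Categorical features are string levels, booleans become "yes"/"no",
    continuous features are floats.
    """
    yn = lambda b: "yes" if b else "no"
    return {
        "sex": profile.sex.value,
        "ethnicity": profile.ethnicity.value,
        "townsend_quintile": profile.townsend_quintile.value,
        "smoking": profile.smoking.value,
        "physical_activity": profile.physical_activity.value,
        "diet": profile.diet.value,
        "bmi_category": profile.bmi_category.value,
        "ldl_mmol_per_l": profile.ldl_mmol_per_l,
        "hdl_mmol_per_l": profile.hdl_mmol_per_l,
        "creatinine_umol_per_l": profile.creatinine_umol_per_l,
        "sbp_mmhg": profile.sbp_mmhg,
        "dbp_mmhg": profile.dbp_mmhg,
        "on_antihypertensive": yn(profile.on_antihypertensive),
        "severe_mental_illness": yn(profile.severe_mental_illness),
        "prior_type1_diabetes": yn(profile.prior_type1_diabetes),
        "prior_cvd_category": profile.prior_cvd_category.value,
        "current_age_years": state.current_age_years,
        "mi_duration": state.mi_duration.value,
        "stroke_duration": state.stroke_duration.value,
        "crv_duration": state.crv_duration.value,
        "diabetes_duration": state.diabetes_duration.value,
        "cancer_duration": state.cancer_duration.value,
        "vd_this_year": yn(state.vd_this_year),
        "nvd_this_year": yn(state.nvd_this_year),
        "observed_fraction": state.observed_fraction,
    }


def _indicator(features: Mapping[str, object], fld: str,
               levels: Sequence[str], term_name: str) -> float:
    value = features.get(fld)
    if value is None:
        raise KeyError(f"term {term_name!r}: feature {fld!r} missing")
    return 1.0 if value in levels else 0.0


def term_value(term: ModelTerm, features: Mapping[str, object]) -> float:
    """Value of one design entry for a flattened feature map."""
    if term.kind == "intercept":
        return 1.0
    if term.kind == "categorical_level":
        return _indicator(features, term.field, term.levels, term.name)
    if term.kind == "continuous":
        return term.transform.apply(float(features[term.field]))
    if term.kind == "interaction":
        v = 1.0
        for comp in term.components:
            v *= _indicator(features, comp.field, comp.levels, term.name)
        return v
    raise ValueError(f"unknown term kind {term.kind!r}")


def encode_design_row(profile: CovariateProfile, state: AnnualEventState,
                      model: CoefficientSet) -> DesignRow:
    features = extract_features(profile, state)
    return DesignRow(values={t.name: term_value(t, features)
                             for t in model.terms})


def design_matrix(frame, model: CoefficientSet,
                  terms: Optional[Sequence[ModelTerm]] = None
                  ) -> tuple[np.ndarray, list[str]]:
    """Vectorised design matrix for a person-year table.

    ``frame`` is a pandas DataFrame using the shared feature namespace
    (categorical levels as strings, booleans as "yes"/"no"). Returns the
    matrix (one column per model term, in term order) and the term names.
    """
    use = list(terms) if terms is not None else list(model.terms)
    n = len(frame)
    X = np.empty((n, len(use)))
    for j, t in enumerate(use):
        if t.kind == "intercept":
            X[:, j] = 1.0
        elif t.kind == "categorical_level":
            X[:, j] = frame[t.field].isin(t.levels).to_numpy(dtype=float)
        elif t.kind == "continuous":
            x = frame[t.field].to_numpy(dtype=float)
            tr = t.transform
            if tr.type == "linear":
                X[:, j] = (x - tr.center) / tr.scale
            elif tr.type == "log":
                X[:, j] = np.log(x)
            else:
                X[:, j] = (np.log(x) - tr.center) / tr.scale
        elif t.kind == "interaction":
            v = np.ones(n)
            for comp in t.components:
                v *= frame[comp.field].isin(comp.levels).to_numpy(dtype=float)
            X[:, j] = v
        else:
            raise ValueError(f"unknown term kind {t.kind!r}")
    return X, [t.name for t in use]


def _linear_predictor(row: DesignRow, model: CoefficientSet) -> float:
    return sum(t.coefficient * row.values[t.name] for t in model.terms)


def predict_primary_cost(row: DesignRow, model: CoefficientSet
                         ) -> tuple[float, tuple[str, ...]]:
    """Annual primary care cost in pounds with flooring flag.

    Negative linear predictors (possible under the identity link) are
    floored at zero and flagged.
    """
    if model.service is not Service.PRIMARY:
        raise ValueError(f"expected a primary-care model, got "
                         f"{model.service.value}")
    lp = _linear_predictor(row, model)
    if lp < 0:
        return 0.0, (FLAG_FLOORED,)
    return lp, ()


def predict_hospital_cost(
    part1_row: DesignRow,
    part2_row: DesignRow,
    part1: CoefficientSet,
    part2: CoefficientSet,
    features: Optional[Mapping[str, object]] = None,
) -> CostPrediction:
    """Two-part annual hospital cost.

    ``features`` is needed to evaluate the part-1 certainty rules; when
    omitted the rules are checked against the part-1 design row levels.
    """
    if part1.service is not Service.HOSPITAL_PART1:
        raise ValueError("part1 must be a hospital part-1 model")
    if part2.service is not Service.HOSPITAL_PART2:
        raise ValueError("part2 must be a hospital part-2 model")
    if part1.stratum is not part2.stratum:
        raise ValueError("part 1 and part 2 strata differ")

    flags: list[str] = []
    log_odds = _linear_predictor(part1_row, part1)
    if not math.isfinite(log_odds):
        raise ValueError("non-finite part-1 linear predictor")
    odds = math.exp(log_odds)
    p = odds / (1.0 + odds)

    certain = False
    if features is not None:
        certain = any(r.fires(features) for r in part1.certainty_rules)
    else:
        # fall back: a certainty rule fires when a term indicator for the
        # rule's (field, level) is active in the design row
        for r in part1.certainty_rules:
            for t in part1.terms:
                if (t.kind == "categorical_level" and t.field == r.when_field
                        and r.when_level in t.levels
                        and part1_row.values.get(t.name, 0.0) == 1.0):
                    certain = True
    if certain:
        p = 1.0
        flags.append(FLAG_CRV_CERTAIN)

    conditional = _linear_predictor(part2_row, part2)
    if conditional < 0:
        conditional = 0.0
        flags.append(FLAG_FLOORED)
    return CostPrediction(
        primary_gbp=math.nan, hospital_probability=p,
        hospital_conditional_gbp=conditional,
        hospital_gbp=p * conditional, flags=tuple(flags))


def predict_costs(profile: CovariateProfile, state: AnnualEventState,
                  models: Mapping[tuple[CohortStratum, Service],
                                  CoefficientSet],
                  stratum: CohortStratum) -> CostPrediction:
    """Primary + hospital prediction for one annual period."""
    primary = models[(stratum, Service.PRIMARY)]
    part1 = models[(stratum, Service.HOSPITAL_PART1)]
    part2 = models[(stratum, Service.HOSPITAL_PART2)]
    features = extract_features(profile, state)
    prow = DesignRow({t.name: term_value(t, features)
                      for t in primary.terms})
    p1row = DesignRow({t.name: term_value(t, features) for t in part1.terms})
    p2row = DesignRow({t.name: term_value(t, features) for t in part2.terms})
    primary_gbp, pflags = predict_primary_cost(prow, primary)
    hosp = predict_hospital_cost(p1row, p2row, part1, part2,
                                 features=features)
    return replace(hosp, primary_gbp=primary_gbp,
                   flags=tuple(pflags) + hosp.flags)


def annual_states(
    profile: CovariateProfile,
    event_first_years: Mapping[str, Optional[int]],
    horizon_years: int,
) -> list[AnnualEventState]:
    """Derive per-year event states from first-occurrence years.

    ``event_first_years`` may hold keys mi, stroke, crv, diabetes, cancer,
    vd, nvd (values: annual-period index of the first occurrence, or
    None). Durations advance annually; a death year is the final period.
    Baseline prior diabetes/cancer seed the duration clocks from their
    years-since-diagnosis at entry.
    """
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    ev = {k: event_first_years.get(k) for k in
          ("mi", "stroke", "crv", "diabetes", "cancer", "vd", "nvd")}
    unknown = set(event_first_years) - set(ev)
    if unknown:
        raise ValueError(f"unknown event keys {sorted(unknown)!r}")
    if ev["vd"] is not None and ev["nvd"] is not None:
        raise ValueError("at most one of vd/nvd may occur")
    death_year = ev["vd"] if ev["vd"] is not None else ev["nvd"]
    for k, y in ev.items():
        if y is None:
            continue
        if y < 0:
            raise ValueError(f"{k} first year is negative")
        if death_year is not None and y > death_year:
            raise ValueError(f"{k} at year {y} occurs after death year "
                             f"{death_year}")
    if (profile.prior_type1_diabetes or profile.prior_type2_diabetes) and \
            ev["diabetes"] is not None:
        raise ValueError("incident diabetes conflicts with prior diabetes "
                         "at entry")
    if profile.prior_cancer and ev["cancer"] is not None:
        raise ValueError("incident cancer conflicts with prior cancer at "
                         "entry")

    # offset the duration clocks for conditions present at entry
    diab_entry = (profile.years_since_diabetes_diagnosis_at_entry
                  if (profile.prior_type1_diabetes
                      or profile.prior_type2_diabetes) else None)
    cancer_entry = (profile.years_since_cancer_diagnosis_at_entry
                    if profile.prior_cancer else None)

    def cat(first_year: Optional[int], year: int, kind: str):
        # before the first occurrence the state is "no event"
        if first_year is None or year < first_year:
            return duration_category(None, year, kind)
        return duration_category(first_year, year, kind)

    states = []
    for year in range(horizon_years):
        if death_year is not None and year > death_year:
            break
        if diab_entry is not None:
            diabetes = (DiabetesDuration.LT10Y
                        if diab_entry + year < 10 else DiabetesDuration.GE10Y)
        else:
            diabetes = cat(ev["diabetes"], year, "diabetes")
        if cancer_entry is not None:
            years_since = int(cancer_entry) + year
            cancer = duration_category(0, years_since, "cancer")
        else:
            cancer = cat(ev["cancer"], year, "cancer")
        states.append(AnnualEventState(
            year_index=year,
            current_age_years=profile.age_at_entry_years + year,
            mi_duration=cat(ev["mi"], year, "mi"),
            stroke_duration=cat(ev["stroke"], year, "stroke"),
            crv_duration=cat(ev["crv"], year, "crv"),
            diabetes_duration=diabetes,
            cancer_duration=cancer,
            vd_this_year=(ev["vd"] == year),
            nvd_this_year=(ev["nvd"] == year),
        ))
    return states


def predict_trajectory(
    profile: CovariateProfile,
    event_first_years: Mapping[str, Optional[int]],
    horizon_years: int,
    models: Mapping[tuple[CohortStratum, Service], CoefficientSet],
    stratum: CohortStratum,
    validate: bool = True,
) -> list[CostPrediction]:
    """Per-year cost predictions from entry, truncated at the death year."""
    if validate:
        validate_profile(profile, stratum)
    states = annual_states(profile, event_first_years, horizon_years)
    return [predict_costs(profile, s, models, stratum) for s in states]
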