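"""Domain types and published coefficient fixtures.

The package ships one JSON fixture encoding the published annual-cost
models: a one-part identity-link Poisson GLM for primary care costs and a
two-part model (logistic "any cost" part plus identity-link Poisson
conditional-cost part) for hospital costs, each estimated separately for
people without and with previous cardiovascular disease (CVD).

Coefficients are stored exactly as printed (additive 2020 UK pounds for
cost parts; odds ratios for the logistic part). Temporal categories that
were merged during model selection carry ``merged_with_preceding=True``
and resolve, at load time, to the coefficient of the preceding temporal
category of the same covariate.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "CohortStratum", "Sex", "Ethnicity", "TownsendQuintile", "Smoking",
    "PhysicalActivity", "Diet", "BmiCategory", "PriorCvd", "EventDuration",
    "DiabetesDuration", "CancerDuration", "Service", "Transform",
    "InteractionComponent", "ModelTerm", "CoefficientSet", "CertaintyRule",
    "CovariateProfile", "AnnualEventState", "ProfileValidationError",
    "FixtureValidationError", "load_published_models",
    "default_fixture_path", "fixture_checksum", "validate_profile",
    "reference_profile", "reference_state", "serialise_models",
    "FEATURE_FIELDS",
]


class CohortStratum(str, enum.Enum):
    WITHOUT_CVD = "without_cvd"
    WITH_CVD = "with_cvd"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Ethnicity(str, enum.Enum):
    WHITE = "white"
    BLACK = "black"
    SOUTH_ASIAN = "south_asian"
    OTHER = "other"
    MISSING = "missing"


class TownsendQuintile(str, enum.Enum):
    Q1 = "q1"
    Q2 = "q2"
    Q3 = "q3"
    Q4 = "q4"
    Q5 = "q5"


class Smoking(str, enum.Enum):
    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"


class PhysicalActivity(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    MISSING = "missing"


class Diet(str, enum.Enum):
    HEALTHY = "healthy"
    UNHEALTHY = "unhealthy"


class BmiCategory(str, enum.Enum):
    LT18_5 = "lt18.5"
    FROM18_5_TO25 = "18.5to25"
    FROM25_TO30 = "25to30"
    FROM30_TO35 = "30to35"
    FROM35_TO40 = "35to40"
    GE40 = "ge40"


class PriorCvd(str, enum.Enum):
    NONE = "none"
    MI_ONLY = "mi_only"
    STROKE_ONLY = "stroke_only"
    PAD_ONLY = "pad_only"
    OTHER_CHD_ONLY = "other_chd_only"
    TWO_OR_MORE = "two_or_more"


class EventDuration(str, enum.Enum):
    """Five-level time-since-first-event category for MI, stroke and CRV."""

    NONE = "none"
    SAME_YEAR = "same_year"
    ONE_YEAR_AGO = "one_year_ago"
    TWO_YEARS_AGO = "two_years_ago"
    THREE_PLUS_YEARS_AGO = "three_plus_years_ago"


class DiabetesDuration(str, enum.Enum):
    NONE = "none"
    LT10Y = "lt10y"
    GE10Y = "ge10y"


class CancerDuration(str, enum.Enum):
    NONE = "none"
    SAME_YEAR = "same_year"
    ONE_YEAR_AGO = "one_year_ago"
    TWO_YEARS_AGO = "two_years_ago"
    THREE_YEARS_AGO = "three_years_ago"
    FOUR_YEARS_AGO = "four_years_ago"
    FIVE_TO_TEN_YEARS_AGO = "five_to_ten_years_ago"
    GE10Y = "ge10y"


class Service(str, enum.Enum):
    PRIMARY = "primary"
    HOSPITAL_PART1 = "hospital_part1"
    HOSPITAL_PART2 = "hospital_part2"


# Feature namespace shared by the encoder, the simulator panel and the
# estimator design builder. Categorical fields map to string levels;
# boolean fields map to "yes"/"no".
FEATURE_FIELDS = {
    "sex": "categorical",
    "ethnicity": "categorical",
    "townsend_quintile": "categorical",
    "smoking": "categorical",
    "physical_activity": "categorical",
    "diet": "categorical",
    "bmi_category": "categorical",
    "ldl_mmol_per_l": "continuous",
    "hdl_mmol_per_l": "continuous",
    "creatinine_umol_per_l": "continuous",
    "sbp_mmhg": "continuous",
    "dbp_mmhg": "continuous",
    "on_antihypertensive": "categorical",
    "severe_mental_illness": "categorical",
    "prior_type1_diabetes": "categorical",
    "prior_cvd_category": "categorical",
    "current_age_years": "continuous",
    "mi_duration": "categorical",
    "stroke_duration": "categorical",
    "crv_duration": "categorical",
    "diabetes_duration": "categorical",
    "cancer_duration": "categorical",
    "vd_this_year": "categorical",
    "nvd_this_year": "categorical",
    "observed_fraction": "continuous",
}


class FixtureValidationError(ValueError):
    """Raised when a coefficient fixture violates the schema."""


class ProfileValidationError(ValueError):
    """Raised for hard covariate-profile errors."""


@dataclass(frozen=True)
class Transform:
    """Continuous covariate transform.

    ``linear``      -> (x - center) / scale
    ``log``         -> ln(x)
    ``log_linear``  -> (ln(x) - center) / scale
    """

    type: str
    center: float = 0.0
    scale: float = 1.0

    def apply(self, x: float) -> float:
        if self.type == "linear":
            return (x - self.center) / self.scale
        if self.type == "log":
            return math.log(x)
        if self.type == "log_linear":
            return (math.log(x) - self.center) / self.scale
        raise FixtureValidationError(f"unknown transform type {self.type!r}")


@dataclass(frozen=True)
class InteractionComponent:
    field: str
    levels: tuple[str, ...]


@dataclass(frozen=True)
class ModelTerm:
    name: str
    group: str
    kind: str  # intercept | categorical_level | continuous | interaction
    coefficient: float  # additive GBP, or log-odds for the logistic part
    se: Optional[float] = None
    field: Optional[str] = None
    levels: tuple[str, ...] = ()
    transform: Optional[Transform] = None
    components: tuple[InteractionComponent, ...] = ()
    merged_with_preceding: bool = False
    odds_ratio: Optional[float] = None  # as printed, logistic part only

    def source_fields(self) -> tuple[str, ...]:
        if self.kind == "interaction":
            return tuple(c.field for c in self.components)
        if self.field is not None:
            return (self.field,)
        return ()


@dataclass(frozen=True)
class CertaintyRule:
    """Part-1 override: incurring cost is certain in given state."""

    when_field: str
    when_level: str
    probability: float = 1.0

    def fires(self, features: dict) -> bool:
        return features.get(self.when_field) == self.when_level


@dataclass(frozen=True)
class CoefficientSet:
    stratum: CohortStratum
    service: Service
    scale: str  # additive_gbp | log_odds
    terms: tuple[ModelTerm, ...]
    certainty_rules: tuple[CertaintyRule, ...] = ()
    price_year: int = 2020

    @property
    def intercept(self) -> ModelTerm:
        return self.terms[0]

    def non_intercept_terms(self) -> tuple[ModelTerm, ...]:
        return self.terms[1:]

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline characteristics in model-ready semantic form."""

    sex: Sex = Sex.FEMALE
    ethnicity: Ethnicity = Ethnicity.WHITE
    townsend_quintile: TownsendQuintile = TownsendQuintile.Q3
    smoking: Smoking = Smoking.NEVER
    physical_activity: PhysicalActivity = PhysicalActivity.MODERATE
    diet: Diet = Diet.HEALTHY
    bmi_category: BmiCategory = BmiCategory.FROM18_5_TO25
    ldl_mmol_per_l: float = 3.6
    hdl_mmol_per_l: float = 1.0
    creatinine_umol_per_l: float = math.exp(4.4)  # 81.45, prints as 81.5
    sbp_mmhg: float = 140.0
    dbp_mmhg: float = 80.0
    on_antihypertensive: bool = False
    severe_mental_illness: bool = False
    prior_type1_diabetes: bool = False
    prior_type2_diabetes: bool = False
    years_since_diabetes_diagnosis_at_entry: Optional[float] = None
    prior_cancer: bool = False
    years_since_cancer_diagnosis_at_entry: Optional[float] = None
    prior_cvd_category: PriorCvd = PriorCvd.NONE
    age_at_entry_years: float = 60.0


@dataclass(frozen=True)
class AnnualEventState:
    """Time-updated state for one annual period."""

    year_index: int
    current_age_years: float
    mi_duration: EventDuration = EventDuration.NONE
    stroke_duration: EventDuration = EventDuration.NONE
    crv_duration: EventDuration = EventDuration.NONE
    diabetes_duration: DiabetesDuration = DiabetesDuration.NONE
    cancer_duration: CancerDuration = CancerDuration.NONE
    vd_this_year: bool = False
    nvd_this_year: bool = False
    observed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.vd_this_year and self.nvd_this_year:
            raise ValueError("vd_this_year and nvd_this_year both set")
        if not (0.0 < self.observed_fraction <= 1.0):
            raise ValueError("observed_fraction must be in (0, 1]")


# ------------------------------------------------------------------ fixtures

def default_fixture_path() -> Path:
    return Path(resources.files("cvcost").joinpath(
        "fixtures/published_models.json"))


def fixture_checksum(path: Optional[Path] = None) -> str:
    p = Path(path) if path is not None else default_fixture_path()
    return hashlib.sha256(p.read_bytes()).hexdigest()


def _parse_transform(raw: Optional[dict]) -> Optional[Transform]:
    if raw is None:
        return None
    return Transform(type=raw["type"], center=float(raw.get("center", 0.0)),
                     scale=float(raw.get("scale", 1.0)))


def _parse_term(raw: dict, scale: str, model_name: str) -> ModelTerm:
    kind = raw["kind"]
    merged = bool(raw.get("merged_with_preceding", False))
    if scale == "log_odds":
        if kind == "intercept":
            odds = float(raw["odds"])
            coef, or_printed = math.log(odds), odds
        elif merged:
            coef, or_printed = math.nan, None
        else:
            or_printed = float(raw["odds_ratio"])
            if or_printed <= 0:
                raise FixtureValidationError(
                    f"{model_name}: non-positive odds ratio in "
                    f"{raw.get('name')!r}")
            coef = math.log(or_printed)
        se = None
    else:
        coef = math.nan if merged else float(raw["coefficient"])
        se = raw.get("se")
        se = None if se is None else float(se)
        or_printed = None
    components = tuple(
        InteractionComponent(c["field"], tuple(c["levels"]))
        for c in raw.get("components", ()))
    return ModelTerm(
        name=raw["name"], group=raw.get("group", raw["name"]), kind=kind,
        coefficient=coef, se=se, field=raw.get("field"),
        levels=tuple(raw.get("levels", ())),
        transform=_parse_transform(raw.get("transform")),
        components=components, merged_with_preceding=merged,
        odds_ratio=or_printed)


def _resolve_merged(terms: list[ModelTerm], model_name: str
                    ) -> list[ModelTerm]:
    resolved: list[ModelTerm] = []
    for t in terms:
        if not t.merged_with_preceding:
            resolved.append(t)
            continue
        prev = resolved[-1] if resolved else None
        if prev is None or prev.field != t.field:
            raise FixtureValidationError(
                f"{model_name}: term {t.name!r} marked merged but has no "
                "preceding term for the same covariate")
        resolved.append(replace(t, coefficient=prev.coefficient, se=prev.se,
                                odds_ratio=prev.odds_ratio))
    return resolved


def _validate_set(cs: CoefficientSet, model_name: str) -> None:
    if cs.terms[0].kind != "intercept":
        raise FixtureValidationError(f"{model_name}: first term must be the "
                                     "intercept")
    n_intercepts = sum(1 for t in cs.terms if t.kind == "intercept")
    if n_intercepts != 1:
        raise FixtureValidationError(
            f"{model_name}: expected exactly one intercept, got "
            f"{n_intercepts}")
    seen: set[str] = set()
    for t in cs.terms:
        if t.name in seen:
            raise FixtureValidationError(
                f"{model_name}: duplicate term {t.name!r}")
        seen.add(t.name)
        for f in t.source_fields():
            if f not in FEATURE_FIELDS:
                raise FixtureValidationError(
                    f"{model_name}: term {t.name!r} references unknown "
                    f"field {f!r}")
        if t.kind == "categorical_level" and not t.levels:
            raise FixtureValidationError(
                f"{model_name}: categorical term {t.name!r} has no levels")
        if t.kind == "continuous" and t.transform is None:
            raise FixtureValidationError(
                f"{model_name}: continuous term {t.name!r} has no transform")
        if not math.isfinite(t.coefficient):
            raise FixtureValidationError(
                f"{model_name}: non-finite coefficient in {t.name!r}")
    # no duplicate (field, level) indicator pairs among plain categoricals
    pairs: set[tuple[str, str]] = set()
    for t in cs.terms:
        if t.kind != "categorical_level":
            continue
        for lv in t.levels:
            if (t.field, lv) in pairs:
                raise FixtureValidationError(
                    f"{model_name}: level {lv!r} of {t.field!r} covered by "
                    "more than one term")
            pairs.add((t.field, lv))


def load_published_models(fixture_path: Optional[Path] = None
                          ) -> dict[tuple[CohortStratum, Service],
                                    CoefficientSet]:
    """Load the coefficient fixture into six validated coefficient sets.

    Returns a map keyed by ``(stratum, service)``. Merged temporal
    categories are resolved to the preceding category's value; logistic
    odds ratios are converted to log-odds coefficients (the printed OR is
    retained on each term).
    """
    path = Path(fixture_path) if fixture_path else default_fixture_path()
    raw = json.loads(path.read_text())
    if raw.get("schema_version") != 1:
        raise FixtureValidationError(
            f"unsupported schema_version {raw.get('schema_version')!r}")
    models: dict[tuple[CohortStratum, Service], CoefficientSet] = {}
    for m in raw["models"]:
        stratum = CohortStratum(m["stratum"])
        service = Service(m["service"])
        name = f"{stratum.value}/{service.value}"
        scale = m["scale"]
        expected = ("log_odds" if service is Service.HOSPITAL_PART1
                    else "additive_gbp")
        if scale != expected:
            raise FixtureValidationError(
                f"{name}: scale {scale!r}, expected {expected!r}")
        terms = _resolve_merged(
            [_parse_term(t, scale, name) for t in m["terms"]], name)
        rules = tuple(CertaintyRule(r["when_field"], r["when_level"],
                                    float(r.get("probability", 1.0)))
                      for r in m.get("certainty_rules", ()))
        cs = CoefficientSet(
            stratum=stratum, service=service, scale=scale,
            terms=tuple(terms), certainty_rules=rules,
            price_year=int(raw.get("price_year", 2020)))
        _validate_set(cs, name)
        if (stratum, service) in models:
            raise FixtureValidationError(f"{name}: listed twice")
        models[(stratum, service)] = cs
    if len(models) != 6:
        raise FixtureValidationError(
            f"expected 6 coefficient sets, got {len(models)}")
    return models


def serialise_models(models: dict[tuple[CohortStratum, Service],
                                  CoefficientSet]) -> dict:
    """Inverse of :func:`load_published_models` (resolved coefficients)."""
    out = {"schema_version": 1, "price_year": 2020, "currency": "GBP",
           "models": []}
    for (_, _), cs in sorted(models.items(),
                             key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        terms = []
        for t in cs.terms:
            d: dict = {"name": t.name, "group": t.group, "kind": t.kind}
            if t.field is not None:
                d["field"] = t.field
            if t.levels:
                d["levels"] = list(t.levels)
            if t.transform is not None:
                d["transform"] = {"type": t.transform.type,
                                  "center": t.transform.center,
                                  "scale": t.transform.scale}
            if t.components:
                d["components"] = [{"field": c.field,
                                    "levels": list(c.levels)}
                                   for c in t.components]
            if cs.scale == "log_odds":
                if t.kind == "intercept":
                    d["odds"] = (t.odds_ratio if t.odds_ratio is not None
                                 else math.exp(t.coefficient))
                else:
                    d["odds_ratio"] = (t.odds_ratio if t.odds_ratio is not
                                       None else math.exp(t.coefficient))
            else:
                d["coefficient"] = t.coefficient
                if t.se is not None:
                    d["se"] = t.se
            terms.append(d)
        out["models"].append({
            "stratum": cs.stratum.value, "service": cs.service.value,
            "scale": cs.scale,
            "certainty_rules": [{"when_field": r.when_field,
                                 "when_level": r.when_level,
                                 "probability": r.probability}
                                for r in cs.certainty_rules],
            "terms": terms})
    return out


# ------------------------------------------------------------------ profiles

def reference_profile(stratum: CohortStratum = CohortStratum.WITHOUT_CVD
                      ) -> CovariateProfile:
    """The reference individual: a 60-year-old white woman in Townsend
    quintile 3 who never smoked, with moderate physical activity, healthy
    diet, BMI 18.5-25, LDL 3.6 mmol/L, HDL 1 mmol/L, creatinine ~81.5
    umol/L, blood pressure 140/80 mmHg, no treatment and no histories.
    In the with-CVD stratum her only history is prior MI.
    """
    prior = (PriorCvd.MI_ONLY if stratum is CohortStratum.WITH_CVD
             else PriorCvd.NONE)
    return CovariateProfile(prior_cvd_category=prior)


def reference_state(year_index: int = 0, age: float = 60.0
                    ) -> AnnualEventState:
    return AnnualEventState(year_index=year_index, current_age_years=age)


def validate_profile(profile: CovariateProfile, stratum: CohortStratum
                     ) -> list[str]:
    """Check a profile for use with the given stratum's models.

    Returns a list of warnings for recoverable issues; raises
    :class:`ProfileValidationError` for hard errors (inconsistent prior-CVD
    history or biomarkers outside the domain of their transforms).
    """
    if stratum is CohortStratum.WITH_CVD:
        if profile.prior_cvd_category is PriorCvd.NONE:
            raise ProfileValidationError(
                "with_cvd stratum requires a prior CVD category")
    elif profile.prior_cvd_category is not PriorCvd.NONE:
        raise ProfileValidationError(
            "without_cvd stratum requires prior_cvd_category = none")
    if profile.hdl_mmol_per_l <= 0:
        raise ProfileValidationError("HDL must be positive (its log is "
                                     "taken)")
    if profile.creatinine_umol_per_l <= 0:
        raise ProfileValidationError("creatinine must be positive")
    if profile.ldl_mmol_per_l < 0:
        raise ProfileValidationError("LDL must be non-negative")
    if profile.sbp_mmhg <= 0 or profile.dbp_mmhg <= 0:
        raise ProfileValidationError("blood pressures must be positive")
    if not (18.0 <= profile.age_at_entry_years <= 110.0):
        raise ProfileValidationError("age at entry outside [18, 110]")
    if (profile.prior_type1_diabetes or profile.prior_type2_diabetes) and \
            profile.years_since_diabetes_diagnosis_at_entry is None:
        raise ProfileValidationError(
            "prior diabetes requires years_since_diabetes_diagnosis_at_entry")
    if profile.prior_cancer and \
            profile.years_since_cancer_diagnosis_at_entry is None:
        raise ProfileValidationError(
            "prior cancer requires years_since_cancer_diagnosis_at_entry")

    warnings: list[str] = []
    if profile.ethnicity is Ethnicity.MISSING:
        warnings.append("ethnicity 'missing' has no published coefficient; "
                        "treated as the reference level (white)")
    if not (0.5 <= profile.ldl_mmol_per_l <= 10.0):
        warnings.append(f"LDL {profile.ldl_mmol_per_l} mmol/L outside the "
                        "plausible range 0.5-10")
    if not (0.3 <= profile.hdl_mmol_per_l <= 5.0):
        warnings.append(f"HDL {profile.hdl_mmol_per_l} mmol/L outside the "
                        "plausible range 0.3-5")
    if not (20.0 <= profile.creatinine_umol_per_l <= 400.0):
        warnings.append(f"creatinine {profile.creatinine_umol_per_l} umol/L "
                        "outside the plausible range 20-400")
    if not (70.0 <= profile.sbp_mmhg <= 250.0):
        warnings.append(f"SBP {profile.sbp_mmhg} mmHg outside the plausible "
                        "range 70-250")
    if not (40.0 <= profile.dbp_mmhg <= 150.0):
        warnings.append(f"DBP {profile.dbp_mmhg} mmHg outside the plausible "
                        "range 40-150")
    if profile.prior_type1_diabetes and profile.prior_type2_diabetes:
        warnings.append("both type 1 and type 2 prior diabetes flagged")
    return warnings
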