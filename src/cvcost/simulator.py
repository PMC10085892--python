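"""Synthetic cohort and person-year cost panel generation.

Baseline covariates follow the published baseline marginal distributions
(hospital-analysis columns) per stratum; first-occurrence events fire with
constant annual hazards (optional log-linear age modifier) with death
absorbing; annual costs are generated from the published model means: the
primary-care and conditional hospital costs from a positive noise family
(gamma or lognormal) around the identity-link linear predictor, and the
any-hospital-cost indicator from the part-1 probability, honouring the
same-year-revascularization certainty rule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_spec import (
    AnnualEventState,
    BmiCategory,
    CohortStratum,
    CoefficientSet,
    CovariateProfile,
    Diet,
    Ethnicity,
    PhysicalActivity,
    PriorCvd,
    Service,
    Sex,
    Smoking,
    TownsendQuintile,
)
from .predictor import annual_states, design_matrix, extract_features

__all__ = [
    "SimulationConfig", "AdmissionRecord", "PersonYearPanel",
    "BASELINE_MARGINALS", "sample_baseline", "simulate_events",
    "simulate_costs", "simulate_panel", "allocate_admission_cost",
    "apply_registration_gaps",
]

EVENT_KEYS = ("mi", "stroke", "crv", "diabetes", "cancer", "vd", "nvd")

# Baseline marginal distributions per stratum (proportions over observed
# levels; continuous biomarkers as mean/SD of normals truncated to > 0).
BASELINE_MARGINALS: dict[str, dict] = {
    "without_cvd": {
        "male": 0.439,
        "ethnicity": {"white": 0.940, "black": 0.016, "south_asian": 0.016,
                      "other": 0.022, "missing": 0.005},
        "townsend": {"q1": 0.374, "q2": 0.201, "q3": 0.163, "q4": 0.145,
                     "q5": 0.117},
        "smoking": {"never": 0.559, "former": 0.332, "current": 0.103},
        "physical_activity": {"low": 0.148, "moderate": 0.329, "high": 0.327,
                              "missing": 0.196},
        "diet_unhealthy": 0.335 / (0.643 + 0.335),
        "bmi": {"lt18.5": 0.005, "18.5to25": 0.335, "25to30": 0.423,
                "30to35": 0.167, "35to40": 0.046, "ge40": 0.018},
        "age": (56.0, 8.1),
        "ldl": (3.6, 0.8), "hdl": (1.5, 0.4), "creatinine": (71.5, 15.1),
        "sbp": (137.8, 18.6), "dbp": (82.4, 10.1),
        "antihypertensive": 0.162,
        "prior_t1d": 0.006, "prior_t2d": 0.043,
        "prior_cancer": 0.074, "smi": 0.081,
        "prior_cvd": {"none": 1.0},
    },
    "with_cvd": {
        "male": 0.589,
        "ethnicity": {"white": 0.945, "black": 0.013, "south_asian": 0.018,
                      "other": 0.017, "missing": 0.006},
        "townsend": {"q1": 0.331, "q2": 0.191, "q3": 0.157, "q4": 0.160,
                     "q5": 0.160},
        "smoking": {"never": 0.434, "former": 0.436, "current": 0.121},
        "physical_activity": {"low": 0.176, "moderate": 0.309, "high": 0.293,
                              "missing": 0.222},
        "diet_unhealthy": 0.352 / (0.621 + 0.352),
        "bmi": {"lt18.5": 0.004, "18.5to25": 0.233, "25to30": 0.417,
                "30to35": 0.228, "35to40": 0.075, "ge40": 0.032},
        "age": (60.4, 7.0),
        "ldl": (3.1, 0.9), "hdl": (1.3, 0.4), "creatinine": (77.0, 19.8),
        "sbp": (138.9, 18.9), "dbp": (80.9, 10.5),
        "antihypertensive": 0.457,
        "prior_t1d": 0.024, "prior_t2d": 0.119,
        "prior_cancer": 0.102, "smi": 0.110,
        "prior_cvd": {"mi_only": 0.036, "stroke_only": 0.090,
                      "pad_only": 0.119, "other_chd_only": 0.506,
                      "two_or_more": 0.250},
    },
}

DEFAULT_HAZARDS = {"mi": 0.002, "stroke": 0.0017, "crv": 0.0025,
                   "diabetes": 0.003, "cancer": 0.0095,
                   "vd": 0.0009, "nvd": 0.0033}


@dataclass
class SimulationConfig:
    n_participants: int = 1000
    horizon_years: int = 7
    stratum_mix: float = 0.114  # proportion with previous CVD
    hazards: dict = dc_field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    hazards_with_cvd: Optional[dict] = None
    age_log_hazard_slope: float = 0.0  # per 10 years over age 60
    primary_noise: str = "gamma"  # gamma | lognormal
    primary_dispersion: float = 0.5
    hospital_noise: str = "gamma"
    hospital_dispersion: float = 0.5
    registration_gap_probability: float = 0.0
    mean_floor_gbp: float = 1.0  # floor for non-positive generative means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not (0.0 <= self.stratum_mix <= 1.0):
            raise ValueError("stratum_mix must be in [0, 1]")
        if not (0.0 <= self.registration_gap_probability < 1.0):
            raise ValueError("registration_gap_probability must be in [0,1)")
        if self.primary_dispersion <= 0 or self.hospital_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for k, v in self.hazards.items():
            if k not in EVENT_KEYS:
                raise ValueError(f"unknown event {k!r} in hazards")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"hazard for {k!r} outside [0, 1]")

    def hazard_map(self, stratum: CohortStratum) -> dict:
        h = dict(DEFAULT_HAZARDS)
        h.update(self.hazards)
        if stratum is CohortStratum.WITH_CVD and self.hazards_with_cvd:
            h.update(self.hazards_with_cvd)
        return h


@dataclass(frozen=True)
class AdmissionRecord:
    person_id: int
    admission: date
    discharge: date
    total_cost_gbp: float

    def __post_init__(self) -> None:
        if self.discharge < self.admission:
            raise ValueError("discharge before admission")
        if self.total_cost_gbp < 0:
            raise ValueError("cost must be non-negative")


@dataclass
class PersonYearPanel:
    """Person-year records with costs; one row per annual period."""

    data: pd.DataFrame
    seed: Optional[int] = None

    def to_csv(self, path: Path) -> None:
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: Path) -> "PersonYearPanel":
        seed = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# seed="):
            seed = int(first.strip().split("=", 1)[1])
        df = pd.read_csv(path, comment="#",
                         keep_default_na=False, na_values=[""])
        return cls(data=df, seed=seed)


def _pick(rng: np.random.Generator, n: int, probs: Mapping[str, float]
          ) -> np.ndarray:
    levels = list(probs)
    p = np.asarray([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


def _trunc_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                  lower: float = 1e-6) -> np.ndarray:
    x = rng.normal(mean, sd, size=n)
    bad = x <= lower
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= lower
    return x


def sample_baseline(n: int, stratum: CohortStratum, seed: int = 0,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[CovariateProfile]:
    """Draw baseline covariate profiles from the stratum's marginals.

    Covariates are sampled independently (no correlation structure);
    biomarkers come from truncated normals. Years since diagnosis for
    conditions prevalent at entry are uniform on [0, 15).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = BASELINE_MARGINALS[stratum.value]
    male = rng.random(n) < m["male"]
    eth = _pick(rng, n, m["ethnicity"])
    town = _pick(rng, n, m["townsend"])
    smoking = _pick(rng, n, m["smoking"])
    pa = _pick(rng, n, m["physical_activity"])
    unhealthy = rng.random(n) < m["diet_unhealthy"]
    bmi = _pick(rng, n, m["bmi"])
    age = np.clip(rng.normal(*m["age"], size=n), 40.0, 70.0)
    ldl = _trunc_normal(rng, n, *m["ldl"])
    hdl = _trunc_normal(rng, n, *m["hdl"], lower=0.05)
    creat = _trunc_normal(rng, n, *m["creatinine"], lower=5.0)
    sbp = _trunc_normal(rng, n, *m["sbp"], lower=50.0)
    dbp = _trunc_normal(rng, n, *m["dbp"], lower=30.0)
    aht = rng.random(n) < m["antihypertensive"]
    u = rng.random(n)
    t1d = u < m["prior_t1d"]
    t2d = (~t1d) & (u < m["prior_t1d"] + m["prior_t2d"])
    diab_years = rng.uniform(0.0, 15.0, size=n)
    cancer = rng.random(n) < m["prior_cancer"]
    cancer_years = rng.uniform(0.0, 15.0, size=n)
    smi = rng.random(n) < m["smi"]
    cvd_cat = _pick(rng, n, m["prior_cvd"])

    profiles = []
    for i in range(n):
        profiles.append(CovariateProfile(
            sex=Sex.MALE if male[i] else Sex.FEMALE,
            ethnicity=Ethnicity(eth[i]),
            townsend_quintile=TownsendQuintile(town[i]),
            smoking=Smoking(smoking[i]),
            physical_activity=PhysicalActivity(pa[i]),
            diet=Diet.UNHEALTHY if unhealthy[i] else Diet.HEALTHY,
            bmi_category=BmiCategory(bmi[i]),
            ldl_mmol_per_l=float(ldl[i]),
            hdl_mmol_per_l=float(hdl[i]),
            creatinine_umol_per_l=float(creat[i]),
            sbp_mmhg=float(sbp[i]),
            dbp_mmhg=float(dbp[i]),
            on_antihypertensive=bool(aht[i]),
            severe_mental_illness=bool(smi[i]),
            prior_type1_diabetes=bool(t1d[i]),
            prior_type2_diabetes=bool(t2d[i]),
            years_since_diabetes_diagnosis_at_entry=(
                float(diab_years[i]) if (t1d[i] or t2d[i]) else None),
            prior_cancer=bool(cancer[i]),
            years_since_cancer_diagnosis_at_entry=(
                float(cancer_years[i]) if cancer[i] else None),
            prior_cvd_category=PriorCvd(cvd_cat[i]),
            age_at_entry_years=float(age[i]),
        ))
    return profiles


def simulate_events(cohort: Sequence[CovariateProfile],
                    config: SimulationConfig,
                    stratum: CohortStratum = CohortStratum.WITHOUT_CVD,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[dict[str, Optional[int]]]:
    """First-occurrence years per person; death years are absorbing.

    Each not-yet-occurred event fires independently per year with its
    hazard; at most one death occurs (vascular drawn first). Non-fatal
    events may co-occur with death in the death year; no event occurs
    after it. Prevalent diabetes/cancer at entry suppress the respective
    incident event.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(cohort)
    h = config.hazard_map(stratum)
    age0 = np.asarray([p.age_at_entry_years for p in cohort])
    prior_diab = np.asarray([p.prior_type1_diabetes or p.prior_type2_diabetes
                             for p in cohort])
    prior_cancer = np.asarray([p.prior_cancer for p in cohort])

    first: dict[str, np.ndarray] = {k: np.full(n, -1, dtype=int)
                                    for k in EVENT_KEYS}
    alive = np.ones(n, dtype=bool)
    for year in range(config.horizon_years):
        if config.age_log_hazard_slope != 0.0:
            mod = np.exp(config.age_log_hazard_slope
                         * (age0 + year - 60.0) / 10.0)
        else:
            mod = 1.0
        for k in ("mi", "stroke", "crv", "diabetes", "cancer"):
            hazard = np.minimum(h[k] * mod, 1.0)
            can_fire = alive & (first[k] < 0)
            if k == "diabetes":
                can_fire &= ~prior_diab
            elif k == "cancer":
                can_fire &= ~prior_cancer
            fire = can_fire & (rng.random(n) < hazard)
            first[k][fire] = year
        vd_fire = alive & (rng.random(n) < np.minimum(h["vd"] * mod, 1.0))
        nvd_fire = (alive & ~vd_fire
                    & (rng.random(n) < np.minimum(h["nvd"] * mod, 1.0)))
        first["vd"][vd_fire] = year
        first["nvd"][nvd_fire] = year
        alive &= ~(vd_fire | nvd_fire)
    return [{k: (int(first[k][i]) if first[k][i] >= 0 else None)
             for k in EVENT_KEYS} for i in range(n)]


def _positive_noise(rng: np.random.Generator, mean: np.ndarray,
                    family: str, dispersion: float) -> np.ndarray:
    if family == "gamma":
        shape = 1.0 / dispersion
        return rng.gamma(shape, mean / shape)
    if family == "lognormal":
        sigma = np.sqrt(np.log1p(dispersion))
        return rng.lognormal(np.log(mean) - sigma ** 2 / 2.0, sigma)
    raise ValueError(f"unknown noise family {family!r}")


def simulate_costs(cohort: Sequence[CovariateProfile],
                   events: Sequence[dict],
                   models: Mapping[tuple[CohortStratum, Service],
                                   CoefficientSet],
                   config: SimulationConfig,
                   stratum: CohortStratum = CohortStratum.WITHOUT_CVD,
                   rng: Optional[np.random.Generator] = None,
                   first_person_id: int = 0) -> PersonYearPanel:
    """Generate the person-year panel of annual costs for one stratum."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for i, (profile, ev) in enumerate(zip(cohort, events)):
        for state in annual_states(profile, ev, config.horizon_years):
            feats = extract_features(profile, state)
            feats["person_id"] = first_person_id + i
            feats["year_index"] = state.year_index
            feats["stratum"] = stratum.value
            rows.append(feats)
    df = pd.DataFrame(rows)

    primary = models[(stratum, Service.PRIMARY)]
    part1 = models[(stratum, Service.HOSPITAL_PART1)]
    part2 = models[(stratum, Service.HOSPITAL_PART2)]
    floor = config.mean_floor_gbp

    Xp, _ = design_matrix(df, primary)
    mean_primary = np.maximum(
        Xp @ np.asarray([t.coefficient for t in primary.terms]), floor)
    if not np.all(np.isfinite(mean_primary)):
        raise ValueError("non-finite primary-care generative mean")
    df["primary_gbp"] = _positive_noise(rng, mean_primary,
                                        config.primary_noise,
                                        config.primary_dispersion)

    X1, _ = design_matrix(df, part1)
    log_odds = X1 @ np.asarray([t.coefficient for t in part1.terms])
    p_any = 1.0 / (1.0 + np.exp(-log_odds))
    for rule in part1.certainty_rules:
        p_any = np.where(df[rule.when_field] == rule.when_level,
                         rule.probability, p_any)
    any_cost = rng.random(len(df)) < p_any

    X2, _ = design_matrix(df, part2)
    mean_cond = np.maximum(
        X2 @ np.asarray([t.coefficient for t in part2.terms]), floor)
    if not np.all(np.isfinite(mean_cond)):
        raise ValueError("non-finite hospital generative mean")
    cond = _positive_noise(rng, mean_cond, config.hospital_noise,
                           config.hospital_dispersion)
    df["hospital_any"] = np.where(any_cost, "yes", "no")
    df["hospital_gbp"] = np.where(any_cost, cond, 0.0)
    df["primary_excluded"] = "no"
    front = ["person_id", "year_index", "stratum"]
    df = df[front + [c for c in df.columns if c not in front]]
    return PersonYearPanel(data=df, seed=config.seed)


def simulate_panel(config: SimulationConfig,
                   models: Mapping[tuple[CohortStratum, Service],
                                   CoefficientSet]) -> PersonYearPanel:
    """Full pipeline: baseline -> events -> costs, both strata mixed."""
    rng = np.random.default_rng(config.seed)
    n_with = int(round(config.n_participants * config.stratum_mix))
    n_without = config.n_participants - n_with
    panels = []
    offset = 0
    for stratum, n in ((CohortStratum.WITHOUT_CVD, n_without),
                       (CohortStratum.WITH_CVD, n_with)):
        if n == 0:
            continue
        cohort = sample_baseline(n, stratum, rng=rng)
        events = simulate_events(cohort, config, stratum, rng=rng)
        panel = simulate_costs(cohort, events, models, config, stratum,
                               rng=rng, first_person_id=offset)
        panels.append(panel.data)
        offset += n
    out = PersonYearPanel(data=pd.concat(panels, ignore_index=True),
                          seed=config.seed)
    return apply_registration_gaps(out, config, rng=rng)


def allocate_admission_cost(admission: AdmissionRecord,
                            period_boundaries: Sequence[date]
                            ) -> dict[int, float]:
    """Split an admission's cost across annual periods pro rata by nights.

    Periods are half-open intervals between consecutive boundaries. Shares
    are computed to the penny with a largest-remainder correction so they
    sum to the input cost exactly. Same-day stays (zero nights) assign the
    full cost to the period containing the admission date.
    """
    bounds = list(period_boundaries)
    if sorted(bounds) != bounds or len(bounds) < 2:
        raise ValueError("period_boundaries must be >= 2 ascending dates")
    periods = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    nights = (admission.discharge - admission.admission).days
    if nights == 0:
        for idx, (lo, hi) in enumerate(periods):
            if lo <= admission.admission < hi:
                return {idx: round(admission.total_cost_gbp, 2)}
        raise ValueError("admission date outside all periods")

    overlap: dict[int, int] = {}
    for idx, (lo, hi) in enumerate(periods):
        start = max(admission.admission, lo)
        end = min(admission.discharge, hi)
        n = (end - start).days
        if n > 0:
            overlap[idx] = n
    if not overlap:
        raise ValueError("admission does not overlap any period")

    total_pennies = int(round(admission.total_cost_gbp * 100))
    covered = sum(overlap.values())
    raw = {idx: total_pennies * n / covered for idx, n in overlap.items()}
    shares = {idx: int(np.floor(v)) for idx, v in raw.items()}
    left = total_pennies - sum(shares.values())
    for idx in sorted(overlap, key=lambda j: (-(raw[j] - shares[j]), j)):
        if left <= 0:
            break
        shares[idx] += 1
        left -= 1
    return {idx: pennies / 100.0 for idx, pennies in shares.items()}


def apply_registration_gaps(panel: PersonYearPanel, config: SimulationConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> PersonYearPanel:
    """Flag person-years with primary-care registration gaps.

    Flagged rows keep their hospital costs but must be excluded from
    primary-care estimation.
    """
    p = config.registration_gap_probability
    if p == 0.0:
        return panel
    if rng is None:
        rng = np.random.default_rng(config.seed)
    df = panel.data.copy()
    gap = rng.random(len(df)) < p
    df["primary_excluded"] = np.where(gap, "yes", "no")
    return PersonYearPanel(data=df, seed=panel.seed)
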