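"""Synthetic longitudinal cohort generator with known mediation truth.

Emulates the structure of a three-visit posttreatment colorectal-cancer
survivor cohort (209 participants at 6 weeks, thinning to ~174 at 6
months and ~143 at 12 months through monotone dropout): time-invariant
demographics, time-varying clinical and lifestyle covariates, dietary
intake in grams and kcal per day, the nine plasma kynurenine-pathway
metabolites, and EORTC-style HRQoL scales.

The causal content is user-set: a designated exposure column feeds the
mediators through per-SD a-path coefficients, and the designated outcome
is built from the direct effect c', the mediator b-paths, and a random
intercept. Everything else is realistic-looking noise. The generating
coefficients travel alongside the cohort as a :class:`SyntheticTruth`
sidecar so estimates can be joined to truth.

Outcomes are Gaussian by default ("none" mode), which keeps linear-model
parameter recovery exact; the "clip" mode truncates HRQoL scales to
[0, 100] for realism at the cost of a small attenuation bias.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ColumnDef, LongCohortTable, VariableSchema
from .derived import (
    ENERGY_KCAL_PER_GRAM,
    METABOLITES,
    add_ratio_columns,
    standardization_scale,
)
from .errors import ContractError, DomainError

HRQOL_OUTCOMES = (
    "physical_functioning",
    "role_functioning",
    "global_qol",
    "summary_score",
)

#: Per-visit (T1, T2, T3) means and SDs of dietary intake in g/day.
_DIET_GRAMS = {
    "animal_protein_g": ((47.9, 16.2), (44.6, 12.1), (45.5, 13.2)),
    "plant_protein_g": ((31.8, 8.8), (30.7, 8.1), (31.3, 7.9)),
    "mono_disaccharides_g": ((94.0, 33.5), (82.3, 31.7), (84.9, 37.5)),
    "polysaccharides_g": ((135.2, 36.5), (129.3, 34.0), (133.2, 34.6)),
    "saturated_fat_g": ((30.8, 10.4), (29.2, 9.6), (29.0, 9.9)),
    "unsaturated_fat_g": ((45.8, 14.5), (42.5, 12.3), (42.7, 12.2)),
    "alcohol_g": ((12.8, 16.7), (13.5, 19.8), (15.0, 19.8)),
    "fiber_g": ((21.3, 6.0), (20.9, 6.3), (21.4, 6.1)),
}
_MICRONUTRIENTS = {
    "vitamin_b2": ((1.3, 0.4), (1.2, 0.4), (1.2, 0.4)),
    "vitamin_b6": ((1.9, 0.6), (1.8, 0.7), (1.8, 0.6)),
    "magnesium": ((320.3, 83.8), (306.1, 82.1), (313.0, 84.7)),
    "zinc": ((9.9, 2.6), (9.5, 2.2), (9.5, 2.3)),
}
_PATTERNS = {
    "dhd_score": ((66.9, 16.1), (69.3, 14.8), (67.0, 15.1)),
    "wcrf_score": ((1.9, 0.7), (2.1, 0.7), (2.0, 0.7)),
}
#: grams column -> (kcal column, energy component)
_GRAM_TO_KCAL = {
    "protein_g": ("protein_kcal", "protein"),
    "animal_protein_g": ("animal_protein_kcal", "protein"),
    "plant_protein_g": ("plant_protein_kcal", "protein"),
    "carbohydrate_g": ("carbohydrate_kcal", "carbohydrate"),
    "mono_disaccharides_g": ("mono_disaccharides_kcal", "carbohydrate"),
    "polysaccharides_g": ("polysaccharides_kcal", "carbohydrate"),
    "fat_g": ("fat_kcal", "fat"),
    "saturated_fat_g": ("saturated_fat_kcal", "fat"),
    "unsaturated_fat_g": ("unsaturated_fat_kcal", "fat"),
    "alcohol_g": ("alcohol_kcal", "alcohol"),
    "fiber_g": ("fiber_kcal", "fiber"),
}

#: Typical levels (and spreads) of the nine plasma metabolites; Trp and
#: Kyn in umol/L, the rest nmol/L. Spreads approximate IQR / 1.35.
_METABOLITE_MEAN = {
    "Trp": 67.0, "Kyn": 1.9, "HK": 48.0, "KA": 57.0, "XA": 14.0,
    "AA": 16.0, "HAA": 43.0, "Pic": 35.0, "QA": 490.0,
}
_METABOLITE_SD = {
    "Trp": 9.0, "Kyn": 0.45, "HK": 17.0, "KA": 20.0, "XA": 7.0,
    "AA": 5.5, "HAA": 13.0, "Pic": 12.0, "QA": 210.0,
}
_OUTCOME_MEAN = {
    "physical_functioning": (78.3, 82.5, 83.8),
    "role_functioning": (72.3, 83.1, 85.4),
    "global_qol": (74.6, 78.9, 78.4),
    "summary_score": (84.7, 88.7, 88.8),
}


@dataclass
class CohortDesign:
    """Sample sizes, visit schedule and covariate marginals of the cohort."""

    n_t1: int = 209
    retention: tuple[float, float] = (174 / 209, 143 / 209)  # at T2, T3
    visit_weeks: tuple[float, float, float] = (6.0, 26.0, 52.0)
    age_mean: float = 66.1
    age_sd: float = 9.1
    male_frac: float = 0.675
    chemotherapy_frac: float = 0.364
    comorbidity_probs: tuple[float, float, float] = (0.19, 0.26, 0.55)
    stoma_probs: tuple[float, float, float] = (0.30, 0.18, 0.14)
    education_probs: tuple[float, float, float] = (0.254, 0.392, 0.354)
    smoking_probs: tuple[float, float, float] = (0.335, 0.579, 0.086)
    bmi_mean: float = 27.7
    bmi_sd: float = 4.4
    sedentary_mean: float = 4.8
    sedentary_sd: float = 2.4
    mvpa_median: float = 7.5
    mvpa_log_sd: float = 1.0
    creatinine_median: float = 82.0
    creatinine_log_sd: float = 0.19
    seed: int | None = None

    def __post_init__(self):
        r2, r3 = self.retention
        if not (0.0 <= r3 <= r2 <= 1.0):
            raise DomainError("retention must be non-increasing and in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generating coefficients and variance components of a cohort.

    ``a`` is in mediator units per 1 SD of exposure, ``b`` in outcome
    units per mediator unit, ``c_prime`` in outcome units per exposure
    SD. ``rho`` is the common residual correlation across mediators.
    The outcome intercept is re-centred internally so that the marginal
    outcome mean stays near ``outcome_mean`` whatever ``b`` is.
    """

    exposure: str = "fiber_kcal"
    outcome: str = "physical_functioning"
    mediators: tuple[str, ...] = METABOLITES
    a: tuple[float, ...] = None  # type: ignore[assignment]
    b: tuple[float, ...] = None  # type: ignore[assignment]
    c_prime: float = 0.0
    rho: float = 0.3
    mediator_intercept_sd_frac: float = 1.0  # tau_m as multiple of resid SD
    outcome_mean: float = 80.0
    outcome_intercept_sd: float = 12.0
    outcome_resid_sd: float = 10.0
    lognormal_mediators: bool = False
    dropout_outcome_coef: float = 0.0  # >0: poor outcome raises dropout

    def __post_init__(self):
        k = len(self.mediators)
        if self.a is None:
            self.a = (0.0,) * k
        if self.b is None:
            self.b = (0.0,) * k
        if len(self.a) != k or len(self.b) != k:
            raise ContractError("a and b must match the mediator count")
        if not -1.0 < self.rho < 1.0:
            raise DomainError("cross-mediator correlation must be in (-1, 1)")

    # -- sidecar serialization ----------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        for key in ("mediators", "a", "b"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _per_visit(values, visit_idx):
    return np.asarray(values, float)[visit_idx]


def generate_cohort(
    design: CohortDesign | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
    mode: str = "none",
) -> tuple[LongCohortTable, SyntheticTruth]:
    """Simulate one cohort; returns the table and an echo of the truth.

    ``mode`` is forwarded to :func:`bounded_outcome_transform` ("none"
    keeps Gaussian outcomes, "clip" truncates HRQoL scales to [0, 100]).
    The exposure named by ``truth.exposure`` is standardized by the
    realized mean of per-visit SDs before entering the mediator and
    outcome models, so ``truth.a`` and ``truth.c_prime`` are per-SD.
    """
    design = CohortDesign() if design is None else design
    truth = SyntheticTruth() if truth is None else truth
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_t1
    r2, r3 = design.retention

    # --- subject-level draws -----------------------------------------
    age = rng.normal(design.age_mean, design.age_sd, n)
    male = rng.random(n) < design.male_frac
    chemo = rng.random(n) < design.chemotherapy_frac
    comorb = rng.choice(["0", "1", "2+"], n, p=_norm(design.comorbidity_probs))
    educ = rng.choice(["low", "medium", "high"], n, p=_norm(design.education_probs))
    smoke = rng.choice(["never", "former", "current"], n, p=_norm(design.smoking_probs))
    appetite = rng.normal(0.0, 1.0, n)  # shared diet-level latent factor
    diet_u = {v: rng.normal(0.0, 1.0, n) for v in
              list(_DIET_GRAMS) + list(_MICRONUTRIENTS) + list(_PATTERNS)}
    u_med = rng.normal(0.0, 1.0, (n, len(truth.mediators)))
    u_out = {o: rng.normal(0.0, 1.0, n) for o in HRQOL_OUTCOMES}
    bmi0 = rng.normal(design.bmi_mean, design.bmi_sd, n)
    dropout_u = rng.random(n)  # nested-uniform monotone dropout

    # visits retained per subject: T1 always; T2 iff u < r2; T3 iff u < r3
    n_visits = 1 + (dropout_u < r2).astype(int) + (dropout_u < r3).astype(int)
    subj_rows = np.repeat(np.arange(n), n_visits)
    visit_idx = np.concatenate([np.arange(k) for k in n_visits])
    m = len(subj_rows)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in subj_rows],
            "visit": np.array(["T1", "T2", "T3"])[visit_idx],
            "weeks_since_treatment_end": (
                _per_visit(design.visit_weeks, visit_idx)
                + rng.uniform(-1.5, 1.5, m)
            ),
            "age": age[subj_rows],
            "sex": np.where(male[subj_rows], "male", "female"),
            "chemotherapy": np.where(chemo[subj_rows], "yes", "no"),
            "comorbidities": comorb[subj_rows],
            "education": educ[subj_rows],
            "smoking": smoke[subj_rows],
        }
    )
    df["stoma"] = np.where(
        rng.random(m) < _per_visit(design.stoma_probs, visit_idx), "yes", "no"
    )
    df["bmi"] = bmi0[subj_rows] + rng.normal(0.0, 0.8, m)
    df["sedentary_time"] = np.maximum(
        0.0, rng.normal(design.sedentary_mean, design.sedentary_sd, m)
    )
    df["mvpa"] = design.mvpa_median * np.exp(
        rng.normal(0.0, design.mvpa_log_sd, m)
    )
    df["creatinine"] = design.creatinine_median * np.exp(
        rng.normal(0.0, design.creatinine_log_sd, m)
    )

    # --- dietary intake ----------------------------------------------
    # Each variable tracks a shared appetite factor (subject-stable, with
    # per-visit wobble) plus its own subject-level habit; males eat more.
    sex_factor = np.where(male[subj_rows], 1.08, 0.85)
    intake_factor = sex_factor * (
        1.0 + 0.10 * appetite[subj_rows] + 0.05 * rng.normal(0.0, 1.0, m)
    )
    for var, per_visit in {**_DIET_GRAMS, **_MICRONUTRIENTS}.items():
        mu = _per_visit([p[0] for p in per_visit], visit_idx)
        sd = _per_visit([p[1] for p in per_visit], visit_idx)
        # subject-habit vs visit-noise split preserves the marginal SD
        vals = (
            mu * intake_factor
            + 0.745 * sd * diet_u[var][subj_rows]
            + 0.667 * sd * rng.normal(0.0, 1.0, m)
        )
        df[var] = np.maximum(0.0, vals)
    for var, per_visit in _PATTERNS.items():
        mu = _per_visit([p[0] for p in per_visit], visit_idx)
        sd = _per_visit([p[1] for p in per_visit], visit_idx)
        df[var] = (
            mu
            + 0.6 * sd * diet_u[var][subj_rows]
            + 0.8 * sd * rng.normal(0.0, 1.0, m)
        )
    df["protein_g"] = df["animal_protein_g"] + df["plant_protein_g"]
    df["carbohydrate_g"] = df["mono_disaccharides_g"] + df["polysaccharides_g"]
    df["fat_g"] = df["saturated_fat_g"] + df["unsaturated_fat_g"]
    for gram_col, (kcal_col, comp) in _GRAM_TO_KCAL.items():
        df[kcal_col] = df[gram_col] * ENERGY_KCAL_PER_GRAM[comp]
    df["energy_kcal"] = (
        df["protein_kcal"] + df["carbohydrate_kcal"] + df["fat_kcal"]
        + df["alcohol_kcal"] + df["fiber_kcal"]
    )

    # --- mediators ----------------------------------------------------
    if truth.exposure not in df.columns:
        raise ContractError(f"unknown exposure column {truth.exposure!r}")
    scale = standardization_scale(df, truth.exposure)
    x_std = (df[truth.exposure] / scale.scale).to_numpy()

    k = len(truth.mediators)
    med_sd = np.array([_METABOLITE_SD.get(mname, 1.0) for mname in truth.mediators])
    med_mu = np.array([_METABOLITE_MEAN.get(mname, 0.0) for mname in truth.mediators])
    corr = np.full((k, k), truth.rho) + (1.0 - truth.rho) * np.eye(k)
    chol = np.linalg.cholesky(corr)
    resid_frac = 1.0 / np.sqrt(1.0 + truth.mediator_intercept_sd_frac**2)
    eps = rng.normal(0.0, 1.0, (m, k)) @ chol.T
    med = (
        med_mu
        + np.outer(x_std, np.asarray(truth.a, float))
        + med_sd * resid_frac
        * (truth.mediator_intercept_sd_frac * u_med[subj_rows] + eps)
    )
    if truth.lognormal_mediators:
        # re-express as a right-skewed positive variable, same median
        med = med_mu * np.exp((med - med_mu) / np.maximum(med_mu, 1e-9))
    # keep concentrations positive: floor at 1% of the typical level
    # (a ~1e-4-probability truncation of the Gaussian left tail)
    med = np.maximum(med, np.where(med_mu > 0, 0.01 * med_mu, -np.inf))
    for j, mname in enumerate(truth.mediators):
        df[mname] = med[:, j]
    if set(METABOLITES) <= set(df.columns):
        df = add_ratio_columns(df)

    # --- outcomes -----------------------------------------------------
    b = np.asarray(truth.b, float)
    for out in HRQOL_OUTCOMES:
        mu = _per_visit(_OUTCOME_MEAN[out], visit_idx)
        base = mu - np.mean(_OUTCOME_MEAN[out])
        if out == truth.outcome:
            df[out] = (
                truth.outcome_mean
                + base
                - float(b @ med_mu)  # re-centre so E[Y] ~ outcome_mean
                + truth.c_prime * x_std
                + med @ b
                + truth.outcome_intercept_sd * u_out[out][subj_rows]
                + truth.outcome_resid_sd * rng.normal(0.0, 1.0, m)
            )
        else:
            df[out] = (
                mu
                + 12.0 * u_out[out][subj_rows]
                + 9.0 * rng.normal(0.0, 1.0, m)
            )

    # informative dropout (optional): re-thin after outcomes are known
    if truth.dropout_outcome_coef > 0.0:
        keep = np.ones(m, bool)
        y = df[truth.outcome].to_numpy()
        shift = truth.dropout_outcome_coef * (truth.outcome_mean - y) / 100.0
        for t, r in ((1, r2), (2, r3)):
            at_t = visit_idx == t
            keep[at_t] = dropout_u[subj_rows[at_t]] < np.clip(
                r - shift[at_t], 0.0, 1.0
            )
        df = df[keep].reset_index(drop=True)

    df = bounded_outcome_transform(df, mode)
    schema = default_schema(bounded=(mode == "clip"))
    return LongCohortTable(df, schema), truth


def _norm(p):
    p = np.asarray(p, float)
    return p / p.sum()


def bounded_outcome_transform(
    df: pd.DataFrame, mode: str, columns=HRQOL_OUTCOMES
) -> pd.DataFrame:
    """Leave Gaussian outcomes as-is ("none") or truncate to [0, 100]."""
    if mode == "none":
        return df
    if mode == "clip":
        out = df.copy()
        for col in columns:
            if col in out.columns:
                out[col] = out[col].clip(0.0, 100.0)
        return out
    raise ContractError(f"unknown outcome transform mode {mode!r}")


def default_schema(bounded: bool = True) -> VariableSchema:
    """Schema describing the generated cohort's columns.

    ``bounded=False`` drops the [0, 100] / non-negativity bounds, for
    untransformed Gaussian synthetic outcomes.
    """
    cols: dict[str, ColumnDef] = {
        "subject_id": ColumnDef("id"),
        "visit": ColumnDef("time", kind="categorical", levels=("T1", "T2", "T3")),
        "weeks_since_treatment_end": ColumnDef("time", unit="weeks"),
        "age": ColumnDef("covariate", unit="years"),
        "sex": ColumnDef("covariate", kind="categorical", levels=("male", "female")),
        "chemotherapy": ColumnDef("covariate", kind="categorical", levels=("no", "yes")),
        "stoma": ColumnDef("covariate", kind="categorical", levels=("no", "yes")),
        "comorbidities": ColumnDef("covariate", kind="categorical", levels=("0", "1", "2+")),
        "smoking": ColumnDef("covariate", kind="categorical", levels=("never", "former", "current")),
        "education": ColumnDef("covariate", kind="categorical", levels=("low", "medium", "high")),
        "bmi": ColumnDef("covariate", unit="kg/m^2"),
        "mvpa": ColumnDef("covariate", unit="h/week"),
        "sedentary_time": ColumnDef("covariate", unit="h/day"),
        "creatinine": ColumnDef("covariate", unit="umol/L"),
        "energy_kcal": ColumnDef("covariate", unit="kcal/day"),
    }
    for gram_col, (kcal_col, _) in _GRAM_TO_KCAL.items():
        cols[gram_col] = ColumnDef("exposure", unit="g/day")
        cols[kcal_col] = ColumnDef("exposure", unit="kcal/day")
    for var in _MICRONUTRIENTS:
        cols[var] = ColumnDef("exposure", unit="mg/day")
    for var in _PATTERNS:
        cols[var] = ColumnDef("exposure", unit="points")
    conc_bounds = (0.0, None) if bounded else None
    for mname in METABOLITES:
        unit = "umol/L" if mname in ("Trp", "Kyn") else "nmol/L"
        cols[mname] = ColumnDef("mediator", unit=unit, bounds=conc_bounds)
    for rname in ("KTR", "HKr", "KA_QA"):
        cols[rname] = ColumnDef("mediator", bounds=conc_bounds)
    hr_bounds = (0.0, 100.0) if bounded else None
    for out in HRQOL_OUTCOMES:
        cols[out] = ColumnDef("outcome", unit="0-100", bounds=hr_bounds)
    return VariableSchema(cols)
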