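"""Derived analysis variables.

Covers four groups of constructions used throughout the pipeline:

* energy bookkeeping — Atwater-style conversion of nutrient grams/day to
  kcal/day and the energy-adjustment covariate sets (all-components
  method for macronutrients, standard method for micronutrients and
  dietary-pattern scores);
* kynurenine-pathway ratios — KTR (kynurenine-to-tryptophan, with the
  micromolar-to-nanomolar unit bridge), HKr (hydroxykynurenine ratio, a
  functional vitamin B6 marker) and KA/QA (kynurenic over quinolinic
  acid);
* per-SD exposure standardization — the pooled scale is the unweighted
  mean of the per-visit sample standard deviations, so slopes read as
  "per 1 SD of intake";
* EORTC QLQ-C30 scoring — linear 0-100 transform of subscale item means
  and the 13-subscale summary score with symptom scales reversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError

# --------------------------------------------------------------------------
# Energy conversion
# --------------------------------------------------------------------------

#: kcal per gram of each energy-bearing dietary component.
ENERGY_KCAL_PER_GRAM = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "fat": 9.0,
    "alcohol": 7.0,
    "fiber": 2.0,
}


def grams_to_kcal(nutrient: str, grams_per_day: float) -> float:
    """Convert a nutrient intake in g/day to kcal/day."""
    if nutrient not in ENERGY_KCAL_PER_GRAM:
        raise ContractError(
            f"no energy factor for {nutrient!r}; known: "
            f"{sorted(ENERGY_KCAL_PER_GRAM)}"
        )
    if np.any(np.asarray(grams_per_day) < 0):
        raise DomainError("intake in grams must be non-negative")
    return grams_per_day * ENERGY_KCAL_PER_GRAM[nutrient]


# --------------------------------------------------------------------------
# Kynurenine-pathway ratios
# --------------------------------------------------------------------------

#: The nine plasma metabolites of the kynurenine pathway. Trp and Kyn are
#: measured in umol/L, the downstream metabolites in nmol/L.
METABOLITES = ("Trp", "Kyn", "HK", "KA", "XA", "AA", "HAA", "Pic", "QA")


@dataclass(frozen=True)
class RatioDefinition:
    """Numerator/denominator components of a metabolite ratio.

    ``numerator_factor`` bridges units (KTR multiplies Kyn in umol/L by
    1000 to express it in nmol/L before dividing by Trp in umol/L).
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    numerator_factor: float = 1.0


RATIOS: dict[str, RatioDefinition] = {
    "KTR": RatioDefinition("KTR", ("Kyn",), ("Trp",), numerator_factor=1000.0),
    "HKr": RatioDefinition("HKr", ("HK",), ("KA", "XA", "AA", "HAA")),
    "KA_QA": RatioDefinition("KA_QA", ("KA",), ("QA",)),
}


def compute_ratio(
    definition: str | RatioDefinition, concentrations: Mapping[str, float]
) -> float:
    """Evaluate one kynurenine ratio on a mapping metabolite -> value."""
    if isinstance(definition, str):
        try:
            definition = RATIOS[definition]
        except KeyError:
            raise ContractError(
                f"unknown ratio {definition!r}; known: {sorted(RATIOS)}"
            ) from None
    for comp in definition.numerator + definition.denominator:
        if comp not in concentrations or pd.isna(concentrations[comp]):
            raise ContractError(
                f"ratio {definition.name}: missing metabolite {comp!r}"
            )
    num = definition.numerator_factor * sum(
        concentrations[c] for c in definition.numerator
    )
    den = sum(concentrations[c] for c in definition.denominator)
    if den <= 0:
        raise DomainError(
            f"ratio {definition.name}: non-positive denominator {den}"
        )
    return num / den


def add_ratio_columns(df: pd.DataFrame, ratios: Iterable[str] = ("KTR", "HKr", "KA_QA")) -> pd.DataFrame:
    """Return a copy of ``df`` with ratio columns appended (vectorized).

    Rows with any missing component get a missing ratio; rows with a
    non-positive denominator raise :class:`DomainError`.
    """
    out = df.copy()
    for name in ratios:
        d = RATIOS[name]
        num = d.numerator_factor * sum(out[c] for c in d.numerator)
        den = sum(out[c] for c in d.denominator)
        if (den <= 0).any():
            raise DomainError(f"ratio {name}: non-positive denominator present")
        out[name] = num / den
    return out


# --------------------------------------------------------------------------
# Per-SD standardization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationScale:
    """Pooled per-SD scale of an exposure.

    ``per_visit_sd`` holds the sample SD (n-1 denominator) at each visit
    with at least two non-missing values; ``scale`` is their unweighted
    arithmetic mean. Dividing an exposure by ``scale`` puts slopes on the
    per-1-SD-of-intake scale.
    """

    exposure: str
    per_visit_sd: tuple[float, ...]

    @property
    def scale(self) -> float:
        return float(np.mean(self.per_visit_sd))

    def __post_init__(self):
        if not self.per_visit_sd:
            raise DomainError(
                f"{self.exposure}: no visit has >= 2 non-missing values"
            )
        if self.scale <= 0:
            raise DomainError(f"{self.exposure}: pooled SD scale is not > 0")

    @classmethod
    def from_sds(cls, exposure: str, sds: Sequence[float]) -> "StandardizationScale":
        return cls(exposure, tuple(float(s) for s in sds if s > 0))


def standardization_scale(
    df: pd.DataFrame, exposure: str, visit_col: str = "visit"
) -> StandardizationScale:
    """Pooled mean-of-per-visit-SDs scale for ``exposure`` in ``df``."""
    sds = []
    for _, grp in df.groupby(visit_col, sort=True, observed=True):
        vals = grp[exposure].dropna()
        if len(vals) >= 2:
            sd = float(vals.std(ddof=1))
            if sd > 0:
                sds.append(sd)
    if not sds:
        raise DomainError(f"{exposure}: all visits degenerate (no spread)")
    return StandardizationScale(exposure, tuple(sds))


def apply_standardization(values, scale: StandardizationScale):
    """Divide exposure values by the pooled scale (no centering)."""
    return values / scale.scale


# --------------------------------------------------------------------------
# Energy-adjustment covariate schemes
# --------------------------------------------------------------------------

#: Confounders shared by every model.
BASE_COVARIATES = (
    "age",
    "sex",
    "chemotherapy",
    "creatinine",
    "comorbidities",
    "stoma",
    "weeks_since_treatment_end",
    "bmi",
    "mvpa",
    "smoking",
    "education",
    "sedentary_time",
)

#: kcal/day columns of the five energy-bearing components.
COMPONENT_KCAL = {
    "protein": "protein_kcal",
    "carbohydrate": "carbohydrate_kcal",
    "fat": "fat_kcal",
    "alcohol": "alcohol_kcal",
    "fiber": "fiber_kcal",
}

#: Which energy component each macronutrient exposure belongs to. Subtype
#: exposures (e.g. saturated fat) map to their parent component so the
#: all-components set drops the parent kcal total and keeps the other four,
#: avoiding exposure/parent collinearity.
MACRONUTRIENT_COMPONENT = {
    "protein_kcal": "protein",
    "animal_protein_kcal": "protein",
    "carbohydrate_kcal": "carbohydrate",
    "mono_disaccharides_kcal": "carbohydrate",
    "polysaccharides_kcal": "carbohydrate",
    "fat_kcal": "fat",
    "saturated_fat_kcal": "fat",
    "unsaturated_fat_kcal": "fat",
    "alcohol_kcal": "alcohol",
    "fiber_kcal": "fiber",
}

SCHEMES = (
    "macronutrient_all_components",
    "plant_protein_special",
    "micronutrient_standard",
    "pattern_standard",
)

#: Default scheme per exposure for the full analysis grid.
EXPOSURE_SCHEME = {
    **{e: "macronutrient_all_components" for e in MACRONUTRIENT_COMPONENT},
    "plant_protein_kcal": "plant_protein_special",
    "vitamin_b2": "micronutrient_standard",
    "vitamin_b6": "micronutrient_standard",
    "magnesium": "micronutrient_standard",
    "zinc": "micronutrient_standard",
    "dhd_score": "pattern_standard",
    "wcrf_score": "pattern_standard",
}


def build_covariates(
    exposure: str,
    scheme: str | None = None,
    base: Sequence[str] = BASE_COVARIATES,
) -> list[str]:
    """Base confounders plus the energy-adjustment terms for ``exposure``.

    * macronutrient (all-components): kcal of the five energy components
      except the exposure's own component;
    * plant protein: animal-protein kcal plus carbohydrate, fat, fiber
      and alcohol kcal;
    * micronutrient (standard): alcohol kcal plus total energy kcal;
    * dietary-pattern score (standard): total energy kcal.
    """
    if scheme is None:
        scheme = EXPOSURE_SCHEME.get(exposure)
    if scheme not in SCHEMES:
        raise ContractError(
            f"cannot classify exposure {exposure!r} (scheme {scheme!r}); "
            f"known schemes: {SCHEMES}"
        )
    cov = list(base)
    if scheme == "macronutrient_all_components":
        own = MACRONUTRIENT_COMPONENT.get(exposure)
        if own is None:
            raise ContractError(
                f"{exposure!r} is not a known macronutrient exposure"
            )
        cov += [
            kcal for comp, kcal in COMPONENT_KCAL.items() if comp != own
        ]
    elif scheme == "plant_protein_special":
        cov += [
            "animal_protein_kcal",
            COMPONENT_KCAL["carbohydrate"],
            COMPONENT_KCAL["fat"],
            COMPONENT_KCAL["fiber"],
            COMPONENT_KCAL["alcohol"],
        ]
    elif scheme == "micronutrient_standard":
        cov += [COMPONENT_KCAL["alcohol"], "energy_kcal"]
    elif scheme == "pattern_standard":
        cov += ["energy_kcal"]
    assert exposure not in cov
    return cov


# --------------------------------------------------------------------------
# EORTC QLQ-C30 scoring
# --------------------------------------------------------------------------

FUNCTIONING_SCALES = (
    "physical_functioning",
    "role_functioning",
    "cognitive_functioning",
    "emotional_functioning",
    "social_functioning",
)
SYMPTOM_SCALES = (
    "fatigue",
    "pain",
    "nausea_vomiting",
    "dyspnea",
    "insomnia",
    "appetite_loss",
    "constipation",
    "diarrhea",
)
#: The 13 subscales entering the summary score (global QoL and financial
#: difficulties are excluded).
SUMMARY_CONSTITUENTS = FUNCTIONING_SCALES + SYMPTOM_SCALES


def eortc_scale_score(raw_mean: float, item_range: float, direction: str) -> float:
    """Linear 0-100 transform of a subscale raw item mean.

    Functioning scales are oriented so that higher = better functioning;
    symptom scales so that higher = worse symptoms. ``item_range`` is the
    difference between the maximum and minimum item response (3 for the
    4-point items, 6 for the 7-point global items).
    """
    if direction not in ("functioning", "symptom"):
        raise ContractError(f"unknown direction {direction!r}")
    if not (1.0 <= raw_mean <= 1.0 + item_range):
        raise DomainError(
            f"raw item mean {raw_mean} outside [1, {1 + item_range}]"
        )
    frac = (raw_mean - 1.0) / item_range
    score = (1.0 - frac) * 100.0 if direction == "functioning" else frac * 100.0
    return float(min(100.0, max(0.0, score)))


def eortc_summary(subscale_scores: Mapping[str, float]) -> float:
    """Summary score: mean of the 13 subscales with symptoms reversed."""
    missing = [s for s in SUMMARY_CONSTITUENTS if s not in subscale_scores]
    if missing:
        raise ContractError(f"summary score: missing subscale(s) {missing}")
    vals = [float(subscale_scores[s]) for s in FUNCTIONING_SCALES]
    vals += [100.0 - float(subscale_scores[s]) for s in SYMPTOM_SCALES]
    return float(np.mean(vals))
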