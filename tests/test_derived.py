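"""Derived variables: kcal conversion, ratios, standardization, EORTC."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kpmediation import (
    StandardizationScale,
    apply_standardization,
    build_covariates,
    compute_ratio,
    eortc_scale_score,
    eortc_summary,
    grams_to_kcal,
    standardization_scale,
)
from kpmediation.derived import FUNCTIONING_SCALES, SUMMARY_CONSTITUENTS, SYMPTOM_SCALES
from kpmediation.errors import ContractError, DomainError


class TestGramsToKcal:
    @pytest.mark.parametrize(
        "nutrient,grams,kcal",
        [
            ("alcohol", 12.8, 89.6),
            ("fiber", 21.3, 42.6),
            ("protein", 79.6, 318.4),
            ("carbohydrate", 229.3, 917.2),
            ("fat", 0.0, 0.0),
        ],
    )
    def test_component_factors(self, nutrient, grams, kcal):
        assert grams_to_kcal(nutrient, grams) == pytest.approx(kcal, abs=1e-9)

    def test_unknown_component_rejected(self):
        with pytest.raises(ContractError):
            grams_to_kcal("caffeine", 1.0)

    def test_negative_intake_rejected(self):
        with pytest.raises(DomainError):
            grams_to_kcal("fat", -1.0)


class TestRatios:
    CONC = {
        "Trp": 66.4, "Kyn": 1.9, "HK": 49.9, "KA": 53.8, "XA": 13.1,
        "AA": 16.0, "HAA": 42.9, "Pic": 33.5, "QA": 515.0,
    }

    def test_ktr_unit_bridge(self):
        # Kyn in umol/L is converted to nmol/L before dividing by Trp
        assert compute_ratio("KTR", self.CONC) == pytest.approx(1900 / 66.4)

    def test_hkr(self):
        assert compute_ratio("HKr", self.CONC) == pytest.approx(49.9 / 125.8)

    def test_ka_qa(self):
        assert compute_ratio("KA_QA", self.CONC) == pytest.approx(53.8 / 515.0)

    def test_missing_metabolite_rejected(self):
        conc = {k: v for k, v in self.CONC.items() if k != "QA"}
        with pytest.raises(ContractError, match="QA"):
            compute_ratio("KA_QA", conc)

    def test_zero_denominator_rejected(self):
        conc = dict(self.CONC, QA=0.0)
        with pytest.raises(DomainError):
            compute_ratio("KA_QA", conc)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_hkr_and_kaqa_scale_invariant(self, c):
        scaled = {k: v * c for k, v in self.CONC.items()}
        for name in ("HKr", "KA_QA"):
            assert compute_ratio(name, scaled) == pytest.approx(
                compute_ratio(name, self.CONC)
            )

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_ktr_linear_in_kyn(self, c):
        scaled = dict(self.CONC, Kyn=self.CONC["Kyn"] * c)
        assert compute_ratio("KTR", scaled) == pytest.approx(
            c * compute_ratio("KTR", self.CONC)
        )


class TestStandardization:
    @pytest.mark.parametrize(
        "sds,pooled",
        [
            ((116.2, 138.9, 138.5), 131.2),
            ((78.2, 62.7, 65.6), 68.83),
            ((133.8, 126.9, 150.2), 136.97),
        ],
    )
    def test_mean_of_per_visit_sds(self, sds, pooled):
        scale = StandardizationScale.from_sds("x", sds)
        assert scale.scale == pytest.approx(pooled, abs=0.005)

    def test_degenerate_visits_excluded(self):
        scale = StandardizationScale.from_sds("x", (0.0, 5.0, 5.0))
        assert scale.scale == 5.0

    def test_sample_sd_uses_n_minus_1(self):
        df = pd.DataFrame(
            {"visit": ["T1"] * 3, "x": [1.0, 2.0, 3.0]}
        )
        scale = standardization_scale(df, "x")
        assert scale.scale == pytest.approx(1.0)  # not sqrt(2/3)

    def test_all_degenerate_rejected(self):
        df = pd.DataFrame({"visit": ["T1", "T1"], "x": [2.0, 2.0]})
        with pytest.raises(DomainError):
            standardization_scale(df, "x")

    def test_apply_divides_without_centering(self):
        scale = StandardizationScale.from_sds("x", (131.2,))
        assert apply_standardization(131.2, scale) == pytest.approx(1.0)
        assert apply_standardization(0.0, scale) == 0.0

    def test_invariant_to_record_order(self, small_cohort):
        df = small_cohort.data
        shuffled = df.sample(frac=1.0, random_state=3)
        s1 = standardization_scale(df, "alcohol_kcal").scale
        s2 = standardization_scale(shuffled, "alcohol_kcal").scale
        assert s1 == pytest.approx(s2)

    def test_slope_equivalence_raw_vs_standardized(self, small_cohort):
        # slope on standardized exposure == slope on raw exposure * scale
        from kpmediation import RandomInterceptLMM

        df = small_cohort.data.copy()
        scale = standardization_scale(df, "fiber_kcal")
        df["fiber_std"] = apply_standardization(df["fiber_kcal"], scale)
        raw = RandomInterceptLMM("physical_functioning", ["fiber_kcal"]).fit(df)
        std = RandomInterceptLMM("physical_functioning", ["fiber_std"]).fit(df)
        assert std.params_["fiber_std"] == pytest.approx(
            raw.params_["fiber_kcal"] * scale.scale
        )


class TestCovariateSchemes:
    def test_macronutrient_all_components(self):
        cov = build_covariates("fiber_kcal", "macronutrient_all_components")
        kcals = {c for c in cov if c.endswith("_kcal")}
        assert kcals == {
            "protein_kcal", "carbohydrate_kcal", "fat_kcal", "alcohol_kcal"
        }

    def test_subtype_drops_parent_component(self):
        cov = build_covariates("saturated_fat_kcal")
        assert "fat_kcal" not in cov
        assert {"protein_kcal", "carbohydrate_kcal", "alcohol_kcal",
                "fiber_kcal"} <= set(cov)

    def test_plant_protein_special(self):
        cov = build_covariates("plant_protein_kcal")
        assert "animal_protein_kcal" in cov
        assert "protein_kcal" not in cov
        assert {"carbohydrate_kcal", "fat_kcal", "fiber_kcal",
                "alcohol_kcal"} <= set(cov)

    def test_micronutrient_standard(self):
        cov = build_covariates("zinc")
        assert {"alcohol_kcal", "energy_kcal"} <= set(cov)
        assert "protein_kcal" not in cov

    def test_pattern_standard(self):
        cov = build_covariates("dhd_score")
        assert "energy_kcal" in cov
        assert "alcohol_kcal" not in cov

    @pytest.mark.parametrize(
        "exposure", ["fiber_kcal", "plant_protein_kcal", "zinc", "dhd_score"]
    )
    def test_never_contains_own_exposure(self, exposure):
        assert exposure not in build_covariates(exposure)

    def test_unclassifiable_exposure_rejected(self):
        with pytest.raises(ContractError):
            build_covariates("mystery_compound")


class TestEortc:
    @pytest.mark.parametrize(
        "raw,rng,direction,score",
        [
            (1.0, 3, "functioning", 100.0),
            (4.0, 3, "functioning", 0.0),
            (1.0, 3, "symptom", 0.0),
            (4.0, 3, "symptom", 100.0),
            (2.5, 3, "functioning", 50.0),
            (1.0, 6, "functioning", 100.0),
        ],
    )
    def test_linear_transform(self, raw, rng, direction, score):
        assert eortc_scale_score(raw, rng, direction) == pytest.approx(score)

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(DomainError):
            eortc_scale_score(4.5, 3, "functioning")

    def test_summary_extremes_and_constant(self):
        best = {s: 100.0 for s in FUNCTIONING_SCALES}
        best.update({s: 0.0 for s in SYMPTOM_SCALES})
        assert eortc_summary(best) == 100.0
        worst = {s: 0.0 for s in FUNCTIONING_SCALES}
        worst.update({s: 100.0 for s in SYMPTOM_SCALES})
        assert eortc_summary(worst) == 0.0
        const = {s: 80.0 for s in FUNCTIONING_SCALES}
        const.update({s: 20.0 for s in SYMPTOM_SCALES})
        assert eortc_summary(const) == 80.0

    def test_missing_subscale_rejected_no_prorating(self):
        scores = {s: 50.0 for s in SUMMARY_CONSTITUENTS if s != "pain"}
        with pytest.raises(ContractError, match="pain"):
            eortc_summary(scores)
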