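"""Formula registry: derived quantities, predictions, applicability rules."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsesv import (
    Condition,
    HemodynamicObservation,
    Posture,
    SubjectProfile,
    ValidationError,
    compute_cardiac_index,
    compute_cardiac_output,
    derive_bsa,
    derive_pulse_pressure,
    predict_all,
    predict_sv,
    predict_vector,
)
from pulsesv.registry import MissingInputError, VolumeFactorTable


def make_obs(sap=120.0, dap=80.0, hr=70.0, sv=80.0):
    return HemodynamicObservation(
        "S01", 1, Posture.SUPINE, Condition.THERMONEUTRAL, sap, dap, hr, sv
    )


SUBJECT = SubjectProfile("S01", age=21.5, height=1.80, weight=81.5)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "sap,dap,expected", [(120, 80, 40), (135.5, 72.25, 63.25)]
    )
    def test_pulse_pressure(self, sap, dap, expected):
        assert derive_pulse_pressure(sap, dap) == pytest.approx(expected)

    @pytest.mark.parametrize("sap,dap", [(80, 80), (70, 80), (50, -10), (0, 0)])
    def test_pulse_pressure_rejects_nonpositive_or_inverted(self, sap, dap):
        with pytest.raises(ValidationError):
            derive_pulse_pressure(sap, dap)

    @pytest.mark.parametrize(
        "method,expected", [("dubois", 2.01), ("mosteller", 2.02)]
    )
    def test_bsa_at_cohort_mean_anthropometry(self, method, expected):
        # 0.007184·180^0.725·81.5^0.425 and sqrt(180·81.5/3600)
        assert derive_bsa(1.80, 81.5, method) == pytest.approx(expected, abs=5e-3)

    def test_bsa_unknown_method_and_range_checks(self):
        with pytest.raises(ValidationError):
            derive_bsa(1.80, 81.5, "boyd")
        with pytest.raises(ValidationError):
            derive_bsa(0.9, 81.5)
        with pytest.raises(ValidationError):
            derive_bsa(1.80, 20.0)

    def test_cardiac_output_and_index(self):
        co = compute_cardiac_output(70, 70)
        assert co == pytest.approx(4.9)
        assert compute_cardiac_index(co, 2.0) == pytest.approx(2.45)
        with pytest.raises(ValidationError):
            compute_cardiac_output(0, 70)
        with pytest.raises(ValidationError):
            compute_cardiac_index(4.9, 0)

    def test_subject_profile_derives_bsa_and_bmi(self):
        assert SUBJECT.bmi == pytest.approx(81.5 / 1.80**2)
        assert SUBJECT.bsa == pytest.approx(2.012, abs=1e-3)


class TestRegistryStructure:
    def test_has_exactly_22_unique_formulae(self, registry):
        assert len(registry) == 22
        assert len(set(registry.formula_ids)) == 22

    def test_order_is_stable_and_starts_with_starr_eq72(self, registry):
        assert registry.formula_ids[0] == "starr54_eq72"
        assert registry.formula_ids == [s.formula_id for s in registry]

    def test_every_entry_keeps_printed_equation_string(self, registry):
        for spec in registry:
            assert spec.source_text.startswith("SV=")


class TestPredictions:
    @pytest.mark.parametrize(
        "formula_id,expected",
        [
            ("starr54_eq72", 100 + 0.5 * 40 - 0.6 * 80 - 0.6 * 21.5),  # 59.1
            ("starr54_eq68", 93 + 0.54 * 40 - 0.47 * 80 - 0.61 * 21.5),  # 63.885
            ("starr54_eq59a", 91 + 0.54 * 40 - 0.57 * 80 - 0.61 * 21.5),
            ("bridwell56", 66 + 0.34 * 40 - 0.11 * 80 - 0.36 * 21.5),
        ],
    )
    def test_pressure_linear_exact_affine_values(self, registry, formula_id, expected):
        rec = predict_sv(formula_id, SUBJECT, make_obs(), registry)
        assert rec.applicable
        assert rec.sv_predicted == pytest.approx(expected, abs=1e-12)

    def test_intercept_only_prediction_at_zero_inputs(self, registry):
        # degenerate inputs are representable in the vectorised path only
        frame = pd.DataFrame({"pp": [0.0], "dap": [0.0], "age": [0.0]})
        sv, _ = predict_vector(registry["starr54_eq72"], frame)
        assert sv[0] == pytest.approx(100.0)

    def test_anthropometric_formulae(self, registry):
        rec = predict_sv("desimone97_weight", SUBJECT, make_obs(), registry)
        assert rec.sv_predicted == pytest.approx(3.59 * 81.5**0.71, rel=1e-12)
        assert round(rec.sv_predicted, 1) == 81.7
        light = SubjectProfile("S02", age=21.5, height=1.80, weight=70.0)
        rec = predict_sv("skrabal05_weight", light, make_obs(), registry)
        assert rec.sv_predicted == pytest.approx(82.9)
        # height enters in cm for Skrabal, metres for de Simone
        rec = predict_sv("skrabal05_height", light, make_obs(), registry)
        assert rec.sv_predicted == pytest.approx(1.19 * 180 - 112)
        rec = predict_sv("desimone97_height", light, make_obs(), registry)
        assert rec.sv_predicted == pytest.approx(23.99 * 1.80**2.04, rel=1e-12)

    def test_lu_formula_is_cardiac_output_over_hr(self, registry):
        rec = predict_sv("lu15", SUBJECT, make_obs(hr=70), registry)
        co = 6.963 + 0.446 - 0.037 * 21.5 + 0.013 * 81.5
        assert rec.sv_predicted == pytest.approx(1000 * co / 70)

    def test_lu_formula_missing_hr_raises_named_error(self, registry):
        with pytest.raises(MissingInputError, match="heart rate"):
            predict_sv("lu15", SUBJECT, make_obs(hr=None), registry)

    def test_high_bmi_subject_inapplicable_for_de_simone(self, registry):
        heavy = SubjectProfile("S03", age=22.0, height=1.80, weight=85.0)
        assert heavy.bmi > 25.25
        rec = predict_sv("desimone97_weight", heavy, make_obs(), registry)
        assert not rec.applicable
        assert rec.sv_predicted is None
        assert "25.25" in rec.skip_reason

    def test_predict_all_emits_one_record_per_registry_entry(self, registry):
        records = predict_all(SUBJECT, make_obs(), registry)
        assert len(records) == 22
        assert [r.formula_id for r in records] == registry.formula_ids
        # no Remington table supplied → that entry alone is a skip record
        skipped = [r for r in records if not r.applicable]
        assert {r.formula_id for r in skipped} == {"remington48"}

    def test_predict_all_flags_three_de_simone_rows_for_high_bmi(self, registry):
        heavy = SubjectProfile("S03", age=22.0, height=1.80, weight=85.0)
        records = predict_all(heavy, make_obs(), registry)
        flagged = {r.formula_id for r in records if not r.applicable}
        assert flagged == {
            "desimone97_weight",
            "desimone97_bsa",
            "desimone97_height",
            "remington48",
        }

    def test_predict_all_without_hr_still_emits_full_batch(self, registry):
        records = predict_all(SUBJECT, make_obs(hr=None), registry)
        assert len(records) == 22
        lu = next(r for r in records if r.formula_id == "lu15")
        assert not lu.applicable and "heart rate" in lu.skip_reason
        assert sum(r.applicable for r in records) == 20  # all but Lu and Remington

    def test_remington_with_user_supplied_volume_factor_table(self, registry):
        table = VolumeFactorTable([40, 80, 120, 160], [10.0, 30.0, 55.0, 85.0])
        rec = predict_sv(
            "remington48", SUBJECT, make_obs(sap=120, dap=80), registry,
            remington_table=table,
        )
        assert rec.sv_predicted == pytest.approx((55.0 - 30.0) * SUBJECT.bsa)

    def test_volume_factor_table_must_be_monotone(self):
        with pytest.raises(ValidationError):
            VolumeFactorTable([40, 80, 120], [10.0, 5.0, 55.0])


class TestAlgebraicStructure:
    """Cross-formula identities implied by the printed coefficients."""

    @staticmethod
    def random_input_frame(n=10_000, seed=42):
        rng = np.random.default_rng(seed)
        dap = rng.uniform(40, 110, n)
        pp = rng.uniform(10, 90, n)
        return pd.DataFrame(
            {
                "pp": pp,
                "dap": dap,
                "sap": dap + pp,
                "age": rng.uniform(18, 80, n),
                "hr": rng.uniform(45, 120, n),
                "weight": rng.uniform(50, 110, n),
                "height": rng.uniform(1.55, 2.0, n),
                "bsa": rng.uniform(1.5, 2.4, n),
                "bmi": rng.uniform(18, 25, n),
            }
        )

    def test_jackson_equals_starr_eq71_everywhere(self, registry):
        frame = self.random_input_frame()
        a, _ = predict_vector(registry["jackson55"], frame)
        b, _ = predict_vector(registry["starr54_eq71"], frame)
        assert np.max(np.abs(a - b)) < 1e-9

    def test_starr_eq62_equals_eq59b_exactly(self, registry):
        frame = self.random_input_frame()
        a, _ = predict_vector(registry["starr54_eq62"], frame)
        b, _ = predict_vector(registry["starr54_eq59b"], frame)
        assert np.max(np.abs(a - b)) < 1e-9

    def test_starr_eq64_is_eq59b_minus_constant(self, registry):
        frame = self.random_input_frame()
        a, _ = predict_vector(registry["starr54_eq64"], frame)
        b, _ = predict_vector(registry["starr54_eq59b"], frame)
        assert np.allclose(a - b, -0.01, atol=1e-9)

    def test_pressure_linear_predictions_are_affine(self, registry):
        f1 = self.random_input_frame(n=500, seed=1)
        f2 = self.random_input_frame(n=500, seed=2)
        alpha = 0.37
        mix = f1 * alpha + f2 * (1 - alpha)
        for formula_id in ("starr54_eq72", "grollman30", "warren45", "bridwell56"):
            spec = registry[formula_id]
            p1, _ = predict_vector(spec, f1)
            p2, _ = predict_vector(spec, f2)
            pm, _ = predict_vector(spec, mix)
            assert np.allclose(pm, alpha * p1 + (1 - alpha) * p2, atol=1e-9)

    def test_all_predictions_finite_in_valid_ranges(self, registry):
        frame = self.random_input_frame(n=2000, seed=3)
        for spec in registry:
            if spec.form == "remington_table":
                continue
            sv, applicable = predict_vector(spec, frame)
            assert np.isfinite(sv[applicable]).all()

    def test_composite_formulae_are_scaled_starr_bases(self, registry):
        """Grollman/Warren/Liljestrand/Cathcart are scale·base + offset."""
        frame = self.random_input_frame(n=1000, seed=4)
        base68, _ = predict_vector(registry["starr54_eq68"], frame)
        base59a, _ = predict_vector(registry["starr54_eq59a"], frame)
        for fid, base, scale, offset in [
            ("grollman30", base68, 0.45, 43.0),
            ("warren45", base59a, 1.5, 8.9),
            ("liljestrand28", base68, 1.81, -25.9),
            ("cathcart53", base68, 1.02, 39.6),
        ]:
            got, _ = predict_vector(registry[fid], frame)
            assert np.allclose(got, scale * base + offset, atol=1e-9), fid
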