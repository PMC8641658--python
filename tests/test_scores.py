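import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graftval.errors import InsufficientLabs
from graftval.features import MeafInputs
from graftval.scores import (
    MEAF_MAX,
    assign_risk_group,
    classify_ead,
    ease_linear_predictor,
    ease_score,
    lgraft10_linear_predictor,
    lgraft7_linear_predictor,
    meaf_component,
    meaf_score,
    score_panel,
)
from graftval.synthetic import generate_known_answer_set

from conftest import complete_lab_table, make_labs


def ead_labs(tbil7=2.0, inr7=1.1, alt_peak=500.0, ast_peak=600.0):
    return make_labs(
        "E",
        {
            "TBIL": {7: tbil7},
            "INR": {7: inr7},
            "ALT": {1: alt_peak, 3: alt_peak / 2},
            "AST": {1: ast_peak, 3: ast_peak / 2},
        },
    )


class TestEad:
    def test_bilirubin_boundary_inclusive(self):
        res = classify_ead(ead_labs(tbil7=10.0, inr7=1.2))
        assert res.positive
        assert res.bilirubin_ge_10 and not res.inr_ge_1_6 and not res.transaminase_gt_2000

    def test_transaminase_boundary_strict(self):
        res = classify_ead(ead_labs(tbil7=9.9, inr7=1.59, alt_peak=2000.0, ast_peak=1500.0))
        assert not res.positive

    def test_transaminase_just_over(self):
        res = classify_ead(ead_labs(ast_peak=2000.0000001))
        assert res.positive and res.transaminase_gt_2000

    def test_inr_boundary_inclusive(self):
        assert classify_ead(ead_labs(inr7=1.6)).inr_ge_1_6

    def test_all_normal_all_flags_false(self):
        res = classify_ead(ead_labs())
        assert res == type(res)(False, False, False, False)

    def test_missing_pod7_inr_insufficient(self):
        labs = ead_labs()
        del labs.observations[("INR", 7)]
        with pytest.raises(InsufficientLabs):
            classify_ead(labs)

    @given(
        tbil=st.floats(0.5, 30.0),
        inr=st.floats(0.8, 4.0),
        bump=st.floats(0.0, 3000.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_raising_labs_never_turns_negative(self, tbil, inr, bump):
        base = classify_ead(ead_labs(tbil7=tbil, inr7=inr))
        raised = classify_ead(
            ead_labs(tbil7=tbil + 1.0, inr7=inr + 0.2, ast_peak=600.0 + bump)
        )
        assert not (base.positive and not raised.positive)


class TestMeaf:
    def test_midpoints_give_half_amplitudes(self):
        res = meaf_score(
            MeafInputs(math.exp(6.1723), math.exp(0.6658), math.exp(1.0607))
        )
        assert res.alt_component == pytest.approx(3.29 / 2, abs=1e-12)
        assert res.inr_component == pytest.approx(3.29 / 2, abs=1e-12)
        assert res.bilirubin_component == pytest.approx(3.4 / 2, abs=1e-12)
        assert res.score == pytest.approx(4.99, abs=1e-12)
        assert res.risk_group == 2

    def test_components_against_hand_evaluation(self):
        # independent evaluation of the printed sigmoids
        alt, inr, bil = 1000.0, 1.2, 1.0
        exp_alt = 3.29 / (1 + math.exp(-1.9132 * (math.log(alt) - 6.1723)))
        exp_inr = 3.29 / (1 + math.exp(-6.8204 * (math.log(inr) - 0.6658)))
        exp_bil = 3.4 / (1 + math.exp(-1.8005 * (math.log(bil) - 1.0607)))
        res = meaf_score(MeafInputs(alt, inr, bil))
        assert res.alt_component == pytest.approx(exp_alt, abs=1e-14)
        assert res.inr_component == pytest.approx(exp_inr, abs=1e-14)
        assert res.bilirubin_component == pytest.approx(exp_bil, abs=1e-14)

    def test_upper_limit_is_sum_of_amplitudes(self):
        res = meaf_score(MeafInputs(1e12, 1e12, 1e12))
        assert res.score == pytest.approx(MEAF_MAX, abs=1e-9)
        assert res.score <= 10.0
        assert MEAF_MAX == pytest.approx(9.98)
        assert res.risk_group == 5

    def test_tiny_inputs_do_not_overflow(self):
        res = meaf_score(MeafInputs(1e-300, 1e-300, 1e-300))
        assert res.score >= 0.0

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            meaf_component(0.0, (3.29, 1.9132, 6.1723))

    @given(st.floats(1.0, 1e8), st.floats(1.0, 1e8))
    @settings(max_examples=100, deadline=None)
    def test_component_strictly_increasing_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        params = (3.29, 1.9132, 6.1723)
        ca, cb = meaf_component(lo, params), meaf_component(hi, params)
        assert 0.0 < ca < 3.29 and 0.0 < cb < 3.29
        if hi > lo:
            assert cb > ca


# the printed polynomial coefficients, re-typed as independent term lists
_LG7_TERMS = [
    (-0.5799, "a", 1), (0.00844, "a", 2), (5.25347, "s", 1), (4.65046, "s", 2),
    (-0.03475, "b", 1), (0.00562, "b", 2), (4.31135, "t", 1), (5.84724, "t", 2),
    (-0.05115, "p", 1),
]


def lg7_oracle(a, s, i, b, t, p):
    total = 6.9647 + 1.14098 * math.log(i)
    env = {"a": a, "s": s, "b": b, "t": t, "p": p}
    for coef, var, power in _LG7_TERMS:
        total += coef * env[var] ** power
    return total


class TestLgraft7:
    def test_intercept_feature_vector(self):
        score = lgraft7_linear_predictor(0, 0, 1.0, 0, 0, 0)
        assert score == pytest.approx(6.9647, abs=1e-15)
        rg = assign_risk_group(score, "lgraft7")
        assert rg.group == 7 and rg.high

    def test_spreadsheet_oracle_vector(self):
        got = lgraft7_linear_predictor(10, -0.1, 7, 5, -0.05, 30)
        assert got == pytest.approx(lg7_oracle(10, -0.1, 7, 5, -0.05, 30), abs=1e-12)
        assert got == pytest.approx(1.98, abs=0.2)

    def test_slope_negation_changes_only_linear_term(self):
        s = 0.17
        up = lgraft7_linear_predictor(0, s, 1.0, 0, 0, 0)
        down = lgraft7_linear_predictor(0, -s, 1.0, 0, 0, 0)
        # the quadratic term survives negation, so the change is 2*linear
        assert up - down == pytest.approx(2 * 5.25347 * s, abs=1e-12)

    def test_nonpositive_auc_inr_rejected(self):
        with pytest.raises(ValueError):
            lgraft7_linear_predictor(0, 0, 0.0, 0, 0, 0)


class TestLgraft10:
    def test_intercept_feature_vector(self):
        assert lgraft10_linear_predictor(0, 0, 1.0, 0, 0, 0, 0) == pytest.approx(
            9.77, abs=1e-15
        )

    def test_oracle_vector(self):
        a, s7, i, b, t, p, u = 20.0, -0.2, 2.1, 8.0, 0.05, 38.0, -0.03
        expected = (
            9.77 - 0.42926 * a + 0.00462 * a**2 + 4.60719 * s7 + 4.4129 * s7**2
            + 0.88974 * math.log(i) - 0.04852 * b + 0.00363 * b**2 + 5.33627 * t
            - 0.04621 * p - 5.24897 * u + 13.08633 * u**2
        )
        assert lgraft10_linear_predictor(a, s7, i, b, t, p, u) == pytest.approx(
            expected, abs=1e-12
        )

    def test_low_score_risk_group_1(self):
        assert assign_risk_group(-3.24, "lgraft10").group == 1


class TestEase:
    def test_intercept(self):
        assert ease_linear_predictor(0, 0, False, 0, 0, 0, 0, False) == pytest.approx(
            -0.602, abs=1e-15
        )

    def test_thrombosis_adds_2_567(self):
        base = ease_linear_predictor(12, 4, False, 30, 35, 0.02, -0.05, False)
        with_thrombosis = ease_linear_predictor(12, 4, True, 30, 35, 0.02, -0.05, False)
        assert with_thrombosis - base == pytest.approx(2.567, abs=1e-12)

    def test_high_volume_center_subtracts_0_402(self):
        base = ease_linear_predictor(12, 4, False, 30, 35, 0.02, -0.05, False)
        high_volume = ease_linear_predictor(12, 4, False, 30, 35, 0.02, -0.05, True)
        assert high_volume - base == pytest.approx(-0.402, abs=1e-12)

    def test_ast_term_is_squared(self):
        a0 = ease_linear_predictor(0, 0, False, 0, 0, 0, 0, False)
        a10 = ease_linear_predictor(0, 0, False, 10, 0, 0, 0, False)
        assert a10 - a0 == pytest.approx(0.000534 * 100, abs=1e-12)

    def test_missing_clinical_inputs(self, complete_labs):
        from graftval.cohort import ClinicalRecord
        from graftval.features import ease_features

        clin = ClinicalRecord(patient_id="PT1")  # no MELD, no RBC
        with pytest.raises(InsufficientLabs, match="meld"):
            ease_score(clin, ease_features(complete_labs))


class TestRiskBins:
    @pytest.mark.parametrize(
        "score,model,group",
        [
            (-1.5, "lgraft7", 4),   # left-closed boundary
            (-0.5000000001, "lgraft7", 4),
            (2.0, "meaf", 1),       # right-closed boundary
            (2.0000000001, "meaf", 2),
            (-1.0, "ease", 3),
            (-3.43, "ease", 2),
            (-1.26, "ease", 2),
            (-1.25, "ease", 3),
            (0.0, "ease", 5),
            (-3.23, "lgraft10", 2),
            (1.3, "lgraft10", 5),
        ],
    )
    def test_printed_bin_boundaries(self, score, model, group):
        assert assign_risk_group(score, model).group == group

    def test_lgraft7_high_low_dichotomy(self):
        assert assign_risk_group(-1.5, "lgraft7").high is True
        assert assign_risk_group(-1.6, "lgraft7").high is False

    def test_ease_gap_values_resolved_by_rounding(self):
        # raw scores inside the printed 0.01-wide gaps still land in a bin
        assert assign_risk_group(-1.2551, "ease").group == 2   # rounds to -1.26
        assert assign_risk_group(-1.2549, "ease").group == 3   # rounds to -1.25

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_risk_group(8.0, "lgraft7").group == 7
        with pytest.warns(UserWarning):
            assert assign_risk_group(12.0, "ease").group == 5

    def test_infinite_score_rejected(self):
        with pytest.raises(ValueError):
            assign_risk_group(float("inf"), "meaf")

    @given(st.floats(-30, 30))
    @settings(max_examples=300, deadline=None)
    def test_assignment_total_function(self, score):
        import warnings

        for model in ("meaf", "lgraft7", "lgraft10", "ease"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                group = assign_risk_group(score, model).group
            n_groups = {"meaf": 5, "lgraft7": 7, "lgraft10": 5, "ease": 5}[model]
            assert 1 <= group <= n_groups


class TestScorePanel:
    def test_complete_fixture_all_five_present(self, complete_labs, default_clinical):
        panel = score_panel(complete_labs, default_clinical)
        assert all(panel.sufficiency.values())
        assert panel.ead is not None and panel.meaf is not None
        assert panel.lgraft7 is not None and panel.lgraft10 is not None
        assert panel.ease is not None

    def test_missing_pod8_10_flags_10day_models(self, default_clinical):
        table = {
            a: {p: v for p, v in d.items() if p <= 7}
            for a, d in complete_lab_table().items()
        }
        panel = score_panel(make_labs("PT1", table), default_clinical)
        assert panel.sufficiency["lgraft7"] and panel.sufficiency["meaf"]
        assert panel.sufficiency["ead"]
        assert not panel.sufficiency["lgraft10"] and not panel.sufficiency["ease"]
        assert panel.lgraft10 is None and panel.ease is None

    def test_empty_labs_all_absent(self, default_clinical):
        from graftval.cohort import LabSeries

        panel = score_panel(LabSeries("PT1"), default_clinical)
        assert not any(panel.sufficiency.values())


class TestKnownAnswerFixtures:
    def test_known_answers_reproduce(self):
        fixtures = generate_known_answer_set()
        p = score_panel(fixtures["meaf-midpoint"].labs, fixtures["meaf-midpoint"].clinical)
        assert p.meaf.score == pytest.approx(4.99, abs=1e-12)
        assert p.meaf.risk_group == 2

        p = score_panel(fixtures["ead-boundary"].labs, fixtures["ead-boundary"].clinical)
        assert p.ead.positive
        assert (p.ead.bilirubin_ge_10, p.ead.inr_ge_1_6, p.ead.transaminase_gt_2000) == (
            True, False, False,
        )

        fx = fixtures["lgraft7-intercept"]
        p = score_panel(fx.labs, fx.clinical)
        assert p.lgraft7 == pytest.approx(6.9647, abs=1e-12)
        assert p.lgraft7_group == 7 and p.lgraft7_high

        fx = fixtures["lgraft10-intercept"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # the 7-day score clamps on this fixture
            p = score_panel(fx.labs, fx.clinical)
        assert p.lgraft10 == pytest.approx(9.77, abs=1e-12)
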