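import math

import numpy as np
import pandas as pd
import pytest

from exomir import (
    ControlFailedError,
    ValidationError,
    arm_preference,
    censor_cq,
    collate_significant,
    control_cq,
    delta_cq,
    detectability_filter,
    quantify,
    significance_tier,
)
from exomir.qpcr import CONTROL_ASSAYS, CqTable, students_t_test, trim_outliers
from exomir.simulate import CqSimConfig, simulate_cq_table

from conftest import make_cq_table, sample_wells


class TestCensoring:
    def test_imputation_rules(self):
        table = make_cq_table(
            [
                ("s1", "L", 1, 1, "miR-1-5p", 35.6),
                ("s1", "L", 1, 2, "miR-1-5p", None),
                ("s1", "L", 1, 3, "miR-1-5p", 34.2),
                ("s1", "L", 1, 4, "miR-1-5p", 35.0),
            ]
        )
        out = censor_cq(table).data.sort_values("technical_replicate")
        assert out["cq"].tolist() == [36.0, 36.0, 34.2, 35.0]
        assert out["censored"].tolist() == [True, True, False, False]

    def test_idempotent(self):
        table = make_cq_table(
            [("s1", "L", 1, 1, "m", 35.6), ("s1", "L", 1, 2, "m", None)]
        )
        once = censor_cq(table)
        twice = censor_cq(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_invalid_parameters_and_values(self):
        table = make_cq_table([("s1", "L", 1, 1, "m", 30.0)])
        with pytest.raises(ValidationError):
            censor_cq(table, ceiling=36, imputed=36)
        with pytest.raises(ValidationError):
            make_cq_table([("s1", "L", 1, 1, "m", -3.0)])
        with pytest.raises(ValidationError):
            make_cq_table([("s1", "L", 1, 1, "m", 30.0), ("s1", "L", 1, 1, "m", 31.0)])


class TestDetectability:
    @pytest.mark.parametrize("n_detected,expected", [(0, False), (1, False), (2, True)])
    def test_twenty_percent_rule_on_nine_wells(self, n_detected, expected):
        rows = []
        for i in range(9):
            cq = 30.0 if i < n_detected else 36.5
            rows.append(("s1", "L", 1, i, "m", cq))
        report = detectability_filter(make_cq_table(rows))
        assert report.detectable[("L", "m")] is expected

    def test_samples_without_any_value_are_dropped(self):
        rows = [("dead", "L", 1, 1, "m", None), ("alive", "L", 2, 1, "m", 30.0)]
        report = detectability_filter(make_cq_table(rows))
        assert report.dropped_samples == ("dead",)


class TestControlAndDelta:
    def test_control_average_of_two_assays(self):
        rows = sample_wells("s1", "L", 1, {"m": 24.0})
        table = make_cq_table(rows)  # controls at 20 and 22
        assert control_cq(table, "s1") == pytest.approx(21.0)
        assert delta_cq(table, "s1", "m") == pytest.approx(3.0)

    def test_identical_controls_and_zero_delta(self):
        rows = []
        for tech in (1, 2):
            rows += [
                ("s1", "L", 1, tech, CONTROL_ASSAYS[0], 19.5),
                ("s1", "L", 1, tech, CONTROL_ASSAYS[1], 19.5),
                ("s1", "L", 1, tech, "m", 19.5),
            ]
        table = make_cq_table(rows)
        assert control_cq(table, "s1") == pytest.approx(19.5)
        assert delta_cq(table, "s1", "m") == pytest.approx(0.0)

    def test_missing_control_fails_explicitly(self):
        rows = [
            ("s1", "L", 1, 1, CONTROL_ASSAYS[0], 20.0),
            ("s1", "L", 1, 1, CONTROL_ASSAYS[1], None),
            ("s1", "L", 1, 1, "m", 24.0),
        ]
        with pytest.raises(ControlFailedError):
            control_cq(make_cq_table(rows), "s1")

    def test_censored_wells_participate_in_means(self):
        rows = [
            ("s1", "L", 1, 1, "m", 34.0),
            ("s1", "L", 1, 2, "m", None),  # becomes 36 after censoring
        ] + sample_wells("s1", "L", 1, {})
        table = censor_cq(make_cq_table(rows))
        assert delta_cq(table, "s1", "m") == pytest.approx(35.0 - 21.0)


class TestSignificanceTier:
    @pytest.mark.parametrize(
        "p,tier",
        [
            (0.0691, "ns"),
            (0.04, "*"),
            (0.0005, "***"),
            (0.05, "*"),
            (0.01, "**"),
            (0.001, "***"),
            (0.050001, "ns"),
            (1.0, "ns"),
            (0.0, "***"),
        ],
    )
    def test_tier_map_with_inclusive_boundaries(self, p, tier):
        assert significance_tier(p) == tier

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            significance_tier(bad)


class TestTTest:
    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.normal(0, 1, size=rng.integers(2, 8))
            b = rng.normal(0.5, 2, size=rng.integers(2, 8))
            t, _ = students_t_test(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
            assert t == pytest.approx(expected, abs=1e-10)

    def test_degenerate_zero_variance(self):
        assert students_t_test([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = students_t_test([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(t) and p == 0.0

    def test_outlier_trim_never_drops_below_two(self):
        values = np.array([10.0, 10.1, 55.0])
        trimmed = trim_outliers(values)
        assert len(trimmed) == 2 and 55.0 not in trimmed
        assert len(trim_outliers(np.array([1.0, 99.0]))) == 2


def two_line_config(**kw):
    defaults = dict(
        cell_lines=("CTRL", "TUMOR"),
        mirs=("miR-1-5p", "miR-1-3p"),
        base_cq={"miR-1-5p": 25.0, "miR-1-3p": 27.0},
        control_cell_line="CTRL",
        noise_sd=0.0,
        sample_effect_sd=0.0,
        n_bio=3,
        n_tech=3,
        seed=7,
    )
    defaults.update(kw)
    return CqSimConfig(**defaults)


class TestQuantify:
    def test_noiseless_fold_change_recovery(self):
        table, _ = simulate_cq_table(
            two_line_config(true_log2_fc={("TUMOR", "miR-1-5p"): 3.0})
        )
        frame = quantify(table, "CTRL").to_frame().set_index(["cell_line", "mir"])
        assert frame.loc[("TUMOR", "miR-1-5p"), "log2_fc"] == pytest.approx(3.0)
        assert frame.loc[("TUMOR", "miR-1-3p"), "log2_fc"] == pytest.approx(0.0)

    def test_control_line_vs_itself_is_zero(self):
        table, _ = simulate_cq_table(two_line_config())
        frame = quantify(table, "CTRL").to_frame()
        ctrl = frame[frame["cell_line"] == "CTRL"]
        assert (ctrl["log2_fc"] == 0.0).all() and (ctrl["p_value"] == 1.0).all()

    def test_identical_replicates_give_null_result(self):
        table, _ = simulate_cq_table(two_line_config())
        row = (
            quantify(table, "CTRL")
            .to_frame()
            .set_index(["cell_line", "mir"])
            .loc[("TUMOR", "miR-1-5p")]
        )
        assert row["p_value"] == 1.0 and row["tier"] == "ns"

    def test_one_sided_detection_uses_censored_values(self):
        # detected only in the tumor line; control side sits at the imputed 36
        table, _ = simulate_cq_table(
            two_line_config(
                base_cq={"miR-1-5p": 40.0, "miR-1-3p": 25.0},
                true_log2_fc={("TUMOR", "miR-1-5p"): 8.0},
            )
        )
        row = (
            quantify(table, "CTRL")
            .to_frame()
            .set_index(["cell_line", "mir"])
            .loc[("TUMOR", "miR-1-5p")]
        )
        assert row["one_sided_detection"]
        # tumor delta 32-21=11, censored control delta 36-21=15 -> lfc 4
        assert row["log2_fc"] == pytest.approx(4.0)

    def test_undetectable_in_both_lines_flagged(self):
        table, _ = simulate_cq_table(two_line_config(base_cq={"miR-1-5p": 40.0, "miR-1-3p": 25.0}))
        row = (
            quantify(table, "CTRL")
            .to_frame()
            .set_index(["cell_line", "mir"])
            .loc[("TUMOR", "miR-1-5p")]
        )
        assert not row["detectable"] and math.isnan(row["log2_fc"])

    def test_record_order_invariance(self):
        table, _ = simulate_cq_table(
            two_line_config(noise_sd=0.3, true_log2_fc={("TUMOR", "miR-1-5p"): 2.0})
        )
        shuffled = CqTable(data=table.data.sample(frac=1.0, random_state=5))
        pd.testing.assert_frame_equal(
            quantify(table, "CTRL").to_frame(), quantify(shuffled, "CTRL").to_frame()
        )

    def test_missing_control_line_rejected(self):
        table, _ = simulate_cq_table(two_line_config())
        with pytest.raises(ValidationError):
            quantify(table, "NOPE")

    def test_bh_adjustment_is_available_but_separate(self):
        table, _ = simulate_cq_table(
            two_line_config(noise_sd=0.2, true_log2_fc={("TUMOR", "miR-1-5p"): 4.0})
        )
        results = quantify(table, "CTRL")
        frame = results.with_adjusted_pvalues()
        assert "p_adjusted" in frame.columns
        mask = frame["p_adjusted"].notna()
        assert (frame.loc[mask, "p_adjusted"] >= frame.loc[mask, "p_value"] - 1e-12).all()


class TestCollation:
    def test_all_nonsignificant_gives_empty_list(self):
        table, _ = simulate_cq_table(two_line_config())
        collation = collate_significant(quantify(table, "CTRL"))
        assert collation.significant == ()


class TestArmPreference:
    def test_symmetric_arms_have_no_preference(self):
        rows = []
        for bio, shift in enumerate((0.0, 0.3, -0.3), start=1):
            rows += sample_wells(
                f"s{bio}", "L", bio, {"miR-9-5p": 28.0 + shift, "miR-9-3p": 28.0 + shift}
            )
        comparison = arm_preference(make_cq_table(rows), "miR-9", "L")
        assert comparison.rel_expr_3p_vs_5p == pytest.approx(1.0)
        assert comparison.preferred_arm == "none"

    def test_rel_expression_follows_delta_cq_difference(self):
        rows = []
        for bio in (1, 2, 3):
            rows += sample_wells(
                f"s{bio}", "L", bio,
                {"miR-9-5p": 25.0 + 0.01 * bio, "miR-9-3p": 28.0 + 0.01 * bio},
            )
        comparison = arm_preference(make_cq_table(rows), "miR-9", "L")
        assert comparison.rel_expr_3p_vs_5p == pytest.approx(0.125, rel=1e-3)
        assert comparison.preferred_arm == "5p"
        assert comparison.p_value <= 0.05

    def test_single_arm_family_not_applicable(self):
        rows = sample_wells("s1", "L", 1, {"miR-429": 30.0})
        comparison = arm_preference(make_cq_table(rows), "miR-429", "L")
        assert not comparison.applicable

    def test_fully_undetected_arm_is_flagged_and_censored(self):
        rows = []
        for bio in (1, 2, 3):
            rows += sample_wells(
                f"s{bio}", "L", bio, {"miR-9-5p": 27.0 + 0.01 * bio, "miR-9-3p": None}
            )
        comparison = arm_preference(make_cq_table(rows), "miR-9", "L")
        assert comparison.one_arm_undetected
        # 3p side enters at the imputed 36: rel = 2^(~6 - 15)
        assert comparison.rel_expr_3p_vs_5p == pytest.approx(2.0 ** (27.01 - 36.0), rel=1e-2)
        assert comparison.preferred_arm == "5p"
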