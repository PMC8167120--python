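"""Dual-flashlight classification rules, counts, and exports."""

import pytest

from fluxscreen import (
    Category,
    ConditionEffect,
    EffectSummary,
    Thresholds,
    classify_compound,
    classify_screen,
    dual_flashlight_export,
    flag_autofluorescence,
    published_condition_effects,
    ssmd_from_moments,
)
from fluxscreen.hits import counts_to_dict


def eff(cid, cond, d, s, n=3):
    return ConditionEffect(
        summary=EffectSummary.from_moments(cid, cond, d, s, n),
        ssmd=ssmd_from_moments(cid, cond, d, s, n),
    )


class TestClassifyCompound:
    def test_flux_inhibitor_from_starvation_only_qualifying(self):
        call = classify_compound(
            eff("Arzanol", "full", 5.0, 10.0),
            eff("Arzanol", "starvation", 164.6, 63.9),
        )
        assert call.category is Category.FLUX_INHIBITOR

    def test_dual_modulator(self):
        call = classify_compound(
            eff("P05E07", "full", -34.4, 6.0),
            eff("P05E07", "starvation", 67.4, 19.5),
        )
        assert call.category is Category.DUAL_MODULATOR

    def test_large_ssmd_but_small_effect_is_not_a_hit(self):
        call = classify_compound(eff("X", "full", -14.9, 1.0), None)
        assert call.category is Category.NO_EFFECT
        assert "missing_condition" in call.flags

    def test_inclusive_boundary(self):
        # exactly -15% and exactly SSMD -1.0 qualifies (comparisons are >=)
        from fluxscreen import SSMDResult, Condition

        summary = EffectSummary.from_moments("X", "full", -15.0, 6.0, 3)
        ssmd = SSMDResult(
            compound_id="X",
            condition=Condition.FULL,
            ssmd_umvue=-1.0,
            ssmd_mm=-1.0 * (3.14159265**0.5),
            n=3,
            correction_factor=1 / 3.14159265**0.5,
        )
        call = classify_compound(ConditionEffect(summary, ssmd), None)
        assert call.category is Category.INDUCER

    def test_basal_inhibitor(self):
        call = classify_compound(eff("X", "full", 40.0, 10.0), None)
        assert call.category is Category.BASAL_INHIBITOR

    def test_both_conditions_absent_rejected(self):
        with pytest.raises(ValueError):
            classify_compound(None, None)


class TestMonotonicity:
    @pytest.mark.parametrize("d,s", [(-20.0, 8.0), (30.0, 10.0), (160.0, 60.0)])
    def test_raising_thresholds_never_creates_hits(self, d, s):
        base = classify_compound(eff("X", "full", d, s), None, Thresholds())
        for effect_th in (15.0, 25.0, 50.0, 200.0):
            for ssmd_th in (1.0, 2.0, 5.0):
                call = classify_compound(
                    eff("X", "full", d, s),
                    None,
                    Thresholds(effect_percent=effect_th, ssmd_abs=ssmd_th),
                )
                if base.category is Category.NO_EFFECT:
                    assert call.category is Category.NO_EFFECT


@pytest.fixture(scope="module")
def published():
    full = published_condition_effects("full")
    starv = published_condition_effects("starvation")
    return classify_screen(full, starv)


class TestScreenClassification:

    def test_inducer_qualifying_count_is_8(self, published):
        _, counts = published
        assert counts.inducers_total == 8

    def test_starvation_inhibitor_count_is_64(self, published):
        _, counts = published
        assert counts.starvation_inhibitors_total == 64

    def test_four_dual_modulators_by_intersection(self, published):
        calls, counts = published
        duals = {
            c.compound_id for c in calls if c.category is Category.DUAL_MODULATOR
        }
        assert duals == {"P05E07", "P04C02", "P05C06", "P03F08"}
        assert counts.dual_modulator == 4

    def test_partition_is_exhaustive_and_exclusive(self, published):
        calls, counts = published
        assert counts.n_compounds == len(calls)
        assert len({c.compound_id for c in calls}) == len(calls)

    def test_all_no_effect_when_nothing_qualifies(self):
        full = [eff(f"X{i}", "full", 5.0, 10.0) for i in range(5)]
        calls, counts = classify_screen(full, [])
        assert all(c.category is Category.NO_EFFECT for c in calls)
        assert counts.no_effect == 5


class TestAutofluorescence:
    def test_extreme_signal_flagged(self):
        call = classify_compound(None, eff("P05D05", "starvation", 2590.4, 765.1))
        assert "autofluorescence_suspect" in call.flags
        assert call.category is Category.FLUX_INHIBITOR  # category unchanged

    def test_moderate_signal_not_flagged(self):
        call = classify_compound(None, eff("Arzanol", "starvation", 164.6, 63.9))
        assert "autofluorescence_suspect" not in call.flags

    def test_lower_user_threshold_flags_more(self):
        th = Thresholds(autofluorescence_percent=200.0)
        call = classify_compound(
            None, eff("P05B05", "starvation", 234.4, 44.8), th
        )
        assert "autofluorescence_suspect" in call.flags

    def test_flag_never_changes_category(self):
        call = classify_compound(None, eff("X", "starvation", 30.0, 10.0))
        flagged = flag_autofluorescence(
            call, Thresholds(autofluorescence_percent=20.0)
        )
        assert flagged.category is call.category
        assert "autofluorescence_suspect" in flagged.flags


class TestExport:
    def test_inducer_rows_have_negative_axes(self):
        full = published_condition_effects("full")
        calls, _ = classify_screen(full, [])
        frame = dual_flashlight_export(calls)
        assert len(frame) == 8
        assert (frame["mean_difference"] < 0).all()
        assert (frame["ssmd_umvue"] < 0).all()

    def test_empty_input_empty_table(self):
        assert dual_flashlight_export([]).empty

    def test_reclassify_from_export_is_idempotent(self):
        full = published_condition_effects("full")
        starv = published_condition_effects("starvation")
        calls, _ = classify_screen(full, starv)
        frame = dual_flashlight_export(calls)
        # rebuild effects from the exported axes values and re-classify
        rebuilt_full, rebuilt_starv = [], []
        for row in frame.itertuples(index=False):
            e = eff(row.compound_id, row.condition, row.mean_difference, row.sd, row.n)
            (rebuilt_full if row.condition == "full" else rebuilt_starv).append(e)
        calls2, _ = classify_screen(rebuilt_full, rebuilt_starv)
        cat1 = {c.compound_id: c.category for c in calls}
        cat2 = {c.compound_id: c.category for c in calls2}
        assert cat1 == cat2

    def test_counts_dict_partition_arithmetic(self):
        full = published_condition_effects("full")
        starv = published_condition_effects("starvation")
        _, counts = classify_screen(full, starv)
        d = counts_to_dict(counts)
        assert (
            d["starvation_inhibitors_total"]
            - d["dual_modulator"]
            - d["basal_inhibitor"]
            == d["flux_inhibitor"]
        )
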