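"""Vehicle normalization, effect summaries, and SSMD estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxscreen import (
    Condition,
    effect_summary,
    percent_of_control,
    screen_effects,
    ssmd_from_moments,
    ssmd_umvue,
    umvue_correction_factor,
)
from fluxscreen.simulate import ScreenSimConfig, simulate_screen

from conftest import random_screen_table


class TestPercentOfControl:
    def test_exact_doubling(self, small_screen):
        pct = percent_of_control(small_screen, "starvation")
        assert pct["A1"] == pytest.approx([200.0, 200.0, 200.0])

    def test_vehicle_self_normalizes_to_mean_100(self, small_screen):
        pct = percent_of_control(small_screen, "full")
        assert np.mean(pct["DMSO"]) == pytest.approx(100.0)

    def test_hand_arithmetic(self, small_screen):
        # vehicle mean 1000; compound medians 550/990/1100
        pct = percent_of_control(small_screen, "full")
        assert pct["A1"] == pytest.approx([55.0, 99.0, 110.0])

    def test_no_vehicle_raises(self, small_screen):
        small_screen.wells = [
            w for w in small_screen.wells if w.compound_id != "DMSO"
        ]
        with pytest.raises(ValueError, match="vehicle"):
            percent_of_control(small_screen, "full")


class TestEffectSummary:
    def test_no_effect_no_spread(self):
        s = effect_summary("X", "full", [100.0, 100.0, 100.0])
        assert s.mean_difference == 0.0 and s.sd == 0.0 and s.n == 3

    def test_closed_form_sample_sd(self):
        s = effect_summary("X", "full", [90.0, 100.0, 110.0])
        assert s.mean_difference == pytest.approx(0.0)
        assert s.sd == pytest.approx(10.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            effect_summary("X", "full", [100.0])


class TestUMVUEFactor:
    def test_n3_is_inverse_sqrt_pi(self):
        assert umvue_correction_factor(3) == pytest.approx(1 / math.sqrt(math.pi), rel=1e-12)

    def test_monotone_increase_to_one(self):
        factors = [umvue_correction_factor(n) for n in range(3, 101)]
        assert all(b > a for a, b in zip(factors, factors[1:]))
        assert factors[-1] < 1.0
        assert factors[-1] > 0.99

    def test_n_below_3_rejected(self):
        with pytest.raises(ValueError):
            umvue_correction_factor(2)


class TestSSMD:
    @pytest.mark.parametrize(
        "d, s, expected",
        [
            (164.6, 63.9, 1.45),   # flux-inhibitor hit row (arzanol)
            (-22.0, 11.2, -1.11),  # inducer hit row
            (-18.1, 8.1, -1.26),
            (78.1, 19.0, 2.32),
        ],
    )
    def test_published_rows_two_decimals(self, d, s, expected):
        r = ssmd_from_moments("X", "full", d, s, 3)
        assert round(r.ssmd_umvue, 2) == expected

    def test_zero_numerator(self):
        r = ssmd_from_moments("X", "full", 0.0, 5.0, 3)
        assert r.ssmd_umvue == 0.0

    def test_degenerate_sd_flagged_with_signed_infinity(self):
        summ = effect_summary("X", "full", [120.0, 120.0, 120.0])
        r = ssmd_umvue(summ)
        assert r.degenerate and r.ssmd_umvue == math.inf
        down = ssmd_from_moments("X", "full", -20.0, 0.0, 3)
        assert down.degenerate and down.ssmd_umvue == -math.inf

    def test_n_below_3_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ssmd_from_moments("X", "full", 10.0, 5.0, 2)

    def test_umvue_equals_factor_times_mm(self):
        for n in (3, 5, 10, 50):
            r = ssmd_from_moments("X", "full", 30.0, 12.0, n)
            assert r.ssmd_umvue == pytest.approx(
                umvue_correction_factor(n) * r.ssmd_mm, rel=1e-12
            )
            assert math.copysign(1, r.ssmd_umvue) == math.copysign(
                1, r.ssmd_mm
            )

    def test_unbiased_on_normal_triplicates(self):
        """Mean of the UMVUE over simulated triplicates recovers beta;
        the moment estimate is inflated by sqrt(pi) for n = 3."""
        rng = np.random.default_rng(7)
        beta, sigma, m = 1.0, 10.0, 20_000
        draws = rng.normal(beta * sigma, sigma, size=(m, 3))
        d = draws.mean(axis=1)
        s = draws.std(axis=1, ddof=1)
        umvue = (1 / math.sqrt(math.pi)) * d / s
        est = np.array(
            [
                ssmd_from_moments("X", "full", di, si, 3).ssmd_umvue
                for di, si in zip(d[:200], s[:200])
            ]
        )
        np.testing.assert_allclose(est, umvue[:200], rtol=1e-12)
        se = umvue.std(ddof=1) / math.sqrt(m)
        assert abs(umvue.mean() - beta) < 3 * se


class TestScaleInvariance:
    @given(c=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_global_rescaling_leaves_effects_unchanged(self, c, seed):
        rng = np.random.default_rng(seed)
        table = random_screen_table(rng, n_compounds=3)
        base = {
            (s.compound_id, s.condition): (s.mean_difference, s.sd, r.ssmd_umvue)
            for s, r in screen_effects(table, "full")
        }
        import dataclasses

        table.wells = [
            dataclasses.replace(w, median_fluorescence=w.median_fluorescence * c)
            for w in table.wells
        ]
        scaled = {
            (s.compound_id, s.condition): (s.mean_difference, s.sd, r.ssmd_umvue)
            for s, r in screen_effects(table, "full")
        }
        for key, (d0, s0, b0) in base.items():
            d1, s1, b1 = scaled[key]
            assert d1 == pytest.approx(d0, abs=1e-9)
            assert s1 == pytest.approx(s0, abs=1e-9)
            assert b1 == pytest.approx(b0, rel=1e-9, abs=1e-9)


def test_planted_effect_recovered_within_se():
    """A 2x planted fold-change under starvation comes back as roughly
    +100% mean difference across seeds."""
    diffs = []
    for seed in range(30):
        cfg = ScreenSimConfig(
            n_compounds=5,
            replicate_cv=0.05,
            planted_effects={"C001": {Condition.STARVATION: 2.0}},
            seed=seed,
            n_vehicle_replicates=6,
        )
        table, _ = simulate_screen(cfg)
        effs = dict(
            (s.compound_id, s.mean_difference)
            for s, _ in screen_effects(table, "starvation")
        )
        diffs.append(effs["C001"])
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - 100.0) < 3 * se + 1.0
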