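"""Calibration, LOD/LOQ, Langmuir, repeatability and panel statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eisassay import (
    CalibrationModel,
    DoseResponseSeries,
    compare_conditions,
    fit_langmuir,
    fit_semilog,
    invert_calibration,
    lod_blank_plus_3sd,
    lod_sigma33_over_slope,
    repeatability_rsd,
)
from eisassay.assay import CalibrationRangeWarning

INTEGRIN_CONCS = [1.0, 2.0, 4.0, 5.0, 10.0, 20.0]
SEV_CONCS = [1e2, 1e3, 1e4, 1e5]


def line_series(slope, intercept, concs, unit="ng/mL", blanks=()):
    pts = tuple(
        (c, np.array([slope * np.log10(c) + intercept])) for c in concs
    )
    return DoseResponseSeries(
        analyte="test", unit=unit, points=pts, blanks=np.asarray(blanks, float)
    )


class TestSemilog:
    def test_exact_integrin_line(self):
        model = fit_semilog(line_series(10944.0, 3940.0, INTEGRIN_CONCS))
        assert model.slope == pytest.approx(10944.0, rel=1e-9)
        assert model.intercept == pytest.approx(3940.0, rel=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.range == (1.0, 20.0)

    def test_exact_sev_line(self):
        model = fit_semilog(line_series(5860.0, 11400.0, SEV_CONCS, unit="S-EVs/mL"))
        assert model.slope == pytest.approx(5860.0, rel=1e-9)
        assert model.intercept == pytest.approx(11400.0, rel=1e-9)

    def test_two_points_interpolate_exactly(self):
        model = fit_semilog(line_series(5000.0, 100.0, [1.0, 10.0]))
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_window_restricts_fit(self):
        # outside-window points lie off the line; the windowed fit ignores them
        s = line_series(10944.0, 3940.0, INTEGRIN_CONCS)
        pts = s.points + ((50.0, np.array([30000.0])),)
        s2 = DoseResponseSeries(analyte="t", unit="ng/mL", points=pts)
        model = fit_semilog(s2, window=(1.0, 20.0))
        assert model.slope == pytest.approx(10944.0, rel=1e-9)
        assert model.range == (1.0, 20.0)

    def test_replicates_enter_individually(self):
        pts = tuple(
            (c, 10944.0 * np.log10(c) + 3940.0 + np.array([-500.0, 500.0]))
            for c in INTEGRIN_CONCS
        )
        s = DoseResponseSeries(analyte="t", unit="ng/mL", points=pts)
        model = fit_semilog(s)
        assert model.n_points == 12
        assert model.slope == pytest.approx(10944.0, rel=1e-9)  # symmetric noise
        assert model.r_squared < 1.0

    def test_rejects_single_concentration(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_semilog(line_series(1.0, 0.0, [5.0]))

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError, match="> 0"):
            DoseResponseSeries(
                analyte="t", unit="ng/mL", points=((0.0, np.array([1.0])),)
            )

    def test_zero_noise_recovery_property(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            slope = rng.uniform(100, 2e4)
            intercept = rng.uniform(0, 2e4)
            m = fit_semilog(line_series(slope, intercept, [1, 3, 10, 30, 100]))
            assert m.slope == pytest.approx(slope, rel=1e-9)
            assert m.intercept == pytest.approx(intercept, rel=1e-9)

    def test_slope_unbiased_under_multiplicative_noise(self):
        sigma, slope, intercept = 0.05, 10944.0, 3940.0
        ests = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pts = tuple(
                (c, (slope * np.log10(c) + intercept)
                 * rng.lognormal(0, sigma, 3))
                for c in INTEGRIN_CONCS
            )
            s = DoseResponseSeries(analyte="t", unit="ng/mL", points=pts)
            ests.append(fit_semilog(s).slope)
        assert abs(np.mean(ests) - slope) < sigma * slope / 10


class TestInvert:
    def test_intercept_maps_to_unit_concentration(self):
        m = CalibrationModel(10944.0, 3940.0, 0.986, (1.0, 20.0), "ng/mL")
        assert invert_calibration(m, 3940.0) == pytest.approx(1.0, rel=1e-12)

    def test_four_decades(self):
        m = CalibrationModel(5860.0, 11400.0, 0.985, (1e2, 1e5), "S-EVs/mL")
        assert invert_calibration(m, 11400.0 + 5860.0 * 4) == pytest.approx(
            1e4, rel=1e-12
        )

    def test_round_trip_identity(self):
        m = CalibrationModel(10944.0, 3940.0, 1.0, (1.0, 20.0), "ng/mL")
        for c in [1.0, 2.7, 19.0]:
            assert invert_calibration(m, float(m.predict(c))) == pytest.approx(
                c, rel=1e-12
            )

    def test_out_of_range_warns(self):
        m = CalibrationModel(10944.0, 3940.0, 1.0, (1.0, 20.0), "ng/mL")
        with pytest.warns(CalibrationRangeWarning):
            invert_calibration(m, 100.0)

    def test_zero_slope_refused(self):
        m = CalibrationModel(0.0 + 1e-300, 0.0, 1.0, (1.0, 2.0), "ng/mL")
        object.__setattr__(m, "slope", 0.0)
        with pytest.raises(ZeroDivisionError):
            invert_calibration(m, 10.0)


class TestLodBlank3SD:
    MODEL = CalibrationModel(10944.0, 3940.0, 0.986, (1.0, 20.0), "ng/mL")

    def test_arithmetic_oracle(self):
        # blanks {3900, 3940, 3980}: mean 3940, sd 40, threshold 4060;
        # lod = 10**(120/10944) frozen from the closed-form oracle
        res = lod_blank_plus_3sd([3900.0, 3940.0, 3980.0], self.MODEL)
        assert res.blank_mean == pytest.approx(3940.0)
        assert res.blank_sd == pytest.approx(40.0)
        assert res.lod == pytest.approx(1.0255690646571352, rel=1e-12)
        assert res.lod == pytest.approx(10 ** (120 / 10944), rel=1e-12)

    def test_zero_sd_degenerates_to_mean(self):
        res = lod_blank_plus_3sd([3940.0, 3940.0, 3940.0], self.MODEL)
        assert res.lod == pytest.approx(invert_calibration(self.MODEL, 3940.0))

    def test_loq_is_exactly_three_lod(self):
        res = lod_blank_plus_3sd([3711.0, 3940.2, 4031.7], self.MODEL)
        assert res.loq == 3.0 * res.lod

    def test_requires_three_blanks(self):
        with pytest.raises(ValueError, match=">= 3"):
            lod_blank_plus_3sd([3900.0, 3980.0], self.MODEL)

    def test_monotone_in_blank_sd_and_slope(self):
        lods_sd = [
            lod_blank_plus_3sd([3940 - d, 3940.0, 3940 + d], self.MODEL).lod
            for d in (10.0, 40.0, 160.0)
        ]
        assert lods_sd[0] < lods_sd[1] < lods_sd[2]
        blanks = [3900.0, 3940.0, 3980.0]
        lods_slope = [
            lod_blank_plus_3sd(
                blanks,
                CalibrationModel(s, 3940.0, 1.0, (1.0, 20.0), "ng/mL"),
            ).lod
            for s in (20000.0, 10944.0, 5000.0)
        ]
        assert lods_slope[0] < lods_slope[1] < lods_slope[2]


class TestLodSigma33:
    MODEL = CalibrationModel(5860.0, 11400.0, 0.985, (1e2, 1e5), "S-EVs/mL")

    def test_hand_formula_with_anchor(self):
        sd = 1200.0
        res = lod_sigma33_over_slope(sd, self.MODEL)
        assert res.lod == pytest.approx(10 ** (2 + 3.3 * sd / 5860.0), rel=1e-12)
        assert res.method == "sigma33_over_slope"
        assert "log10" in res.note

    def test_zero_noise_limit_is_anchor(self):
        res = lod_sigma33_over_slope(1e-9, self.MODEL)
        assert res.lod == pytest.approx(1e2, rel=1e-6)

    def test_doubling_sd_doubles_log_increment(self):
        r1 = lod_sigma33_over_slope(500.0, self.MODEL)
        r2 = lod_sigma33_over_slope(1000.0, self.MODEL)
        dx1 = math.log10(r1.lod / 1e2)
        dx2 = math.log10(r2.lod / 1e2)
        assert dx2 == pytest.approx(2 * dx1, rel=1e-9)

    def test_loq_identity_and_validation(self):
        res = lod_sigma33_over_slope(800.0, self.MODEL)
        assert res.loq == 3.0 * res.lod
        with pytest.raises(ValueError):
            lod_sigma33_over_slope(0.0, self.MODEL)


def langmuir_series(k=5.3, dmax=45000.0, base=3000.0, concs=(0.5, 1, 2, 5, 10, 20, 50),
                    noise_sigma=0.0, seed=0, replicates=1):
    rng = np.random.default_rng(seed)
    pts = []
    for c in concs:
        y = base + dmax * c / (k + c)
        reps = y * rng.lognormal(0, noise_sigma, replicates) if noise_sigma else np.full(replicates, y)
        pts.append((float(c), reps))
    return DoseResponseSeries(analyte="avb6", unit="ng/mL", points=tuple(pts))


class TestLangmuir:
    def test_exact_recovery(self):
        fit = fit_langmuir(langmuir_series())
        assert fit.k_app == pytest.approx(5.3, rel=1e-3)
        assert fit.delta_rct_max == pytest.approx(45000.0, rel=1e-3)
        assert fit.baseline_rct == pytest.approx(3000.0, rel=1e-3)
        assert fit.spans_saturation

    def test_half_saturation_identity(self):
        fit = fit_langmuir(langmuir_series())
        assert float(fit.predict(fit.k_app)) - fit.baseline_rct == pytest.approx(
            fit.delta_rct_max / 2, rel=1e-12
        )

    def test_noisy_median_within_10_percent(self):
        ks = [
            fit_langmuir(langmuir_series(noise_sigma=0.05, seed=s)).k_app
            for s in range(50)
        ]
        assert abs(np.median(ks) - 5.3) / 5.3 <= 0.10

    def test_blanks_pin_baseline(self):
        s = langmuir_series()
        s2 = DoseResponseSeries(
            analyte=s.analyte, unit=s.unit, points=s.points,
            blanks=np.array([3000.0, 3000.0, 3000.0]),
        )
        fit = fit_langmuir(s2)
        assert fit.baseline_rct == pytest.approx(3000.0, rel=1e-6)

    def test_needs_four_concentrations(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_langmuir(langmuir_series(concs=(1, 5, 20)))

    def test_not_spanning_saturation_warns(self):
        with pytest.warns(UserWarning, match="saturation"):
            fit = fit_langmuir(langmuir_series(k=100.0, concs=(0.5, 1, 2, 4, 8)))
        assert not fit.spans_saturation


class TestRepeatability:
    def test_identical_values(self):
        assert repeatability_rsd([10.0, 10.0, 10.0]) == (10.0, 0.0, 0.0)

    def test_printed_moments_quotient(self):
        # mean 39.5 kOhm, sd 4 kOhm: the exact RSD is 10.126...%, not 11%
        vals = [35.5e3, 39.5e3, 43.5e3]  # mean 39.5e3, sd 4e3 exactly
        mean, sd, rsd = repeatability_rsd(vals)
        assert mean == pytest.approx(39.5e3)
        assert sd == pytest.approx(4.0e3)
        assert rsd == pytest.approx(10.126582278481013, rel=1e-9)

    def test_hand_computed_oracle(self):
        mean, sd, rsd = repeatability_rsd([36e3, 39e3, 43.5e3])
        assert mean == pytest.approx(39.5e3)
        assert sd == pytest.approx(3774.917217635375, rel=1e-12)
        assert rsd == pytest.approx(9.55675244970981, rel=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            repeatability_rsd([5.0])

    @given(
        scale=st.floats(1e-3, 1e6),
        values=st.lists(st.floats(1.0, 1e3), min_size=2, max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_rsd_scale_invariance(self, scale, values):
        _, _, rsd1 = repeatability_rsd(values)
        _, _, rsd2 = repeatability_rsd([scale * v for v in values])
        assert rsd2 == pytest.approx(rsd1, rel=1e-9, abs=1e-9)


class TestCompareConditions:
    BLANK = [1950.0, 2000.0, 2050.0]  # mean 2000, sd 50

    def test_group_identical_to_blank_not_detected(self):
        df = compare_conditions({"same": self.BLANK}, self.BLANK)
        assert df.loc[0, "fold_over_blank"] == pytest.approx(1.0)
        assert not df.loc[0, "detected"]

    def test_threshold_construction(self):
        # target at blank + 10*SD, interferent at blank + 0.5*SD
        groups = {
            "avb6": [2000 + 10 * 50] * 3,
            "avb3": [2000 + 0.5 * 50] * 3,
        }
        df = compare_conditions(groups, self.BLANK)
        assert df.set_index("label")["detected"].to_dict() == {
            "avb6": True,
            "avb3": False,
        }

    def test_six_group_panel_flags(self):
        # hand check: threshold = 2000 + 3*50 = 2150; only R80/PC3 exceed it
        groups = {
            "R80": [9000.0, 9100.0],
            "PC3": [7000.0, 7100.0],
            "A549": [2050.0, 2080.0],
            "HCT116": [2100.0, 2090.0],
            "H460": [2010.0, 1990.0],
            "HEK293": [2060.0, 2040.0],
        }
        df = compare_conditions(groups, self.BLANK)
        flags = df.set_index("label")["detected"]
        assert flags["R80"] and flags["PC3"]
        assert not flags[["A549", "HCT116", "H460", "HEK293"]].any()
        assert list(df["mean"]) == sorted(df["mean"], reverse=True)
        assert df.attrs["threshold"] == pytest.approx(2150.0)

    def test_rejects_small_groups(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_conditions({"x": [1.0]}, self.BLANK)
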