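import math

import numpy as np
import pandas as pd
import pytest

from platequant.calibration import (
    TimeCourse,
    fit_calibration,
    precision_accuracy,
    predict_product_concentration,
    recovery,
    select_stabilization_time,
)
from platequant.plate import PrepChain
from platequant.photometry import extract_plate
from platequant.simulate import (
    ColourModel,
    NoiseModel,
    calibration_design_layout,
    render_plate,
)


def normal_equation_fit(x, y):
    """Independent closed-form OLS oracle (textbook normal equations)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    slope = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    return slope, intercept


def standards_frame(conc, sig, role=None):
    df = pd.DataFrame({"conc_pct_wv": conc, "signal": sig})
    if role is not None:
        df["role"] = role
    return df


class TestFitCalibration:
    def test_exact_line(self):
        c = np.array([0.5, 1.0, 1.5, 2.0])
        model = fit_calibration(standards_frame(c, 2 * c + 1))
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.s_r == pytest.approx(0.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0)

    def test_lod_loq_formulas(self):
        """With S_r = 0.0072*m/3.3 the LOD is 0.0072 and the LOQ 0.0218."""
        rng = np.random.default_rng(5)
        c = np.linspace(0.04, 0.125, 8)
        model = fit_calibration(standards_frame(c, 1865 * c - 19 + rng.normal(0, 2, 8)))
        # ratio holds exactly whatever the data
        assert model.loq / model.lod == pytest.approx(10 / 3.3, rel=1e-12)
        assert model.lod < model.loq
        implied_lod = 3.3 * model.s_r / model.slope
        assert model.lod == pytest.approx(implied_lod, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.01, 0.2, 12)
        s = rng.normal(0, 50, 12) + 800 * c
        model = fit_calibration(standards_frame(c, s), exclude_blank=False)
        slope, intercept = normal_equation_fit(c, s)
        assert model.slope == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-10)

    def test_blank_exclusion(self):
        conc = [0.0, 0.04, 0.08, 0.125]
        sig = [40.0, 1865 * 0.04 - 19, 1865 * 0.08 - 19, 1865 * 0.125 - 19]
        role = ["blank", "standard", "standard", "standard"]
        excl = fit_calibration(standards_frame(conc, sig, role))
        incl = fit_calibration(standards_frame(conc, sig, role), exclude_blank=False)
        assert excl.n_points == 3 and incl.n_points == 4
        # the chromatically different blank drags the fit off the true line
        assert excl.s_r == pytest.approx(0.0, abs=1e-10)
        assert incl.s_r > 1.0

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match=">= 3 distinct"):
            fit_calibration(standards_frame([0.04, 0.08], [50, 120]))

    def test_nonincreasing_signal_flagged(self):
        c = np.array([0.04, 0.06, 0.08, 0.1])
        model = fit_calibration(standards_frame(c, -100 * c + 50))
        assert "nonincreasing_signal" in model.flags


class TestStabilizationTime:
    def first_order_course(self, k=math.log(3) / 90, top=1865.0):
        # acquisitions every 15 min for 3 h, starting at the first
        # post-preparation photograph (no calibration exists at t=0)
        t = np.arange(15.0, 181.0, 15.0)
        return TimeCourse(t, top * (1 - np.exp(-k * t)))

    def test_first_order_selects_90(self):
        """Remaining-gain < 1/3 first happens at 90 min for k = ln3/90."""
        t, flags = select_stabilization_time(self.first_order_course())
        assert t == 90.0
        assert flags == ()

    def test_constant_slopes_flat_flag(self):
        course = TimeCourse(np.array([0.0, 15.0, 30.0]), np.array([5.0, 5.0, 5.0]))
        t, flags = select_stabilization_time(course)
        assert t == 0.0
        assert "flat_course" in flags

    def test_linear_growth_strict_boundary(self):
        """Remaining fraction hits exactly 1/3 at 120; strict < selects 135."""
        t = np.arange(0.0, 181.0, 15.0)
        course = TimeCourse(t, 10.0 * t)
        sel, _ = select_stabilization_time(course)
        assert sel == 135.0

    @pytest.mark.parametrize("lo,hi", [(0.2, 0.4), (0.1, 0.5), (0.3333, 0.34)])
    def test_monotone_in_threshold(self, lo, hi):
        course = self.first_order_course()
        t_lo, _ = select_stabilization_time(course, threshold=lo)
        t_hi, _ = select_stabilization_time(course, threshold=hi)
        assert t_hi <= t_lo

    def test_interval_variant(self):
        course = self.first_order_course()
        t, _ = select_stabilization_time(course, mode="interval", threshold=0.1)
        increments = np.diff(course.slopes) / (course.slopes[-1] - course.slopes[0])
        expected = course.times_min[1:][increments < 0.1][0]
        assert t == expected

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match="3 time points"):
            select_stabilization_time(
                TimeCourse(np.array([0.0, 15.0]), np.array([1.0, 2.0]))
            )


class TestInversePrediction:
    def exact_model(self):
        c = np.linspace(0.04, 0.125, 8)
        return fit_calibration(standards_frame(c, 1865 * c - 19))

    def test_serum_product_conversion(self):
        model = self.exact_model()
        prep = PrepChain(dilution=100, aliquot_ul=320, total_ul=400)
        pred = predict_product_concentration(model, 1865 * 0.08 - 19, prep)
        assert pred.conc_well == pytest.approx(0.08)
        assert pred.conc_product == pytest.approx(10.0)

    def test_concentrated_dissolution(self):
        model = self.exact_model()
        prep = PrepChain(dilution=62.5, aliquot_ul=320, total_ul=400)
        pred = predict_product_concentration(model, 1865 * 0.064 - 19, prep)
        assert pred.conc_product == pytest.approx(5.0)

    def test_signal_at_intercept_is_zero_conc(self):
        model = self.exact_model()
        pred = predict_product_concentration(model, model.intercept)
        assert pred.conc_well == pytest.approx(0.0, abs=1e-12)
        assert "below_loq" in pred.flags
        assert "extrapolation" in pred.flags

    def test_round_trip_exact_when_noise_free(self):
        model = self.exact_model()
        for c in np.linspace(0.04, 0.125, 8):
            pred = predict_product_concentration(model, model.predict_signal(c))
            assert pred.conc_well == pytest.approx(c, rel=1e-12)

    def test_replicates_propagate_sd(self):
        model = self.exact_model()
        sigs = [model.predict_signal(c) for c in (0.079, 0.080, 0.081)]
        pred = predict_product_concentration(
            model, sigs, PrepChain(dilution=100, aliquot_ul=320, total_ul=400)
        )
        assert pred.conc_well == pytest.approx(0.080)
        assert pred.sd_well == pytest.approx(np.std([0.079, 0.080, 0.081], ddof=1))
        assert pred.sd_product == pytest.approx(pred.sd_well * 400 / 320 * 100)


class TestPrecisionAccuracy:
    def test_perfect_replicates(self):
        df = pd.DataFrame({
            "nominal": [0.06] * 3, "value": [0.06] * 3, "image_id": ["a"] * 3,
        })
        reports = precision_accuracy(df)
        for r in reports:
            assert r.accuracy_pct == pytest.approx(0.0)
            assert r.rsd_pct == pytest.approx(0.0)

    def test_nine_ten_eleven(self):
        df = pd.DataFrame({
            "nominal": [10.0] * 3, "value": [9.0, 10.0, 11.0], "image_id": ["a"] * 3,
        })
        reports = {r.scope: r for r in precision_accuracy(df)}
        assert reports["intra_image"].accuracy_pct == pytest.approx(0.0)
        assert reports["intra_image"].rsd_pct == pytest.approx(10.0)

    def test_single_replicate_rejected(self):
        df = pd.DataFrame({"nominal": [10.0], "value": [9.0], "image_id": ["a"]})
        with pytest.raises(ValueError, match="replicate"):
            precision_accuracy(df)

    def test_intra_below_inter_on_default_simulations(self):
        """Exposure jitter between images exceeds replicate spread within one."""
        from platequant.simulate import STANDARD_CONCS

        layout = calibration_design_layout()
        colour = ColourModel()
        level = min(STANDARD_CONCS, key=lambda c: abs(c - 0.09))
        values = []
        for seed in range(20):
            img = render_plate(layout, colour, NoiseModel(seed=seed))
            table = extract_plate(img, layout)
            std = table[np.isclose(table["conc_pct_wv"].astype(float), level)]
            for s in std["signal"]:
                values.append({"nominal": level, "value": s,
                               "image_id": f"img{seed}"})
        reports = {r.scope: r for r in precision_accuracy(pd.DataFrame(values))}
        assert reports["intra_image"].rsd_pct < reports["inter_image"].rsd_pct


class TestRecovery:
    @pytest.mark.parametrize("base,spiked,added,expected", [
        (0.080, 0.100, 0.020, 100.0),
        (0.080, 0.0972, 0.020, 86.0),
        (0.080, 0.1028, 0.020, 114.0),
    ])
    def test_recovery_formula(self, base, spiked, added, expected):
        rep = recovery(base, spiked, added)
        assert rep.recovery_pct == pytest.approx(expected, rel=1e-9)

    def test_positive_spike_required(self):
        with pytest.raises(ValueError, match="positive"):
            recovery(0.08, 0.1, 0.0)


class TestParameterRecovery:
    def test_slope_recovered_across_seeds(self):
        """Mean fitted slope over 20 default simulations is within ±43 of 1865
        and mean R² stays above 0.99."""
        layout = calibration_design_layout()
        colour = ColourModel()
        slopes, r2s = [], []
        for seed in range(1, 21):
            img = render_plate(layout, colour, NoiseModel(seed=seed))
            model = fit_calibration(extract_plate(img, layout))
            slopes.append(model.slope)
            r2s.append(model.r_squared)
        assert abs(np.mean(slopes) - 1865.0) < 43.0
        assert np.mean(r2s) >= 0.99

    def test_round_trip_within_propagated_uncertainty(self):
        """Standards predicted from their own noisy signals land within 3 SD."""
        layout = calibration_design_layout()
        colour = ColourModel()
        img = render_plate(layout, colour, NoiseModel(seed=42))
        table = extract_plate(img, layout)
        model = fit_calibration(table)
        std = table[table["role"] == "standard"]
        for conc, grp in std.groupby("conc_pct_wv"):
            pred = predict_product_concentration(model, grp["signal"].to_numpy())
            sd = max(pred.sd_well, 1e-4)
            assert abs(pred.conc_well - conc) < 3 * sd + 3 * model.s_r / model.slope
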