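"""Single-cell chain: counting statistics, Poisson filter, geometry,
allometry, per-cell assimilation and growth rates."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lakesip import (
    RoiMeasurement,
    SimTruth,
    biovolume,
    calibrate_label_fraction,
    carbon_content,
    cell_assimilation_rate,
    excess_atpct,
    gen_roi_table,
    growth_rate,
    morphotype_summary,
    percell_from_bulk,
    poisson_filter,
    process_roi_table,
    roi_ratio_and_error,
)


def make_roi(n13, n12, n15=0, n14=0, **kw):
    defaults = dict(roi_id="r1", fov_id="f1", morphotype="large_rod")
    defaults.update(kw)
    return RoiMeasurement(
        counts_12C=n12, counts_13C=n13, counts_12C14N=n14, counts_12C15N=n15,
        **defaults,
    )


class TestRatioAndError:
    def test_worked_example(self):
        roi = roi_ratio_and_error(make_roi(400, 40000))
        assert roi.ratio_C == pytest.approx(400 / 40400)
        assert roi.rel_poisson_error_C == pytest.approx(
            math.sqrt(1 / 400 + 1 / 40000), rel=1e-12
        )

    def test_one_percent_error_case(self):
        roi = roi_ratio_and_error(make_roi(10_000, 1_000_000))
        assert roi.rel_poisson_error_C == pytest.approx(0.01004987, rel=1e-6)

    def test_zero_minor_counts_flagged(self):
        roi = roi_ratio_and_error(make_roi(0, 1000))
        assert roi.ratio_C == 0.0
        assert math.isinf(roi.rel_poisson_error_C)
        assert roi.flagged

    def test_zero_total_counts_raises(self):
        with pytest.raises(ValueError):
            roi_ratio_and_error(make_roi(0, 0))

    def test_monte_carlo_sd_matches_formula(self):
        # brute-force Poisson draws vs the closed-form relative ratio error
        rng = np.random.default_rng(11)
        for n in (1e3, 1e4, 1e6):
            p = 0.011
            minor = rng.poisson(n * p, size=100_000)
            major = rng.poisson(n * (1 - p), size=100_000)
            ok = (minor > 0) & (major > 0)
            ratio = minor[ok] / major[ok]
            analytic = math.sqrt(1 / (n * p) + 1 / (n * (1 - p)))
            assert np.std(ratio) / np.mean(ratio) == pytest.approx(analytic, rel=0.10)


class TestPoissonFilter:
    def test_threshold_splits_worked_examples(self):
        bad = make_roi(400, 40000, roi_id="bad")       # rel err 0.0503
        good = make_roi(10_000, 1_000_000, roi_id="good")  # rel err 0.0100
        kept, excluded = poisson_filter([bad, good], threshold=0.05)
        assert [r.roi_id for r in kept] == ["good"]
        assert [r.roi_id for r in excluded] == ["bad"]

    def test_exclusion_matches_closed_form_prediction(self):
        truth = SimTruth(seed=9, true_enrichment=0.0, mean_counts=3000)
        rois = gen_roi_table(truth, n_rois=300, n_background=3)
        kept, excluded = poisson_filter(rois)
        for roi in rois:
            if roi.counts_13C and roi.counts_12C15N:
                predicted_excluded = (
                    math.sqrt(1 / roi.counts_13C + 1 / roi.counts_12C) > 0.05
                    or math.sqrt(1 / roi.counts_12C15N + 1 / roi.counts_12C14N) > 0.05
                )
            else:
                predicted_excluded = True
            assert predicted_excluded == any(r is roi for r in excluded)

    def test_infinite_threshold_keeps_everything(self):
        rois = [make_roi(5, 100), make_roi(1, 10)]
        kept, excluded = poisson_filter(rois, threshold=math.inf)
        assert len(kept) == 2 and not excluded

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            poisson_filter([], threshold=0.0)


class TestExcess:
    def test_subtraction_against_constant_background(self):
        roi = roi_ratio_and_error(make_roi(30_000, 70_000))
        roi = excess_atpct(roi, None)
        assert roi.background_fallback
        assert roi.excess_C_atfrac == pytest.approx(0.30 - 0.011)

    def test_background_roi_near_zero_against_own_fov(self):
        truth = SimTruth(seed=5, true_enrichment=0.21, mean_counts=1e6)
        rois = gen_roi_table(truth, n_rois=50, n_background=5)
        df = process_roi_table(rois)
        sample = df[~df["is_background"]]
        assert sample["excess_C_atfrac"].mean() == pytest.approx(0.21, abs=0.005)
        bgs = [r for r in rois if r.is_background]
        checked = excess_atpct(bgs[0], bgs)
        assert abs(checked.excess_C_atfrac) < 0.005

    def test_two_backgrounds_insufficient(self):
        roi = make_roi(400, 40000)
        bgs = [make_roi(11, 989, roi_id=f"b{i}", is_background=True) for i in range(2)]
        with pytest.raises(ValueError):
            excess_atpct(roi, bgs)


class TestGeometry:
    def test_coccus_inverts_printed_mean_volume(self):
        d = (6 * 3.2 / math.pi) ** (1 / 3)
        assert biovolume("coccus", d) == pytest.approx(3.2)

    def test_degenerate_rod_is_sphere(self):
        assert biovolume("large_rod", 1.2, 1.2) == pytest.approx(
            biovolume("coccus", 1.2)
        )

    def test_filament_cylinder(self):
        assert biovolume("filament", 1.0, 70.4) == pytest.approx(55.3, abs=0.05)

    def test_rod_shorter_than_wide_rejected(self):
        with pytest.raises(ValueError):
            biovolume("small_rod", 1.0, 0.5)


class TestAllometry:
    def test_unit_volume(self):
        assert carbon_content(1.0) == 197.0

    @pytest.mark.parametrize("v,c", [(55.3, 1248.0), (7.4, 494.7), (3.2, 336.4)])
    def test_printed_volumes(self, v, c):
        assert carbon_content(v) == pytest.approx(c, rel=5e-4)

    @given(st.floats(0.01, 1000.0, allow_nan=False))
    def test_strictly_increasing_and_concave(self, v):
        eps = v * 1e-3
        lo, mid, hi = carbon_content(v), carbon_content(v + eps), carbon_content(v + 2 * eps)
        assert lo < mid < hi
        assert (mid - lo) > (hi - mid)  # concavity: exponent < 1


class TestPerCellRates:
    @pytest.mark.parametrize(
        "volume,excess,printed",
        [
            (55.3, 0.29, 30.1),   # Crenothrix-like filaments, hypoxic
            (7.4, 0.24, 9.8),     # large rods, hypoxic
            (3.2, 0.23, 6.4),     # cocci, hypoxic
            (1.6, 0.21, 4.2),     # small rods, hypoxic
            (7.4, 0.21, 8.6),     # large rods, anoxic
        ],
    )
    def test_full_chain_reproduces_reported_rates(self, volume, excess, printed):
        rate = cell_assimilation_rate(carbon_content(volume), excess, 1.0)
        assert rate == pytest.approx(printed, rel=0.05)

    def test_zero_excess_zero_rate(self):
        assert cell_assimilation_rate(500.0, 0.0, 1.0) == 0.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            cell_assimilation_rate(500.0, 0.2, 0.0)


class TestGrowthRate:
    def test_closed_form_values(self):
        assert growth_rate(0.29, 1.0, 0.74) == pytest.approx(0.497, abs=0.001)
        assert growth_rate(0.24, 1.0, 0.74) == pytest.approx(0.392, abs=0.001)

    def test_small_label_taylor_limit(self):
        a, t = 0.74, 1.0
        e = 1e-6
        assert growth_rate(e, t, a) == pytest.approx(e / (a * t), rel=1e-4)

    @given(
        e=st.floats(1e-4, 0.5, allow_nan=False),
        a=st.floats(0.55, 1.0, allow_nan=False),
    )
    def test_exponential_dominates_naive_linear(self, e, a):
        mu = growth_rate(e, 1.0, a)
        assert mu >= e / a

    def test_saturation_raises(self):
        with pytest.raises(ValueError):
            growth_rate(0.8, 1.0, 0.74)

    def test_calibration_recovers_effective_label_fraction(self):
        # pairs generated at a known A must be recovered by the fit
        a_true = 0.8
        pairs = [(e, growth_rate(e, 1.0, a_true)) for e in (0.1, 0.2, 0.3)]
        assert calibrate_label_fraction(pairs) == pytest.approx(a_true, abs=1e-4)

    def test_calibrated_model_reproduces_reported_growth_rates(self):
        pairs = [(0.29, 0.49), (0.24, 0.39), (0.23, 0.38), (0.21, 0.34)]
        a_hat = calibrate_label_fraction(pairs)
        for excess, mu in pairs:
            assert growth_rate(excess, 1.0, a_hat) == pytest.approx(mu, abs=0.02)


class TestPerCellFromBulk:
    def test_anoxic_large_rod_apportionment(self):
        assert percell_from_bulk(0.18, 2.0e4) == pytest.approx(9.0)

    def test_zero_bulk(self):
        assert percell_from_bulk(0.0, 1e4) == 0.0

    def test_inverse_proportionality_in_density(self):
        assert percell_from_bulk(1.0, 5e3) == pytest.approx(
            2 * percell_from_bulk(1.0, 1e4)
        )

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            percell_from_bulk(0.1, 0.0)


def test_morphotype_summary_matches_quantiles():
    truth = SimTruth(seed=6, true_enrichment={"large_rod": 0.2}, mean_counts=1e6)
    rois = gen_roi_table(truth, n_rois=40, n_background=3)
    df = process_roi_table(rois)
    summary = morphotype_summary(df)
    row = summary.loc[summary["morphotype"] == "large_rod"].iloc[0]
    vals = df.loc[df["kept"], "excess_C_atfrac"]
    assert row["median"] == pytest.approx(vals.median())
    assert row["q05"] == pytest.approx(vals.quantile(0.05))
    assert row["n"] == len(vals)
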