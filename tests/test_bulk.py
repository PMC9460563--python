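"""Bulk assay: threshold concentrations, bootstrap fractions, onset, yield."""

import numpy as np
import pytest

from crispritools.assay import (
    AssayParams,
    CultureSeries,
    KnockdownAssay,
    MW_TABLE,
    WellSeries,
    conc_at_threshold,
    detect_onset,
    gfp_fraction,
    growth_rate_at,
    theoretical_yield,
    yield_and_titer,
)
from crispritools.simulate import BulkSimConfig, simulate_plate_reader

LN2 = np.log(2.0)


def _well(conc, well_id="w", role="knockdown", media="minimal"):
    """A well whose OD hits the minimal-media threshold (0.05) exactly at a
    sample where fluorescence equals conc * 0.05."""
    od = np.array([0.025, 0.05, 0.1, 0.2])
    t = np.arange(4.0)
    return WellSeries(well_id, role, media, t, od, conc * od)


class TestConcAtThreshold:
    def test_exact_sample_crossing(self):
        w = WellSeries(
            "a", "knockdown", "minimal",
            np.arange(4.0), np.array([0.02, 0.05, 0.1, 0.2]),
            np.array([100.0, 500.0, 900.0, 1800.0]),
        )
        assert conc_at_threshold(w) == pytest.approx(500.0 / 0.05)

    def test_interpolated_crossing(self):
        w = WellSeries(
            "a", "knockdown", "minimal",
            np.array([0.0, 1.0]), np.array([0.04, 0.06]), np.array([40.0, 60.0]),
        )
        # crossing halfway: F* = 50, conc = 50 / 0.05 = 1000
        assert conc_at_threshold(w) == pytest.approx(1000.0)

    def test_threshold_below_first_sample_errors(self):
        w = WellSeries(
            "w7", "knockdown", "minimal",
            np.arange(3.0), np.array([0.1, 0.2, 0.4]), np.ones(3),
        )
        with pytest.raises(ValueError, match="w7"):
            conc_at_threshold(w)

    def test_never_crossing_errors(self):
        w = WellSeries(
            "w9", "knockdown", "minimal",
            np.arange(3.0), np.array([0.01, 0.02, 0.03]), np.ones(3),
        )
        with pytest.raises(ValueError, match="w9"):
            conc_at_threshold(w)

    def test_simulated_control_invariant_to_threshold(self):
        cfg = BulkSimConfig(
            carrying_capacity=None, od_noise_sd=0.0, fluor_noise_sd=0.0, n_replicates=1
        )
        ctrl = next(
            w for w in simulate_plate_reader(cfg) if w.strain_role == "gfp_control"
        )
        c1 = conc_at_threshold(ctrl, AssayParams(od_threshold_minimal=0.05))
        c2 = conc_at_threshold(ctrl, AssayParams(od_threshold_minimal=0.1))
        assert c1 == pytest.approx(c2, rel=1e-9)
        assert c1 == pytest.approx(
            cfg.synthesis_rate / cfg.growth_rate + cfg.autofluorescence_per_od,
            rel=1e-9,
        )


class TestGfpFraction:
    def test_noiseless_triplicates(self):
        res = gfp_fraction(
            [_well(30.0) for _ in range(3)],
            [_well(100.0, role="gfp_control") for _ in range(3)],
            [_well(10.0, role="nonfluorescent") for _ in range(3)],
        )
        assert res.fraction == pytest.approx((30 - 10) / (100 - 10))
        assert res.ci_low == pytest.approx(res.fraction)
        assert res.ci_high == pytest.approx(res.fraction)

    def test_identity_case(self):
        res = gfp_fraction(
            [_well(c) for c in (95.0, 100.0, 105.0)],
            [_well(c, role="gfp_control") for c in (95.0, 100.0, 105.0)],
            [_well(0.0, role="nonfluorescent") for _ in range(2)],
        )
        assert res.fraction == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_negative_lower_limit_clamped_to_zero(self):
        res = gfp_fraction(
            [_well(c) for c in (10.0, 20.0, 30.0)],  # mean 20 == background
            [_well(100.0, role="gfp_control") for _ in range(3)],
            [_well(20.0, role="nonfluorescent") for _ in range(3)],
        )
        assert res.fraction == pytest.approx(0.0)
        assert res.ci_low == 0.0  # raw percentile is negative; clamped

    def test_scale_invariance(self):
        def build(scale):
            return (
                [_well(scale * c) for c in (25.0, 30.0, 35.0)],
                [_well(scale * c, role="gfp_control") for c in (90.0, 100.0, 110.0)],
                [_well(scale * 10.0, role="nonfluorescent") for _ in range(3)],
            )

        r1 = gfp_fraction(*build(1.0))
        r7 = gfp_fraction(*build(7.0))
        assert r7.fraction == pytest.approx(r1.fraction, rel=1e-12)
        assert r7.ci_low == pytest.approx(r1.ci_low, rel=1e-12)
        assert r7.ci_high == pytest.approx(r1.ci_high, rel=1e-12)

    def test_control_below_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            gfp_fraction(
                [_well(5.0) for _ in range(2)],
                [_well(10.0, role="gfp_control") for _ in range(2)],
                [_well(50.0, role="nonfluorescent") for _ in range(2)],
            )

    def test_requires_replicates(self):
        with pytest.raises(ValueError, match="replicate"):
            gfp_fraction(
                [_well(30.0)],
                [_well(100.0, role="gfp_control")] * 2,
                [_well(0.0, role="nonfluorescent")] * 2,
            )


class TestGrowthRateAt:
    def test_exact_exponential(self):
        t = np.arange(0.0, 5.0, 0.25)
        w = WellSeries("a", "knockdown", "minimal", t, 0.05 * np.exp(0.3 * t), np.ones(t.size))
        assert growth_rate_at(w, 2.0) == pytest.approx(0.3, abs=1e-12)
        assert growth_rate_at(w, "threshold") == pytest.approx(0.3, abs=1e-12)

    def test_plateau_near_zero(self):
        t = np.arange(0.0, 8.1, 0.5)
        od = np.minimum(0.05 * np.exp(0.5 * t), 0.5) + 1e-4 * t  # keep monotone
        w = WellSeries("a", "knockdown", "minimal", t, od, np.ones(t.size))
        assert abs(growth_rate_at(w, 7.5)) < 0.01

    def test_matches_full_window_regression_on_exponential(self):
        t = np.arange(0.0, 4.0, 0.25)
        od = 0.05 * np.exp(0.42 * t)
        w = WellSeries("a", "knockdown", "minimal", t, od, np.ones(t.size))
        full = np.polyfit(t, np.log(od), 1)[0]
        assert growth_rate_at(w, 1.5) == pytest.approx(full, rel=0.02)

    def test_too_few_points_missing(self):
        w = WellSeries("a", "knockdown", "minimal", [0.0, 1.0], [0.05, 0.1], [1.0, 2.0])
        with pytest.warns(UserWarning):
            assert np.isnan(growth_rate_at(w, 0.5))


class TestDetectOnset:
    @pytest.mark.parametrize("tau_q", [0.5, 1.0, 1.75, 3.0])
    def test_recovers_programmed_quiescence_noiseless(self, tau_q):
        cfg = BulkSimConfig(
            quiescent_delay=tau_q,
            od_noise_sd=0.0,
            fluor_noise_sd=0.0,
            n_replicates=2,
        )
        wells = simulate_plate_reader(cfg)
        res = detect_onset(
            [w for w in wells if w.strain_role == "knockdown"],
            [w for w in wells if w.strain_role == "gfp_control"],
            cfg.induction_time,
        )
        assert res is not None
        interval = cfg.sampling_interval / 60.0
        assert abs(res.quiescent_h - tau_q) <= interval

    def test_doublings_identity(self):
        cfg = BulkSimConfig(od_noise_sd=0.0, fluor_noise_sd=0.0, n_replicates=2)
        wells = simulate_plate_reader(cfg)
        res = detect_onset(
            [w for w in wells if w.strain_role == "knockdown"],
            [w for w in wells if w.strain_role == "gfp_control"],
            cfg.induction_time,
        )
        assert res.quiescent_doublings == pytest.approx(
            res.quiescent_h * res.growth_rate / LN2, rel=1e-12
        )

    def test_control_against_control_no_onset(self):
        cfg = BulkSimConfig(od_noise_sd=0.0, fluor_noise_sd=0.0, n_replicates=2)
        ctrl = [
            w for w in simulate_plate_reader(cfg) if w.strain_role == "gfp_control"
        ]
        with pytest.warns(UserWarning, match="no sustained"):
            assert detect_onset(ctrl, ctrl, cfg.induction_time) is None

    def test_induction_outside_series_rejected(self):
        cfg = BulkSimConfig(n_replicates=2)
        wells = simulate_plate_reader(cfg)
        kd = [w for w in wells if w.strain_role == "knockdown"]
        with pytest.raises(ValueError):
            detect_onset(kd, kd, t_ind=99.0)


class TestYieldAndTiter:
    @staticmethod
    def _culture(s, p, t=None):
        n = len(s)
        t = np.arange(n, dtype=float) if t is None else np.asarray(t)
        z = np.zeros(n)
        return CultureSeries(t, np.ones(n), np.asarray(s, float), z, z, np.asarray(p, float))

    def test_printed_yield_arithmetic(self):
        c = self._culture([40.0, 20.0, 0.0], [0.0, 15.0, 30.4])
        titer, y, t_exh = yield_and_titer(c)
        assert y == pytest.approx(30.4 / 40.0)  # 0.76
        assert t_exh == 2.0

    def test_unit_round_trip_to_grams(self):
        c = self._culture([40.0, 0.0], [0.0, 27.42])
        titer, _, _ = yield_and_titer(c)
        assert titer == pytest.approx(27.42 * 160.125 / 1000.0, rel=1e-9)
        assert titer == pytest.approx(4.39, abs=0.01)

    def test_molecular_weights_from_formulas(self):
        assert MW_TABLE["beta_ketoadipate"] == pytest.approx(160.12, abs=0.01)
        assert MW_TABLE["p_coumarate"] == pytest.approx(164.16, abs=0.01)

    def test_theoretical_yield_is_one(self):
        assert theoretical_yield() == 1.0

    def test_unexhausted_series_warns(self):
        c = self._culture([40.0, 30.0, 20.0], [0.0, 5.0, 10.0])
        with pytest.warns(UserWarning, match="never exhausted"):
            _, y, t_exh = yield_and_titer(c)
        assert t_exh == 2.0 and y == pytest.approx(0.25)

    def test_missing_mw_rejected(self):
        c = self._culture([40.0, 0.0], [0.0, 30.0])
        with pytest.raises(ValueError, match="molecular weight"):
            yield_and_titer(c, mw_table={})


class TestKnockdownAssayModel:
    def test_fit_summary_and_results(self):
        cfg = BulkSimConfig(seed=2)
        model = KnockdownAssay(
            simulate_plate_reader(cfg), induction_time=cfg.induction_time
        )
        res = model.fit()
        assert 0.0 <= res.gfp_fraction
        lo, hi = res.conf_int
        assert lo <= hi
        assert res.quiescent_h == pytest.approx(1.75, abs=0.5)
        text = res.summary()
        assert "GFP fraction" in text and "quiescent phase" in text

    def test_fit_reproducible(self):
        cfg = BulkSimConfig(seed=4)
        wells = simulate_plate_reader(cfg)
        r1 = KnockdownAssay(wells, induction_time=4.0).fit()
        r2 = KnockdownAssay(wells, induction_time=4.0).fit()
        assert r1.gfp_fraction == r2.gfp_fraction
        assert r1.conf_int == r2.conf_int
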