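"""Minute-signal derivation: block means, AMP, CPP and reactivity indices."""

import numpy as np
import pytest

import neurocast as nc
from neurocast.derive import compute_amp_frames, moving_correlation_index
from neurocast.simulate import SimulationConfig, SlowWave


class TestBlockMean:
    def test_constant_signal(self):
        vals, valid = nc.block_mean_10s(np.full(3000, 10.0), 100)
        assert np.allclose(vals, [10.0, 10.0, 10.0])
        assert valid.all()

    def test_ramp_frame_means(self):
        """Frame means of an arithmetic ramp follow the closed form."""
        vals, _ = nc.block_mean_10s(np.arange(3000.0), 100)
        assert np.allclose(vals, [499.5, 1499.5, 2499.5])

    def test_trailing_partial_frame_dropped(self):
        vals, _ = nc.block_mean_10s(np.ones(2500), 100)  # 25 s
        assert len(vals) == 2

    def test_empty_input(self):
        vals, valid = nc.block_mean_10s(np.empty(0), 100)
        assert len(vals) == 0 and len(valid) == 0

    def test_majority_validity_rule(self):
        x = np.ones(2000)
        mask = np.zeros(2000, dtype=bool)
        mask[:501] = True  # frame 0: 49.9% unmasked -> invalid
        mask[1000:1500] = True  # frame 1: exactly 50% unmasked -> valid
        vals, valid = nc.block_mean_10s(x, 100, mask)
        assert not valid[0] and np.isnan(vals[0])
        assert valid[1] and vals[1] == 1.0


class TestAmp:
    def test_pure_sine_amplitude(self):
        t = np.arange(1000) / 100.0
        frame = 5.0 * np.sin(2 * np.pi * 1.2 * t)
        assert nc.compute_amp(frame, 100) == pytest.approx(5.0, abs=0.01)

    def test_least_squares_oracle_agreement(self):
        """AMP matches an independent sinusoid least-squares fit at the
        known cardiac frequency for a noisy bin-centered pulse."""
        rng = np.random.default_rng(0)
        t = np.arange(1000) / 100.0
        frame = 70 + 3.5 * np.sin(2 * np.pi * 1.2 * t + 0.7) + rng.normal(0, 0.1, 1000)
        X = np.column_stack(
            [np.ones(1000), np.sin(2 * np.pi * 1.2 * t), np.cos(2 * np.pi * 1.2 * t)]
        )
        beta, *_ = np.linalg.lstsq(X, frame, rcond=None)
        oracle = np.hypot(beta[1], beta[2])
        assert nc.compute_amp(frame, 100) == pytest.approx(oracle, abs=0.05)

    def test_zero_frame(self):
        assert nc.compute_amp(np.zeros(1000), 100) == 0.0

    def test_dc_only_frame(self):
        assert nc.compute_amp(np.full(1000, 7.0), 100) == pytest.approx(0.0, abs=1e-9)

    def test_dc_offset_invariance(self):
        t = np.arange(1000) / 100.0
        frame = 2.0 * np.sin(2 * np.pi * 1.0 * t)
        assert nc.compute_amp(frame + 55.0, 100) == pytest.approx(
            nc.compute_amp(frame, 100), abs=1e-9
        )

    def test_short_frame_rejected(self):
        with pytest.raises(ValueError):
            nc.compute_amp(np.zeros(999), 100)

    def test_masked_frame_invalid(self):
        x = np.ones(2000)
        mask = np.zeros(2000, dtype=bool)
        mask[5] = True
        vals, valid = compute_amp_frames(x, 100, mask)
        assert not valid[0] and np.isnan(vals[0])
        assert valid[1]


class TestCppAndPearson:
    def test_cpp_subtraction(self):
        assert nc.compute_cpp(87.0, 12.0) == 75.0
        assert nc.compute_cpp(0.0, 0.0) == 0.0
        assert nc.compute_cpp(80.0, 90.0) == -10.0  # implausible but allowed

    def test_pearson_exact_cases(self):
        assert nc.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert nc.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert nc.pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pearson_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            xc, yc = x - x.mean(), y - y.mean()
            oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert nc.pearson(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_pearson_zero_variance_is_missing(self):
        assert np.isnan(nc.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pearson_input_validation(self):
        with pytest.raises(ValueError):
            nc.pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            nc.pearson([1, 2], [1, 2])


class TestMovingCorrelation:
    def test_linear_relationship_gives_unity(self):
        x = np.sin(np.arange(60.0))
        out = nc.moving_correlation_index(x, 2 * x + 1)
        assert np.isnan(out[:4]).all()  # fewer than 30 prior frames
        assert np.allclose(out[4:], 1.0)

    def test_anti_linear_gives_minus_one(self):
        x = np.sin(np.arange(60.0))
        out = nc.moving_correlation_index(x, -x)
        assert np.allclose(out[4:], -1.0)

    def test_symmetry_in_arguments(self, rng):
        x, y = rng.normal(size=120), rng.normal(size=120)
        assert np.allclose(
            nc.moving_correlation_index(x, y),
            nc.moving_correlation_index(y, x),
            equal_nan=True,
        )

    def test_null_distribution_spread(self, rng):
        """Independent white noise: index mean ~0 and SD ~1/sqrt(29)."""
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        out = nc.moving_correlation_index(x, y)
        vals = out[np.isfinite(out)]
        assert abs(vals.mean()) < 0.03
        assert 0.8 / np.sqrt(29) < vals.std() < 1.2 / np.sqrt(29)

    def test_invalid_frames_invalidate_windows(self):
        x = np.sin(np.arange(60.0))
        valid = np.ones(60, dtype=bool)
        valid[35] = False
        out = nc.moving_correlation_index(x, 2 * x, valid)
        # windows covering frame 35 are minutes ceil((35+1-30)/6)..floor(35/6)
        assert np.isnan(out[5])  # window frames 6..35 contains frame 35
        assert np.isfinite(out[4])  # window frames 0..29 does not


class TestDeriveMinuteRecord:
    def test_impaired_record_shape_and_prx(self, impaired_minutes):
        assert len(impaired_minutes) == 120
        assert np.isnan(impaired_minutes["PRx"][:4]).all()
        assert np.isfinite(impaired_minutes["PRx"][4:]).all()
        assert np.nanmean(impaired_minutes["PRx"]) > 0.5

    def test_intact_record_prx_negative(self, intact_minutes):
        assert np.nanmean(intact_minutes["PRx"]) < -0.5

    def test_cpp_identity_rowwise(self, impaired_minutes):
        df = impaired_minutes.dropna(subset=["MAP", "ICP", "CPP"])
        assert np.allclose(df["CPP"], df["MAP"] - df["ICP"], atol=1e-9)

    def test_indices_bounded(self, impaired_minutes):
        for col in ("PRx", "PAx", "RAC", "RAP"):
            vals = impaired_minutes[col].dropna()
            assert ((vals >= -1.0) & (vals <= 1.0)).all()

    def test_constant_record_indices_missing(self):
        n = 100 * 60 * 10
        rec = nc.WaveformRecord("flat", 100, np.full(n, 90.0), np.full(n, 12.0))
        table = nc.derive_minute_record(rec)
        assert table["PRx"].isna().all()
        assert np.allclose(table["CPP"], 78.0)

    def test_gap_invalidates_overlapping_windows(self):
        cfg = SimulationConfig(duration_minutes=20.0, seed=2)
        rec = nc.generate_patient_waveforms(cfg)
        # 6 frames = 1 minute of samples masked starting at minute 10
        start = 10 * 60 * 100
        rec = nc.inject_missingness(rec, [(start, 60 * 100)])
        table = nc.derive_minute_record(rec)
        assert np.isnan(table["MAP"][10])
        assert np.isnan(table["PRx"][10:15]).all()  # windows overlap the gap
        assert np.isfinite(table["PRx"][16:]).all()

    def test_short_record_rejected(self):
        n = 100 * 60 * 5  # 5 minutes
        rec = nc.WaveformRecord("short", 100, np.ones(n), np.ones(n))
        with pytest.raises(ValueError, match="6 minutes"):
            nc.derive_minute_record(rec)
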