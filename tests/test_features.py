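"""Feature catalogue: registry, per-minute computation, windowed HRV,
DFA/Poincare/ApEn oracles, baseline normalization."""

import numpy as np
import pandas as pd
import pytest

from bioradar import features, synth, vitals
from bioradar.features import (FEATURE_IDS, FEATURE_REGISTRY, WINDOWED_IDS,
                               FeatureMatrix, Observation, SessionRecord,
                               apen, baseline_normalize, band_power, dfa2,
                               hrv_feature_windows, impute_flagged, poincare,
                               segment_observations, welch_psd)

FS = 100.0


def _sinusoid_vitals(resp_hz=0.25, card_hz=1.0, dur=600.0, seed=0):
    """Hand-built VitalSigns: sinusoidal RS, pulse-train CS, exact peaks."""
    t = np.arange(int(dur * FS)) / FS
    rs = np.sin(2 * np.pi * resp_hz * t)
    cs = np.sin(2 * np.pi * card_hz * t)
    card_peaks = np.arange(0.25, dur, 1.0 / card_hz)
    resp_peaks = np.arange(1.0, dur, 1.0 / resp_hz)
    resp_valleys = np.arange(3.0, dur, 1.0 / resp_hz)
    return vitals.VitalSigns(rs=rs, cs=cs, fs=FS,
                             cardiac_peak_times=card_peaks,
                             breath_peaks=resp_peaks,
                             breath_valleys=resp_valleys,
                             source="bR", pre_bpf=cs.copy())


class TestRegistry:
    def test_sixty_features_each_present_once(self):
        assert FEATURE_IDS == [f"F{i}" for i in range(1, 61)]
        assert set(FEATURE_REGISTRY) == set(FEATURE_IDS)

    def test_categories_cover_catalogue(self):
        cats = {s.category for s in FEATURE_REGISTRY.values()}
        assert cats == {"waveform", "statistical", "spectral", "HRV"}
        # spot checks against the catalogue layout
        assert FEATURE_REGISTRY["F2"].description.startswith("Signal rate")
        assert FEATURE_REGISTRY["F45"].category == "spectral"
        assert FEATURE_REGISTRY["F55"].description == "Poincare SD12, m=1"
        assert FEATURE_REGISTRY["F58"].description == "Poincare SD2, m=10"

    def test_windowed_set_is_cardiac_hrv(self):
        expected = {"F15", "F16", "F17", "F18", "F46", "F48"} | \
            {f"F{i}" for i in range(50, 61)}
        assert set(WINDOWED_IDS) == expected


class TestSegmentation:
    def test_baseline_and_condition_counts(self):
        obs = segment_observations(900.0, 300.0)
        assert len(obs) == 15
        assert sum(o.is_baseline for o in obs) == 5
        assert sum(not o.is_baseline for o in obs) == 10

    def test_partial_trailing_minute_dropped(self):
        assert len(segment_observations(359.0, 60.0)) == 5

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            segment_observations(59.0, 30.0)

    def test_labels_propagate_to_observations(self):
        vit = _sinusoid_vitals(dur=180.0)
        rec = SessionRecord(vit, "S07", 2, "fear", baseline_duration=60.0)
        _, _, meta = features.session_feature_table(rec)
        assert (meta["label"] == "fear").all()
        assert meta["is_baseline"].tolist() == [True, False, False]


class TestMinuteFeatures:
    def test_respiratory_rate_feature(self):
        vit = _sinusoid_vitals(resp_hz=0.25, dur=300.0)
        rec = SessionRecord(vit, "S01", 1, "neutral", 60.0)
        row = features.compute_minute_features(rec, 60.0, 120.0)
        assert row["F2"] == 15.0  # 0.25 Hz = 15 breaths/min
        assert row["F1"] == 60.0  # 1 Hz cardiac train

    def test_psd_band_of_pure_tone_dominates(self):
        vit = _sinusoid_vitals(resp_hz=0.2, dur=300.0)
        rec = SessionRecord(vit, "S01", 1, "neutral", 60.0)
        row = features.compute_minute_features(rec, 60.0, 120.0)
        bands = [row[f"F{i}"] for i in range(39, 45)]
        assert np.argmax(bands) == 2  # 0.2-0.3 Hz band is F41
        assert row["F45"] > 10.0      # low/high PSD ratio >> 1

    def test_variance_and_kurtosis_of_rs(self):
        vit = _sinusoid_vitals(dur=300.0)
        rec = SessionRecord(vit, "S01", 1, "neutral", 60.0)
        row = features.compute_minute_features(rec, 60.0, 120.0)
        assert abs(row["F14"] - 0.5) < 1e-3          # var of unit sinusoid
        assert abs(row["F12"] - 1.5) < 0.01          # kurtosis of sinusoid

    def test_feature_computation_deterministic(self):
        vit = _sinusoid_vitals(dur=300.0)
        rec = SessionRecord(vit, "S01", 1, "neutral", 60.0)
        r1 = features.compute_minute_features(rec, 0.0, 60.0)
        r2 = features.compute_minute_features(rec, 0.0, 60.0)
        assert r1 == r2


class TestWindowedHrvFeatures:
    def _records(self, dur, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        peaks = synth.cardiac_beat_times(dur, 70.0, jitter, rng)
        t = np.arange(int(dur * FS)) / FS
        vit = vitals.VitalSigns(
            rs=np.sin(2 * np.pi * 0.25 * t), cs=np.zeros(t.size), fs=FS,
            cardiac_peak_times=peaks,
            breath_peaks=np.arange(1.0, dur, 4.0),
            breath_valleys=np.arange(3.0, dur, 4.0),
            source="bP")
        return SessionRecord(vit, "S01", 1, "happy", 0.0)

    def test_central_minute_window_assignment(self):
        rec = self._records(600.0, jitter=30.0)
        obs = segment_observations(600.0, 0.0)
        vals, edge = hrv_feature_windows(rec, obs)
        # observation index 2 is the centre of minutes 0-4: not edge-flagged
        assert edge == [True, True] + [False] * 6 + [True, True]
        # edge observations inherit the nearest valid window's values
        assert vals[0] == vals[1] == vals[2]
        assert vals[-1] == vals[-2] == vals[-3]
        assert vals[3] != vals[2]

    def test_constant_ibis_give_equal_windows_and_zero_pnn50(self):
        rec = self._records(600.0, jitter=0.0)
        obs = segment_observations(600.0, 0.0)
        vals, _ = hrv_feature_windows(rec, obs)
        sdnn = [v["F46"] for v in vals]
        assert max(sdnn) - min(sdnn) < 1e-4
        assert all(v["F50"] == 0.0 for v in vals)
        # log transform floors at log(eps) for (numerically) zero SDNN
        assert abs(vals[0]["F46"] - np.log(features.LOG_EPS)) < 1e-4

    def test_short_session_flags_all_hrv_features(self):
        rec = self._records(240.0, jitter=30.0)
        obs = segment_observations(240.0, 0.0)
        vals, edge = hrv_feature_windows(rec, obs)
        assert all(e for e in edge)
        assert all(np.isnan(v[f]) for v in vals for f in WINDOWED_IDS)


class TestDfa:
    def test_white_noise_alpha_half(self):
        alphas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a1, _ = dfa2(1000 + 50 * rng.standard_normal(2000))
            alphas.append(a1)
        assert abs(np.mean(alphas) - 0.5) < 0.1

    def test_integrated_noise_alpha_three_halves(self):
        alphas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            _, a2 = dfa2(np.cumsum(rng.standard_normal(2000)))
            alphas.append(a2)
        assert abs(np.mean(alphas) - 1.5) < 0.1

    def test_box_sizes_restricted_to_stated_ranges(self):
        # alpha1 uses 20-60 beats, alpha2 10-100: a series long enough only
        # for the short range yields NaN alpha2
        rng = np.random.default_rng(1)
        a1, a2 = dfa2(rng.standard_normal(99))
        assert np.isnan(a2)

    def test_too_few_beats_flagged(self):
        assert all(np.isnan(a) for a in dfa2(np.ones(10)))


class TestPoincare:
    def test_constant_series_degenerate(self):
        sd1, sd2, sd12, sdrr = poincare(np.full(50, 1000.0), 1)
        assert sd1 < 1e-9 and sd2 < 1e-9 and sdrr < 1e-9

    def test_sd1_identity_with_successive_differences(self):
        # SD1^2 = Var(diff)/2 = mean(diff^2)/2 - mean(diff)^2/2
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = 1000 + 40 * rng.standard_normal(100)
            sd1, _, _, _ = poincare(v, 1)
            d = np.diff(v)
            oracle = np.sqrt(0.5 * np.mean(d**2) - 0.5 * np.mean(d) ** 2)
            assert abs(sd1 - oracle) < 1e-9

    def test_alternating_two_cycle_brute_force(self):
        v = np.array([900.0, 1100.0] * 10)
        sd1, sd2, sd12, sdrr = poincare(v, 1)
        x, y = v[:-1], v[1:]
        assert abs(sd1 - np.std((x - y) / np.sqrt(2))) < 1e-12
        assert abs(sd2 - np.std((x + y) / np.sqrt(2))) < 1e-12
        assert abs(sdrr - 100.0) < 1e-9

    def test_lagged_variant_differs(self):
        rng = np.random.default_rng(2)
        v = 1000 + np.cumsum(rng.standard_normal(200))
        assert poincare(v, 1)[0] != poincare(v, 10)[0]

    def test_too_few_for_lag_flagged(self):
        assert all(np.isnan(x) for x in poincare(np.ones(5), 10))


class TestApEn:
    def test_constant_series_zero(self):
        assert abs(apen(np.full(300, 2.0))) < 1e-9

    def test_noise_more_irregular_than_sinusoid(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 60, 600)
        sine = np.sin(2 * np.pi * 0.25 * t)
        noise = rng.standard_normal(600) * np.std(sine)
        assert apen(noise) > apen(sine)


def test_psd_bands_capture_in_band_variance():
    """Band powers over 0-1.5 Hz sum to the in-band variance share."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(600 * int(FS))
    f, p = welch_psd(x, FS)
    band_sum = sum(band_power(f, p, lo, hi)
                   for lo, hi in features.PSD_BANDS)
    # independent estimate: periodogram share below 1.5 Hz times variance
    ff = np.fft.rfftfreq(x.size, 1 / FS)
    pp = np.abs(np.fft.rfft(x)) ** 2
    share = pp[(ff >= 0) & (ff < 1.5)].sum() / pp.sum()
    expected = share * np.var(x)
    assert abs(band_sum - expected) / expected < 0.10


class TestBaselineNormalize:
    def _matrix(self):
        values = np.array([
            [1.0, 10.0], [1.0, 10.0],       # S01 baseline
            [3.0, 12.0], [5.0, 14.0],       # S01 condition
            [100.0, -5.0], [100.0, -5.0],   # S02 baseline
            [102.0, -3.0], [104.0, -1.0],   # S02 condition
        ])
        fm = FeatureMatrix.from_arrays(
            values, ["F1", "F2"],
            ["neutral"] * 2 + ["fear"] * 2 + ["neutral"] * 2 + ["fear"] * 2,
            subject_id=["S01"] * 4 + ["S02"] * 4,
            day_index=[1] * 8,
            is_baseline=[True, True, False, False, True, True, False, False])
        return fm

    def test_condition_minus_baseline_mean(self):
        out = baseline_normalize(self._matrix())
        cond = out.condition_rows()
        # identical offsets for both subjects despite different baselines
        np.testing.assert_allclose(cond.values,
                                   [[2.0, 2.0], [4.0, 4.0]] * 2)

    def test_condition_equal_to_baseline_normalizes_to_zero(self):
        fm = FeatureMatrix.from_arrays(
            np.array([[5.0], [5.0], [5.0]]), ["F1"],
            ["neutral", "fear", "fear"],
            subject_id=["S01"] * 3, day_index=[1] * 3,
            is_baseline=[True, False, False])
        out = baseline_normalize(fm)
        np.testing.assert_allclose(out.condition_rows().values, 0.0)

    def test_missing_baseline_names_subject_and_day(self):
        fm = FeatureMatrix.from_arrays(
            np.ones((2, 1)), ["F1"], ["fear", "fear"],
            subject_id=["S03"] * 2, day_index=[2] * 2,
            is_baseline=[False, False])
        with pytest.raises(ValueError, match="S03.*2"):
            baseline_normalize(fm)


def test_impute_uses_subject_median_and_flags():
    values = np.array([[1.0], [3.0], [np.nan], [10.0], [np.nan]])
    fm = FeatureMatrix.from_arrays(
        values, ["F1"], ["fear"] * 5,
        subject_id=["S01", "S01", "S01", "S02", "S02"])
    out = impute_flagged(fm)
    assert out.df.loc[2, "F1"] == 2.0    # S01 median
    assert out.df.loc[4, "F1"] == 10.0   # S02 median
    assert out.flags.loc[2, "F1"] and out.flags.loc[4, "F1"]
    assert not out.flags.loc[0, "F1"]


def test_feature_matrix_csv_roundtrip(tmp_path):
    fm = synth.planted_feature_matrix(n_obs=30, seed=2)
    path = tmp_path / "features.csv"
    fm.to_csv(path)
    back = FeatureMatrix.read_csv(path)
    np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
    assert list(back.labels) == list(fm.labels)


def test_full_session_matrix_complete(noisy_vitals):
    """End-to-end extraction yields 60 complete features per minute."""
    vit, _ = noisy_vitals
    rec = SessionRecord(vit, "S01", 1, "happy", baseline_duration=120.0)
    fm = features.build_feature_matrix([rec])
    assert fm.df.shape == (8, 60)
    assert not fm.df.isna().any().any()
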