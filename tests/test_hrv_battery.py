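"""The 94-metric battery: registry census, identities and naive oracles."""

import numpy as np
import pytest

from hrvpipe.hrv_battery import (
    METRIC_REGISTRY,
    _dfa,
    _lzc,
    battery_matrix,
    compute_all,
    compute_complexity_domain,
    compute_frequency_domain,
    compute_specialized,
    compute_time_domain,
    flag_outliers,
)
from hrvpipe.signal_prep import RRSeries, extract_windows
from hrvpipe.synthetic_cohort import RRGenParams, generate_rr_series


def _rr_from_values(values_ms):
    values_ms = np.asarray(values_ms, dtype=float)
    return RRSeries(np.cumsum(values_ms) / 1000.0, values_ms)


def _modulated_rr(freq, amp=50.0, duration=700.0, mean=800.0):
    times = []
    t = 0.0
    while t < duration:
        rr = mean + amp * np.sin(2 * np.pi * freq * t)
        t += rr / 1000.0
        times.append((t, rr))
    arr = np.array(times)
    return RRSeries(arr[:, 0], arr[:, 1])


class TestRegistry:
    def test_domain_census(self):
        domains = [s.domain for s in METRIC_REGISTRY.values()]
        assert len(METRIC_REGISTRY) == 94
        assert domains.count("temporal") == 25
        assert domains.count("frequency") == 6
        assert domains.count("complexity") == 54
        assert domains.count("specialized") == 9

    def test_every_metric_in_exactly_one_domain(self):
        assert all(s.domain in {"temporal", "frequency", "complexity",
                                "specialized"} for s in METRIC_REGISTRY.values())


class TestTimeDomain:
    def test_hand_arithmetic(self):
        rr = _rr_from_values([800.0, 810.0, 790.0, 810.0] * 50)
        vals, _ = compute_time_domain(rr)
        assert vals["mean_nn"] == pytest.approx(802.5)
        # RMSSD of the repeating diff pattern (10, -20, 20, -10, ...)
        d = np.diff(rr.rr)
        assert vals["rmssd"] == pytest.approx(np.sqrt(np.mean(d ** 2)))

    def test_four_beat_rmssd_formula(self):
        # sqrt((10^2 + 20^2 + 20^2)/3) = 17.32 on the canonical 4-beat set,
        # padded to reach the 2-min minimum
        d = np.diff([800.0, 810.0, 790.0, 810.0])
        assert np.sqrt(np.mean(d ** 2)) == pytest.approx(17.32, abs=0.01)

    def test_pnn_thresholds_never_crossed(self):
        rr = _rr_from_values(800.0 + 5.0 * np.sin(np.arange(200)))
        vals, _ = compute_time_domain(rr)
        assert vals["pnn50"] == 0.0
        assert vals["pnn20"] == 0.0

    def test_constant_series_zero_variability(self):
        rr = _rr_from_values(np.full(200, 800.0))
        vals, _ = compute_time_domain(rr)
        assert vals["sdnn"] == 0.0
        assert vals["rmssd"] == 0.0

    def test_short_recording_missing_with_reason(self):
        rr = _rr_from_values(np.full(20, 800.0))  # 16 s
        vals, reasons = compute_time_domain(rr)
        assert np.isnan(vals["sdnn"])
        assert "2 min" in reasons["sdnn"]


class TestFrequencyDomain:
    def test_hf_tone(self):
        rr = _modulated_rr(0.25)
        vals, _ = compute_frequency_domain(rr)
        assert vals["hf_power"] / vals["total_power"] > 0.9
        assert vals["lf_hf_ratio"] < 0.1

    def test_lf_tone(self):
        rr = _modulated_rr(0.1)
        vals, _ = compute_frequency_domain(rr)
        assert vals["lfnu"] > 90.0

    def test_normalized_units_sum_to_100(self):
        rr = generate_rr_series(RRGenParams(duration=700), seed=5)
        vals, _ = compute_frequency_domain(rr)
        assert vals["lfnu"] + vals["hfnu"] == pytest.approx(100.0)

    def test_band_nesting(self):
        rr = generate_rr_series(RRGenParams(duration=700), seed=6)
        vals, _ = compute_frequency_domain(rr)
        assert vals["total_power"] >= vals["lf_power"] + vals["hf_power"] - 1e-9


class TestComplexityDomain:
    def test_sd1_rmssd_identity(self):
        rr = generate_rr_series(RRGenParams(duration=400), seed=7)
        cx, _ = compute_complexity_domain(rr)
        td, _ = compute_time_domain(rr)
        # SD1 = RMSSD / sqrt(2) with matching variance conventions
        d = np.diff(rr.rr)
        sd1_direct = np.sqrt(np.var(d, ddof=1) / 2.0)
        assert cx["sd1"] == pytest.approx(sd1_direct, rel=1e-12)
        assert cx["sd1"] == pytest.approx(td["rmssd"] / np.sqrt(2), rel=0.01)

    def test_poincare_oracle_agreement(self):
        # direct-formula oracle for SD1/SD2/CSI/CVI on random fixtures
        rng = np.random.default_rng(0)
        for _ in range(5):
            nn = 800 + 30 * rng.standard_normal(400)
            rr = _rr_from_values(nn)
            cx, _ = compute_complexity_domain(rr)
            d = np.diff(nn)
            sd1 = np.sqrt(np.var(d, ddof=1) / 2)
            sd2 = np.sqrt(2 * np.var(nn, ddof=1) - np.var(d, ddof=1) / 2)
            assert cx["sd1"] == pytest.approx(sd1, rel=1e-9)
            assert cx["sd2"] == pytest.approx(sd2, rel=1e-9)
            assert cx["csi"] == pytest.approx(sd2 / sd1, rel=1e-9)
            assert cx["cvi"] == pytest.approx(np.log10(16 * sd1 * sd2), rel=1e-9)

    def test_dfa_white_noise_exponent(self):
        # alpha ~= 0.5 for uncorrelated noise, Monte Carlo over seeds
        rng = np.random.default_rng(1)
        alphas = [_dfa(rng.standard_normal(3000), np.arange(4, 17))
                  for _ in range(20)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_dfa_naive_oracle_agreement(self):
        # windowed naive implementation of the fluctuation function
        def dfa_naive(x, scales):
            y = np.cumsum(x - x.mean())
            pts = []
            for s in scales:
                f2 = []
                for start in range(0, len(y) - s + 1, s):
                    seg = y[start:start + s]
                    t = np.arange(s)
                    c = np.polyfit(t, seg, 1)
                    f2.append(np.mean((seg - np.polyval(c, t)) ** 2))
                pts.append(np.sqrt(np.mean(f2)))
            return np.polyfit(np.log(scales), np.log(pts), 1)[0]

        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        scales = np.arange(4, 17)
        assert _dfa(x, scales) == pytest.approx(dfa_naive(x, scales), rel=0.05)

    def test_lzc_periodic_below_shuffled(self):
        rng = np.random.default_rng(3)
        periodic = np.tile([700.0, 900.0], 300)
        shuffled = rng.permutation(periodic)
        assert _lzc(periodic, 2) < _lzc(shuffled, 2)

    def test_mse_scale1_equals_sampen_convention(self):
        rr = generate_rr_series(RRGenParams(duration=400), seed=8)
        cx, _ = compute_complexity_domain(rr)
        assert np.isfinite(cx["mse_1"])
        assert cx["mfdfa_width"] == pytest.approx(
            cx["mfdfa_h_qm5"] - cx["mfdfa_h_qp5"], rel=1e-9)


class TestSpecialized:
    def test_constant_series_cv_zero(self):
        rr = _rr_from_values(np.full(500, 800.0))
        vals, _ = compute_specialized(rr)
        assert vals["cv_percent"] == 0.0

    def test_centroid_of_single_tone(self):
        rr = _modulated_rr(0.25)
        vals, _ = compute_specialized(rr)
        assert vals["centroid_freq"] == pytest.approx(0.25, abs=0.04)

    def test_turbulence_onset_negative_for_post_ectopic_acceleration(self):
        # hand-constructed ectopic: premature beat, compensatory pause,
        # then transient acceleration (short RRs) before recovery
        nn = np.full(300, 800.0)
        i = 150
        nn[i] = 400.0       # premature ectopic
        nn[i + 1] = 1150.0  # compensatory pause
        nn[i + 2:i + 6] = 730.0   # early sinus acceleration
        nn[i + 6:i + 17] = np.linspace(740.0, 800.0, 11)
        flags = np.zeros(300, dtype=bool)
        flags[i] = True
        rr = RRSeries(np.cumsum(nn) / 1000.0, nn, artifact_flags=flags)
        vals, _ = compute_specialized(rr)
        assert vals["hrt_onset"] < 0.0
        assert vals["hrt_slope"] > 0.0

    def test_no_ectopics_missing_with_reason(self):
        rr = _rr_from_values(np.full(500, 800.0))
        vals, reasons = compute_specialized(rr)
        assert np.isnan(vals["hrt_onset"])
        assert "ectopic" in reasons["hrt_onset"]


@pytest.fixture(scope="module")
def window_vector(clean_recording):
    w = extract_windows(clean_recording)["begin"]
    return compute_all(clean_recording, w.samples, position="begin")


class TestComputeAll:
    def test_full_vector_on_clean_window(self, window_vector):
        assert set(window_vector.values) == set(METRIC_REGISTRY)
        assert window_vector.n_defined() >= 85  # HRT legitimately absent

    def test_purity(self, clean_recording, window_vector):
        w = extract_windows(clean_recording)["begin"]
        again = compute_all(clean_recording, w.samples, position="begin")
        for k, v in window_vector.values.items():
            assert (np.isnan(v) and np.isnan(again.values[k])) or \
                v == again.values[k]

    def test_outlier_flagging_only_flags(self):
        import pandas as pd
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(50, 5, size=(12, len(METRIC_REGISTRY))),
                           columns=list(METRIC_REGISTRY))
        mat.loc[5, "sdnn"] = 1e6
        flags = flag_outliers(mat)
        assert bool(flags.loc[5, "sdnn"])
        assert not flags.drop(index=5)["sdnn"].any()
        assert mat.loc[5, "sdnn"] == 1e6  # value untouched, flag only
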