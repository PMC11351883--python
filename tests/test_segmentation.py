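"""QRS detection, R-to-R segmentation, quality screening and windowing."""

import warnings

import numpy as np
import pytest

from hemobeat.segmentation import (
    CardiacCycle,
    QualityScreener,
    RPeakList,
    detect_r_peaks,
    pad_to_window,
    split_cycles,
)
from hemobeat.signal_io import MultichannelRecord, preprocess_record
from hemobeat.synthetic import SyntheticConfig, ecg_beat, simulate_record

FS = 1000.0


def _regular_ecg(n_beats, rr, lead_in=500, seed=0, snr_db=None):
    """ECG of identical beats at fixed R-R, R apexes at known samples."""
    sig = np.zeros(lead_in + n_beats * rr + 500)
    r_times = []
    for k in range(n_beats):
        s = lead_in + k * rr
        sig[s : s + rr] += ecg_beat(rr, FS)
        r_times.append(s)
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        rms = np.sqrt(np.mean(sig**2))
        sig = sig + rms / 10 ** (snr_db / 20.0) * rng.standard_normal(sig.size)
    return sig, np.array(r_times)


class TestDetectRPeaks:
    def test_clean_regular_rhythm(self):
        # 60 beats at 120 bpm: every R found within 10 ms
        ecg, truth = _regular_ecg(60, rr=500)
        peaks = detect_r_peaks(ecg, FS)
        assert len(peaks) == 60
        offsets = np.abs(peaks.indices[:, None] - truth[None, :]).min(axis=1)
        assert offsets.max() <= 10

    def test_flat_signal_empty_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            peaks = detect_r_peaks(np.zeros(10000), FS)
        assert len(peaks) == 0

    def test_noisy_sensitivity(self):
        # 20 dB SNR, 100 beats: sensitivity and PPV both high
        ecg, truth = _regular_ecg(100, rr=450, snr_db=20.0, seed=1)
        peaks = detect_r_peaks(ecg, FS)
        d = np.abs(peaks.indices[:, None] - truth[None, :])
        tp = (d.min(axis=0) <= 50).sum()
        assert tp / len(truth) >= 0.99
        assert (d.min(axis=1) <= 50).sum() / len(peaks) >= 0.99

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            detect_r_peaks(np.random.default_rng(0).standard_normal(500), FS)

    def test_indices_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            RPeakList(np.array([10, 10, 20]), FS)


def _record_from_channels(n, ecg=None, pcg=None, ppg=None, lvbp=None):
    z = np.zeros(n)
    return MultichannelRecord(
        "r0", "s0", FS,
        ecg=z if ecg is None else ecg,
        pcg=z.copy() if pcg is None else pcg,
        ppg=z.copy() if ppg is None else ppg,
        lvbp=lvbp,
    )


class TestSplitCycles:
    def test_two_cycles_from_three_peaks(self):
        rec = _record_from_channels(1200, lvbp=np.linspace(0, 1, 1200))
        peaks = RPeakList(np.array([0, 500, 1000]), FS)
        cycles = split_cycles(rec, peaks)
        assert [c.length for c in cycles] == [500, 500]
        assert cycles[0].bp_seg is not None
        assert cycles[1].start == 500

    def test_length_conservation(self):
        rng = np.random.default_rng(4)
        idx = np.sort(rng.choice(np.arange(100, 60000, 7), size=61, replace=False))
        rec = _record_from_channels(61000)
        cycles = split_cycles(rec, RPeakList(idx, FS))
        assert len(cycles) == 60
        assert sum(c.length for c in cycles) == idx[-1] - idx[0]

    def test_fewer_than_two_peaks(self):
        rec = _record_from_channels(5000)
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert split_cycles(rec, RPeakList(np.array([100]), FS)) == []

    def test_no_bp_when_lvbp_absent(self):
        rec = _record_from_channels(1200)
        cycles = split_cycles(rec, RPeakList(np.array([0, 600]), FS))
        assert cycles[0].bp_seg is None

    def test_bp_segment_one_systolic_peak(self):
        # every segmented pressure beat contains exactly one systolic maximum
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, truth = simulate_record(
                SyntheticConfig(duration_s=30.0, seed=5, corruption_fraction=0.0)
            )
            pre = preprocess_record(rec)
            peaks = detect_r_peaks(pre.ecg, pre.fs)
            cycles = split_cycles(pre, peaks)
        assert len(cycles) >= 40
        from scipy.signal import find_peaks

        for c in cycles:
            prominent, _ = find_peaks(c.bp_seg, prominence=0.3 * np.ptp(c.bp_seg))
            assert len(prominent) <= 1  # plateau peak may sit at the edge


def _cycle(pcg, ppg, **kw):
    return CardiacCycle(
        subject_id="s", record_id="r", cycle_index=0, start=0,
        length=len(pcg), fs=FS, pcg_seg=pcg, ppg_seg=ppg, **kw,
    )


class TestQualityScreening:
    def _clean_beat(self, seed=0, n=500):
        t = np.arange(n) / FS
        pcg = np.exp(-0.5 * ((t - 0.05) / 0.012) ** 2) * np.sin(2 * np.pi * 50 * t)
        ppg = 0.5 * (1 - np.cos(2 * np.pi * np.clip((t - 0.15) / 0.2, 0, 1)))
        rng = np.random.default_rng(seed)
        return pcg + 0.01 * rng.standard_normal(n), ppg + 0.01 * rng.standard_normal(n)

    def test_self_similarity_scores_high(self):
        screener = QualityScreener()
        pcg, ppg = self._clean_beat()
        score0, ok0 = screener.assess_quality(_cycle(pcg, ppg))
        assert ok0 and score0 == 1.0  # seeds the template
        score1, ok1 = screener.assess_quality(_cycle(pcg.copy(), ppg.copy()))
        assert ok1 and score1 > 0.99

    def test_flat_ppg_rejected(self):
        screener = QualityScreener()
        pcg, _ = self._clean_beat()
        score, ok = screener.assess_quality(_cycle(pcg, np.zeros_like(pcg)))
        assert not ok and score == 0.0

    def test_rr_gate(self):
        screener = QualityScreener()
        pcg, ppg = self._clean_beat(n=200)  # 200 ms beat: below gate
        _, ok = screener.assess_quality(_cycle(pcg, ppg))
        assert not ok

    def test_corrupted_beats_rejected_clean_kept(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, truth = simulate_record(
                SyntheticConfig(duration_s=40.0, seed=7, corruption_fraction=0.05)
            )
            pre = preprocess_record(rec)
            peaks = detect_r_peaks(pre.ecg, pre.fs)
            cycles = split_cycles(pre, peaks)
        screener = QualityScreener(threshold=0.8)
        screener.screen(cycles)
        corrupt_starts = truth.loc[truth.corrupted, "r_sample"].to_numpy()
        flags = np.array(
            [np.any(np.abs(corrupt_starts - c.start) < 20) for c in cycles]
        )
        passes = np.array([c.quality_pass for c in cycles])
        assert flags.sum() >= 2
        assert (~passes[flags]).mean() >= 0.9  # corrupted rejected
        assert (~passes[~flags]).mean() <= 0.05  # clean retained


class TestPadToWindow:
    def _cycle_of(self, n):
        return _cycle(np.linspace(1, 2, n), np.linspace(3, 4, n))

    def test_padding_tail_is_zero(self):
        win = pad_to_window(self._cycle_of(600))
        assert win.shape == (1000, 2)
        assert np.all(win[600:] == 0.0)
        assert np.all(win[:600, 0] == np.linspace(1, 2, 600))

    def test_exact_length_unchanged(self):
        win = pad_to_window(self._cycle_of(1000))
        np.testing.assert_array_equal(win[:, 1], np.linspace(3, 4, 1000))

    def test_long_cycle_excluded_or_truncated(self):
        cyc = self._cycle_of(1200)
        with pytest.warns(UserWarning, match="excluded"):
            assert pad_to_window(cyc) is None
        win = pad_to_window(cyc, long_cycle_policy="truncate")
        assert win.shape == (1000, 2)
        with pytest.raises(ValueError):
            pad_to_window(cyc, long_cycle_policy="bogus")
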