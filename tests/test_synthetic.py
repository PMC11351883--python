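"""Generator behaviour: trajectories, waveform kernels, pipeline closure."""

import warnings

import numpy as np
import pytest
from scipy.signal import hilbert

from hemobeat.labels import HemodynamicLabel, extract_labels
from hemobeat.synthetic import (
    PROFILE_B,
    TOTAL_RANGES,
    SubjectProfile,
    SyntheticConfig,
    bolus_trajectory,
    lv_pressure_beat,
    pcg_beat,
    ppg_beat,
    sample_feasible_labels,
    simulate_record,
    simulate_subject,
)

FS = 1000.0


class TestBolusTrajectory:
    def test_dose_monotonicity(self):
        peaks = {}
        for dose in (0.5, 2.0):
            cfg = SyntheticConfig(dose=dose, seed=42)
            traj = bolus_trajectory(cfg, np.random.default_rng(1))
            peaks[dose] = traj["sbp"].max()
        assert peaks[2.0] > peaks[0.5]

    def test_pre_injection_plateau(self):
        cfg = SyntheticConfig(dose=2.0, seed=3)
        traj = bolus_trajectory(cfg, np.random.default_rng(3))
        prof = cfg.profile
        pre = traj[traj["t"] < cfg.injection_time_s]
        assert len(pre) >= 10
        # before the bolus each parameter stays within 1% of its excursion
        for name, base, delta in [
            ("sbp", prof.sbp0, prof.sbp_delta),
            ("dbp", prof.dbp0, prof.dbp_delta),
            ("mrr", prof.mrr0, prof.mrr_delta),
            ("mrd", prof.mrd0, prof.mrd_delta),
        ]:
            assert np.max(np.abs(pre[name] - base)) <= 0.01 * abs(delta) * 3

    def test_parameters_stay_in_total_ranges(self):
        # Monte-Carlo across seeds and doses
        for seed in range(100):
            cfg = SyntheticConfig(dose=[0.5, 1.0, 2.0][seed % 3], seed=seed, duration_s=30.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = bolus_trajectory(cfg, np.random.default_rng(seed))
            for name, (lo, hi) in TOTAL_RANGES.items():
                assert traj[name].min() >= lo - 1e-9
                assert traj[name].max() <= hi + 1e-9

    def test_invalid_dose(self):
        with pytest.raises(ValueError, match="dose"):
            bolus_trajectory(SyntheticConfig(dose=3.0), np.random.default_rng(0))

    def test_short_record_warns(self):
        with pytest.warns(UserWarning, match="return to baseline"):
            bolus_trajectory(SyntheticConfig(duration_s=15.0), np.random.default_rng(0))


class TestLVPressureBeat:
    def test_generator_extractor_closure(self):
        lab = HemodynamicLabel(180.0, -5.0, 5000.0, -3500.0)
        beat = lv_pressure_beat(lab, rr=500, fs=FS)
        got = extract_labels(beat, FS)
        assert got.sbp == pytest.approx(180.0, abs=1.0)
        assert got.dbp == pytest.approx(-5.0, abs=1.0)
        assert got.mrr == pytest.approx(5000.0, rel=0.02)
        assert got.mrd == pytest.approx(-3500.0, rel=0.02)

    def test_zero_mrr_infeasible(self):
        with pytest.raises(ValueError, match="MRR"):
            lv_pressure_beat(HemodynamicLabel(150.0, 0.0, 0.0, -2000.0), rr=500)

    def test_slow_rise_does_not_fit(self):
        # large pulse pressure with tiny MRR cannot fit in one beat
        with pytest.raises(ValueError, match="fit"):
            lv_pressure_beat(HemodynamicLabel(250.0, -40.0, 300.0, -3000.0), rr=400)

    def test_instantaneous_rise_rejected(self):
        # tiny pulse pressure with huge MRR: sub-15 ms upstroke is unphysical
        with pytest.raises(ValueError, match="too fast"):
            lv_pressure_beat(HemodynamicLabel(90.0, 20.0, 9000.0, -3000.0), rr=500)

    def test_doubling_mrr_doubles_peak_derivative(self):
        lab1 = HemodynamicLabel(180.0, -5.0, 2500.0, -3000.0)
        lab2 = HemodynamicLabel(180.0, -5.0, 5000.0, -3000.0)
        d = []
        for lab in (lab1, lab2):
            beat = lv_pressure_beat(lab, rr=600, fs=FS)
            d.append(np.max(np.gradient(beat) * FS))
        assert d[1] / d[0] == pytest.approx(2.0, rel=0.05)


class TestAcousticAndOpticalKernels:
    def test_s1_amplitude_linear_in_mrr(self):
        prof = SubjectProfile()
        lab1 = HemodynamicLabel(180.0, -5.0, 2000.0, -3000.0)
        lab2 = HemodynamicLabel(180.0, -5.0, 4000.0, -3000.0)
        envs = []
        for lab in (lab1, lab2):
            seg = pcg_beat(lab, rr=600, fs=FS, profile=prof)
            env = np.abs(hilbert(seg))
            envs.append(env[:200].max())  # S1 region
        expect = (prof.s1_gain * 4000 + prof.s1_offset) / (prof.s1_gain * 2000 + prof.s1_offset)
        assert envs[1] / envs[0] == pytest.approx(expect, rel=0.05)

    def test_zero_coupling_degenerate(self):
        # S1 lives in the first ~120 ms here; S2 arrives later
        prof = SubjectProfile(s1_gain=0.0)
        lab1 = HemodynamicLabel(180.0, -5.0, 2000.0, -3000.0)
        lab2 = HemodynamicLabel(180.0, -5.0, 6000.0, -3000.0)
        a = np.abs(hilbert(pcg_beat(lab1, 600, FS, prof)))[:120].max()
        b = np.abs(hilbert(pcg_beat(lab2, 600, FS, prof)))[:120].max()
        assert b == pytest.approx(a, rel=0.02)

    def test_ppg_delay_decreases_with_sbp(self):
        prof = SubjectProfile()
        lo = ppg_beat(HemodynamicLabel(100.0, -5.0, 3000.0, -2000.0), 700, FS, prof)
        hi = ppg_beat(HemodynamicLabel(250.0, -5.0, 6000.0, -4000.0), 700, FS, prof)

        def foot(x):
            x = x - x[0]
            return np.argmax(x > 0.05 * x.max())

        assert foot(hi) < foot(lo)

    def test_ppg_amplitude_tracks_pulse_pressure(self):
        prof = SubjectProfile()
        small = ppg_beat(HemodynamicLabel(140.0, 10.0, 3000.0, -2000.0), 600, FS, prof)
        large = ppg_beat(HemodynamicLabel(250.0, -30.0, 6000.0, -4000.0), 600, FS, prof)
        assert np.ptp(large) > np.ptp(small)


class TestSimulateSubject:
    def test_cardinality_and_truth_table(self):
        cfg = SyntheticConfig(duration_s=25.0, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, truth = simulate_subject(cfg, 3)
        assert len(records) == 3
        assert set(truth["record_id"]) == {r.record_id for r in records}
        assert truth.groupby("record_id")["cycle_index"].is_monotonic_increasing.all()
        doses = [r.dose for r in records]
        assert doses == [0.5, 1.0, 2.0]

    def test_pipeline_closure_noiseless(self):
        # preprocess -> segment -> extract recovers the generator's labels
        from hemobeat.evaluation import prepare_beat_dataset
        from hemobeat.segmentation import QualityScreener, detect_r_peaks, split_cycles
        from hemobeat.signal_io import preprocess_record

        cfg = SyntheticConfig(
            duration_s=35.0,
            seed=6,
            corruption_fraction=0.0,
            snr_db={"ecg": 60.0, "pcg": 60.0, "ppg": 60.0, "lvbp": 80.0},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, truth = simulate_record(cfg, "closure")
            pre = preprocess_record(rec)
            cycles = split_cycles(pre, detect_r_peaks(pre.ecg, pre.fs))
            accepted = QualityScreener().screen(cycles)
        assert len(accepted) >= len(truth) - 5
        r_samples = truth["r_sample"].to_numpy()
        got, ref = [], []
        for c in accepted:
            j = np.argmin(np.abs(r_samples - c.start))
            if abs(r_samples[j] - c.start) > 20:
                continue
            lab = extract_labels(c.bp_seg, pre.fs)
            got.append(lab.as_array())
            ref.append(truth.iloc[j][["sbp", "dbp", "mrr", "mrd"]].to_numpy(float))
        got, ref = np.array(got), np.array(ref)
        assert len(got) >= len(truth) - 5
        for j in range(4):
            assert np.corrcoef(got[:, j], ref[:, j])[0, 1] > 0.999

    def test_distinct_record_seeds(self):
        cfg = SyntheticConfig(duration_s=25.0, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, _ = simulate_subject(cfg, 2)
        assert not np.array_equal(records[0].ecg[:5000], records[1].ecg[:5000])


class TestFeasibleLabelSampling:
    def test_within_ranges_and_realizable(self):
        rng = np.random.default_rng(0)
        pairs = sample_feasible_labels(200, rng)
        for lab, rr in pairs:
            for name, (lo, hi) in TOTAL_RANGES.items():
                assert lo <= getattr(lab, name) <= hi
            beat = lv_pressure_beat(lab, rr, FS)  # must not raise
            assert beat.size == rr

    def test_marginal_coverage(self):
        rng = np.random.default_rng(1)
        pairs = sample_feasible_labels(400, rng)
        sbp = np.array([lab.sbp for lab, _ in pairs])
        mrr = np.array([lab.mrr for lab, _ in pairs])
        assert sbp.min() < 100 and sbp.max() > 250
        assert mrr.min() < 1500 and mrr.max() > 8000
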