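"""Synthetic multichannel cardiovascular records with beat-wise ground truth.

Emulates the drug-bolus protocol used to produce wide hemodynamic
excursions: each record starts with a ~10 s resting plateau, after which an
intravenous epinephrine bolus drives SBP/MRR up and DBP/MRD down along a
double-exponential rise/decay whose magnitude grows with dose (0.5, 1 or
2 units/kg), returning to baseline within the record.  Beats are laid on an
R-R grid whose instantaneous heart rate also rises with the bolus.

Waveform kernels are deliberately minimal but physiologically shaped:

* LV pressure — raised-cosine systolic upstroke and downstroke joined by a
  short plateau and a smooth diastolic refill, parameterized analytically
  so the requested (SBP, DBP, MRR, MRD) are exactly the waveform's
  maximum, post-peak minimum, and derivative extrema;
* PCG — S1 and S2 bursts (Gaussian-modulated sinusoids in the 30-150 Hz
  band) locked to the upstroke and to end-systole, with S1 amplitude linear
  in MRR and S2 amplitude linear in |MRD| (the classical first-heart-sound
  / contractility relationship);
* PPG — a delayed femoral pulse whose transit delay decreases linearly
  with SBP, amplitude proportional to pulse pressure (SBP - DBP), baseline
  offset coupled to DBP, plus a small dicrotic bump;
* ECG — a narrow biphasic R spike at each beat onset plus a low T wave,
  sufficient for QRS detection.

Coupling coefficients live in :class:`SubjectProfile`; two profiles with
different couplings produce a controlled domain shift for cross-subject
experiments.  White noise is added per channel at a configurable SNR, and
a configurable fraction of beats is overwritten with high-amplitude
artifact bursts (flagged in the ground truth) to exercise quality
screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labels import HemodynamicLabel
from .signal_io import MultichannelRecord

__all__ = [
    "SubjectProfile",
    "SyntheticConfig",
    "TOTAL_RANGES",
    "bolus_trajectory",
    "ecg_beat",
    "lv_pressure_beat",
    "pcg_beat",
    "ppg_beat",
    "sample_feasible_labels",
    "simulate_record",
    "simulate_subject",
]

#: Observed total ranges of the four parameters (SBP mmHg, DBP mmHg,
#: MRR mmHg/s, MRD mmHg/s) across all study records.
TOTAL_RANGES = {
    "sbp": (77.0, 272.0),
    "dbp": (-47.0, 20.0),
    "mrr": (106.0, 9181.0),
    "mrd": (-5896.0, -70.0),
}

#: Dose (units/kg) -> peak-response multiplier.
DOSE_MULTIPLIERS = {0.5: 0.55, 1.0: 0.75, 2.0: 1.0}


@dataclass(frozen=True)
class SubjectProfile:
    """Couplings linking hemodynamics to waveform morphology, per subject."""

    # baselines
    sbp0: float = 130.0
    dbp0: float = 5.0
    mrr0: float = 2000.0
    mrd0: float = -2000.0
    hr0: float = 100.0  # bpm
    # peak bolus deltas (at dose multiplier 1)
    sbp_delta: float = 115.0
    dbp_delta: float = -32.0
    mrr_delta: float = 5800.0
    mrd_delta: float = -2900.0
    hr_rise: float = 0.35  # fractional HR increase at peak
    # PCG couplings: S1 amplitude = s1_gain*MRR + s1_offset, S2 on |MRD|
    s1_gain: float = 1.0e-4
    s1_offset: float = 0.05
    s2_gain: float = 1.2e-4
    s2_offset: float = 0.05
    s1_freq: float = 50.0
    s2_freq: float = 70.0
    # PPG couplings
    ppg_amp_gain: float = 4.0e-3  # amplitude per mmHg pulse pressure
    ppg_base_gain: float = 0.02  # baseline offset per mmHg DBP
    ptt_intercept: float = 0.28  # s, transit delay at SBP = 0
    ptt_slope: float = 6.0e-4  # s decrease per mmHg SBP
    # LV waveform
    edp_offset: float = 12.0  # end-diastolic pressure above DBP, mmHg


#: A second profile creating a controlled domain shift for cross-subject
#: experiments.  Its waveforms *look* like the default subject's (same
#: heart-sound frequencies, overlapping heart rate and pressure ranges) but
#: the couplings between hemodynamics and morphology conflict: weaker and
#: offset S1/S2 amplitude laws, a flatter and shorter pulse-transit-delay
#: law, weaker pulse-pressure gain, and an opposite-sign DBP baseline
#: coupling.  A network cannot satisfy both mappings at once on
#: similar-looking inputs, so plain cross-subject transfer degrades and a
#: single calibration record recovers only part of the gap.
PROFILE_B = SubjectProfile(
    sbp0=135.0,
    dbp0=7.0,
    mrr0=2300.0,
    mrd0=-2200.0,
    hr0=105.0,
    sbp_delta=105.0,
    dbp_delta=-29.0,
    mrr_delta=5400.0,
    mrd_delta=-2600.0,
    s1_gain=0.5e-4,
    s1_offset=0.35,
    s2_gain=0.6e-4,
    s2_offset=0.30,
    ppg_amp_gain=2.0e-3,
    ppg_base_gain=-0.02,
    ptt_intercept=0.20,
    ptt_slope=2.5e-4,
)


@dataclass
class SyntheticConfig:
    """Conditions of one simulated bolus recording."""

    profile: SubjectProfile = field(default_factory=SubjectProfile)
    subject_id: str = "synthA"
    dose: float = 1.0  # units/kg, one of {0.5, 1, 2}
    duration_s: float = 60.0
    fs: float = 1000.0
    lead_in_s: float = 0.5  # signal-free margin before the first beat
    injection_time_s: float = 10.0
    rise_tau_s: float = 6.0
    decay_tau_s: float = 10.0
    snr_db: dict = field(
        default_factory=lambda: {"ecg": 25.0, "pcg": 25.0, "ppg": 25.0, "lvbp": 45.0}
    )
    corruption_fraction: float = 0.02
    #: per-record sensor re-placement jitter: between records the microphone
    #: and optical probe are re-seated, scaling the acoustic/optical gains
    #: (lognormal, this sigma) and shifting the heart-sound carrier
    #: frequencies and transit-delay intercept slightly
    placement_jitter: float = 0.10
    # AR(1) beat-to-beat variability (innovation SDs per parameter)
    beat_noise_sd: tuple = (0.4, 0.1, 20.0, 10.0)
    beat_noise_phi: float = 0.9
    rr_jitter: float = 0.01  # fractional R-R jitter
    seed: int = 0


# ---------------------------------------------------------------------------
# Per-beat parameter trajectory


def _bolus_shape(t: np.ndarray, t0: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Normalized double-exponential bolus response, peak value 1."""
    x = np.maximum(t - t0, 0.0)
    g = (1.0 - np.exp(-x / tau_r)) * np.exp(-x / tau_d)
    xs = np.linspace(0, 10 * tau_d, 4000)
    peak = np.max((1.0 - np.exp(-xs / tau_r)) * np.exp(-xs / tau_d))
    return np.where(t > t0, g / peak, 0.0)


def bolus_trajectory(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-beat parameter 4-tuples and heart-rate series for one record.

    Beats are placed sequentially at the instantaneous heart rate; each
    parameter follows baseline -> dose-scaled double-exponential excursion
    -> baseline, with small AR(1) beat-to-beat variability, clipped to the
    observed total ranges.
    """
    rng = rng or np.random.default_rng(config.seed)
    prof = config.profile
    try:
        mult = DOSE_MULTIPLIERS[float(config.dose)]
    except KeyError:
        raise ValueError(f"dose must be one of {sorted(DOSE_MULTIPLIERS)}") from None

    # beat times at instantaneous heart rate
    times, rrs = [], []
    t = 0.0
    while t < config.duration_s:
        g = float(_bolus_shape(np.array([t]), config.injection_time_s,
                               config.rise_tau_s, config.decay_tau_s)[0])
        hr = prof.hr0 * (1.0 + prof.hr_rise * mult * g)
        rr = 60.0 / hr * (1.0 + config.rr_jitter * rng.standard_normal())
        times.append(t)
        rrs.append(rr)
        t += rr
    times, rrs = np.array(times), np.array(rrs)
    g = _bolus_shape(times, config.injection_time_s, config.rise_tau_s, config.decay_tau_s)
    if g[-1] > 0.2:
        warnings.warn("record too short for parameters to return to baseline", stacklevel=2)

    base = np.array([prof.sbp0, prof.dbp0, prof.mrr0, prof.mrd0])
    delta = np.array([prof.sbp_delta, prof.dbp_delta, prof.mrr_delta, prof.mrd_delta])
    params = base[None, :] + mult * delta[None, :] * g[:, None]
    # AR(1) beat noise
    noise = np.zeros_like(params)
    for k in range(1, len(times)):
        noise[k] = config.beat_noise_phi * noise[k - 1] + np.array(
            config.beat_noise_sd
        ) * rng.standard_normal(4)
    params = params + noise
    for j, name in enumerate(("sbp", "dbp", "mrr", "mrd")):
        lo, hi = TOTAL_RANGES[name]
        params[:, j] = np.clip(params[:, j], lo, hi)
    # keep the waveform constructible: SBP well above end-diastolic pressure
    params[:, 1] = np.minimum(params[:, 1], params[:, 0] - prof.edp_offset - 25.0)
    return pd.DataFrame(
        {
            "t": times,
            "rr_s": rrs,
            "sbp": params[:, 0],
            "dbp": params[:, 1],
            "mrr": params[:, 2],
            "mrd": params[:, 3],
        }
    )


# ---------------------------------------------------------------------------
# Waveform kernels


def _beat_timing(label: HemodynamicLabel, rr_s: float, edp_offset: float) -> tuple[float, float, float, float, float]:
    """Systolic timing (rise, plateau, fall, diastole durations) for a beat.

    Raises ``ValueError`` for label combinations the waveform cannot
    realize (non-positive MRR, non-negative MRD, or a systole that would
    not fit inside the R-R interval).
    """
    p_start = label.dbp + edp_offset
    if label.mrr <= 0:
        raise ValueError("MRR must be positive: zero upstroke cannot reach the peak")
    if label.mrd >= 0:
        raise ValueError("MRD must be negative: pressure must fall after systole")
    if label.sbp <= p_start:
        raise ValueError(f"SBP {label.sbp} not above end-diastolic pressure {p_start}")
    t_rise = np.pi * (label.sbp - p_start) / (2.0 * label.mrr)
    t_fall = np.pi * (label.sbp - label.dbp) / (2.0 * abs(label.mrd))
    # isovolumic contraction/relaxation cannot be instantaneous; the floor
    # also keeps the peak slope well resolved on the 1 kHz grid
    if t_rise < 0.015 or t_fall < 0.015:
        raise ValueError(
            f"systolic rise/fall of {min(t_rise, t_fall) * 1e3:.1f} ms too fast "
            "for the requested pulse pressure"
        )
    t_plateau = min(0.06, 0.1 * rr_s)
    t_dias = rr_s - (t_rise + t_plateau + t_fall)
    if t_dias < 0.04 * rr_s:
        raise ValueError(
            f"systole ({t_rise + t_plateau + t_fall:.3f} s) does not fit in the "
            f"{rr_s:.3f} s beat: MRR/MRD too low for the requested pulse pressure"
        )
    # the diastolic refill must be much slower than the systolic upstroke,
    # or the refill slope would masquerade as the beat's +dP/dt maximum
    if 1.5 * edp_offset / t_dias > 0.5 * label.mrr:
        raise ValueError(
            f"diastolic refill ({t_dias * 1e3:.0f} ms) too short for MRR "
            f"{label.mrr:.0f} mmHg/s: refill slope would rival the upstroke"
        )
    return p_start, t_rise, t_plateau, t_fall, t_dias


def lv_pressure_beat(label: HemodynamicLabel, rr: int, fs: float = 1000.0,
                     edp_offset: float = 12.0) -> np.ndarray:
    """One LV pressure beat realizing the requested label exactly.

    Piecewise construction over the ``rr``-sample beat: raised-cosine
    upstroke from end-diastolic pressure to SBP whose peak slope equals
    MRR, a short flat systolic plateau at SBP, a raised-cosine downstroke
    to DBP with peak slope MRD, and a smoothstep diastolic refill back to
    end-diastolic pressure.
    """
    rr_s = rr / fs
    p_start, t_rise, t_plateau, t_fall, t_dias = _beat_timing(label, rr_s, edp_offset)
    t = np.arange(rr) / fs
    p = np.empty(rr)
    m_rise = t < t_rise
    p[m_rise] = p_start + 0.5 * (label.sbp - p_start) * (1 - np.cos(np.pi * t[m_rise] / t_rise))
    m_plat = (t >= t_rise) & (t < t_rise + t_plateau)
    p[m_plat] = label.sbp
    m_fall = (t >= t_rise + t_plateau) & (t < t_rise + t_plateau + t_fall)
    tf = t[m_fall] - (t_rise + t_plateau)
    p[m_fall] = label.sbp - 0.5 * (label.sbp - label.dbp) * (1 - np.cos(np.pi * tf / t_fall))
    m_dias = t >= t_rise + t_plateau + t_fall
    u = (t[m_dias] - (t_rise + t_plateau + t_fall)) / t_dias
    p[m_dias] = label.dbp + (p_start - label.dbp) * (3 * u**2 - 2 * u**3)
    return p


def _burst(t: np.ndarray, center: float, sigma: float, freq: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.sin(2 * np.pi * freq * (t - center))


def pcg_beat(label: HemodynamicLabel, rr: int, fs: float = 1000.0,
             profile: SubjectProfile | None = None) -> np.ndarray:
    """PCG segment: S1 at the upstroke, S2 at end-systole.

    S1 amplitude is linear in MRR (``s1_gain*MRR + s1_offset``); S2
    amplitude is linear in |MRD|.
    """
    prof = profile or SubjectProfile()
    rr_s = rr / fs
    _, t_rise, t_plateau, t_fall, _ = _beat_timing(label, rr_s, prof.edp_offset)
    t = np.arange(rr) / fs
    s1_amp = prof.s1_gain * label.mrr + prof.s1_offset
    s2_amp = prof.s2_gain * abs(label.mrd) + prof.s2_offset
    out = _burst(t, 0.5 * t_rise, 0.012, prof.s1_freq, s1_amp)
    out += _burst(t, t_rise + t_plateau + t_fall, 0.010, prof.s2_freq, s2_amp)
    return out


def ppg_beat(label: HemodynamicLabel, rr: int, fs: float = 1000.0,
             profile: SubjectProfile | None = None) -> np.ndarray:
    """Delayed femoral PPG pulse for one beat.

    Transit delay decreases linearly with SBP; amplitude is proportional to
    pulse pressure; the cycle baseline is offset in proportion to DBP.
    """
    prof = profile or SubjectProfile()
    rr_s = rr / fs
    t = np.arange(rr) / fs
    delay = max(0.03, prof.ptt_intercept - prof.ptt_slope * label.sbp)
    amp = prof.ppg_amp_gain * (label.sbp - label.dbp)
    width = 0.30 * rr_s
    if delay + width > 0.95 * rr_s:
        width = max(0.95 * rr_s - delay, 0.1 * rr_s)
    u = (t - delay) / width
    pulse = np.where((u >= 0) & (u < 1), 0.5 * amp * (1 - np.cos(2 * np.pi * u)), 0.0)
    v = (t - delay - 0.55 * width) / (0.5 * width)
    pulse += np.where((v >= 0) & (v < 1), 0.1 * amp * (1 - np.cos(2 * np.pi * v)), 0.0)
    return pulse + prof.ppg_base_gain * label.dbp


def ecg_beat(rr: int, fs: float = 1000.0) -> np.ndarray:
    """ECG segment: biphasic R spike at beat onset plus a low T wave."""
    rr_s = rr / fs
    t = np.arange(rr) / fs
    out = 1.0 * np.exp(-0.5 * (t / 0.005) ** 2)
    out -= 0.3 * np.exp(-0.5 * ((t - 0.015) / 0.008) ** 2)
    out += 0.12 * np.exp(-0.5 * ((t - 0.30 * rr_s) / 0.03) ** 2)
    return out


# ---------------------------------------------------------------------------
# Record assembly


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    rms = np.sqrt(np.mean(np.square(x - np.mean(x))))
    if rms == 0:
        return x
    sigma = rms / 10 ** (snr_db / 20.0)
    return x + sigma * rng.standard_normal(x.size)


def simulate_record(config: SyntheticConfig, record_id: str = "synth-r00") -> tuple[MultichannelRecord, pd.DataFrame]:
    """Simulate one bolus record; returns the record and its ground truth.

    The ground-truth table has one row per generated beat: R sample, R-R
    length, the four parameters the waveforms encode, and a corruption
    flag for beats overwritten with artifact bursts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    traj = bolus_trajectory(config, rng)
    fs = config.fs
    lead = int(round(config.lead_in_s * fs))
    r_samples = lead + np.round(traj["t"].to_numpy() * fs).astype(int)
    rr_samples = np.diff(np.append(r_samples, r_samples[-1] + int(traj["rr_s"].iloc[-1] * fs)))
    n_total = int(r_samples[-1] + rr_samples[-1])

    ecg = np.zeros(n_total)
    pcg = np.zeros(n_total)
    ppg = np.zeros(n_total)
    lvbp = np.zeros(n_total)
    # hold the lead-in at the first beat's end-diastolic pressure so the
    # pressure trace has no step at the first R-wave
    lvbp[:lead] = traj["dbp"].iloc[0] + config.profile.edp_offset

    rows = []
    for k in range(len(r_samples)):
        s, n = int(r_samples[k]), int(rr_samples[k])
        if n < 5 or s + n > n_total:
            continue
        lab = HemodynamicLabel(
            sbp=float(traj["sbp"].iloc[k]),
            dbp=float(traj["dbp"].iloc[k]),
            mrr=float(traj["mrr"].iloc[k]),
            mrd=float(traj["mrd"].iloc[k]),
            cycle_index=k,
        )
        lvbp[s : s + n] = lv_pressure_beat(lab, n, fs, config.profile.edp_offset)
        pcg[s : s + n] += pcg_beat(lab, n, fs, config.profile)
        ppg[s : s + n] += ppg_beat(lab, n, fs, config.profile)
        ecg[s : s + n] += ecg_beat(n, fs)
        rows.append(
            {
                "record_id": record_id,
                "cycle_index": k,
                "r_sample": s,
                "rr_samples": n,
                "sbp": lab.sbp,
                "dbp": lab.dbp,
                "mrr": lab.mrr,
                "mrd": lab.mrd,
                "corrupted": False,
            }
        )
    truth = pd.DataFrame(rows)

    # artifact corruption of a fraction of beats (PCG + PPG)
    n_beats = len(truth)
    n_corrupt = int(round(config.corruption_fraction * n_beats))
    if n_corrupt > 0:
        picks = rng.choice(n_beats, size=n_corrupt, replace=False)
        for i in picks:
            s = int(truth.loc[i, "r_sample"])
            n = int(truth.loc[i, "rr_samples"])
            lo, hi = s + int(0.1 * n), s + int(0.9 * n)
            pcg[lo:hi] += 8.0 * np.std(pcg) * rng.standard_normal(hi - lo)
            ppg[lo:hi] += 8.0 * np.std(ppg) * rng.standard_normal(hi - lo)
            truth.loc[i, "corrupted"] = True

    snr = config.snr_db
    record = MultichannelRecord(
        record_id=record_id,
        subject_id=config.subject_id,
        fs=fs,
        ecg=_add_noise(ecg, snr["ecg"], rng),
        pcg=_add_noise(pcg, snr["pcg"], rng),
        ppg=_add_noise(ppg, snr["ppg"], rng),
        lvbp=_add_noise(lvbp, snr["lvbp"], rng),
        dose=config.dose,
    )
    return record, truth


def simulate_subject(
    config: SyntheticConfig, n_records: int
) -> tuple[list[MultichannelRecord], pd.DataFrame]:
    """Simulate ``n_records`` independent bolus records for one subject.

    Records share the subject profile; doses cycle through 0.5/1/2 and each
    record derives its own sub-seed deterministically from the config seed.
    """
    doses = [0.5, 1.0, 2.0]
    records, truths = [], []
    for i in range(n_records):
        sub_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        profile = _replace_sensors(config.profile, config.placement_jitter,
                                   np.random.default_rng(np.random.SeedSequence([config.seed, i, 7])))
        rec_config = replace(config, seed=sub_seed, dose=doses[i % len(doses)], profile=profile)
        rec_id = f"{config.subject_id}-r{i:02d}"
        rec, truth = simulate_record(rec_config, rec_id)
        records.append(rec)
        truths.append(truth)
    return records, pd.concat(truths, ignore_index=True)


def _replace_sensors(profile: SubjectProfile, jitter: float,
                     rng: np.random.Generator) -> SubjectProfile:
    """Per-record sensor re-placement: gain/frequency/delay perturbations.

    Emulates re-seating the microphone and optical probe between records:
    acoustic and optical gains scale lognormally, the heart-sound carrier
    frequencies shift by a few hertz, and the transit-delay intercept moves
    by a few milliseconds.  The subject's underlying physiology (baselines,
    bolus response) is untouched.
    """
    if jitter <= 0:
        return profile
    g = lambda: float(np.exp(jitter * rng.standard_normal()))
    return replace(
        profile,
        s1_gain=profile.s1_gain * g(),
        s1_offset=profile.s1_offset * g(),
        s2_gain=profile.s2_gain * g(),
        s2_offset=profile.s2_offset * g(),
        ppg_amp_gain=profile.ppg_amp_gain * g(),
        s1_freq=profile.s1_freq + 40.0 * jitter * rng.standard_normal(),
        s2_freq=profile.s2_freq + 40.0 * jitter * rng.standard_normal(),
        ptt_intercept=profile.ptt_intercept + 0.05 * jitter * rng.standard_normal(),
    )


# ---------------------------------------------------------------------------
# Feasible label sampling (for generator-extractor closure checks)


def sample_feasible_labels(
    n: int,
    rng: np.random.Generator,
    rr_range_s: tuple[float, float] = (0.35, 0.9),
    edp_offset: float = 12.0,
    fs: float = 1000.0,
) -> list[tuple[HemodynamicLabel, int]]:
    """Rejection-sample jointly feasible (label, rr) pairs over the ranges.

    Marginals are uniform over the observed total ranges; combinations the
    pressure waveform cannot realize within the drawn beat length (e.g. a
    tiny MRR with a large pulse pressure) are redrawn.
    """
    out: list[tuple[HemodynamicLabel, int]] = []
    while len(out) < n:
        rr_s = rng.uniform(*rr_range_s)
        sbp = rng.uniform(*TOTAL_RANGES["sbp"])
        dbp = rng.uniform(*TOTAL_RANGES["dbp"])
        mrr = rng.uniform(*TOTAL_RANGES["mrr"])
        mrd = rng.uniform(*TOTAL_RANGES["mrd"])
        if sbp <= dbp + edp_offset + 5.0:
            continue
        lab = HemodynamicLabel(sbp, dbp, mrr, mrd, cycle_index=len(out))
        try:
            _beat_timing(lab, rr_s, edp_offset)
        except ValueError:
            continue
        out.append((lab, int(round(rr_s * fs))))
    return out
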