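"""R-wave detection, cardiac-cycle segmentation, quality screening, windowing.

Every downstream quantity is defined on the R-to-R grid: the ECG R-wave is
the per-beat fiducial, cycles are the half-open sample intervals
``[R_k, R_{k+1})``, and each accepted cycle becomes one fixed 1000-sample
(1 s at 1 kHz) two-channel model input (PCG, PPG), zero-padded at the tail.

R-waves are found with the Pan-Tompkins algorithm implemented in its
classical stages: QRS-band filtering, five-point derivative, squaring,
moving-window integration, and adaptive dual signal/noise thresholds with
search-back for missed beats.  Detected fiducials are refined to the local
ECG maximum within +/-50 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import MultichannelRecord

__all__ = [
    "CardiacCycle",
    "QualityScreener",
    "RPeakList",
    "detect_r_peaks",
    "pad_to_window",
    "split_cycles",
]

#: Model input window: 1 s at 1 kHz, channels (PCG, PPG).
WINDOW_SAMPLES = 1000
WINDOW_CHANNELS = 2

#: Physiological R-R gate (ms) applied during screening.
RR_GATE_MS = (250.0, 1500.0)


@dataclass
class RPeakList:
    """Detected R-wave sample positions (0-based, strictly increasing)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def rr_intervals_ms(self) -> np.ndarray:
        return np.diff(self.indices) * 1000.0 / self.fs


@dataclass
class CardiacCycle:
    """One R-to-R beat with per-channel slices.

    ``bp_seg`` is present only when the record carries the invasive LVBP
    channel; quality fields are filled by :class:`QualityScreener`.
    """

    subject_id: str
    record_id: str
    cycle_index: int
    start: int
    length: int
    fs: float
    pcg_seg: np.ndarray
    ppg_seg: np.ndarray
    bp_seg: np.ndarray | None = None
    quality_score: float = 1.0
    quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("cycle length must be >= 1")
        for name in ("pcg_seg", "ppg_seg", "bp_seg"):
            seg = getattr(self, name)
            if seg is not None and len(seg) != self.length:
                raise ValueError(f"{name} has {len(seg)} samples, expected {self.length}")

    @property
    def rr_ms(self) -> float:
        return self.length * 1000.0 / self.fs


# ---------------------------------------------------------------------------
# Pan-Tompkins R-wave detection


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_ms: float = 200.0,
    refine_ms: float = 50.0,
) -> RPeakList:
    """Pan-Tompkins QRS detection on a (pre-filtered) ECG.

    Stages: 5-15 Hz band-pass to isolate QRS energy, five-point derivative,
    squaring, 150 ms moving-window integration, then adaptive dual
    thresholds.  The signal/noise running estimates follow the original
    recursions (SPK <- 0.125 PEAK + 0.875 SPK on signal peaks, similarly for
    NPK; threshold = NPK + 0.25 (SPK - NPK)); a search-back at half
    threshold fires when no QRS is seen for 1.66x the running RR average.
    Each detected fiducial is refined to the ECG maximum within
    ``+/-refine_ms``.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    if n < int(2 * fs):
        raise ValueError("ECG shorter than the 2 s detector warm-up")
    if np.std(ecg) == 0:
        warnings.warn("zero-variance ECG: no QRS energy", stacklevel=2)
        return RPeakList(np.empty(0, dtype=int), fs)

    nyq = fs / 2.0
    sos = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    # Five-point derivative (Pan-Tompkins kernel), squared, integrated.
    h = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, h[::-1], mode="same")
    squared = deriv**2
    mwi = _moving_window_integral(squared, max(int(0.150 * fs), 1))

    refractory = int(refractory_ms / 1000.0 * fs)
    # Candidate fiducials: local maxima of the integrated signal, excluding
    # the filter edge transients at the very ends of the record.
    candidates, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    edge = int(0.1 * fs)
    candidates = candidates[(candidates >= edge) & (candidates < n - edge)]
    if candidates.size == 0:
        warnings.warn("no integrator peaks found", stacklevel=2)
        return RPeakList(np.empty(0, dtype=int), fs)

    # Robust running-estimate initialization from the candidate peak
    # heights (upper quartile ~ QRS, lower quartile ~ noise): a single
    # large artifact must not dominate the starting threshold.
    heights = mwi[candidates]
    spk = float(np.percentile(heights, 75))
    npk = 0.5 * float(np.percentile(heights, 25))
    threshold = npk + 0.25 * (spk - npk)

    detected: list[int] = []
    rr_avg = fs  # running RR estimate, seeded at 60 bpm
    last_qrs = -refractory
    noise_peaks: list[int] = []

    for idx in candidates:
        peak = mwi[idx]
        if idx - last_qrs < refractory:
            continue
        if peak > threshold:
            detected.append(int(idx))
            spk = 0.125 * peak + 0.875 * spk
            if len(detected) >= 2:
                rr = detected[-1] - detected[-2]
                rr_avg = 0.125 * rr + 0.875 * rr_avg
            last_qrs = idx
        else:
            noise_peaks.append(int(idx))
            npk = 0.125 * peak + 0.875 * npk
            # Search-back: if a beat is overdue, accept the largest missed
            # candidate above half threshold.
            if detected and idx - last_qrs > 1.66 * rr_avg:
                window = [c for c in noise_peaks if last_qrs + refractory <= c <= idx]
                if window:
                    best = max(window, key=lambda c: mwi[c])
                    if mwi[best] > 0.5 * threshold:
                        detected.append(int(best))
                        detected.sort()
                        spk = 0.25 * mwi[best] + 0.75 * spk
                        last_qrs = best
                        noise_peaks = []
        threshold = npk + 0.25 * (spk - npk)

    if not detected:
        warnings.warn("no QRS detected above threshold", stacklevel=2)
        return RPeakList(np.empty(0, dtype=int), fs)

    # Refine each fiducial to the local ECG maximum within +/-refine_ms.
    half = int(refine_ms / 1000.0 * fs)
    refined = []
    for idx in detected:
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    return RPeakList(refined, fs)


# ---------------------------------------------------------------------------
# Cycle segmentation


def split_cycles(record: MultichannelRecord, r_peaks: RPeakList) -> list[CardiacCycle]:
    """Split all channels into R-to-R cycles (half-open ``[R_k, R_{k+1})``).

    One cycle per consecutive R-pair; the trailing partial beat after the
    last R-wave is discarded.  The LVBP segment is attached only when the
    record has the pressure channel.
    """
    idx = r_peaks.indices
    if len(idx) < 2:
        warnings.warn("fewer than 2 R-peaks: no complete cycle", stacklevel=2)
        return []
    cycles = []
    for k in range(len(idx) - 1):
        start, stop = int(idx[k]), int(idx[k + 1])
        cycles.append(
            CardiacCycle(
                subject_id=record.subject_id,
                record_id=record.record_id,
                cycle_index=k,
                start=start,
                length=stop - start,
                fs=record.fs,
                pcg_seg=record.pcg[start:stop].copy(),
                ppg_seg=record.ppg[start:stop].copy(),
                bp_seg=record.lvbp[start:stop].copy() if record.has_lvbp else None,
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# Quality screening


def _normalized(seg: np.ndarray, length: int, envelope: bool = False) -> np.ndarray:
    """Length-normalize a segment by linear interpolation and z-score it.

    For oscillatory channels (PCG) the analytic-signal envelope is
    correlated instead of the raw waveform: tiny carrier-phase shifts
    between beats would otherwise destroy the correlation of two bursts
    that are morphologically identical.
    """
    x = np.asarray(seg, dtype=float)
    if envelope:
        x = np.abs(sps.hilbert(x))
    x = np.interp(np.linspace(0, 1, length), np.linspace(0, 1, len(x)), x)
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros(length)


@dataclass
class QualityScreener:
    """Template-correlation quality gate for PCG/PPG cycles.

    A running per-channel template (exponentially weighted mean of accepted,
    length-normalized cycles, update weight ``template_weight``) scores each
    new cycle by normalized cross-correlation; the cycle score is the
    minimum over the two channels.  A cycle passes when the score reaches
    ``threshold`` and both segments survive amplitude sanity checks
    (flat-line variance, clipping at the rails).  The first clean cycle
    seeds the template.
    """

    threshold: float = 0.8
    template_weight: float = 0.1
    template_length: int = 500
    flat_eps: float = 1e-10
    clip_fraction: float = 0.01
    templates: dict[str, np.ndarray] = field(default_factory=dict)

    def _amplitude_ok(self, seg: np.ndarray) -> bool:
        if np.var(seg) < self.flat_eps:
            return False
        rail = np.max(np.abs(seg))
        if rail == 0:
            return False
        at_rail = np.mean(np.abs(np.abs(seg) - rail) < 1e-9 * rail)
        return at_rail < self.clip_fraction

    def assess_quality(self, cycle: CardiacCycle, update: bool = True) -> tuple[float, bool]:
        """Score one cycle and (optionally) update the running templates."""
        segs = {"pcg": cycle.pcg_seg, "ppg": cycle.ppg_seg}
        if not all(self._amplitude_ok(s) for s in segs.values()):
            cycle.quality_score, cycle.quality_pass = 0.0, False
            return 0.0, False
        lo, hi = RR_GATE_MS
        if not lo <= cycle.rr_ms <= hi:
            cycle.quality_score, cycle.quality_pass = 0.0, False
            return 0.0, False
        scores = []
        normed = {
            k: _normalized(v, self.template_length, envelope=(k == "pcg"))
            for k, v in segs.items()
        }
        for name, x in normed.items():
            tmpl = self.templates.get(name)
            if tmpl is None:
                scores.append(1.0)
            else:
                scores.append(float(np.dot(x, tmpl) / self.template_length))
        score = float(min(scores))
        passed = score >= self.threshold
        if passed and update:
            for name, x in normed.items():
                tmpl = self.templates.get(name)
                if tmpl is None:
                    self.templates[name] = x.copy()
                else:
                    tmpl += self.template_weight * (x - tmpl)
                    sd = np.std(tmpl)
                    if sd > 0:
                        self.templates[name] = (tmpl - np.mean(tmpl)) / sd
        cycle.quality_score, cycle.quality_pass = score, passed
        return score, passed

    def screen(self, cycles: list[CardiacCycle]) -> list[CardiacCycle]:
        """Score all cycles in order; return the accepted subset."""
        return [c for c in cycles if self.assess_quality(c)[1]]


# ---------------------------------------------------------------------------
# Fixed-length model inputs


def pad_to_window(
    cycle: CardiacCycle,
    window: int = WINDOW_SAMPLES,
    long_cycle_policy: str = "exclude",
) -> np.ndarray | None:
    """Zero-pad a cycle's (PCG, PPG) pair to a ``window x 2`` array.

    Cycles longer than the window (heart rate below 60 bpm at the default
    1 s window) are excluded by default — truncation would cut diastolic
    content — or truncated when ``long_cycle_policy='truncate'``.  Returns
    ``None`` for excluded cycles.
    """
    n = cycle.length
    if n > window:
        if long_cycle_policy == "exclude":
            warnings.warn(
                f"cycle {cycle.record_id}/{cycle.cycle_index} of {n} samples "
                f"exceeds the {window}-sample window: excluded",
                stacklevel=2,
            )
            return None
        if long_cycle_policy != "truncate":
            raise ValueError(f"unknown long_cycle_policy {long_cycle_policy!r}")
        n = window
    out = np.zeros((window, WINDOW_CHANNELS), dtype=float)
    out[:n, 0] = cycle.pcg_seg[:n]
    out[:n, 1] = cycle.ppg_seg[:n]
    return out
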