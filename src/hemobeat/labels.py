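"""Beat-wise hemodynamic ground truth from the LV pressure segment.

Four parameters are extracted per R-to-R cycle from the intraventricular
pressure trace:

* SBP — peak systolic LV pressure (cycle maximum), mmHg;
* DBP — minimum LV pressure in the diastolic phase (after the systolic
  peak), mmHg; intraventricular minima can be negative relative to the
  transducer calibration;
* MRR (LV +dP/dt_max) — maximum of the first pressure derivative, mmHg/s,
  an index of contractility;
* MRD (LV -dP/dt_max) — minimum of the derivative, mmHg/s, an index of
  relaxation capacity.

The derivative is estimated by central differences scaled by the sampling
rate; the pressure channel is already low-passed at 20 Hz, so no extra
smoothing is applied.  Per-record spike repair uses a 3-sigma rule on the
beat-to-beat difference series with a robust (median/MAD) sigma estimate —
a plain mean/SD of the difference series is inflated by the very spikes it
should flag and misses isolated outliers on short records.

Training targets are the fixed per-parameter scalings SBP/50, DBP/10,
MRR/2000, MRD/1000, which bring the four losses to comparable magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCALE_DIVISORS",
    "HemodynamicLabel",
    "PARAM_NAMES",
    "extract_labels",
    "fix_outliers",
    "inverse_scale",
    "labels_to_frame",
    "scale_targets",
]

PARAM_NAMES = ("sbp", "dbp", "mrr", "mrd")

#: Fixed target scaling divisors for (SBP, DBP, MRR, MRD).
SCALE_DIVISORS = np.array([50.0, 10.0, 2000.0, 1000.0])


@dataclass(frozen=True)
class HemodynamicLabel:
    """The (SBP, DBP, MRR, MRD) 4-tuple for one beat."""

    sbp: float
    dbp: float
    mrr: float
    mrd: float
    cycle_index: int = 0
    repaired: bool = False

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite label {vals}")
        if self.sbp < self.dbp:
            raise ValueError(f"SBP {self.sbp} < DBP {self.dbp}")
        if self.mrr < self.mrd:
            raise ValueError(f"MRR {self.mrr} < MRD {self.mrd}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sbp, self.dbp, self.mrr, self.mrd], dtype=float)


def extract_labels(bp_seg: np.ndarray, fs: float, cycle_index: int = 0) -> HemodynamicLabel:
    """Extract (SBP, DBP, MRR, MRD) from one cycle's LV pressure segment.

    SBP is the cycle maximum; DBP the minimum over the samples at and after
    the systolic peak (the diastolic phase); MRR/MRD the extrema of the
    central-difference derivative in mmHg/s.
    """
    bp = np.asarray(bp_seg, dtype=float)
    if bp.size < 5:
        raise ValueError(f"pressure segment of {bp.size} samples too short")
    if not np.all(np.isfinite(bp)):
        raise ValueError("non-finite samples in pressure segment")
    peak = int(np.argmax(bp))
    sbp = float(bp[peak])
    dbp = float(np.min(bp[peak:]))
    deriv = np.gradient(bp) * fs  # central differences, one-sided at edges
    return HemodynamicLabel(
        sbp=sbp,
        dbp=dbp,
        mrr=float(np.max(deriv)),
        mrd=float(np.min(deriv)),
        cycle_index=cycle_index,
    )


def _robust_sigma(d: np.ndarray) -> float:
    """MAD-based sigma estimate of a difference series (0 for constants)."""
    med = np.median(d)
    return 1.4826 * float(np.median(np.abs(d - med)))


def fix_outliers(
    labels: list[HemodynamicLabel],
    n_sigma: float = 3.0,
) -> list[HemodynamicLabel]:
    """Repair spike outliers in a record's beat-wise label sequence.

    For each parameter independently, candidate beats are found on the
    beat-to-beat difference series: a difference deviating from the median
    difference by more than ``n_sigma`` robust sigmas marks the beat it
    leads into, and when the next difference is also abnormal with opposite
    sign (the up-then-down signature of an isolated spike) the pair is
    consumed as a single flagged beat.  A candidate is confirmed only if the
    beat value itself deviates from the interpolation of its nearest
    non-candidate neighbours by more than the same threshold — this keeps
    the rule idempotent and protects genuine trends.  Confirmed values are
    replaced by linear interpolation between the nearest unflagged
    neighbours and the beat's ``repaired`` flag is set.  A record whose
    beats are all flagged for some parameter is unusable.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 beats to screen differences")
    values = np.stack([lab.as_array() for lab in labels])
    repaired_any = np.zeros(n, dtype=bool)
    for j in range(values.shape[1]):
        x = values[:, j]
        d = np.diff(x)
        sigma = _robust_sigma(d)
        if sigma == 0:
            continue  # constant-step sequence: nothing abnormal
        med = np.median(d)
        big = np.abs(d - med) > n_sigma * sigma
        candidates = np.zeros(n, dtype=bool)
        i = 0
        while i < d.size:
            if big[i]:
                candidates[i + 1] = True  # d[i] leads into beat i+1
                if i + 1 < d.size and big[i + 1] and d[i + 1] * d[i] < 0:
                    i += 2  # spike pair consumed as one flagged beat
                    continue
            i += 1
        if candidates.all():
            raise ValueError("all beats flagged as outliers: record unusable")
        good = np.nonzero(~candidates)[0]
        ref = np.interp(np.arange(n), good, x[good])
        flagged = candidates & (np.abs(x - ref) > n_sigma * sigma)
        if flagged.any():
            keep = np.nonzero(~flagged)[0]
            x[flagged] = np.interp(np.nonzero(flagged)[0], keep, x[keep])
            values[:, j] = x
            repaired_any |= flagged
    out = []
    for i, lab in enumerate(labels):
        if repaired_any[i]:
            out.append(
                replace(
                    lab,
                    sbp=float(values[i, 0]),
                    dbp=float(values[i, 1]),
                    mrr=float(values[i, 2]),
                    mrd=float(values[i, 3]),
                    repaired=True,
                )
            )
        else:
            out.append(lab)
    return out


def scale_targets(label: HemodynamicLabel | np.ndarray) -> np.ndarray:
    """Scale a label (or ``(n, 4)`` array) to dimensionless training targets."""
    arr = label.as_array() if isinstance(label, HemodynamicLabel) else np.asarray(label, dtype=float)
    return arr / SCALE_DIVISORS


def inverse_scale(target: np.ndarray) -> np.ndarray:
    """Invert :func:`scale_targets` back to physical units."""
    return np.asarray(target, dtype=float) * SCALE_DIVISORS


def labels_to_frame(labels: list[HemodynamicLabel], record_id: str = "") -> pd.DataFrame:
    """Serialize a label sequence as the canonical labels table."""
    return pd.DataFrame(
        {
            "record_id": record_id,
            "cycle_index": [lab.cycle_index for lab in labels],
            "sbp": [lab.sbp for lab in labels],
            "dbp": [lab.dbp for lab in labels],
            "mrr": [lab.mrr for lab in labels],
            "mrd": [lab.mrd for lab in labels],
            "repaired": [lab.repaired for lab in labels],
        }
    )
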