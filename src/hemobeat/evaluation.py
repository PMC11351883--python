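"""Record-level evaluation schemes and agreement metrics.

All splits are at the *record* level, never the cycle level: neighbouring
beats within a record are highly similar, so cycle-level splits leak test
information into training.  Three schemes are provided:

* scheme I (within subject): five-fold cross-validation of one subject's
  records with a 3-1-1 train/validation/test structure — each fold tests
  one fifth of the records and splits the rest 3:1 into train/validation;
  every record is tested exactly once;
* scheme II (cross subject): train on the other subjects' records; the
  target subject's records are halved into validation and test, then the
  halves are swapped for a second pass;
* calibrated scheme II: identical except ``n_cal`` records are moved from
  the target-subject validation half into the training set.

Per-parameter agreement between estimated and measured values is reported
as mean error ME, mean absolute error MAE, the standard deviation SD of
the mean-removed errors (N-1 denominator), and the Pearson correlation CC
with its t-test p-value and Fisher-z 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .labels import PARAM_NAMES, extract_labels, fix_outliers
from .model import HemodynamicRegressor
from .segmentation import QualityScreener, detect_r_peaks, pad_to_window, split_cycles
from .signal_io import MultichannelRecord, preprocess_record

__all__ = [
    "BeatDataset",
    "MetricsReport",
    "SplitPlan",
    "compute_metrics",
    "make_folds_scheme1",
    "make_split_calibration",
    "make_split_scheme2",
    "prepare_beat_dataset",
    "run_scheme",
]


@dataclass(frozen=True)
class SplitPlan:
    """Record-level fold assignments for one evaluation scheme."""

    scheme: str
    folds: tuple[dict, ...]  # each: {"train": [...], "val": [...], "test": [...]}
    seed: int

    def __post_init__(self) -> None:
        for fold in self.folds:
            sets = [set(fold["train"]), set(fold["val"]), set(fold["test"])]
            for i in range(3):
                for j in range(i + 1, 3):
                    if sets[i] & sets[j]:
                        raise ValueError(
                            f"overlapping record sets in fold: {sets[i] & sets[j]}"
                        )


def make_folds_scheme1(record_ids: list[str], k: int = 5, seed: int = 0) -> SplitPlan:
    """Within-subject k-fold plan with 3-1-1 train/validation/test structure.

    Records are shuffled and partitioned into ``k`` near-equal test
    subsets; in each fold the remaining records are randomly split 3:1
    into train and validation.  The union of the test subsets is the full
    record list, so every record is tested exactly once.
    """
    ids = list(record_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} records, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    order = [ids[i] for i in rng.permutation(len(ids))]
    subsets = [list(s) for s in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for i in range(k):
        test = [str(r) for r in subsets[i]]
        rest = [str(r) for j, s in enumerate(subsets) if j != i for r in s]
        rest = [rest[j] for j in rng.permutation(len(rest))]
        n_train = int(round(len(rest) * 0.75))
        n_train = min(max(n_train, 1), len(rest) - 1)
        folds.append({"train": sorted(rest[:n_train]), "val": sorted(rest[n_train:]), "test": sorted(test)})
    return SplitPlan("within_subject_5fold", tuple(folds), seed)


def make_split_scheme2(
    records_by_subject: dict[str, list[str]], target_subject: str, seed: int = 0
) -> SplitPlan:
    """Cross-subject plan: train on other subjects, halve the target's records.

    The target's records are split into two near-equal halves (validation
    and test) and the halves are swapped for a second pass, so every target
    record is tested exactly once across the two passes.
    """
    if target_subject not in records_by_subject:
        raise ValueError(f"target subject {target_subject!r} absent")
    others = [s for s in records_by_subject if s != target_subject]
    if not others:
        raise ValueError("need at least one non-target subject")
    train = sorted(r for s in others for r in records_by_subject[s])
    target = list(records_by_subject[target_subject])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    order = [target[i] for i in rng.permutation(len(target))]
    half = (len(order) + 1) // 2
    a, b = sorted(order[:half]), sorted(order[half:])
    folds = (
        {"train": train, "val": a, "test": b},
        {"train": train, "val": b, "test": a},
    )
    return SplitPlan("cross_subject", folds, seed)


def make_split_calibration(
    records_by_subject: dict[str, list[str]],
    target_subject: str,
    n_cal: int = 1,
    seed: int = 0,
) -> SplitPlan:
    """Cross-subject plan with ``n_cal`` target validation records moved to training.

    Test sets are identical to the plain cross-subject plan for the same
    seed, so calibrated and uncalibrated results are directly comparable.
    """
    base = make_split_scheme2(records_by_subject, target_subject, seed)
    if n_cal == 0:
        return SplitPlan("cross_subject_calibrated", base.folds, seed)
    folds = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    for fold in base.folds:
        val = list(fold["val"])
        if n_cal >= len(val):
            raise ValueError(f"n_cal={n_cal} >= {len(val)} validation records")
        picks = sorted(rng.choice(len(val), size=n_cal, replace=False).tolist())
        cal = [val[i] for i in picks]
        remaining = [v for i, v in enumerate(val) if i not in picks]
        folds.append(
            {
                "train": sorted(fold["train"] + cal),
                "val": remaining,
                "test": list(fold["test"]),
            }
        )
    return SplitPlan("cross_subject_calibrated", tuple(folds), seed)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricsReport:
    """Agreement statistics for one hemodynamic parameter."""

    parameter: str
    n: int
    me: float
    mae: float
    sd: float
    cc: float | None
    p_value: float | None
    ci95_low: float | None
    ci95_high: float | None

    def __post_init__(self) -> None:
        if self.mae < abs(self.me) - 1e-9:
            raise ValueError("MAE must be >= |ME|")


def _one_metric(est: np.ndarray, meas: np.ndarray, name: str) -> MetricsReport:
    err = est - meas
    n = err.size
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    sd = float(np.sqrt(np.sum((err - me) ** 2) / (n - 1))) if n > 1 else 0.0
    cc = p = lo = hi = None
    if n >= 3 and np.std(est) > 0 and np.std(meas) > 0:
        r, p_val = stats.pearsonr(est, meas)
        cc, p = float(r), float(p_val)
        if abs(cc) < 1.0 and n > 3:
            z = np.arctanh(cc)
            se = 1.0 / np.sqrt(n - 3)
            lo = float(np.tanh(z - 1.959963984540054 * se))
            hi = float(np.tanh(z + 1.959963984540054 * se))
        else:
            lo = hi = cc
    return MetricsReport(name, n, me, mae, sd, cc, p, lo, hi)


def compute_metrics(
    estimated: np.ndarray, measured: np.ndarray, parameters: tuple[str, ...] = PARAM_NAMES
) -> list[MetricsReport]:
    """ME/MAE/SD/CC (+ p, 95% CI) per parameter for paired beat series.

    ``estimated`` and ``measured`` are ``(n, p)`` arrays (or 1-D for a
    single parameter).  A constant series leaves CC (and its CI/p) as
    ``None``; the error statistics are still reported.
    """
    est = np.atleast_2d(np.asarray(estimated, dtype=float).T).T
    meas = np.atleast_2d(np.asarray(measured, dtype=float).T).T
    if est.shape != meas.shape:
        raise ValueError(f"shape mismatch {est.shape} vs {meas.shape}")
    if est.shape[0] < 1:
        raise ValueError("empty series")
    return [
        _one_metric(est[:, j], meas[:, j], parameters[j] if j < len(parameters) else f"p{j}")
        for j in range(est.shape[1])
    ]


def metrics_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports]).set_index("parameter")


# ---------------------------------------------------------------------------
# Beat dataset construction (pipeline glue)


@dataclass
class BeatDataset:
    """Windows and labels grouped by record, with a record -> subject map."""

    windows: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 1000, 2)
    labels: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 4) physical units
    subjects: dict[str, str] = field(default_factory=dict)

    def record_ids(self, subject: str | None = None) -> list[str]:
        return sorted(
            r for r, s in self.subjects.items() if subject is None or s == subject
        )

    def by_subject(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r, s in sorted(self.subjects.items()):
            out.setdefault(s, []).append(r)
        return out

    def stack(self, record_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        xs = [self.windows[r] for r in record_ids]
        ys = [self.labels[r] for r in record_ids]
        return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)

    def add_record(self, record_id: str, subject_id: str, windows: np.ndarray, labels: np.ndarray) -> None:
        if len(windows) != len(labels):
            raise ValueError("windows/labels length mismatch")
        self.windows[record_id] = np.asarray(windows, dtype=np.float32)
        self.labels[record_id] = np.asarray(labels, dtype=float)
        self.subjects[record_id] = subject_id


def prepare_beat_dataset(
    records: list[MultichannelRecord],
    quality_threshold: float = 0.8,
    long_cycle_policy: str = "exclude",
    repair_outliers: bool = True,
) -> BeatDataset:
    """Run the full preprocessing pipeline on raw records.

    Per record: zero-phase pre-filtering, QRS detection, R-to-R
    segmentation, template-correlation quality screening, label extraction
    from the LV pressure segment with spike repair, and fixed-window
    padding.  Records without complete accepted beats are skipped.
    """
    ds = BeatDataset()
    for rec in records:
        pre = preprocess_record(rec)
        peaks = detect_r_peaks(pre.ecg, pre.fs)
        cycles = split_cycles(pre, peaks)
        screener = QualityScreener(threshold=quality_threshold)
        accepted = screener.screen(cycles)
        if not accepted or not pre.has_lvbp:
            continue
        labs = [extract_labels(c.bp_seg, pre.fs, c.cycle_index) for c in accepted]
        if repair_outliers and len(labs) >= 3:
            labs = fix_outliers(labs)
        windows, labels = [], []
        for cyc, lab in zip(accepted, labs):
            win = pad_to_window(cyc, long_cycle_policy=long_cycle_policy)
            if win is None:
                continue
            windows.append(win)
            labels.append(lab.as_array())
        if windows:
            ds.add_record(rec.record_id, rec.subject_id, np.stack(windows), np.stack(labels))
    return ds


# ---------------------------------------------------------------------------
# Scheme runner


def run_scheme(
    dataset: BeatDataset,
    plan: SplitPlan,
    epochs: int = 200,
    batch_size: int = 64,
    learning_rate: float = 0.001,
    seed: int = 0,
    **estimator_kwargs,
) -> dict:
    """Train and evaluate per fold; aggregate metrics across folds.

    Returns ``{"folds": [per-fold dict], "aggregate": {param: mean CC and
    errors}}`` where each per-fold dict holds the fitted estimator's
    metrics on the pooled test-record beats.  Aggregation is the unweighted
    mean of per-fold metrics.
    """
    missing = {
        r for fold in plan.folds for part in ("train", "val", "test") for r in fold[part]
    } - set(dataset.subjects)
    if missing:
        raise ValueError(f"plan references unknown records {sorted(missing)}")
    fold_results = []
    for i, fold in enumerate(plan.folds):
        Xtr, ytr = dataset.stack(fold["train"])
        Xv, yv = dataset.stack(fold["val"])
        Xte, yte = dataset.stack(fold["test"])
        est = HemodynamicRegressor(
            epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            seed=seed + i,
            **estimator_kwargs,
        )
        est.fit(Xtr, ytr, X_val=Xv, y_val=yv)
        pred = est.predict(Xte)
        reports = compute_metrics(pred, yte)
        fold_results.append(
            {
                "fold": i,
                "test_records": list(fold["test"]),
                "n_test": len(yte),
                "metrics": reports,
                "best_epoch": est.best_epoch_,
                "estimated": pred,
                "measured": yte,
            }
        )
    aggregate = {}
    for j, name in enumerate(PARAM_NAMES):
        ccs = [f["metrics"][j].cc for f in fold_results if f["metrics"][j].cc is not None]
        aggregate[name] = {
            "cc": float(np.mean(ccs)) if ccs else None,
            "me": float(np.mean([f["metrics"][j].me for f in fold_results])),
            "mae": float(np.mean([f["metrics"][j].mae for f in fold_results])),
            "sd": float(np.mean([f["metrics"][j].sd for f in fold_results])),
        }
    return {"scheme": plan.scheme, "folds": fold_results, "aggregate": aggregate}
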