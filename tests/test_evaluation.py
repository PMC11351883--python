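"""Split plans, agreement metrics, and the scheme runner plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemobeat.evaluation import (
    BeatDataset,
    SplitPlan,
    compute_metrics,
    make_folds_scheme1,
    make_split_calibration,
    make_split_scheme2,
    run_scheme,
)


def _ids(n, prefix="r"):
    return [f"{prefix}{i:02d}" for i in range(n)]


class TestScheme1Folds:
    def test_15_records_3_9_3(self):
        plan = make_folds_scheme1(_ids(15), k=5, seed=0)
        assert len(plan.folds) == 5
        tested = []
        for fold in plan.folds:
            assert len(fold["test"]) == 3
            assert len(fold["train"]) == 9
            assert len(fold["val"]) == 3
            tested += fold["test"]
        assert sorted(tested) == _ids(15)  # every record tested exactly once

    def test_14_records_near_equal(self):
        plan = make_folds_scheme1(_ids(14), k=5, seed=1)
        sizes = sorted(len(f["test"]) for f in plan.folds)
        assert sizes == [2, 3, 3, 3, 3]
        tested = sorted(r for f in plan.folds for r in f["test"])
        assert tested == _ids(14)
        for fold in plan.folds:
            assert len(fold["train"]) + len(fold["val"]) + len(fold["test"]) == 14

    def test_seeded_determinism(self):
        assert make_folds_scheme1(_ids(15), seed=7) == make_folds_scheme1(_ids(15), seed=7)
        assert make_folds_scheme1(_ids(15), seed=7) != make_folds_scheme1(_ids(15), seed=8)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            make_folds_scheme1(_ids(4), k=5)

    def test_overlap_rejected_by_plan(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan("x", ({"train": ["a"], "val": ["a"], "test": ["b"]},), 0)


class TestScheme2Splits:
    by_subject = {
        "A": _ids(15, "a"),
        "B": _ids(14, "b"),
        "C": _ids(11, "c"),
    }

    def test_target_halved_and_swapped(self):
        plan = make_split_scheme2(self.by_subject, "B", seed=0)
        assert len(plan.folds) == 2
        for fold in plan.folds:
            assert len(fold["train"]) == 26  # A union C
            assert set(fold["train"]) == set(self.by_subject["A"] + self.by_subject["C"])
            assert len(fold["val"]) == 7 and len(fold["test"]) == 7
        # swap completeness: the two passes' test sets cover all target records
        tested = set(plan.folds[0]["test"]) | set(plan.folds[1]["test"])
        assert tested == set(self.by_subject["B"])
        assert plan.folds[0]["val"] == plan.folds[1]["test"]

    def test_missing_or_single_subject(self):
        with pytest.raises(ValueError):
            make_split_scheme2(self.by_subject, "Z")
        with pytest.raises(ValueError):
            make_split_scheme2({"A": _ids(5)}, "A")


class TestCalibrationSplit:
    by_subject = TestScheme2Splits.by_subject

    def test_one_record_moved_to_training(self):
        base = make_split_scheme2(self.by_subject, "B", seed=3)
        cal = make_split_calibration(self.by_subject, "B", n_cal=1, seed=3)
        for f0, f1 in zip(base.folds, cal.folds):
            assert len(f1["train"]) == len(f0["train"]) + 1
            assert len(f1["val"]) == len(f0["val"]) - 1
            assert f1["test"] == f0["test"]  # test untouched
            moved = set(f1["train"]) - set(f0["train"])
            assert moved <= set(f0["val"])

    def test_n_cal_zero_identity(self):
        base = make_split_scheme2(self.by_subject, "B", seed=4)
        cal = make_split_calibration(self.by_subject, "B", n_cal=0, seed=4)
        assert cal.folds == base.folds

    def test_n_cal_too_large(self):
        with pytest.raises(ValueError):
            make_split_calibration(self.by_subject, "B", n_cal=7, seed=0)


def _brute_force(est, meas):
    err = [e - m for e, m in zip(est, meas)]
    n = len(err)
    me = sum(err) / n
    mae = sum(abs(e) for e in err) / n
    sd = (sum((e - me) ** 2 for e in err) / (n - 1)) ** 0.5
    mean_e = sum(est) / n
    mean_m = sum(meas) / n
    num = sum((m - mean_m) * (e - mean_e) for e, m in zip(est, meas))
    den = (
        sum((m - mean_m) ** 2 for m in meas) * sum((e - mean_e) ** 2 for e in est)
    ) ** 0.5
    return me, mae, sd, num / den if den > 0 else None


class TestComputeMetrics:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compute_metrics(x, x)[0]
        assert (rep.me, rep.mae, rep.sd) == (0.0, 0.0, 0.0)
        assert rep.cc == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compute_metrics(x + 1.0, x)[0]
        assert rep.me == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.sd == pytest.approx(0.0)
        assert rep.cc == pytest.approx(1.0)

    def test_four_point_hand_case(self):
        est = np.array([1.0, 2.0, 3.0, 4.0])
        meas = np.array([1.5, 1.5, 3.5, 3.5])
        rep = compute_metrics(est, meas)[0]
        me, mae, sd, cc = _brute_force(est, meas)
        assert rep.me == pytest.approx(me, abs=1e-12)
        assert rep.mae == pytest.approx(mae, abs=1e-12)
        assert rep.sd == pytest.approx(sd, abs=1e-12)
        assert rep.cc == pytest.approx(cc, abs=1e-12)

    def test_constant_series_cc_undefined(self):
        rep = compute_metrics(np.full(5, 2.0), np.arange(5.0))[0]
        assert rep.cc is None
        assert rep.me == pytest.approx(2.0 - 2.0)

    def test_p_value_matches_t_statistic(self):
        rng = np.random.default_rng(0)
        meas = rng.standard_normal(40)
        est = meas + 0.5 * rng.standard_normal(40)
        rep = compute_metrics(est, meas)[0]
        t = rep.cc * np.sqrt(38 / (1 - rep.cc**2))
        assert rep.p_value == pytest.approx(2 * stats.t.sf(abs(t), 38), rel=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 60))
    def test_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        est = rng.standard_normal(n) * 10
        meas = rng.standard_normal(n) * 10
        rep = compute_metrics(est, meas)[0]
        me, mae, sd, cc = _brute_force(est.tolist(), meas.tolist())
        assert abs(rep.me - me) < 1e-10
        assert abs(rep.mae - mae) < 1e-10
        assert abs(rep.sd - sd) < 1e-10
        assert abs(rep.cc - cc) < 1e-10
        assert rep.mae >= abs(rep.me) - 1e-12
        assert rep.ci95_low <= rep.cc <= rep.ci95_high

    def test_sd_invariant_under_constant_shift(self):
        rng = np.random.default_rng(1)
        meas = rng.standard_normal(30)
        est = meas + rng.standard_normal(30)
        sd0 = compute_metrics(est, meas)[0].sd
        sd1 = compute_metrics(est + 5.0, meas)[0].sd
        assert sd1 == pytest.approx(sd0, abs=1e-12)


def _toy_dataset(rng, n_records=4, beats=14):
    """Tiny dataset with a linear window->label relation for plumbing tests."""
    ds = BeatDataset()
    for r in range(n_records):
        X = np.zeros((beats, 1000, 2), dtype=np.float32)
        amp = rng.uniform(0.5, 2.0, size=beats)
        X[:, 100:200, 0] = amp[:, None]
        X[:, 300:400, 1] = amp[:, None] * 0.5
        y = np.stack(
            [100 + 50 * amp, 50 * amp - 60, 2000 * amp, -1500 * amp], axis=1
        )
        ds.add_record(f"r{r:02d}", "s0", X, y)
    return ds


class TestRunScheme:
    def test_plumbing_and_anti_leakage(self, rng):
        ds = _toy_dataset(rng)
        plan = SplitPlan(
            "within_subject_5fold",
            (
                {"train": ["r00", "r01"], "val": ["r02"], "test": ["r03"]},
                {"train": ["r01", "r02"], "val": ["r03"], "test": ["r00"]},
            ),
            seed=0,
        )
        result = run_scheme(ds, plan, epochs=1, batch_size=8, seed=0)
        assert len(result["folds"]) == 2
        for fold_res, fold in zip(result["folds"], plan.folds):
            assert fold_res["n_test"] == 14 * len(fold["test"])
            # no test record appears in train or validation
            assert not (set(fold["test"]) & (set(fold["train"]) | set(fold["val"])))
        assert set(result["aggregate"]) == {"sbp", "dbp", "mrr", "mrd"}

    def test_unknown_record_rejected(self, rng):
        ds = _toy_dataset(rng)
        plan = SplitPlan("x", ({"train": ["r00"], "val": ["r01"], "test": ["zz"]},), 0)
        with pytest.raises(ValueError, match="unknown"):
            run_scheme(ds, plan, epochs=1)
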