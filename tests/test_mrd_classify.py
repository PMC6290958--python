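"""Log-reduction MRD classification and ROC/Youden cutoff selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npm1mrd import (
    PatientTimepoints,
    classify,
    classify_cohort,
    log_reduction,
    youden_cutoff,
)


def brute_force_best_j(values, outcomes):
    """Independent oracle: exhaustive scan over every threshold that can
    matter (all observed values nudged either way, plus the infinities)."""
    eps = 1e-9
    candidates = {math.inf, -math.inf}
    for v in values:
        if math.isfinite(v):
            candidates |= {v - eps, v, v + eps}
    n1 = sum(outcomes)
    n0 = len(outcomes) - n1
    best = -2.0
    for t in candidates:
        sens = sum(1 for v, y in zip(values, outcomes) if y and v < t) / n1
        spec = 1 - sum(1 for v, y in zip(values, outcomes) if not y and v < t) / n0
        best = max(best, sens + spec - 1)
    return best


def _cohort(values, outcomes):
    # encode a desired log reduction lr as (PI, PC) = (10**lr * 1e-3, 1e-3)
    patients = []
    for i, (lr, y) in enumerate(zip(values, outcomes)):
        if lr == math.inf:
            pi, pc = 1e-3, 0.0
        elif lr == -math.inf:
            pi, pc = 0.0, 1e-3
        else:
            pi, pc = min(1.0, 10.0**lr * 1e-4), 1e-4
        patients.append(PatientTimepoints(f"p{i}", pi, pc, outcome=y))
    return patients


class TestLogReduction:
    def test_one_log_drop_is_exactly_one(self):
        assert log_reduction(0.05, 0.005) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=50, derandomize=True)
    def test_identical_timepoints_give_zero(self, x):
        assert log_reduction(x, x) == pytest.approx(0.0)

    def test_sentinels(self):
        assert log_reduction(1e-3, 0.0) == math.inf
        assert log_reduction(0.0, 1e-3) == -math.inf
        assert math.isnan(log_reduction(0.0, 0.0))

    def test_negative_vaf_rejected(self):
        with pytest.raises(ValueError):
            log_reduction(-0.1, 0.1)

    @given(
        a=st.floats(min_value=1e-6, max_value=0.5),
        b=st.floats(min_value=1e-6, max_value=0.5),
        k=st.floats(min_value=1e-3, max_value=2.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, a, b, k):
        assert log_reduction(a * k, b * k) == pytest.approx(log_reduction(a, b))


class TestClassify:
    def test_below_cutoff_is_positive(self):
        p = PatientTimepoints("p", 0.05, 0.01)  # 0.7 logs
        assert classify(p, cutoff=1.0).classification == "positive"

    def test_full_clearance_is_negative(self):
        p = PatientTimepoints("p", 0.05, 0.0)
        r = classify(p)
        assert r.log_reduction == math.inf
        assert r.classification == "negative"

    def test_double_zero_is_negative(self):
        r = classify(PatientTimepoints("p", 0.0, 0.0))
        assert math.isnan(r.log_reduction)
        assert r.classification == "negative"

    def test_cohort_split_matches_count_below_cutoff(self):
        # 54 patients of whom 16 fail to clear one log
        cohort = []
        for i in range(16):
            cohort.append(PatientTimepoints(f"pos{i}", 0.04, 0.02))  # 0.3 logs
        for i in range(38):
            cohort.append(PatientTimepoints(f"neg{i}", 0.04, 0.002))  # 1.3 logs
        results = classify_cohort(cohort, cutoff=1.0)
        n_pos = sum(r.classification == "positive" for r in results)
        assert (n_pos, len(results) - n_pos) == (16, 38)

    @given(
        pi=st.floats(min_value=0, max_value=0.5),
        pc=st.floats(min_value=0, max_value=0.5),
        lo=st.floats(min_value=0.1, max_value=1.0),
        hi=st.floats(min_value=1.0, max_value=3.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_cutoff(self, pi, pc, lo, hi):
        p = PatientTimepoints("p", pi, pc)
        if classify(p, cutoff=lo).classification == "positive":
            assert classify(p, cutoff=hi).classification == "positive"


class TestYoudenCutoff:
    def test_perfect_separation_reaches_j_of_one(self):
        patients = _cohort([0.2, 0.4, 1.6, 2.0], [1, 1, 0, 0])
        point, roc = youden_cutoff(patients)
        assert point.youden_j == pytest.approx(1.0)
        # the chosen threshold separates the events (<= 0.4 logs) from the
        # non-events (>= 1.6 logs)
        assert 0.4 <= point.threshold <= 1.6

    def test_equals_brute_force_scan_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            values = list(np.round(rng.normal(1.0, 0.8, n), 3))
            # sprinkle sentinels
            for idx in rng.choice(n, size=n // 5, replace=False):
                values[idx] = math.inf if rng.random() < 0.5 else -math.inf
            outcomes = list(rng.integers(0, 2, n))
            if sum(outcomes) in (0, n):
                outcomes[0] = 1 - outcomes[0]
            patients = _cohort(values, outcomes)
            lrs = [log_reduction(p.vaf_pi, p.vaf_pc) for p in patients]
            point, _ = youden_cutoff(patients)
            assert point.youden_j == pytest.approx(
                brute_force_best_j(lrs, outcomes)
            )

    def test_agrees_with_sklearn_roc(self, rng):
        from sklearn.metrics import roc_curve

        values = list(np.round(rng.normal(1.0, 0.6, 60), 3))
        outcomes = list(rng.integers(0, 2, 60))
        patients = _cohort(values, outcomes)
        lrs = [log_reduction(p.vaf_pi, p.vaf_pc) for p in patients]
        point, _ = youden_cutoff(patients)
        fpr, tpr, _ = roc_curve(outcomes, [-v for v in lrs])
        assert point.youden_j == pytest.approx(float(np.max(tpr - fpr)))

    def test_permutation_null_j_is_small_and_shrinks_with_n(self, rng):
        def mean_null_j(n, n_perm=200):
            values = rng.normal(1.0, 0.5, n)
            base = np.array([1] * (n // 2) + [0] * (n - n // 2))
            js = []
            for _ in range(n_perm):
                perm = rng.permutation(base)
                patients = _cohort(list(values), list(perm))
                point, _ = youden_cutoff(patients)
                js.append(point.youden_j)
            return float(np.mean(js))

        small, large = mean_null_j(16), mean_null_j(80)
        # selection bias of the max keeps the null J positive but modest,
        # and it shrinks as the cohort grows
        assert 0.0 < large < small < 0.8

    def test_degenerate_outcomes_rejected(self):
        patients = _cohort([0.5, 1.5], [1, 1])
        with pytest.raises(ValueError, match="at least one event"):
            youden_cutoff(patients)

    def test_missing_outcome_rejected(self):
        with pytest.raises(ValueError, match="lacks an outcome"):
            youden_cutoff([PatientTimepoints("p", 0.1, 0.01)])
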