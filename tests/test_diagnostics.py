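"""Diagnostic stage: Youden cutoff search, bootstrap, Spearman, cohort
classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpimet import (
    CutoffAnalysis,
    bootstrap_cutoff,
    classify_cohort,
    fit_calibration,
    generate_cohort,
    spec_4t1,
    spearman,
    youden_cutoff,
)
from mpimet.quantify import CalibrationResult


def brute_force_youden(values, labels):
    """Independent oracle: exhaustive enumeration over observed thresholds
    with the fixed >= rule; smallest threshold among J maximizers."""
    best = None
    for thr in sorted(set(values)):
        tp = sum(1 for v, l in zip(values, labels) if l and v >= thr)
        fn = sum(1 for v, l in zip(values, labels) if l and v < thr)
        tn = sum(1 for v, l in zip(values, labels) if not l and v < thr)
        fp = sum(1 for v, l in zip(values, labels) if not l and v >= thr)
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        j = se + sp - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, se, sp)
    return best


class TestYoudenCutoff:
    def test_perfect_separation(self):
        res = youden_cutoff([1, 2, 3, 4], [False, False, True, True])
        assert res.threshold == 3.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0
        assert res.youden_j == 1.0
        assert (res.tp, res.fp, res.tn, res.fn) == (2, 0, 2, 0)

    def test_printed_metric_arithmetic(self):
        """Se 0.71 with Sp 1.00 gives J = 0.71 (the identity is exact)."""
        # 9 negatives; 7 positives, two of which sit inside the negatives
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 3.5, 4.5, 12, 13, 14, 15, 16]
        labels = [False] * 9 + [True] * 7
        res = youden_cutoff(values, labels)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1.0)
        assert res.sensitivity == pytest.approx(5 / 7)
        assert res.specificity == 1.0
        assert res.youden_j == pytest.approx(0.71, abs=0.005)

    def test_tie_breaks_to_smallest_threshold(self):
        # thresholds 3 and 30 both give J = 1; smallest wins
        res = youden_cutoff([1, 2, 3, 30], [False, False, True, True])
        assert res.threshold == 3.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            youden_cutoff([1, 2, 3], [True, True, True])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(4, 12))
        values = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=n, max_size=n))
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [True] * n_pos + [False] * (n - n_pos)
        res = youden_cutoff(values, labels)
        j, thr, se, sp = brute_force_youden(values, labels)
        assert res.youden_j == pytest.approx(j, abs=1e-12)
        assert res.threshold == thr
        assert res.sensitivity == pytest.approx(se)
        assert res.specificity == pytest.approx(sp)

    def test_j_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=10)
        labels = [True] * 5 + [False] * 5
        base = youden_cutoff(values, labels)
        warped = youden_cutoff(np.exp(3.0 * values), labels)
        assert warped.youden_j == pytest.approx(base.youden_j)
        assert warped.sensitivity == pytest.approx(base.sensitivity)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        values = [1, 3, 2, 8, 9, 10, 4, 7]
        labels = [False, False, False, True, True, True, False, True]
        a = bootstrap_cutoff(values, labels, n_iterations=200, seed=7)
        b = bootstrap_cutoff(values, labels, n_iterations=200, seed=7)
        assert a.threshold_frequency == b.threshold_frequency
        assert a.ci_sensitivity == b.ci_sensitivity

    def test_frequencies_sum_to_iterations(self):
        values = [1, 3, 2, 8, 9, 10, 4, 7]
        labels = [False, False, False, True, True, True, False, True]
        summary = bootstrap_cutoff(values, labels, n_iterations=500, seed=1)
        assert sum(summary.threshold_frequency.values()) == 500

    def test_perfectly_separated_modal_frequency_total(self):
        """Zero-variance classes: every resample selects the same threshold."""
        values = [0.0, 0.0, 0.0, 10.0, 10.0, 10.0]
        labels = [False, False, False, True, True, True]
        summary = bootstrap_cutoff(values, labels, n_iterations=300, seed=2)
        assert summary.modal_threshold == 10.0
        assert summary.modal_count == 300

    def test_near_separated_cohort_modal_majority(self):
        """A well-separated synthetic cohort keeps a majority-modal
        threshold across 1,000 resamples (threshold-stability report)."""
        table = generate_cohort(spec_4t1(
            seed=4, signal_per_unit_burden=20000.0, noise_sd=500.0))
        tracer_rows = table[table.treatment == "tracer"]
        summary = bootstrap_cutoff(tracer_rows.lung_signal.to_numpy(),
                                   tracer_rows.metastasis.to_numpy(),
                                   n_iterations=1000, seed=0)
        assert summary.modal_count > 500

    def test_stratified_preserves_class_counts(self):
        values = [1, 2, 3, 4, 9, 10]
        labels = [False, False, False, False, True, True]
        s = bootstrap_cutoff(values, labels, n_iterations=100, seed=3,
                             stratified=True)
        assert sum(s.threshold_frequency.values()) == 100

    def test_ci_bounds_ordered(self):
        values = [1, 3, 2, 8, 9, 10, 4, 7]
        labels = [False, False, False, True, True, True, False, True]
        s = bootstrap_cutoff(values, labels, n_iterations=400, seed=5)
        for lo, hi in (s.ci_sensitivity, s.ci_specificity, s.ci_ppv, s.ci_npv):
            assert lo <= hi

    def test_coverage_of_true_sensitivity(self):
        """Percentile CIs for Se cover the generating model's true Se in at
        least 90% of replicates (Gaussian classes, known optimum)."""
        mu0, mu1, sd = 0.0, 2.0, 1.0
        t_star = (mu0 + mu1) / 2.0  # population Youden threshold, equal sds
        true_se = 1.0 - stats.norm.cdf((t_star - mu1) / sd)
        rng = np.random.default_rng(2024)
        n_rep, covered, n = 200, 0, 30
        for _ in range(n_rep):
            values = np.concatenate([rng.normal(mu0, sd, n),
                                     rng.normal(mu1, sd, n)])
            labels = np.array([False] * n + [True] * n)
            s = bootstrap_cutoff(values, labels, n_iterations=400,
                                 seed=int(rng.integers(2**31)))
            lo, hi = s.ci_sensitivity
            covered += lo <= true_se <= hi
        assert covered / n_rep >= 0.90


class TestSpearman:
    def test_strictly_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_rank_formula_no_ties(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 6 -> 1 - 36/120 = 0.7
        assert spearman([1, 2, 3, 4, 5], [2, 3, 1, 4, 5]) == pytest.approx(0.7)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True),
           st.randoms(use_true_random=False))
    def test_matches_rank_formula(self, xs, rnd):
        ys = list(xs)
        rnd.shuffle(ys)
        n = len(xs)
        rx = {v: i for i, v in enumerate(sorted(xs))}
        ry = {v: i for i, v in enumerate(sorted(ys))}
        d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(xs, ys))
        expected = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        assert spearman(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestClassifyCohort:
    def test_separated_cohort_perfect_metrics(self):
        table = generate_cohort(spec_4t1(
            seed=0, signal_per_unit_burden=50000.0, noise_sd=100.0))
        report = classify_cohort(table, n_iterations=200, seed=0)
        c = report.cutoff
        assert (c.sensitivity, c.specificity, c.ppv, c.npv) == (1.0, 1.0, 1.0, 1.0)
        assert (report.predictions.predicted == report.predictions.metastasis).all()

    def test_overlapping_classes_lower_j(self):
        sep = classify_cohort(generate_cohort(spec_4t1(
            seed=1, signal_per_unit_burden=50000.0, noise_sd=100.0)),
            n_iterations=100, seed=0)
        noisy = classify_cohort(generate_cohort(spec_4t1(
            seed=1, signal_per_unit_burden=100.0, noise_sd=8000.0)),
            n_iterations=100, seed=0)
        assert noisy.cutoff.youden_j < sep.cutoff.youden_j

    def test_threshold_converted_via_zero_intercept_calibration(self):
        cal = CalibrationResult(slope=33_163.0 / 3.2, intercept=0.0,
                                r_squared=1.0, mass_range=(0.0, 1000.0))
        table = generate_cohort(spec_4t1(seed=0))
        # pin the fitted threshold by constructing a cohort around it
        table.loc[table.metastasis, "lung_signal"] = 50_346.7
        table.loc[~table.metastasis, "lung_signal"] = 10_000.0
        report = classify_cohort(table, cal, n_iterations=50, seed=0)
        assert report.cutoff.threshold == pytest.approx(50_346.7)
        assert report.iron_threshold_ug == pytest.approx(4.9)

    def test_controls_excluded_from_fit(self):
        from mpimet import spec_huher2
        table = generate_cohort(spec_huher2(seed=2))
        report = classify_cohort(table, n_iterations=50, seed=0)
        n_tracer = (table.treatment == "tracer").sum()
        assert len(report.predictions) == n_tracer
        c = report.cutoff
        assert c.tp + c.fp + c.tn + c.fn == n_tracer

    def test_model_results_interface(self):
        table = generate_cohort(spec_4t1(seed=6))
        model = CutoffAnalysis.from_dataframe(table[table.treatment == "tracer"])
        res = model.fit()
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1.0)
        boot = model.bootstrap(100, seed=1)
        assert boot.n_iterations == 100
        assert "threshold" in res.summary()
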