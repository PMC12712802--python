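"""Diagnostic threshold analysis for per-animal MPI signal.

The decision rule is "lung signal >= threshold implies metastasis" (tracer
accumulates in metastatic lungs, so the direction is fixed by the biology).
The optimal threshold maximizes the Youden index J = sensitivity +
specificity - 1 over the observed signal values; equal-J ties break toward
the smallest threshold, which favours sensitivity. Threshold stability and
uncertainty come from unstratified bootstrap resampling with percentile
confidence intervals; resamples that lose one class entirely are redrawn so
the iteration count stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CalibrationResult, round_sig, signal_to_iron

__all__ = [
    "CutoffResult",
    "BootstrapSummary",
    "CutoffAnalysis",
    "youden_cutoff",
    "bootstrap_cutoff",
    "spearman",
    "classify_cohort",
    "CohortClassification",
]


@dataclass
class CutoffResult:
    """Optimal-threshold operating point with its confusion table."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int

    def summary(self) -> str:
        return (
            f"threshold {self.threshold:g}: Se {self.sensitivity:.2f}, "
            f"Sp {self.specificity:.2f}, PPV {self.ppv:.2f}, NPV {self.npv:.2f}, "
            f"J {self.youden_j:.2f} "
            f"(tp {self.tp}, fp {self.fp}, tn {self.tn}, fn {self.fn})"
        )


@dataclass
class BootstrapSummary:
    """Percentile CIs and threshold-selection frequencies over resamples."""

    n_iterations: int
    threshold_frequency: dict
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    ci_ppv: tuple[float, float]
    ci_npv: tuple[float, float]
    seed: int | None = None
    sensitivities: np.ndarray = field(default=None, repr=False)
    specificities: np.ndarray = field(default=None, repr=False)
    thresholds: np.ndarray = field(default=None, repr=False)

    @property
    def modal_threshold(self) -> float:
        return max(self.threshold_frequency, key=self.threshold_frequency.get)

    @property
    def modal_count(self) -> int:
        return self.threshold_frequency[self.modal_threshold]

    def summary(self) -> str:
        return (
            f"{self.n_iterations} bootstrap iterations; modal threshold "
            f"{self.modal_threshold:g} selected {self.modal_count}x; "
            f"95% CIs: Se [{self.ci_sensitivity[0]:.2f}, {self.ci_sensitivity[1]:.2f}], "
            f"Sp [{self.ci_specificity[0]:.2f}, {self.ci_specificity[1]:.2f}], "
            f"PPV [{self.ci_ppv[0]:.2f}, {self.ci_ppv[1]:.2f}], "
            f"NPV [{self.ci_npv[0]:.2f}, {self.ci_npv[1]:.2f}]"
        )


def _check_two_classes(values: np.ndarray, labels: np.ndarray) -> None:
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D sequences")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")


def _metrics_matrix(V: np.ndarray, L: np.ndarray):
    """Vectorized operating points for every observed-value threshold.

    V, L: (B, n) value/label matrices (B independent datasets). Candidate
    thresholds are each row's sorted values; the rule is value >= threshold.
    Returns per-row best (threshold, se, sp, ppv, npv, j, tp, fp, tn, fn),
    ties in J broken toward the smallest threshold.
    """
    B, n = V.shape
    thr = np.sort(V, axis=1)  # (B, n) ascending
    pred = V[:, None, :] >= thr[:, :, None]  # (B, n_thr, n)
    pos = L[:, None, :]
    tp = (pred & pos).sum(axis=2)
    fp = (pred & ~pos).sum(axis=2)
    n_pos = L.sum(axis=1)[:, None]
    n_neg = (~L).sum(axis=1)[:, None]
    fn = n_pos - tp
    tn = n_neg - fp
    se = tp / n_pos
    sp = tn / n_neg
    j = se + sp - 1.0
    # exact integer score (J * n_pos * n_neg up to a constant) so equal-J
    # ties stay exact ties and the first maximum = smallest threshold wins
    score = tp * n_neg + tn * n_pos
    best = np.argmax(score, axis=1)
    rows = np.arange(B)
    tp_b, fp_b = tp[rows, best], fp[rows, best]
    tn_b, fn_b = tn[rows, best], fn[rows, best]
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp_b + fp_b > 0, tp_b / (tp_b + fp_b), np.nan)
        npv = np.where(tn_b + fn_b > 0, tn_b / (tn_b + fn_b), np.nan)
    return (thr[rows, best], se[rows, best], sp[rows, best], ppv, npv,
            j[rows, best], tp_b, fp_b, tn_b, fn_b)


def youden_cutoff(values, labels) -> CutoffResult:
    """Optimal cutoff maximizing J = Se + Sp - 1 over observed values.

    Classification rule: predicted positive iff value >= threshold. Ties in
    J break toward the smallest threshold. Raises on single-class input.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(values, labels)
    thr, se, sp, ppv, npv, j, tp, fp, tn, fn = _metrics_matrix(
        values[None, :], labels[None, :])
    return CutoffResult(
        threshold=float(thr[0]),
        sensitivity=float(se[0]), specificity=float(sp[0]),
        ppv=float(ppv[0]), npv=float(npv[0]), youden_j=float(j[0]),
        tp=int(tp[0]), fp=int(fp[0]), tn=int(tn[0]), fn=int(fn[0]),
    )


def bootstrap_cutoff(values, labels, n_iterations: int = 1000,
                     seed: int | None = None,
                     stratified: bool = False) -> BootstrapSummary:
    """Bootstrap the whole cutoff analysis; percentile 95% CIs.

    Unstratified resampling with replacement of (value, label) pairs by
    default (a stratified per-class option is exposed); resamples with a
    single class are redrawn so exactly ``n_iterations`` analyses are kept.
    Deterministic given ``seed``. NPV (and PPV) can be undefined in a
    resample when no animal is predicted negative (positive); such
    iterations are excluded from that interval only.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(values, labels)
    rng = np.random.default_rng(seed)
    n = values.size
    if stratified:
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        ip = pos_idx[rng.integers(0, pos_idx.size, (n_iterations, pos_idx.size))]
        ineg = neg_idx[rng.integers(0, neg_idx.size, (n_iterations, neg_idx.size))]
        idx = np.concatenate([ip, ineg], axis=1)
    else:
        idx = rng.integers(0, n, (n_iterations, n))
        bad = _single_class_rows(labels[idx])
        while bad.size:
            idx[bad] = rng.integers(0, n, (bad.size, n))
            bad = bad[_single_class_rows(labels[idx[bad]])]
    V, L = values[idx], labels[idx]
    thr, se, sp, ppv, npv, *_ = _metrics_matrix(V, L)

    uniq, counts = np.unique(thr, return_counts=True)
    freq = {float(u): int(c) for u, c in zip(uniq, counts)}

    def ci(a):
        a = a[np.isfinite(a)]
        return (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))

    return BootstrapSummary(
        n_iterations=n_iterations, threshold_frequency=freq,
        ci_sensitivity=ci(se), ci_specificity=ci(sp),
        ci_ppv=ci(ppv), ci_npv=ci(npv), seed=seed,
        sensitivities=se, specificities=sp, thresholds=thr,
    )


def _single_class_rows(L: np.ndarray) -> np.ndarray:
    return np.flatnonzero(L.all(axis=1) | ~L.any(axis=1))


class CutoffAnalysis:
    """Model object for the diagnostic-threshold analysis.

    ``CutoffAnalysis(values, labels).fit()`` returns the full-data
    :class:`CutoffResult`; :meth:`bootstrap` quantifies its stability.
    """

    def __init__(self, values, labels):
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels, dtype=bool)
        _check_two_classes(self.values, self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "lung_signal",
                       label_col: str = "metastasis") -> "CutoffAnalysis":
        return cls(df[value_col].to_numpy(), df[label_col].to_numpy())

    def fit(self) -> CutoffResult:
        return youden_cutoff(self.values, self.labels)

    def bootstrap(self, n_iterations: int = 1000, seed: int | None = None,
                  stratified: bool = False) -> BootstrapSummary:
        return bootstrap_cutoff(self.values, self.labels, n_iterations,
                                seed=seed, stratified=stratified)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties).

    Raises on fewer than 3 pairs or on a constant input, where the rank
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("Spearman correlation undefined for a constant input")
    return float(stats.spearmanr(x, y).statistic)


# --------------------------------------------------------------------------
# cohort-level end-to-end classification
# --------------------------------------------------------------------------

@dataclass
class CohortClassification:
    """End-to-end diagnostic report for one (or a pooled) cohort."""

    cutoff: CutoffResult
    bootstrap: BootstrapSummary
    predictions: pd.DataFrame
    iron_threshold_ug: float | None = None

    def summary(self) -> str:
        lines = ["Cohort metastasis classification",
                 "  " + self.cutoff.summary(),
                 "  " + self.bootstrap.summary()]
        if self.iron_threshold_ug is not None:
            lines.append(f"  threshold as iron mass: {self.iron_threshold_ug:g} ugFe")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        c, b = self.cutoff, self.bootstrap
        return {
            "threshold": c.threshold,
            "sensitivity": c.sensitivity, "specificity": c.specificity,
            "ppv": c.ppv, "npv": c.npv, "youden_j": c.youden_j,
            "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
            "bootstrap": {
                "n_iterations": b.n_iterations,
                "modal_threshold": b.modal_threshold,
                "modal_count": b.modal_count,
                "ci_sensitivity": list(b.ci_sensitivity),
                "ci_specificity": list(b.ci_specificity),
                "ci_ppv": list(b.ci_ppv),
                "ci_npv": list(b.ci_npv),
                "seed": b.seed,
            },
            "iron_threshold_ug": self.iron_threshold_ug,
        }


def classify_cohort(table: pd.DataFrame, cal: CalibrationResult | None = None,
                    n_iterations: int = 1000, seed: int | None = 0,
                    stratified: bool = False) -> CohortClassification:
    """Run the full diagnostic stage on a cohort table.

    Only tracer-treated animals enter the cutoff fit (controls define
    background, not disease state). The fitted threshold is converted to an
    iron mass when a calibration is supplied (reported to 2 significant
    figures, matching how such thresholds are printed).
    """
    tracer_rows = table[table["treatment"] == "tracer"]
    if tracer_rows.empty:
        raise ValueError("cohort has no tracer-treated animals")
    analysis = CutoffAnalysis.from_dataframe(tracer_rows)
    cutoff = analysis.fit()
    boot = analysis.bootstrap(n_iterations, seed=seed, stratified=stratified)
    preds = tracer_rows[["animal_id", "lung_signal", "metastasis"]].copy()
    preds["predicted"] = preds["lung_signal"] >= cutoff.threshold
    iron = None
    if cal is not None:
        iron = round_sig(signal_to_iron(cutoff.threshold, cal), 2)
    return CohortClassification(cutoff=cutoff, bootstrap=boot,
                                predictions=preds.reset_index(drop=True),
                                iron_threshold_ug=iron)
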