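"""Imbalance-aware classification metrics and paired-model statistical tests.

Per-class metrics are one-vs-rest; macro averages are unweighted means over
classes so minority classes carry equal weight.  Specificity is per-class
one-vs-rest (TN / (TN + FP)), macro-averaged, and the G-mean is
sqrt(macro recall x macro specificity) — the balance-sensitive summary used
for imbalanced data.  The test battery gates paired t vs Wilcoxon
signed-rank (and ANOVA vs Kruskal-Wallis) on Shapiro-Wilk normality at
alpha = 0.05, and compares two classifiers on the same samples with the
McNemar test (exact binomial when discordant pairs are scarce).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ConfusionMatrix", "MetricsReport", "TestResult", "confusion_matrix",
    "macro_metrics", "mcnemar", "paired_comparison", "group_comparison",
    "write_report", "read_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    conf_int: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    g_means: float
    per_class: pd.DataFrame = field(repr=False)
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_specificity": self.macro_specificity,
            "g_means": self.g_means,
            "n_samples": self.n_samples,
            "per_class": self.per_class.to_dict(orient="list"),
        }


class ConfusionMatrix:
    """C x C count grid; rows are true classes, columns predicted."""

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("confusion matrix entries must be nonnegative integers")
        self.counts = counts

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(predictions, labels, n_classes: int) -> ConfusionMatrix:
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size and (predictions.min() < 0 or predictions.max() >= n_classes
                             or labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts)


def macro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics and their unweighted macro means.

    A class with zero predicted positives gets precision 0 (noted in the
    per-class table); a class absent from the data gets recall 0.
    """
    m = cm.counts
    if m.sum() == 0:
        raise ValueError("empty confusion matrix")
    c = cm.n_classes
    tp = np.diag(m).astype(float)
    fn = m.sum(axis=1) - tp
    fp = m.sum(axis=0) - tp
    tn = m.sum() - tp - fn - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)

    per_class = pd.DataFrame({
        "class": np.arange(c),
        "tp": tp.astype(int), "fp": fp.astype(int),
        "fn": fn.astype(int), "tn": tn.astype(int),
        "precision": precision, "recall": recall,
        "specificity": specificity, "f1": f1,
        "zero_predicted": (tp + fp == 0),
    })
    macro_rec = float(recall.mean())
    macro_spec = float(specificity.mean())
    return MetricsReport(
        accuracy=float(tp.sum() / m.sum()),
        macro_precision=float(precision.mean()),
        macro_recall=macro_rec,
        macro_f1=float(f1.mean()),
        macro_specificity=macro_spec,
        g_means=float(np.sqrt(macro_rec * macro_spec)),
        per_class=per_class,
        n_samples=cm.total,
    )


# ------------------------------------------------------------------- tests

def mcnemar(preds_a, preds_b, labels, exact_threshold: int = 25,
            correction: bool = False) -> TestResult:
    """Paired misclassification test from the discordant counts.

    b = A right & B wrong, c = A wrong & B right.  Chi-square statistic
    (b - c)^2 / (b + c), optional continuity correction; exact binomial
    two-sided p when b + c < ``exact_threshold``.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    labels = np.asarray(labels)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("both prediction vectors and labels must align")
    right_a = preds_a == labels
    right_b = preds_b == labels
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    if b + c == 0:
        return TestResult("mcnemar", 0.0, 1.0, False,
                          note="degenerate: no discordant pairs")
    table = np.array([[0, b], [c, 0]])  # only off-diagonals matter
    exact = (b + c) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=correction)
    name = "mcnemar_exact" if exact else "mcnemar_chi2"
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      bool(res.pvalue < ALPHA), note=f"b={b}, c={c}")


def paired_comparison(samples_a, samples_b, method: str = "auto") -> TestResult:
    """Paired t-test / Wilcoxon signed-rank on paired metric samples.

    ``method`` is "auto" (Shapiro-Wilk normality gate at alpha=0.05 picks the
    branch), "t", or "wilcoxon".
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length paired 1-D samples, n >= 3")
    d = a - b
    if np.allclose(d, 0.0):
        return TestResult("paired_degenerate", 0.0, 1.0, False,
                          note="all paired differences are zero")
    if np.ptp(d) == 0.0:
        return TestResult("paired_degenerate", float(d[0]), np.nan, True,
                          note="constant nonzero difference: deterministic "
                               "separation, no sampling variance")
    if method not in ("auto", "t", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    sw_stat, sw_p = stats.shapiro(d)
    use_t = sw_p >= ALPHA if method == "auto" else method == "t"
    if use_t:
        t_stat, p = stats.ttest_rel(a, b)
        n = d.size
        se = d.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(1 - ALPHA / 2, n - 1) * se
        ci = (float(d.mean() - half), float(d.mean() + half))
        return TestResult("paired_t", float(t_stat), float(p), bool(p < ALPHA),
                          conf_int=ci,
                          note=f"shapiro_p={sw_p:.4f} (normality accepted)")
    mode = "exact" if d.size <= 25 and not np.any(d == 0) else "approx"
    w_stat, p = stats.wilcoxon(a, b, mode=mode)
    return TestResult("wilcoxon_signed_rank", float(w_stat), float(p), bool(p < ALPHA),
                      note=f"shapiro_p={sw_p:.4f} (normality rejected)")


def group_comparison(groups: list, method: str = "auto") -> TestResult:
    """One-way ANOVA / Kruskal-Wallis across k groups.

    ``method`` is "auto" (per-group Shapiro-Wilk normality gate), "anova",
    or "kruskal".
    """
    if method not in ("auto", "anova", "kruskal"):
        raise ValueError(f"unknown method {method!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 3 for a in arrays):
        raise ValueError("each group needs n >= 3")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return TestResult("anova", 0.0, 1.0, False, note="identical constant groups")
    normal = True
    for a in arrays:
        if np.ptp(a) == 0:
            normal = False  # Shapiro undefined on constant samples
            break
        _, p = stats.shapiro(a)
        if p < ALPHA:
            normal = False
            break
    use_anova = normal if method == "auto" else method == "anova"
    if use_anova:
        f_stat, p = stats.f_oneway(*arrays)
        return TestResult("anova", float(f_stat), float(p), bool(p < ALPHA))
    h_stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h_stat), float(p), bool(p < ALPHA))


# ----------------------------------------------------------------- reports

def write_report(report: MetricsReport, tests: list[TestResult],
                 out_path: Path | str) -> tuple[Path, Path]:
    """Write machine-readable JSON plus a per-class CSV next to it."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "metrics": report.to_dict(),
        "tests": [
            {**asdict(t), "conf_int": list(t.conf_int) if t.conf_int else None}
            for t in tests
        ],
    }
    out_path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    csv_path = out_path.with_suffix(".per_class.csv")
    report.per_class.to_csv(csv_path, index=False)
    return out_path, csv_path


def read_report(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
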