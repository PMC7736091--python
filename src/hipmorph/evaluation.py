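"""Agreement and diagnostic-performance statistics.

Compares automated (CAD) hip-development assessments against a reference
reader. Confusion-table statistics are computed in exact rational
arithmetic and only rounded for reporting; paired marginal-homogeneity
tests follow the exact-binomial McNemar convention (2x2) and Bowker's
generalization (k x k).

Reporting precision follows radiology convention: percentages to one
decimal, kappa to three.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedMetricError


@dataclass(frozen=True, eq=False)
class ConfusionTable:
    """A k x k reference-vs-predicted count table.

    Rows are the reference standard, columns the predicted labels, in the
    order given by ``classes``.
    """

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if k < 2:
            raise ParameterError("a confusion table needs at least 2 classes")
        if counts.shape != (k, k):
            raise ParameterError(
                f"counts must be ({k}, {k}) for {k} classes, got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ParameterError("confusion counts must be non-negative")
        if counts.sum() == 0:
            raise ParameterError("confusion table is empty")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))
        self.counts.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.classes)

    def index(self, label) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ParameterError(f"label {label!r} not among classes {self.classes}")


def confusion_table(ref: Sequence, pred: Sequence, classes: Sequence) -> ConfusionTable:
    """Cross-tabulate reference vs predicted labels."""
    ref = list(ref)
    pred = list(pred)
    if len(ref) != len(pred):
        raise ParameterError("reference and predicted label lists differ in length")
    if not ref:
        raise ParameterError("cannot tabulate empty label lists")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for r, p in zip(ref, pred):
        if r not in idx:
            raise ParameterError(f"reference label {r!r} not among classes {classes}")
        if p not in idx:
            raise ParameterError(f"predicted label {p!r} not among classes {classes}")
        counts[idx[r], idx[p]] += 1
    return ConfusionTable(classes, counts)


def diagnostic_metrics(t: ConfusionTable, positive) -> dict:
    """Accuracy, sensitivity, specificity and false-positive rate of a 2x2 table.

    ``positive`` names the disease class (e.g. "dysplasia"). Computed with
    exact fractions, returned as floats in [0, 1].
    """
    if t.k != 2:
        raise ParameterError("diagnostic_metrics needs a 2x2 table")
    pos = t.index(positive)
    neg = 1 - pos
    c = t.counts
    tp, fn = int(c[pos, pos]), int(c[pos, neg])
    tn, fp = int(c[neg, neg]), int(c[neg, pos])
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive reference cases")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative reference cases")
    acc = Fraction(tp + tn, t.n)
    sens = Fraction(tp, tp + fn)
    spec = Fraction(tn, tn + fp)
    return {
        "accuracy": float(acc),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "fpr": float(1 - spec),
    }


def multiclass_accuracy(t: ConfusionTable) -> float:
    """Overall agreement: trace / n."""
    return float(Fraction(int(np.trace(t.counts)), t.n))


def per_class_recall(t: ConfusionTable) -> dict:
    """Reference-class recall (row-normalized diagonal) per class."""
    out = {}
    for i, cls in enumerate(t.classes):
        row = int(t.counts[i].sum())
        out[cls] = float(Fraction(int(t.counts[i, i]), row)) if row else float("nan")
    return out


def cohen_kappa(t: ConfusionTable) -> float:
    """Unweighted Cohen kappa, exact-rational until the final division."""
    c = t.counts
    n = t.n
    po = Fraction(int(np.trace(c)), n)
    pe = sum(
        Fraction(int(c[i].sum()), n) * Fraction(int(c[:, i].sum()), n)
        for i in range(t.k)
    )
    if pe == 1:
        raise UndefinedMetricError("kappa undefined: expected agreement is 1")
    return float((po - pe) / (1 - pe))


def mcnemar(t: ConfusionTable, *, exact: bool = True) -> dict:
    """McNemar test of marginal homogeneity for a 2x2 paired table.

    Default is the exact two-sided binomial test on the discordant counts
    (b, c) at any size; ``exact=False`` gives the continuity-corrected
    chi-square. Returns ``{"statistic", "p", "method"}``; when there are
    no discordant pairs, p = 1 with a note.
    """
    if t.k != 2:
        raise ParameterError("mcnemar needs a 2x2 table")
    b = int(t.counts[0, 1])
    c = int(t.counts[1, 0])
    if b + c == 0:
        return {
            "statistic": 0.0,
            "p": 1.0,
            "method": "degenerate",
            "note": "no discordant pairs",
        }
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        return {"statistic": float(min(b, c)), "p": p, "method": "exact-binomial"}
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    return {
        "statistic": float(stat),
        "p": float(stats.chi2.sf(stat, df=1)),
        "method": "chi2-continuity",
    }


def bowker(t: ConfusionTable) -> dict:
    """Bowker's test of symmetry for a k x k paired table.

    Sum over i < j of (n_ij - n_ji)^2 / (n_ij + n_ji); pairs with zero
    discordant sum contribute nothing and drop one degree of freedom. A
    2x2 input delegates to :func:`mcnemar` (exact).
    """
    if t.k == 2:
        out = mcnemar(t)
        out["df"] = 1
        return out
    stat = 0.0
    df = 0
    c = t.counts
    for i in range(t.k):
        for j in range(i + 1, t.k):
            pair_sum = int(c[i, j] + c[j, i])
            if pair_sum == 0:
                continue
            stat += (int(c[i, j]) - int(c[j, i])) ** 2 / pair_sum
            df += 1
    if df == 0:
        return {"statistic": 0.0, "p": 1.0, "df": 0, "method": "degenerate",
                "note": "no discordant pairs"}
    return {
        "statistic": float(stat),
        "p": float(stats.chi2.sf(stat, df=df)),
        "df": df,
        "method": "bowker",
    }


def pearson_r(x, y) -> dict:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson_r needs two equal-length 1-D arrays")
    if x.size < 3:
        raise ParameterError("pearson_r needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ParameterError("pearson_r undefined for a constant input")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


def cronbach_alpha(m1, m2) -> float:
    """Cronbach alpha for two repeated measurements (k = 2 items).

    alpha = 2 * (1 - (Var(m1) + Var(m2)) / Var(m1 + m2)), sample variances.
    Used for test-retest reliability of angle measurements.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ParameterError("cronbach_alpha needs two equal-length 1-D arrays")
    if m1.size < 3:
        raise ParameterError("cronbach_alpha needs n >= 3")
    v1 = np.var(m1, ddof=1)
    v2 = np.var(m2, ddof=1)
    vt = np.var(m1 + m2, ddof=1)
    if vt == 0:
        raise UndefinedMetricError("cronbach_alpha undefined: total variance is 0")
    return float(2.0 * (1.0 - (v1 + v2) / vt))


@dataclass(frozen=True, eq=False)
class ROCResult:
    """A full ROC curve with its trapezoidal AUC and Youden-optimal cut."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    orientation: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ParameterError(f"AUC {self.auc} outside [0, 1]")


def roc(scores, binary_labels, orientation: str = "higher_is_positive") -> ROCResult:
    """ROC analysis of continuous scores against binary labels.

    Thresholds are the midpoints between consecutive distinct scores plus
    -inf/+inf, so the chosen cut always lies between observations. A score
    is called positive when it is strictly above the threshold (below, for
    ``orientation="lower_is_positive"``, which is the CE-angle convention:
    smaller angles mean worse coverage). AUC is the trapezoid rule over
    the (FPR, TPR) staircase, which equals the Mann-Whitney concordant
    pair fraction with half-credit for ties. The optimal threshold
    maximizes Youden J = sensitivity + specificity - 1, ties resolved
    toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ParameterError("roc needs equal-length 1-D scores and labels")
    if not np.all(np.isfinite(s)):
        raise ParameterError("roc scores must be finite")
    if y.all() or not y.any():
        raise ParameterError("roc needs both classes present")
    if orientation == "lower_is_positive":
        s = -s
    elif orientation != "higher_is_positive":
        raise ParameterError(f"unknown orientation {orientation!r}")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    # positive call: score > threshold
    sens = (pos.size - np.searchsorted(pos, thresholds, side="right")) / pos.size
    spec = np.searchsorted(neg, thresholds, side="right") / neg.size

    fpr = 1.0 - spec  # decreasing in threshold
    order = np.lexsort((sens, fpr))  # ascending fpr, ties by ascending tpr
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best = tied[np.argmax(spec[tied])]
    opt = float(thresholds[best])
    if orientation == "lower_is_positive":
        opt = -opt
        thresholds = -thresholds
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=opt,
        orientation=orientation,
    )


def plot_roc(result: ROCResult, path=None, ax=None):
    """Plot a ROC curve (requires the optional matplotlib dependency)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = 1.0 - result.specificity
    order = np.argsort(fpr, kind="stable")
    ax.plot(fpr[order], result.sensitivity[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {result.auc:.3f}")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def format_percent(value: float, decimals: int = 1) -> float:
    """Report a proportion as a percentage at the conventional precision."""
    return round(100.0 * value, decimals)
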