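"""Multiclass evaluation metrics and cohort statistics.

Conventions (chosen so that every scalar can be reproduced from one
confusion matrix, and pinned by cross-checking against published fractions):

- *per-class accuracy* is the recall of a class: diagonal / row sum;
- *sensitivity* is the macro mean of the per-class recalls — identical to
  the "average accuracy" column of a per-class accuracy table;
- *precision* is the macro mean of per-class precisions (diagonal / column
  sum); a class never predicted contributes 0 and is logged;
- *specificity* is the macro mean of one-vs-rest true-negative rates
  TN/(TN+FP); for k equal-sized classes this equals
  1 - (1 - accuracy)/(k - 1) exactly;
- ROC/AUC are one-vs-rest per class (via scikit-learn's trapezoidal
  integration) with a macro average over classes; a micro (pooled) AUC is
  also reported, clearly labelled.

Cohort statistics: a Pearson chi-square test on a group x sex contingency
table and a one-way ANOVA reconstructed from per-group summary statistics
(mean, SD, n), as printed in demographic tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DataError, NumericError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass
class ConfusionMatrix:
    """Integer class-by-class count table; rows = true, columns = predicted."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.class_names = tuple(self.class_names)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise DataError(f"confusion matrix shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise DataError("confusion matrix requires non-negative integer counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        if self.total == 0:
            raise DataError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)


def confusion_matrix(y_true, y_pred, class_names: Sequence[str]) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise DataError("label sequences differ in length")
    lut = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            raise DataError(f"label {t if t not in lut else p!r} not in class order {tuple(class_names)}")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Recall of each class: diagonal / row sum."""
    rowsum = cm.counts.sum(axis=1)
    if np.any(rowsum == 0):
        bad = cm.class_names[int(np.argwhere(rowsum == 0)[0][0])]
        raise DataError(f"class {bad!r} has no true samples; per-class accuracy undefined")
    return np.diag(cm.counts) / rowsum


def macro_average(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean; the 'average accuracy' of a per-class table."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise DataError("macro_average of an empty vector")
    return float(values.mean())


@dataclass
class MetricsReport:
    accuracy: float
    per_class_accuracy: np.ndarray
    sensitivity: float
    precision: float
    specificity: float
    class_names: tuple
    auc: float | None = None
    auc_micro: float | None = None
    per_class_auc: dict = field(default_factory=dict)
    roc_curves: dict = field(default_factory=dict)

    def scalars(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
        }
        if self.auc is not None:
            out["auc_macro"] = self.auc
            out["auc_micro"] = self.auc_micro
        return out


def macro_report(cm: ConfusionMatrix) -> MetricsReport:
    """All scalar metrics derived from one confusion matrix."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    recalls = per_class_accuracy(cm)
    colsum = counts.sum(axis=0)
    diag = np.diag(counts)
    precisions = np.zeros(len(diag))
    nz = colsum > 0
    precisions[nz] = diag[nz] / colsum[nz]
    if not nz.all():
        never = [cm.class_names[i] for i in np.flatnonzero(~nz)]
        logger.warning("classes never predicted contribute precision 0: %s", never)
    total = counts.sum()
    rowsum = counts.sum(axis=1)
    tp = diag
    fp = colsum - diag
    tn = total - rowsum - fp
    specificities = tn / (tn + fp)
    return MetricsReport(
        accuracy=cm.accuracy(),
        per_class_accuracy=recalls,
        sensitivity=macro_average(recalls),
        precision=macro_average(precisions),
        specificity=macro_average(specificities),
        class_names=cm.class_names,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc_ovr(scores: np.ndarray, y_true, class_names: Sequence[str]) -> dict:
    """One-vs-rest ROC curves and AUCs from an (n_samples, n_classes) score matrix.

    Per class the ROC treats that class as positive and the rest as
    negative; the AUC is the trapezoidal area.  Classes with no positives
    or no negatives are excluded with a warning.  Returns a dict with
    per-class curves/AUCs, the macro AUC (mean over usable classes) and the
    micro AUC (all one-vs-rest decisions pooled).
    """
    scores = np.asarray(scores, dtype=float)
    class_names = tuple(class_names)
    y_true = list(y_true)
    if scores.shape != (len(y_true), len(class_names)):
        raise DataError(
            f"score matrix shape {scores.shape} != ({len(y_true)}, {len(class_names)})"
        )
    curves: dict[str, dict] = {}
    aucs: dict[str, float] = {}
    pooled_y, pooled_s = [], []
    for k, cname in enumerate(class_names):
        pos = np.array([t == cname for t in y_true])
        if pos.all() or not pos.any():
            logger.warning("class %r has no positives or no negatives; AUC undefined", cname)
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores[:, k])
        curves[cname] = {"fpr": fpr, "tpr": tpr}
        aucs[cname] = float(_sk_auc(fpr, tpr))
        pooled_y.append(pos.astype(int))
        pooled_s.append(scores[:, k])
    if not aucs:
        raise NumericError("AUC undefined for every class")
    fpr_mi, tpr_mi, _ = _sk_roc_curve(np.concatenate(pooled_y), np.concatenate(pooled_s))
    return {
        "per_class": aucs,
        "macro": float(np.mean(list(aucs.values()))),
        "micro": float(_sk_auc(fpr_mi, tpr_mi)),
        "curves": curves,
    }


def full_report(cm: ConfusionMatrix, scores: np.ndarray | None = None,
                y_true=None) -> MetricsReport:
    """Macro report, with ROC/AUC fields filled in when scores are given."""
    report = macro_report(cm)
    if scores is not None:
        roc = roc_auc_ovr(scores, y_true, cm.class_names)
        report.auc = roc["macro"]
        report.auc_micro = roc["micro"]
        report.per_class_auc = roc["per_class"]
        report.roc_curves = roc["curves"]
    return report


# ---------------------------------------------------------------------------
# cohort statistics


def chi_square_contingency(counts) -> tuple:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction); returns ``(statistic, dof, p_value)``."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DataError("contingency table must be at least 2 x 2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero margin; expected counts undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_from_summary(means, sds, ns) -> tuple:
    """One-way ANOVA reconstructed from per-group (mean, SD, n) summaries.

    Between-group mean square from the group means and sizes; within-group
    mean square from the pooled sample variances.  Returns
    ``(F, (df_between, df_within), p_value)``.  With two groups F equals
    the square of the pooled-variance t statistic.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.shape == sds.shape == ns.shape) or means.size < 2:
        raise DataError("anova_from_summary needs >= 2 groups of aligned (mean, sd, n)")
    if np.any(ns < 2):
        raise DataError("every group needs n >= 2")
    k = means.size
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, int(N - k)
    if ss_within == 0:
        raise NumericError("zero within-group variance in all groups; F is infinite")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), (df_b, df_w), p


def cohort_table(demographics, group_col: str = "group", age_col: str = "age",
                 sex_col: str = "sex") -> dict:
    """Demographic summary of a per-subject table.

    Returns per-group size, age mean +/- SD, female/male counts, plus the
    gender chi-square and the age ANOVA across groups.  ``sex`` values are
    'F'/'M' (case-insensitive).
    """
    groups = list(dict.fromkeys(demographics[group_col]))
    rows: dict[str, dict] = {}
    sex_counts = []
    means, sds, ns = [], [], []
    for g in groups:
        sub = demographics[demographics[group_col] == g]
        f = int(sub[sex_col].str.upper().eq("F").sum())
        m = int(sub[sex_col].str.upper().eq("M").sum())
        if f + m != len(sub):
            raise DataError(f"group {g!r}: sex values other than F/M present")
        age = sub[age_col].to_numpy(dtype=float)
        rows[g] = {
            "n": len(sub),
            "age_mean": float(age.mean()),
            "age_sd": float(age.std(ddof=1)) if len(age) > 1 else 0.0,
            "female": f,
            "male": m,
        }
        sex_counts.append([f, m])
        means.append(age.mean())
        sds.append(age.std(ddof=1))
        ns.append(len(age))
    chi2, dof, p_chi = chi_square_contingency(sex_counts)
    F, dfs, p_f = anova_from_summary(means, sds, ns)
    return {
        "groups": rows,
        "gender_chi2": {"statistic": chi2, "dof": dof, "p_value": p_chi},
        "age_anova": {"F": F, "dof": dfs, "p_value": p_f},
    }
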