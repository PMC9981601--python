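"""Failure-load scores, Youden-J dichotomization and revision-risk statistics.

Predicted failure loads for a cohort are min-max normalized to a 0–1 score,

    score = (F_failure − F_min) / (F_max − F_min),

so the weakest predicted ligament scores 0 and the strongest 1.  Subjects
with score ≤ threshold form the *low* failure-load group (predicted
positive, at high reinjury risk); the threshold is chosen where Youden's
J = sensitivity + specificity − 1 is maximal over all distinct scores, with
ties broken toward the smallest threshold (fewest subjects labelled
at-risk).  Group-wise revision incidences are compared with a
likelihood-ratio chi-square test, G = 2·Σ O·ln(O/E) on the 2×2 table
against a 1-df chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2

from .relaxometry import ValidationError

__all__ = [
    "ScoreSet",
    "ContingencyTable",
    "ThresholdResult",
    "StratificationResult",
    "RevisionStratification",
    "score_failure_loads",
    "youden_j",
    "optimal_threshold",
    "stratify",
    "lr_chi_square",
]


@dataclass
class ScoreSet:
    """Per-subject estimated failure loads and their 0–1 min-max scores."""

    loads: np.ndarray
    scores: np.ndarray
    f_min: float
    f_max: float

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts; positive = revision, predicted positive = low-score group."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def as_array(self) -> np.ndarray:
        # rows: outcome (revision, none); cols: group (low, high)
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


def score_failure_loads(loads: Sequence[float]) -> ScoreSet:
    """Min-max normalize estimated failure loads onto [0, 1]."""
    loads = np.asarray(loads, dtype=float)
    if loads.size < 2:
        raise ValidationError("need at least 2 loads to score")
    f_min, f_max = float(loads.min()), float(loads.max())
    if f_max == f_min:
        raise ValidationError("all loads equal: score undefined (F_max = F_min)")
    return ScoreSet(loads, (loads - f_min) / (f_max - f_min), f_min, f_max)


def youden_j(table: ContingencyTable) -> float:
    """J = sensitivity + specificity − 1."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise ValidationError("both outcome classes must be present")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.tn + table.fp)
    return sens + spec - 1.0


def _table_at(scores: np.ndarray, outcomes: np.ndarray, t: float) -> ContingencyTable:
    low = scores <= t
    return ContingencyTable(
        tp=int(np.sum(low & (outcomes == 1))),
        fn=int(np.sum(~low & (outcomes == 1))),
        tn=int(np.sum(~low & (outcomes == 0))),
        fp=int(np.sum(low & (outcomes == 0))),
    )


@dataclass
class ThresholdResult:
    threshold: float
    j: float
    roc_points: list[tuple[float, float]]  # (FPR, TPR) per candidate threshold
    auc: float


def optimal_threshold(
    scores: ScoreSet | Sequence[float],
    outcomes: Sequence[int],
) -> ThresholdResult:
    """Sweep every distinct score as a candidate threshold; maximize J.

    The low group at threshold t is ``score ≤ t`` (predicted positive).
    Ties in J are broken toward the smallest threshold.  The ROC is traced
    by the same sweep (plus the all-negative point) and the AUC computed by
    the trapezoid rule.
    """
    s = scores.scores if isinstance(scores, ScoreSet) else np.asarray(scores, float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValidationError("scores and outcomes must have equal length")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    cand = np.unique(s)
    best_t, best_j = None, -np.inf
    roc = [(0.0, 0.0)]  # threshold below min: nobody predicted positive
    for t in cand:
        tab = _table_at(s, y, float(t))
        j = youden_j(tab)
        roc.append((tab.fp / n_neg, tab.tp / n_pos))
        if j > best_j:
            best_t, best_j = float(t), j
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ThresholdResult(best_t, float(best_j), roc, auc)


@dataclass
class StratificationResult:
    """Dichotomized-cohort revision statistics at one threshold."""

    threshold: float
    table: ContingencyTable
    j: float
    incidence_low: float | None       # % revised among low-score group
    incidence_high: float | None      # % revised among high-score group
    percent_risk_increase: float | None          # from 1-decimal incidences
    percent_risk_increase_unrounded: float | None
    g_statistic: float | None = None
    p_value: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def summary(self) -> str:
        def pct(x):
            return "undefined" if x is None else f"{x:.1f}%"

        t = self.table
        lines = [
            f"Score threshold: {self.threshold:.2f} (Youden J = {self.j:.2f})",
            f"  low group  (score <= t): {t.tp + t.fp:3d} subjects, "
            f"{t.tp} revised -> incidence {pct(self.incidence_low)}",
            f"  high group (score  > t): {t.fn + t.tn:3d} subjects, "
            f"{t.fn} revised -> incidence {pct(self.incidence_high)}",
        ]
        if self.percent_risk_increase is not None:
            lines.append(
                f"  risk increase low vs high: {self.percent_risk_increase:.0f}%"
                f" (unrounded {self.percent_risk_increase_unrounded:.0f}%)")
        else:
            lines.append("  risk increase low vs high: undefined (zero-incidence group)")
        if self.g_statistic is not None:
            lines.append(
                f"  likelihood-ratio chi-square: G = {self.g_statistic:.2f}, "
                f"p = {self.p_value:.3g}")
        if self.auc is not None:
            lines.append(f"  ROC AUC: {self.auc:.2f}")
        return "\n".join(lines)

    def to_yaml(self, path: str | Path) -> Path:
        t = self.table
        d = {
            "threshold": self.threshold, "youden_j": self.j,
            "table": {"TP": t.tp, "FN": t.fn, "TN": t.tn, "FP": t.fp},
            "incidence_low_pct": self.incidence_low,
            "incidence_high_pct": self.incidence_high,
            "percent_risk_increase": self.percent_risk_increase,
            "percent_risk_increase_unrounded": self.percent_risk_increase_unrounded,
            "g_statistic": self.g_statistic, "p_value": self.p_value,
            "auc": self.auc,
        }
        Path(path).write_text(yaml.safe_dump(d))
        return Path(path)


def stratify(
    scores: ScoreSet | Sequence[float],
    outcomes: Sequence[int],
    threshold: float,
) -> tuple[ContingencyTable, StratificationResult]:
    """Assign groups at a threshold and compute revision incidences.

    Incidences are percentages; the percent risk increase is computed from
    incidences first rounded to one decimal (with the raw-count value also
    reported).  A zero-incidence or empty comparison group leaves the
    increase undefined (None), never infinite.
    """
    s = scores.scores if isinstance(scores, ScoreSet) else np.asarray(scores, float)
    y = np.asarray(outcomes, dtype=int)
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    tab = _table_at(s, y, threshold)
    n_low = tab.tp + tab.fp
    n_high = tab.fn + tab.tn
    inc_low = 100.0 * tab.tp / n_low if n_low else None
    inc_high = 100.0 * tab.fn / n_high if n_high else None
    if inc_low is not None and inc_high not in (None, 0.0):
        rounded = (round(inc_low, 1) / round(inc_high, 1) - 1.0) * 100.0
        raw = (inc_low / inc_high - 1.0) * 100.0
    else:
        rounded = raw = None
    j = youden_j(tab) if (tab.tp + tab.fn) and (tab.tn + tab.fp) else np.nan
    res = StratificationResult(
        threshold=float(threshold), table=tab, j=float(j),
        incidence_low=inc_low, incidence_high=inc_high,
        percent_risk_increase=rounded, percent_risk_increase_unrounded=raw,
    )
    return tab, res


def lr_chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Likelihood-ratio chi-square on the 2×2 table.

    G = 2·Σ O·ln(O/E) over the four cells, expected counts from the
    margins, with 0·ln(0/E) ≡ 0; p from chi-square with 1 df.
    """
    obs = table.as_array()
    if table.total == 0:
        raise ValidationError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("zero margin: test undefined")
    exp = row @ col / table.total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = float(2.0 * terms.sum())
    g = max(g, 0.0)
    return g, float(chi2.sf(g, df=1))


class RevisionStratification:
    """Dichotomize a scored cohort and relate groups to revision incidence.

    Parameters
    ----------
    loads : sequence of float
        Estimated failure loads (N) — or pass ``scores`` directly.
    outcomes : sequence of {0, 1}
        Revision within follow-up (1) or not (0).
    """

    def __init__(
        self,
        loads: Sequence[float] | None,
        outcomes: Sequence[int],
        scores: Sequence[float] | None = None,
    ) -> None:
        if scores is not None:
            s = np.asarray(scores, dtype=float)
            if np.any(s < 0) or np.any(s > 1):
                raise ValidationError("scores must lie in [0, 1]")
            self.score_set = ScoreSet(s.copy(), s, float(s.min()), float(s.max()))
        elif loads is not None:
            self.score_set = score_failure_loads(loads)
        else:
            raise ValidationError("provide loads or scores")
        self.outcomes = np.asarray(outcomes, dtype=int)
        if self.outcomes.shape != self.score_set.scores.shape:
            raise ValidationError("outcomes and loads/scores must align")

    def fit(self, threshold: float | None = None) -> StratificationResult:
        """Find (or apply) the threshold and compute all group statistics."""
        thr = optimal_threshold(self.score_set, self.outcomes)
        t = thr.threshold if threshold is None else float(threshold)
        tab, res = stratify(self.score_set, self.outcomes, t)
        res.roc_points = thr.roc_points
        res.auc = thr.auc
        if threshold is not None:  # J at the applied, not optimal, threshold
            res.j = youden_j(tab)
        res.g_statistic, res.p_value = lr_chi_square(tab)
        return res

    def plot(self, result: StratificationResult, path: str | Path) -> Path:
        """Youden-J sweep and ROC side by side, written to ``path``."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cand = np.unique(self.score_set.scores)
        js = [youden_j(_table_at(self.score_set.scores, self.outcomes, float(t)))
              for t in cand]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(cand, js, "-o", ms=3)
        ax1.axvline(result.threshold, ls="--", c="grey")
        ax1.set_xlabel("score threshold")
        ax1.set_ylabel("Youden J")
        pts = sorted(result.roc_points)
        ax2.plot([p[0] for p in pts], [p[1] for p in pts], "-o", ms=3)
        ax2.plot([0, 1], [0, 1], ":", c="grey")
        ax2.set_xlabel("false positive rate")
        ax2.set_ylabel("true positive rate")
        ax2.set_title(f"AUC = {result.auc:.2f}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
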