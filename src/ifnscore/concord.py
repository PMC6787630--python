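"""Cross-platform agreement of IFN scores (qPCR vs. in-silico RNA-seq).

Scores from two platforms measured on the same subjects are binned into
ordered categories (e.g. low / intermediate / high signature) with shared
thresholds, cross-tabulated, and tested for association with a Pearson χ²
contingency test (no continuity correction, matching the convention of
common r×c implementations; Yates correction available for 2×2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


class ScoreSummary(NamedTuple):
    mean: float
    sd: float
    cv: float


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p: float


def score_summary(scores: pd.Series | Sequence[float]) -> ScoreSummary:
    """Mean, sample SD (n−1) and CV of a platform's score distribution."""
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValidationError("need at least 2 scores")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ScoreSummary(mean=mean, sd=sd, cv=sd / mean if mean != 0 else float("nan"))


def category_labels(breaks: Sequence[float]) -> list[str]:
    """Human-readable ordered labels for k breaks → k+1 half-open bins."""
    breaks = list(breaks)
    if not breaks:
        return ["all"]
    labels = [f"<{breaks[0]:g}"]
    labels += [f"[{lo:g},{hi:g})" for lo, hi in zip(breaks[:-1], breaks[1:])]
    labels.append(f">={breaks[-1]:g}")
    return labels


def categorize_scores(
    scores: pd.Series, breaks: Sequence[float]
) -> pd.Series:
    """Bin scores into k+1 ordered categories at ascending thresholds.

    Bins are left-closed half-open: a score exactly at a break falls in the
    upper category; the first bin is unbounded below, the last above.
    Empty ``breaks`` put everything in a single category.
    """
    breaks = [float(b) for b in breaks]
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValidationError(f"breaks must be strictly ascending, got {breaks}")
    labels = category_labels(breaks)
    codes = np.searchsorted(np.asarray(breaks), np.asarray(scores, dtype=float), side="right")
    cat = pd.Categorical.from_codes(codes, categories=labels, ordered=True)
    return pd.Series(cat, index=scores.index, name=getattr(scores, "name", None))


def chi2_contingency(table: np.ndarray | pd.DataFrame, yates: bool = False) -> Chi2Result:
    """Pearson χ² test of independence on an r×c table of joint counts.

    χ² = Σ (O−E)²/E with expected counts from the margins; df = (r−1)(c−1).
    ``yates`` applies the continuity correction (2×2 tables only).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero row/column margin")
    if yates and arr.shape != (2, 2):
        raise ValidationError("Yates correction applies to 2x2 tables only")
    res = stats.chi2_contingency(arr, correction=yates)
    return Chi2Result(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


@dataclass(frozen=True)
class ConcordanceResult:
    """Joint categorization of two platforms' scores plus the χ² test."""

    breaks: tuple[float, ...]
    contingency: pd.DataFrame  # categories of a (rows) × categories of b (cols)
    chi2: float
    df: int
    p: float
    summary_a: ScoreSummary
    summary_b: ScoreSummary
    n_shared: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "breaks": list(self.breaks),
            "platform_a": self.contingency.index.name,
            "platform_b": self.contingency.columns.name,
            "contingency": {
                "rows": list(self.contingency.index),
                "cols": list(self.contingency.columns),
                "counts": self.contingency.to_numpy().tolist(),
            },
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "summary_a": self.summary_a._asdict(),
            "summary_b": self.summary_b._asdict(),
            "n_shared": self.n_shared,
            "n_dropped": self.n_dropped,
        }


def compare_platforms(
    a: pd.Series,
    b: pd.Series,
    breaks: Sequence[float],
    yates: bool = False,
) -> ConcordanceResult:
    """Compare two platforms' scores on shared subjects.

    Subjects are matched by id (those on one platform only are dropped with
    a logged count), both series are categorized with the same breaks, the
    joint counts are cross-tabulated, and categories empty on both margins
    are removed before the χ² test.
    """
    shared = a.index.intersection(b.index)
    n_dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if n_dropped:
        logger.info("dropped %d subject(s) present on one platform only", n_dropped)
    if len(shared) < 5:
        raise ValidationError(f"need >= 5 shared subjects, got {len(shared)}")
    a, b = a.loc[shared].astype(float), b.loc[shared].astype(float)
    cat_a = categorize_scores(a, breaks)
    cat_b = categorize_scores(b, breaks)
    labels = category_labels(breaks)
    joint = pd.crosstab(cat_a, cat_b, dropna=False).reindex(
        index=labels, columns=labels, fill_value=0
    )
    joint.index.name = a.name or "platform_a"
    joint.columns.name = b.name or "platform_b"
    # drop categories unused by both platforms; they carry no information
    keep = (joint.sum(axis=1) + joint.sum(axis=0)) > 0
    trimmed = joint.loc[keep, keep]
    test = chi2_contingency(trimmed, yates=yates)
    return ConcordanceResult(
        breaks=tuple(float(x) for x in breaks),
        contingency=trimmed,
        chi2=test.chi2,
        df=test.df,
        p=test.p,
        summary_a=score_summary(a),
        summary_b=score_summary(b),
        n_shared=int(len(shared)),
        n_dropped=int(n_dropped),
    )
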