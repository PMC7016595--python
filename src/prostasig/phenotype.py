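"""Phenotype stratification and group statistics on metagene scores.

Samples are split by the quartiles of one metagene's standardised score row:
the lowest quartile (score <= Q1) is the "low" phenotype — for the luminal
metagene this is the LumE-low group associated with aggressive disease — the
top quartile (> Q3) is "high", and everything between is "intermed".  The
binary labelling collapses this to low vs non-low.  AUC is computed as the
rank (Mann-Whitney) statistic with ties counted 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

LOW, INTERMED, HIGH = "low", "intermed", "high"
BINARY_LOW, BINARY_NONLOW = "LumE_low", "non_LumE_low"


@dataclass
class StratificationResult:
    tertiary: pd.Series  # sample -> {low, intermed, high}
    binary: pd.Series  # sample -> {LumE_low, non_LumE_low}
    cutpoints: tuple[float, float]  # (Q1, Q3)

    def to_frame(self, scores: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"tertiary": self.tertiary, "binary": self.binary})
        if scores is not None:
            out["score"] = scores.reindex(out.index)
        out.index.name = "sample"
        return out


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_value: float
    p_value: float
    n_a: int
    n_b: int


def quartile_stratify(scores: pd.Series) -> StratificationResult:
    """Quartile-based three-group and binary labelling of one score row.

    Q1 and Q3 are empirical quantiles with linear interpolation; a sample is
    "low" iff its score <= Q1 and "high" iff > Q3.  Ties at the cutpoints can
    make group sizes deviate from n/4, n/2, n/4.
    """
    if len(scores) < 4:
        raise ValueError(f"need >=4 samples to form quartiles, got {len(scores)}")
    x = scores.to_numpy(dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    if q1 == q3:
        logger.warning("degenerate score distribution: Q1 == Q3 == %g", q1)
    tertiary = pd.Series(
        np.where(x <= q1, LOW, np.where(x > q3, HIGH, INTERMED)),
        index=scores.index,
        name="tertiary",
    )
    binary = tertiary.map(lambda g: BINARY_LOW if g == LOW else BINARY_NONLOW)
    binary.name = "binary"
    return StratificationResult(tertiary=tertiary, binary=binary, cutpoints=(float(q1), float(q3)))


def auc_rank(scores, positives) -> float:
    """Rank AUC: P(score_pos > score_neg) with ties counted 0.5.

    Computed via the Mann-Whitney rank-sum identity
    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(s, method="average")
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_groups(
    scores: pd.Series,
    labels: pd.Series,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Welch two-sample t-test on scores between two labelled groups."""
    labels = labels.reindex(scores.index)
    a = scores[labels == group_a].to_numpy(dtype=float)
    b = scores[labels == group_b].to_numpy(dtype=float)
    for name, grp in ((group_a, a), (group_b, b)):
        if grp.size == 0:
            raise ValueError(f"group {name!r} absent from labels")
        if grp.size < 2:
            raise ValueError(f"group {name!r} has <2 samples")
    diff = a.mean() - b.mean()
    if np.allclose(a.var(ddof=1), 0) and np.allclose(b.var(ddof=1), 0) and diff != 0:
        # variance floor keeps the statistic finite for constant groups
        floor = 1e-8
        t = diff / np.sqrt(floor / a.size + floor / b.size)
        p = 0.0 + np.finfo(float).tiny
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        if np.isnan(t):  # both groups constant and equal
            t, p = 0.0, 1.0
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_value=float(t),
        p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
        n_a=a.size,
        n_b=b.size,
    )


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-set distribution summary: median, SD, min, max, IQR."""
    if scores.shape[1] == 0:
        raise ValueError("empty score matrix")
    q1 = scores.quantile(0.25, axis=1)
    q3 = scores.quantile(0.75, axis=1)
    return pd.DataFrame(
        {
            "median": scores.median(axis=1),
            "sd": scores.std(axis=1, ddof=1),
            "min": scores.min(axis=1),
            "max": scores.max(axis=1),
            "iqr": q3 - q1,
        }
    )
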