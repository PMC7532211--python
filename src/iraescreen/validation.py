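"""Patient-level validation of candidate irAE markers.

Candidate markers quantified per patient (e.g. IHC staining signals) are
compared between irAE and non-irAE groups by an unpaired two-sided t test,
optionally combined across markers by geometric mean, and assessed as
classifiers by ROC/AUC.  The AUC uses the Mann–Whitney rank formulation,
with half-credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: float
    method: str  # "student" | "welch"


@dataclass(frozen=True)
class ROCResult:
    auc: float
    curve: tuple[tuple[float, float], ...]  # (fpr, tpr), (0,0) .. (1,1)
    n_pos: int
    n_neg: int


def combine_markers(
    values: pd.DataFrame,
    markers: Sequence[str],
    offset: float = 0.0,
) -> pd.Series:
    """Per-patient geometric mean across the named marker columns.

    All values must be positive; a zero or negative value raises unless an
    ``offset`` is supplied, which is added to every value first.
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers to combine")
    sub = values[list(markers)].astype(float) + offset
    bad = sub.le(0)
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"nonpositive marker value for patient {sub.index[row]!r}, "
            f"marker {markers[col]!r} (supply a positive offset)"
        )
    return pd.Series(
        np.exp(np.log(sub.to_numpy()).mean(axis=1)),
        index=values.index,
        name="+".join(markers),
    )


def compare_groups(
    cohort: pd.DataFrame,
    marker: str,
    label_col: str = "irae_label",
    method: str = "student",
) -> TTestResult:
    """Unpaired two-sided t test of a marker between irAE and non-irAE groups.

    ``method='student'`` pools variances (default); ``'welch'`` does not.
    The statistic is oriented as (non-irAE mean) - (irAE mean) over the
    pooled standard error, i.e. negative when the marker is higher in the
    irAE group.
    """
    labels = cohort[label_col].astype(bool)
    x0 = cohort.loc[~labels, marker].to_numpy(dtype=float)
    x1 = cohort.loc[labels, marker].to_numpy(dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least two samples")
    equal_var = method == "student"
    if method not in ("student", "welch"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.ttest_ind(x0, x1, equal_var=equal_var)
    df = len(x0) + len(x1) - 2 if equal_var else float(res.df)
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        method=method,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC curve and AUC for a score that should be higher in positives.

    AUC is the Mann–Whitney probability that a random positive outscores a
    random negative, ties counting one half.  The curve steps through the
    unique score values in descending order.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    ranks = stats.rankdata(s)  # mid-ranks handle ties with half credit
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    sorted_s = s[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(~sorted_y)
    # keep one operating point per distinct threshold
    last_of_threshold = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    tpr = tps[last_of_threshold] / n_pos
    fpr = fps[last_of_threshold] / n_neg
    curve = [(0.0, 0.0), *zip(fpr.tolist(), tpr.tolist())]
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return ROCResult(auc=float(auc), curve=tuple(curve), n_pos=n_pos, n_neg=n_neg)


def trapezoidal_area(curve: Sequence[tuple[float, float]]) -> float:
    """Area under an ROC polyline; equals the rank AUC in the absence of ties."""
    fpr = np.array([p[0] for p in curve])
    tpr = np.array([p[1] for p in curve])
    return float(np.trapezoid(tpr, fpr))


def validate_markers(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    label_col: str = "irae_label",
    combine: bool = True,
    combine_offset: float = 0.0,
    method: str = "student",
) -> dict[str, dict]:
    """Group comparison and ROC/AUC per marker, plus the combined marker.

    Returns {marker: {"t", "p", "df", "auc", "n_pos", "n_neg"}} including a
    ``"+"``-joined entry for the geometric-mean combination when
    ``combine`` is set and >= 2 markers are given.
    """
    work = cohort.copy()
    names = list(markers)
    if combine and len(names) >= 2:
        combined = combine_markers(work, names, offset=combine_offset)
        work[combined.name] = combined
        names.append(str(combined.name))
    out: dict[str, dict] = {}
    labels = work[label_col].astype(bool)
    for m in names:
        t = compare_groups(work, m, label_col=label_col, method=method)
        roc = roc_auc(work[m].to_numpy(dtype=float), labels.to_numpy())
        out[m] = {
            "t": t.statistic,
            "p": t.p_value,
            "df": t.df,
            "auc": roc.auc,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
    return out
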