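"""Pan-cancer factor screening against the irAE reporting odds ratio.

Every candidate factor (a per-cancer-type median) is ranked by its Spearman
correlation with the observed ROR vector across cancer types; p-values are
Benjamini–Hochberg adjusted, by feature family by default since the factor
families (mRNA, miRNA, protein, mutation, curated factors) are screened at
vastly different scales.  Top hits can be tested for over-representation in
annotation categories with a hypergeometric test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Largest n for which the exact permutation null of Spearman's rho is used.
EXACT_PERMUTATION_MAX_N = 9


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho on average-ranked data (Pearson of mid-ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _pvalue_t(rho: float, n: int) -> float:
    """Two-sided p from the t transformation with n-2 df."""
    if n < 3:
        return 1.0
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pvalue_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman's rho (all n! rank orders)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    obs = abs(float(rx_c @ (ry - ry.mean())))
    perms = np.array(list(itertools.permutations(ry)))
    vals = np.abs((perms - ry.mean()) @ rx_c)
    return float(np.mean(vals >= obs - 1e-9))


def spearman_pvalue(rho: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value: exact permutation for small n, t-approximation else."""
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        return _pvalue_exact(x, y)
    return _pvalue_t(rho, n)


def bh_adjust(
    p_values: Sequence[float],
    family_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved.

    With ``family_labels``, the adjustment runs independently within each
    family; otherwise jointly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if family_labels is None:
        out[:] = multipletests(p, method="fdr_bh")[1]
    else:
        labels = np.asarray(family_labels)
        if labels.shape != p.shape:
            raise ValueError("family_labels must match p_values in length")
        for fam in np.unique(labels):
            idx = labels == fam
            out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def spearman_screen(
    factors: pd.DataFrame,
    response: pd.Series,
    families: Mapping[str, str] | pd.Series | None = None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Screen every factor column against the response by Spearman correlation.

    ``factors`` is cancer type x factor (per-type medians); ``response`` the
    aligned ROR vector.  Missing values are handled per factor (pairwise
    complete).  Factors with fewer than ``min_pairs`` complete pairs or zero
    rank variance are skipped with a warning.

    Returns a frame with columns ``factor, rho, n_used, p_value, fdr,
    family`` sorted by \\|rho\\| descending, ties broken by factor name.
    """
    response = response.reindex(factors.index)
    fam_of = (lambda f: "factor") if families is None else (
        families.get if isinstance(families, Mapping) else
        (lambda f: families.get(f, "factor"))
    )

    y = response.to_numpy(dtype=float)
    X = factors.to_numpy(dtype=float)
    names = list(factors.columns)

    rows: list[dict] = []
    skipped: list[str] = []

    y_ok = ~np.isnan(y)
    col_ok = ~np.isnan(X)
    complete = col_ok.all(axis=0) if y_ok.all() else np.zeros(len(names), bool)

    # fast path: columns with no missing data, response complete
    if y_ok.all() and complete.any() and len(y) > EXACT_PERMUTATION_MAX_N:
        sub = X[:, complete]
        ry = stats.rankdata(y)
        rX = np.apply_along_axis(stats.rankdata, 0, sub)
        rXc = rX - rX.mean(axis=0)
        ryc = ry - ry.mean()
        denom = np.sqrt((rXc**2).sum(axis=0) * (ryc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = (rXc.T @ ryc) / denom
        n = len(y)
        for j, idx in enumerate(np.flatnonzero(complete)):
            name = names[idx]
            rho = float(rhos[j])
            if not np.isfinite(rho):
                skipped.append(name)
                continue
            rows.append(
                {"factor": name, "rho": rho, "n_used": n,
                 "p_value": _pvalue_t(rho, n), "family": fam_of(name)}
            )
        remaining = np.flatnonzero(~complete)
    else:
        remaining = np.arange(len(names))

    for idx in remaining:
        name = names[idx]
        mask = y_ok & col_ok[:, idx]
        n = int(mask.sum())
        if n < min_pairs:
            skipped.append(name)
            continue
        xv, yv = X[mask, idx], y[mask]
        rho = spearman_rho(xv, yv)
        if not np.isfinite(rho):
            skipped.append(name)
            continue
        rows.append(
            {"factor": name, "rho": rho, "n_used": n,
             "p_value": spearman_pvalue(rho, xv, yv), "family": fam_of(name)}
        )

    if skipped:
        warnings.warn(
            f"{len(skipped)} factor(s) skipped (constant or <{min_pairs} pairs): "
            f"{skipped[:5]}..."
        )
    if not rows:
        return pd.DataFrame(
            columns=["factor", "rho", "n_used", "p_value", "fdr", "family"]
        )
    res = pd.DataFrame(rows)
    res["fdr"] = bh_adjust(res["p_value"].to_numpy(), res["family"].to_numpy())
    res = res.sort_values(
        by=["rho", "factor"],
        key=lambda s: -s.abs() if s.name == "rho" else s,
        ascending=True,
    ).reset_index(drop=True)
    return res[["factor", "rho", "n_used", "p_value", "fdr", "family"]]


# ---------------------------------------------------------------------------
# Over-representation analysis

def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrichment_test(
    query_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set per category.

    For each category the upper-tail probability P(X >= k) of the overlap k
    under sampling n query genes from a universe of N genes containing K
    category members; BH-adjusted across categories.  Query genes outside
    the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(f"query gene(s) outside universe dropped: {sorted(outside)[:5]}")
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for category in sorted(annotation):
        members = set(annotation[category]) & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"category": category, "k": k, "n": n, "K": K, "N": N,
             "p_value": min(p, 1.0)}
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = bh_adjust(res["p_value"].to_numpy())
        res = res.sort_values(["p_value", "category"]).reset_index(drop=True)
    return res
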