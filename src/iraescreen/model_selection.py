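"""Cross-validated selection of few-variable linear models of the irAE ROR.

With ~26 cancer types and thousands of candidate factors, penalized
regression is unreliable; instead all univariate, bivariate and trivariate
ordinary-least-squares models over a short candidate list are enumerated
and scored by the Spearman correlation (Rs) between leave-one-out
cross-validated predictions and the observed ROR.  Goodness of fit of a
richer model over its best nested submodel is assessed by the
log-likelihood-ratio test; multicollinearity among candidates by the
variance inflation factor.  The selected model is the highest-Rs model
whose likelihood-ratio improvement over its best nested submodel is
significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .omics import FactorTable
from .screening import bh_adjust, spearman_pvalue, spearman_rho

#: Floor on the residual-variance MLE, so that numerically perfect fits keep
#: a finite Gaussian log-likelihood.
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit of ROR on a set of per-cancer factor medians."""

    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    log_likelihood: float
    n: int
    residual_variance: float
    rows: tuple[str, ...]  # cancer types used (complete cases)

    def predict(self, factors: pd.DataFrame) -> pd.Series:
        X = factors[list(self.predictors)].to_numpy(dtype=float)
        return pd.Series(
            X @ np.asarray(self.coefficients) + self.intercept, index=factors.index
        )

    def equation(self, ndigits: int = 2) -> str:
        terms = [
            f"{round(c, ndigits)} x {p}"
            for c, p in zip(self.coefficients, self.predictors)
        ]
        sign = "+" if self.intercept >= 0 else "-"
        return " + ".join(terms) + f" {sign} {abs(round(self.intercept, ndigits))}"


@dataclass(frozen=True)
class CVResult:
    predictions: pd.Series
    observed: pd.Series
    rs: float

    @property
    def unexplained_variance(self) -> float:
        return unexplained_variance(self.rs)


@dataclass(frozen=True)
class ComparisonResult:
    nested: ModelFit
    full: ModelFit
    lr_statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class VIFResult:
    factor: str
    vif: float

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.vif)


def unexplained_variance(rs: float) -> float:
    """Fraction of response variation left unexplained: 1 - Rs^2."""
    return 1.0 - rs * rs


def _complete_rows(table: FactorTable, predictors: tuple[str, ...]) -> pd.Index:
    if table.ror is None:
        raise ValueError("FactorTable has no ROR vector joined")
    sub = table.factors[list(predictors)] if predictors else table.factors[[]]
    mask = ~table.ror.isna()
    if predictors:
        mask &= ~sub.isna().any(axis=1)
    return table.factors.index[mask]


def fit_linear(
    table: FactorTable,
    predictors: tuple[str, ...] | list[str],
    rows: pd.Index | None = None,
) -> ModelFit:
    """OLS of the ROR vector on the named factors (with intercept).

    Rows are the complete cases for exactly these predictors unless ``rows``
    is given.  The Gaussian log-likelihood uses the MLE residual variance
    RSS/n, floored at ``SIGMA2_FLOOR``.
    """
    predictors = tuple(predictors)
    if rows is None:
        rows = _complete_rows(table, predictors)
    n = len(rows)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need >= {len(predictors) + 2} complete rows for {predictors}, have {n}"
        )
    X = np.column_stack(
        [np.ones(n)]
        + [table.factors.loc[rows, p].to_numpy(dtype=float) for p in predictors]
    )
    y = table.ror.loc[rows].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for predictors {predictors}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    sigma2 = max(rss / n, SIGMA2_FLOOR)
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return ModelFit(
        predictors=predictors,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        log_likelihood=ll,
        n=n,
        residual_variance=sigma2,
        rows=tuple(rows),
    )


def loocv_evaluate(
    table: FactorTable, predictors: tuple[str, ...] | list[str]
) -> CVResult:
    """Leave-one-out CV: each cancer type predicted by a fit on all others.

    Performance is the Spearman correlation between held-out predictions and
    the observed ROR.
    """
    predictors = tuple(predictors)
    rows = _complete_rows(table, predictors)
    n = len(rows)
    if n < len(predictors) + 3:
        raise ValueError("too few complete rows for leave-one-out evaluation")
    X = np.column_stack(
        [np.ones(n), table.factors.loc[rows, list(predictors)].to_numpy(dtype=float)]
    )
    y = table.ror.loc[rows].to_numpy(dtype=float)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xt = X[train]
        if np.linalg.matrix_rank(Xt) < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient training design when holding out {rows[i]}"
            )
        beta, *_ = np.linalg.lstsq(Xt, y[train], rcond=None)
        preds[i] = X[i] @ beta
    predictions = pd.Series(preds, index=rows)
    observed = table.ror.loc[rows]
    rs = spearman_rho(predictions.to_numpy(), observed.to_numpy())
    return CVResult(predictions=predictions, observed=observed, rs=rs)


def likelihood_ratio_test(nested: ModelFit, full: ModelFit) -> ComparisonResult:
    """Chi-square LRT between nested OLS fits on the identical row set."""
    if not set(nested.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    if nested.rows != full.rows:
        raise ValueError("fits use different row sets; refit on common rows")
    df = len(full.predictors) - len(nested.predictors)
    if set(nested.predictors) == set(full.predictors):
        df = 0
    stat = max(2.0 * (full.log_likelihood - nested.log_likelihood), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return ComparisonResult(nested=nested, full=full, lr_statistic=stat, df=df, p_value=p)


def vif(
    table: FactorTable | pd.DataFrame, factors: list[str] | tuple[str, ...]
) -> list[VIFResult]:
    """Variance inflation factor 1/(1-R^2_j) per factor.

    Each factor is regressed (with intercept) on the remaining factors over
    their joint complete cases.  Perfect collinearity yields an infinite
    VIF, flagged rather than raised.
    """
    df = table.factors if isinstance(table, FactorTable) else table
    factors = list(factors)
    if len(factors) < 2:
        raise ValueError("VIF needs at least two factors")
    sub = df[factors].dropna()
    results = []
    for j, name in enumerate(factors):
        others = [f for f in factors if f != name]
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[o].to_numpy(dtype=float) for o in others]
        )
        y = sub[name].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            results.append(VIFResult(factor=name, vif=math.inf))
            continue
        r2 = 1.0 - rss / tss
        results.append(
            VIFResult(factor=name, vif=math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        )
    return results


@dataclass
class ModelReport:
    """Ranked enumeration of candidate models with the selected one."""

    models: pd.DataFrame
    selected: tuple[str, ...] | None
    lrt_alpha: float

    def to_json_dict(self) -> dict:
        return {
            "lrt_alpha": self.lrt_alpha,
            "selected": list(self.selected) if self.selected else None,
            "models": self.models.assign(
                predictors=self.models["predictors"].map(list)
            ).to_dict(orient="records"),
        }


def _ftest_p(nested: ModelFit, full: ModelFit) -> float:
    """Exact-F p-value for a nested OLS comparison.

    The chi-square reference for 2*dlogLik is anti-conservative at n in the
    twenties; the F version of the same comparison is exact under Gaussian
    errors and is what the stepwise adoption gates use.
    """
    df = len(full.predictors) - len(nested.predictors)
    n = full.n
    df_resid = n - len(full.predictors) - 1
    if df <= 0 or df_resid <= 0:
        return 1.0
    rss_n = nested.residual_variance * n
    rss_f = full.residual_variance * n
    if rss_f <= 0:
        return 0.0
    f = (rss_n - rss_f) / df / (rss_f / df_resid)
    return float(stats.f.sf(max(f, 0.0), df, df_resid))


def _best_nested_submodel(
    preds: tuple[str, ...], scored: dict[tuple[str, ...], dict]
) -> tuple[str, ...]:
    subs = [
        tuple(sorted(c)) for c in itertools.combinations(preds, len(preds) - 1)
    ]
    subs = [s for s in subs if s in scored]
    # highest cross-validated Rs, deterministic tie-break on the name tuple
    return min(subs, key=lambda s: (-scored[s]["rs"], s))


def enumerate_models(
    table: FactorTable,
    candidates: list[str] | tuple[str, ...],
    max_arity: int = 3,
    lrt_alpha: float = 0.05,
) -> ModelReport:
    """Score every model of up to ``max_arity`` candidate factors.

    Each combination is fit by OLS and scored by leave-one-out
    cross-validated Spearman Rs; Rs p-values are BH-adjusted within each
    arity stratum.  A k-variate model (k >= 2) is LRT-compared against its
    highest-Rs nested (k-1)-variate submodel, refit on the k-variate
    model's rows; a univariate model is compared against the intercept-only
    model.

    Selection is forward-stepwise over arity.  The best univariate by Rs is
    adopted when its LRT against the intercept-only model passes.  At the
    bivariate stage every pair is considered, and the highest-Rs pair is
    adopted when it raises Rs and its LRT against its best nested
    univariate passes.  Beyond that, only one-factor extensions of the
    current selection are considered; each extension is LRT-compared to
    the current model and the gate uses the BH-adjusted p-value across the
    extensions tried, so a chance likelihood gain among many candidate
    additions cannot displace a well-supported smaller model.  Search
    stops at the first arity with no admissible model.  Ordering is fully
    deterministic (Rs descending, then predictor-name tuple ascending).
    """
    candidates = sorted(set(candidates))
    if len(candidates) < 2:
        raise ValueError("need at least two candidate factors")
    scored: dict[tuple[str, ...], dict] = {}
    for arity in range(1, max_arity + 1):
        for combo in itertools.combinations(candidates, arity):
            cv = loocv_evaluate(table, combo)
            fit = fit_linear(table, combo)
            p_rs = spearman_pvalue(
                cv.rs, cv.predictions.to_numpy(), cv.observed.to_numpy()
            )
            scored[combo] = {
                "predictors": combo,
                "arity": arity,
                "rs": cv.rs,
                "rs_p": p_rs,
                "unexplained_variance": cv.unexplained_variance,
                "coefficients": fit.coefficients,
                "intercept": fit.intercept,
                "n": fit.n,
            }

    for combo, rec in scored.items():
        full = fit_linear(table, combo)
        if rec["arity"] == 1:
            nested_preds: tuple[str, ...] = ()
        else:
            nested_preds = _best_nested_submodel(combo, scored)
        nested = fit_linear(table, nested_preds, rows=pd.Index(full.rows))
        comp = likelihood_ratio_test(nested, full)
        rec["lrt_vs"] = nested_preds
        rec["lrt_statistic"] = comp.lr_statistic
        rec["lrt_p"] = comp.p_value
        rec["gate_p"] = _ftest_p(nested, full)

    models = pd.DataFrame(sorted(scored.values(), key=lambda r: (-r["rs"], r["predictors"])))
    models["rs_fdr"] = np.nan
    models["lrt_fdr"] = np.nan
    for arity in models["arity"].unique():
        idx = models.index[models["arity"] == arity]
        models.loc[idx, "rs_fdr"] = bh_adjust(models.loc[idx, "rs_p"].to_numpy())
        models.loc[idx, "lrt_fdr"] = bh_adjust(models.loc[idx, "lrt_p"].to_numpy())

    selected: tuple[str, ...] | None = None
    current_rs = -np.inf
    for arity in (1, 2):
        if arity > max_arity:
            break
        stratum = models[models["arity"] == arity]
        admissible = stratum[
            (stratum["gate_p"] < lrt_alpha) & (stratum["rs"] > current_rs)
        ]
        if len(admissible):
            best = admissible.iloc[0]  # highest rs, deterministic tie-break
            selected = tuple(best["predictors"])
            current_rs = best["rs"]
        elif selected is not None:
            break
    while selected is not None and len(selected) < max_arity:
        current = fit_linear(table, selected)
        ext_rows = []
        for extra in candidates:
            if extra in selected:
                continue
            combo = tuple(sorted((*selected, extra)))
            full = fit_linear(table, combo)
            nested = fit_linear(table, selected, rows=pd.Index(full.rows))
            ext_rows.append((combo, scored[combo]["rs"], _ftest_p(nested, full)))
        if not ext_rows:
            break
        ext_fdr = bh_adjust([p for *_, p in ext_rows])
        admissible_ext = sorted(
            (
                (rs, combo)
                for (combo, rs, _), q in zip(ext_rows, ext_fdr)
                if q < lrt_alpha and rs > current_rs
            ),
            key=lambda t: (-t[0], t[1]),
        )
        if not admissible_ext:
            break
        current_rs, selected = admissible_ext[0]
    return ModelReport(models=models, selected=selected, lrt_alpha=lrt_alpha)
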