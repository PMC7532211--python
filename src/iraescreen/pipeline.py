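"""End-to-end wiring: reports -> ROR -> factor medians -> screen -> select -> validate.

This is the discovery strategy in one call: estimate per-cancer irAE
reporting odds ratios from safety reports, derive per-sample omics scores
and collapse them to per-cancer medians, screen all factors against the
ROR vector by Spearman correlation with FDR control, enumerate bi/
trivariate OLS models over the top screened factors, and validate markers
in a patient-level cohort by t test and ROC/AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model_selection, omics, screening, validation
from .omics import FactorTable
from .pharmacovigilance import RORResult, default_irae_terms, ror_by_cancer_type, parse_reports
from .simulate import SimulatedOmics, SimulationConfig, gen_cohort, gen_omics, gen_reports
from .model_selection import ModelReport


def per_sample_factors(sim: SimulatedOmics) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the sample x factor frame: genes, TMB, cytolytic activity, curated."""
    expr_factors = sim.expression.T
    tmb = omics.compute_tmb(sim.mutations, roster=list(sim.expression.columns))
    cyt = omics.cytolytic_activity(sim.expression)
    per_sample = pd.concat(
        [expr_factors, tmb.rename("TMB"), cyt.rename("cytolytic_activity"),
         sim.curated_factors],
        axis=1,
    )
    return per_sample, sim.sample_types


def factor_families(per_sample: pd.DataFrame, sim: SimulatedOmics) -> dict[str, str]:
    genes = set(sim.expression.index)
    curated = set(sim.curated_factors.columns)
    fams = {}
    for f in per_sample.columns:
        if f in genes:
            fams[f] = "mRNA"
        elif f in curated or f in ("TMB", "cytolytic_activity"):
            fams[f] = "curated-factor"
        else:
            fams[f] = "factor"
    return fams


@dataclass
class PipelineResult:
    ror_results: list[RORResult]
    factor_table: FactorTable
    screen: pd.DataFrame
    model_report: ModelReport
    validation: dict[str, dict]

    def report_dict(self) -> dict:
        return {
            "ror": [r.as_dict() for r in self.ror_results],
            "screen_top": self.screen.head(20).to_dict(orient="records"),
            "models": self.model_report.to_json_dict(),
            "validation": self.validation,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(
    config: SimulationConfig,
    n_top: int = 10,
    max_arity: int = 3,
    lrt_alpha: float = 0.05,
    joint_fdr: bool = False,
    response_scale: str = "log",
) -> PipelineResult:
    """Run the full discovery-and-validation pipeline on simulated inputs.

    Up to ``n_top`` significantly screened factors become the
    model-selection candidates, as in a screen-then-combine strategy.
    Linear models are fit to log-ROR by default (odds ratios live on a
    multiplicative scale; their intervals are log-normal); pass
    ``response_scale='natural'`` to model the ROR directly.  The rank-based
    screen is unaffected by this monotone choice.
    """
    if response_scale not in ("log", "natural"):
        raise ValueError(f"unknown response_scale {response_scale!r}")
    report_df, _ = gen_reports(config)
    reports = _reports_from_frame(report_df)
    ror_results = ror_by_cancer_type(reports, default_irae_terms())
    ror = pd.Series({r.cancer_type: r.ror for r in ror_results}).sort_index()

    sim, _ = gen_omics(config)
    per_sample, sample_types = per_sample_factors(sim)
    response = np.log(ror) if response_scale == "log" else ror
    table = omics.aggregate_medians(per_sample, sample_types).with_ror(response)

    fams = factor_families(per_sample, sim)
    screen = screening.spearman_screen(
        table.factors, table.ror, families=None if joint_fdr else fams
    )
    # combine only significantly correlated factors (the FDR gate keeps
    # chance correlates from the >2,000-feature screen out of the model
    # search); the two strongest marginal correlates always enter so a
    # bivariate model exists even when fewer than two clear the gate
    significant = list(screen.loc[screen["fdr"] < 0.05, "factor"].head(n_top))
    candidates = sorted(set(significant) | set(screen["factor"].head(2)))
    model_report = model_selection.enumerate_models(
        table, candidates, max_arity=max_arity, lrt_alpha=lrt_alpha
    )

    cohort, _ = gen_cohort(config)
    markers = [m for m, _ in config.cohort.effects if m != "CD8"]
    val = validation.validate_markers(cohort, markers)
    return PipelineResult(
        ror_results=ror_results,
        factor_table=table,
        screen=screen,
        model_report=model_report,
        validation=val,
    )


def _reports_from_frame(df: pd.DataFrame):
    """Round-trip a long-format frame through the canonical parser."""
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return parse_reports(buf, sep="\t")
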