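"""Synthetic pharmacovigilance, omics and cohort data with planted truth.

Every pipeline input can be generated at desk scale with known ground
truth: safety reports drawn so that each cancer type has a chosen true
reporting odds ratio; expression/mutation/curated-factor tables in which a
small set of planted features follows the latent log-ROR of each cancer
type while thousands of null features do not; and a patient-level cohort
whose markers separate irAE from non-irAE patients by a chosen
standardized effect size d (analytic AUC Phi(d/sqrt(2))).

Planted features are tied to ln(ROR), the scale on which the pipeline
regresses by default; rank-based screening is invariant to that monotone
choice either way.  ``linear_link`` plants effects on the ROR scale
directly for exact OLS-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pharmacovigilance import (
    DEFAULT_IRAE_TERMS,
    DEFAULT_WINDOW,
    STUDY_DRUGS,
)

#: Per-cancer-type study-report counts: moderately heavy-tailed (lung and
#: melanoma dominate) with a floor of a few hundred reports per type so
#: every stratum yields a usable ROR estimate.  Totals ~18.8k reports
#: across 26 types.
DEFAULT_STUDY_COUNTS: dict[str, int] = {
    "LUAD": 2400, "SKCM": 2200, "LUSC": 1600, "KIRC": 1300, "BLCA": 1100,
    "HNSC": 1000, "BRCA": 850, "COAD": 850, "STAD": 700, "LIHC": 600,
    "PRAD": 500, "ESCA": 480, "OV": 480, "PAAD": 450, "UCEC": 450,
    "CESC": 420, "MESO": 400, "SARC": 400, "GBM": 400, "READ": 380,
    "THCA": 350, "CHOL": 330, "LGG": 320, "UVM": 300, "ACC": 280, "UCS": 260,
}

#: True per-type reporting odds ratios, spanning the plausible range from
#: strongly-reporting lung adenocarcinoma down to sub-unity rare types.
DEFAULT_PLANTED_ROR: dict[str, float] = {
    "LUAD": 3.3, "SKCM": 3.0, "LUSC": 2.8, "KIRC": 2.6, "PRAD": 2.4,
    "BLCA": 2.2, "MESO": 2.1, "BRCA": 2.0, "CESC": 1.9, "UCEC": 1.8,
    "SARC": 1.7, "ESCA": 1.6, "PAAD": 1.5, "OV": 1.45, "HNSC": 1.4,
    "STAD": 1.3, "THCA": 1.25, "CHOL": 1.2, "ACC": 1.1, "READ": 1.05,
    "COAD": 1.0, "LIHC": 0.95, "LGG": 0.9, "GBM": 0.85, "UVM": 0.75,
    "UCS": 0.65,
}

_NON_IRAE_TERMS = (
    "headache", "dizziness", "back pain", "insomnia", "constipation",
    "cough", "anaemia", "oedema peripheral", "injection site reaction",
    "decreased appetite", "pyrexia", "asthenia",
)

_OTHER_DRUGS = (
    "metformin", "atorvastatin", "omeprazole", "lisinopril", "carboplatin",
    "paclitaxel", "docetaxel", "gemcitabine", "aspirin", "levothyroxine",
)

_IRAE_TERMS = tuple(t for t, _ in DEFAULT_IRAE_TERMS)


@dataclass(frozen=True)
class PlantedFeature:
    """An omics feature linearly tied to the latent per-type log-ROR.

    Per-sample values are Normal(intercept + slope * L_t, noise_sd^2),
    truncated at zero for expression-like features.  ``noise_sd=None``
    derives the noise from the configured joint planted R^2.
    """

    name: str
    slope: float = 1.0
    intercept: float = 8.0
    noise_sd: float | None = None


@dataclass(frozen=True)
class OmicsConfig:
    n_null_features: int = 2000
    samples_per_type: int = 50
    planted: tuple[PlantedFeature, ...] = (
        PlantedFeature("LCP1"), PlantedFeature("ADPGK"),
    )
    #: Joint fraction of latent variance the planted set should explain at
    #: the per-type-median level; sets noise_sd when unset.
    planted_r2: float = 0.85
    #: Variance of the zero-sum latent contrasts splitting L across planted
    #: features, as a fraction of Var(L).  Small but nonzero: each planted
    #: feature is a strong marginal correlate, yet no single one carries
    #: the whole signal.
    component_contrast_share: float = 0.03
    #: Cytolytic-activity markers, moderately tied to the latent log-ROR.
    marker_genes: tuple[PlantedFeature, ...] = (
        PlantedFeature("GZMA", slope=0.35, intercept=6.0, noise_sd=3.0),
        PlantedFeature("PRF1", slope=0.35, intercept=6.0, noise_sd=3.0),
    )
    correlated_block_size: int = 5
    correlated_block_r: float = 0.9
    null_mean: float = 5.0
    null_sd: float = 1.0
    #: Per-sample nonsilent mutation counts are overdispersed Poisson:
    #: Poisson(base_rate * exp(mutation_slope * L_t + lognormal noise)).
    mutation_base_rate: float = 30.0
    mutation_slope: float = 0.08
    mutation_overdispersion_sd: float = 1.0
    silent_rate_ratio: float = 0.33
    curated: tuple[PlantedFeature, ...] = (
        PlantedFeature("TCR_diversity", slope=0.6, intercept=10.0, noise_sd=6.0),
        PlantedFeature("CD8_T_cells", slope=0.02, intercept=0.20, noise_sd=0.20),
        PlantedFeature("neoantigen_load", slope=8.0, intercept=60.0, noise_sd=100.0),
        PlantedFeature("eosinophils", slope=0.0, intercept=0.05, noise_sd=0.03),
        PlantedFeature("neutrophils", slope=0.0, intercept=0.30, noise_sd=0.10),
    )
    linear_link: bool = False


@dataclass(frozen=True)
class CohortConfig:
    n_irae: int = 14
    n_no_irae: int = 14
    #: Standardized mean shift d per marker on the log-signal scale; the
    #: analytic AUC is Phi(d / sqrt(2)).
    effects: tuple[tuple[str, float], ...] = (
        ("LCP1", 1.1), ("ADPGK", 1.1), ("CD8", 0.3),
    )
    log_mean: float = 4.0
    n_lung: int = 26  # of n_irae + n_no_irae patients


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    cancer_types: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STUDY_COUNTS)
    )
    comparator_size: int = 30_000
    baseline_irae_prob: float = 0.10
    planted_ror: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_ROR)
    )
    n_excluded_decoys: int = 30
    omics: OmicsConfig = field(default_factory=OmicsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not (0 < self.baseline_irae_prob < 1):
            raise ValueError("baseline_irae_prob must be in (0,1)")
        if set(self.planted_ror) != set(self.cancer_types):
            raise ValueError("planted_ror must cover exactly the cancer types")
        for ct, ror in self.planted_ror.items():
            if ror <= 0:
                raise ValueError(f"planted ROR for {ct} must be positive")
        for ct, n in self.cancer_types.items():
            if n <= 0:
                raise ValueError(f"study count for {ct} must be positive")
        r = self.omics.correlated_block_r
        if not (-1 < r < 1):
            raise ValueError("correlated_block_r must be in (-1, 1)")

    def study_irae_prob(self, cancer_type: str) -> float:
        """p1 solving odds(p1)/odds(p0) = planted ROR for the type."""
        p0 = self.baseline_irae_prob
        odds = self.planted_ror[cancer_type] * p0 / (1 - p0)
        return odds / (1 + odds)

    def latent(self, cancer_type: str) -> float:
        """Latent per-type signal: ln(ROR), or ROR under linear_link."""
        ror = self.planted_ror[cancer_type]
        return ror if self.omics.linear_link else math.log(ror)

    def expected_ror_noise_var(self) -> float:
        """Expected sampling variance of the log-ROR estimate, averaged
        over cancer types (Wald variance at the expected cell counts).

        Zero under ``linear_link``, where the latent is the ROR itself and
        no reporting stage is emulated.
        """
        if self.omics.linear_link:
            return 0.0
        p0 = self.baseline_irae_prob
        n_comp = self.comparator_size
        comp_var = 1.0 / (n_comp * p0) + 1.0 / (n_comp * (1 - p0))
        total = 0.0
        for ct, n in self.cancer_types.items():
            p1 = self.study_irae_prob(ct)
            total += 1.0 / (n * p1) + 1.0 / (n * (1 - p1)) + comp_var
        return total / len(self.cancer_types)


@dataclass
class GroundTruth:
    """Generator bookkeeping: what the pipeline should recover."""

    true_ror: dict[str, float] = field(default_factory=dict)
    contingency: dict[str, dict[str, int]] = field(default_factory=dict)
    expected_excluded: dict[str, str] = field(default_factory=dict)
    planted_features: dict[str, dict[str, float]] = field(default_factory=dict)
    per_sample_tmb: dict[str, int] = field(default_factory=dict)
    cohort_auc: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Safety reports

def _reactions(rng: np.random.Generator, is_irae: bool) -> list[str]:
    if is_irae:
        terms = [str(rng.choice(_IRAE_TERMS))]
        if rng.random() < 0.3:
            terms.append(str(rng.choice(_NON_IRAE_TERMS)))
    else:
        terms = [
            str(t)
            for t in rng.choice(
                _NON_IRAE_TERMS, size=1 + (rng.random() < 0.4), replace=False
            )
        ]
    return terms


def _random_date(rng: np.random.Generator, start: datetime.date, end: datetime.date):
    span = (end - start).days
    return start + datetime.timedelta(days=int(rng.integers(0, span + 1)))


def gen_reports(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a long-format safety-report table plus exact bookkeeping.

    Study reports carry a suspect anti-PD-1/PD-L1 drug and an irAE term
    with the per-type probability implied by the planted ROR; comparator
    reports carry other suspect drugs at the baseline probability.  A small
    set of decoy reports exercises every exclusion branch (anti-CTLA-4
    co-treatment, out-of-window dates, concomitant-only study drugs); those
    that remain in the database at filter time are counted into the
    comparator cells of the ground-truth contingency tables.
    """
    rng = _rngs(config.seed, 4)[0]
    start, end = DEFAULT_WINDOW
    study_drugs = sorted(STUDY_DRUGS)
    truth = GroundTruth(true_ror=dict(config.planted_ror))
    rows: list[dict] = []
    a = {ct: 0 for ct in config.cancer_types}
    b = {ct: 0 for ct in config.cancer_types}
    c = d = 0

    def emit(rid, date, indication, drugs, reactions):
        for i in range(max(len(drugs), len(reactions))):
            name, role = drugs[i] if i < len(drugs) else ("", "")
            rows.append(
                {
                    "report_id": rid,
                    "receipt_date": date.isoformat(),
                    "indication": indication,
                    "drug_name": name,
                    "drug_role": role,
                    "reaction": reactions[i] if i < len(reactions) else "",
                }
            )

    serial = 0
    for ct in sorted(config.cancer_types):
        p1 = config.study_irae_prob(ct)
        for _ in range(config.cancer_types[ct]):
            serial += 1
            rid = f"S{serial:06d}"
            is_irae = rng.random() < p1
            drugs = [(str(rng.choice(study_drugs)), "suspect")]
            if rng.random() < 0.3:
                drugs.append((str(rng.choice(_OTHER_DRUGS)), "concomitant"))
            emit(rid, _random_date(rng, start, end), ct, drugs, _reactions(rng, is_irae))
            if is_irae:
                a[ct] += 1
            else:
                b[ct] += 1

    types = sorted(config.cancer_types)
    p0 = config.baseline_irae_prob
    for k in range(config.comparator_size):
        rid = f"C{k + 1:06d}"
        is_irae = rng.random() < p0
        drugs = [(str(rng.choice(_OTHER_DRUGS)), "suspect")]
        emit(rid, _random_date(rng, start, end), str(rng.choice(types)),
             drugs, _reactions(rng, is_irae))
        if is_irae:
            c += 1
        else:
            d += 1

    # decoys exercising each exclusion branch
    decoy_kinds = ("ctla4", "out_of_window", "concomitant_only")
    for k in range(config.n_excluded_decoys):
        kind = decoy_kinds[k % len(decoy_kinds)]
        rid = f"X{k + 1:06d}"
        ct = str(rng.choice(types))
        is_irae = rng.random() < p0
        rx = _reactions(rng, is_irae)
        if kind == "ctla4":
            drugs = [(str(rng.choice(study_drugs)), "suspect"),
                     ("ipilimumab", "concomitant")]
            date = _random_date(rng, start, end)
            c += is_irae
            d += not is_irae
        elif kind == "out_of_window":
            drugs = [(str(rng.choice(study_drugs)), "suspect")]
            date = start - datetime.timedelta(days=int(rng.integers(1, 400)))
        else:  # concomitant-only study drug; another drug is suspect
            drugs = [(str(rng.choice(_OTHER_DRUGS)), "suspect"),
                     (str(rng.choice(study_drugs)), "concomitant")]
            date = _random_date(rng, start, end)
            c += is_irae
            d += not is_irae
        truth.expected_excluded[rid] = kind
        emit(rid, date, ct, drugs, rx)

    truth.contingency = {
        ct: {"a": a[ct], "b": b[ct], "c": c, "d": d} for ct in types
    }
    df = pd.DataFrame(
        rows,
        columns=["report_id", "receipt_date", "indication",
                 "drug_name", "drug_role", "reaction"],
    )
    return df, truth


# ---------------------------------------------------------------------------
# Omics

@dataclass
class SimulatedOmics:
    expression: pd.DataFrame  # gene x sample, TPM-like
    sample_types: pd.Series  # sample id -> cancer type
    mutations: pd.DataFrame  # MAF-like
    curated_factors: pd.DataFrame  # sample x factor


def _latent_var(config: SimulationConfig) -> float:
    return float(np.var([config.latent(ct) for ct in config.cancer_types]))


def _planted_noise_sd(
    feature: PlantedFeature, config: SimulationConfig
) -> float:
    """Noise sd realising the configured joint planted R^2 at median level.

    The target R^2 is stated against the *observed* response the pipeline
    regresses on — the estimated log-ROR, whose per-type Wald sampling
    variance is part of the unexplained share.  For k planted features
    whose latent components sum to L, the joint residual of the summed
    predictor is k*s^2 + v (per-feature slope-relative median noise s^2
    plus the expected estimation variance v), and the explained fraction
    of Var(L) + v must equal the target.  The per-sample sd follows from
    the asymptotic sd of the median, 1.2533 * sigma / sqrt(n).
    """
    if feature.noise_sd is not None:
        return feature.noise_sd
    var_l = _latent_var(config)
    r2 = config.omics.planted_r2
    k = len(config.omics.planted)
    v = config.expected_ror_noise_var()
    allowed = (1 - r2) * (var_l + v) - v
    if allowed <= 0:
        raise ValueError(
            "planted_r2 unattainable: ROR estimation noise alone exceeds the "
            "unexplained budget; increase report counts or lower planted_r2"
        )
    s2 = abs(feature.slope) ** 2 * allowed / k
    n = config.omics.samples_per_type
    return math.sqrt(s2) * math.sqrt(n) / 1.2533


def _planted_components(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-type latent components, one row per planted feature, summing to L.

    With k >= 2 planted features the latent L_t is split as L_t/k plus
    zero-sum orthogonal contrasts, so no single feature carries the whole
    signal and the planted set is jointly — not individually — optimal.
    The contrast variance is ``component_contrast_share`` of Var(L).
    """
    types = sorted(config.cancer_types)
    L = np.array([config.latent(ct) for ct in types])
    k = len(config.omics.planted)
    if k == 0:
        return np.empty((0, len(types)))
    if k == 1:
        return L[None, :]
    var_l = _latent_var(config)
    share = config.omics.component_contrast_share
    w = rng.normal(0.0, math.sqrt(var_l * share * k / (k - 1)), (k, len(types)))
    contrasts = w - w.mean(axis=0, keepdims=True)
    return L / k + contrasts


def gen_omics(config: SimulationConfig) -> tuple[SimulatedOmics, GroundTruth]:
    """Expression, mutation and curated-factor tables with planted signal.

    Planted genes and curated factors follow the latent log-ROR per type;
    null genes are i.i.d. across types; an equicorrelated feature block
    (shared latent per sample) exercises multicollinearity diagnostics; and
    nonsilent mutation counts are Poisson with a type-level mean tied to
    the latent, planting a TMB effect.
    """
    rng = _rngs(config.seed, 4)[1]
    oc = config.omics
    types = sorted(config.cancer_types)
    n_per = oc.samples_per_type
    samples = [f"{ct}-{i + 1:03d}" for ct in types for i in range(n_per)]
    sample_types = pd.Series(
        [ct for ct in types for _ in range(n_per)], index=samples, name="cancer_type"
    )
    latent = np.repeat([config.latent(ct) for ct in types], n_per)
    n_samples = len(samples)
    truth = GroundTruth(true_ror=dict(config.planted_ror))

    gene_rows: dict[str, np.ndarray] = {}
    components = _planted_components(config, rng)
    for feat, comp in zip(oc.planted, components):
        sd = _planted_noise_sd(feat, config)
        comp_per_sample = np.repeat(comp, n_per)
        vals = feat.intercept + feat.slope * comp_per_sample + rng.normal(0, sd, n_samples)
        gene_rows[feat.name] = np.clip(vals, 0, None)
        truth.planted_features[feat.name] = {
            "slope": feat.slope, "intercept": feat.intercept, "noise_sd": sd,
        }
    for feat in oc.marker_genes:
        sd = _planted_noise_sd(feat, config)
        vals = feat.intercept + feat.slope * latent + rng.normal(0, sd, n_samples)
        gene_rows[feat.name] = np.clip(vals, 0, None)
        truth.planted_features[feat.name] = {
            "slope": feat.slope, "intercept": feat.intercept, "noise_sd": sd,
        }
    if oc.correlated_block_size:
        # shared latent drawn per cancer type so the block's pairwise
        # correlation r survives per-type median aggregation
        shared = np.repeat(rng.normal(0, 1, len(types)), n_per)
        r = oc.correlated_block_r
        for j in range(oc.correlated_block_size):
            vals = (
                oc.null_mean
                + math.sqrt(abs(r)) * shared
                + math.sqrt(1 - abs(r)) * rng.normal(0, 1, n_samples)
            )
            gene_rows[f"CORR{j + 1:02d}"] = np.clip(vals, 0, None)
    null_block = np.clip(
        rng.normal(oc.null_mean, oc.null_sd, (oc.n_null_features, n_samples)), 0, None
    )
    blocks = [null_block]
    if gene_rows:
        blocks.insert(0, np.array(list(gene_rows.values())))
    expr = pd.DataFrame(
        np.vstack(blocks),
        index=[*gene_rows, *(f"GENE{j + 1:05d}" for j in range(oc.n_null_features))],
        columns=samples,
    )

    lam = oc.mutation_base_rate * np.exp(
        oc.mutation_slope * latent
        + rng.normal(0, oc.mutation_overdispersion_sd, n_samples)
    )
    nonsilent = rng.poisson(lam)
    silent = rng.poisson(lam * oc.silent_rate_ratio)
    truth.per_sample_tmb = dict(zip(samples, map(int, nonsilent)))
    nonsilent_classes = np.array(
        ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]
    )
    gene_pool = expr.index.to_numpy()
    mut_rows = {
        "Tumor_Sample_Barcode": np.repeat(samples, nonsilent + silent),
        "Hugo_Symbol": rng.choice(gene_pool, size=int((nonsilent + silent).sum())),
        "Variant_Classification": np.concatenate(
            [
                np.r_[rng.choice(nonsilent_classes, size=ns), np.repeat("Silent", s)]
                for ns, s in zip(nonsilent, silent)
            ]
        ),
    }
    mutations = pd.DataFrame(mut_rows)

    curated = {}
    for feat in oc.curated:
        vals = feat.intercept + feat.slope * latent + rng.normal(
            0, feat.noise_sd, n_samples
        )
        curated[feat.name] = np.clip(vals, 0, None)
        truth.planted_features[feat.name] = {
            "slope": feat.slope, "intercept": feat.intercept,
            "noise_sd": float(feat.noise_sd),
        }
    curated_factors = pd.DataFrame(curated, index=samples)
    return (
        SimulatedOmics(
            expression=expr,
            sample_types=sample_types,
            mutations=mutations,
            curated_factors=curated_factors,
        ),
        truth,
    )


# ---------------------------------------------------------------------------
# Patient cohort

def gen_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Patient-level marker table with planted per-marker effect sizes.

    Markers are log-normal: log-signals are Normal(mu, 1) in non-irAE and
    Normal(mu + d, 1) in irAE patients, so the analytic AUC Phi(d/sqrt(2))
    survives the exponentiation.  irAE patients carry pneumonitis labels and
    the cohort is predominantly lung cancer, mirroring a small IHC cohort.
    """
    cc = config.cohort
    if min(cc.n_irae, cc.n_no_irae) < 2:
        raise ValueError("need at least two patients per group")
    rng = _rngs(config.seed, 4)[2]
    n = cc.n_irae + cc.n_no_irae
    labels = np.r_[np.ones(cc.n_irae, bool), np.zeros(cc.n_no_irae, bool)]
    truth = GroundTruth()
    cols: dict[str, np.ndarray] = {}
    for marker, d in cc.effects:
        z = rng.normal(0, 1, n) + d * labels
        cols[marker] = np.exp(cc.log_mean + z)
        truth.cohort_auc[marker] = float(stats.norm.cdf(d / math.sqrt(2)))
    groups = np.array(["lung"] * n)
    other_idx = rng.choice(n, size=max(n - cc.n_lung, 0), replace=False)
    groups[other_idx] = "other"
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            **cols,
            "irae_label": labels.astype(int),
            "irae_category": np.where(labels, "pneumonitis", ""),
            "cancer_group": groups,
            "age": rng.integers(37, 83, n),
            "sex": rng.choice(["male", "female"], size=n, p=[0.786, 0.214]),
        }
    ).set_index("patient_id")
    return cohort, truth


# ---------------------------------------------------------------------------
# Bundled emission

def simulate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Write every pipeline input file plus ground_truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports, t_rep = gen_reports(config)
    omics, t_om = gen_omics(config)
    cohort, t_coh = gen_cohort(config)
    reports.to_csv(outdir / "reports.tsv", sep="\t", index=False)
    expr = omics.expression.copy()
    expr.index.name = "gene"
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    annot = omics.sample_types.rename_axis("sample_id").reset_index()
    annot.to_csv(outdir / "annot.tsv", sep="\t", index=False)
    omics.mutations.to_csv(outdir / "mutations.maf.tsv", sep="\t", index=False)
    cur = omics.curated_factors.copy()
    cur.index.name = "sample_id"
    cur.to_csv(outdir / "curated_factors.tsv", sep="\t")
    cohort.to_csv(outdir / "cohort.tsv", sep="\t")
    truth = GroundTruth(
        true_ror=t_rep.true_ror,
        contingency=t_rep.contingency,
        expected_excluded=t_rep.expected_excluded,
        planted_features=t_om.planted_features,
        per_sample_tmb=t_om.per_sample_tmb,
        cohort_auc=t_coh.cohort_auc,
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth
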