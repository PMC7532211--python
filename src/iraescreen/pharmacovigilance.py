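"""Individual safety-report handling and reporting-odds-ratio (ROR) estimation.

A spontaneous pharmacovigilance report carries one cancer indication, a list
of drugs (each flagged suspect or concomitant) and a list of adverse-event
(AE) preferred terms.  Reports naming an anti-PD-1/PD-L1 agent as suspect —
and no anti-CTLA-4 agent in any role — form the study stratum; every other
in-window report is the comparator.  A report is an irAE report when at
least one of its AE terms appears in a curated immune-related AE term list.
Disproportionality per cancer type is summarised by the reporting odds
ratio ROR = (a/b)/(c/d) with a Wald confidence interval on the log scale.
"""

from __future__ import annotations

import datetime
import json
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

ROLE_SUSPECT = "suspect"
ROLE_CONCOMITANT = "concomitant"
_ALLOWED_ROLES = frozenset({ROLE_SUSPECT, ROLE_CONCOMITANT})

#: Anti-PD-1 and anti-PD-L1 monoclonal antibodies defining the study stratum.
STUDY_DRUGS = frozenset(
    {"nivolumab", "pembrolizumab", "cemiplimab",
     "atezolizumab", "avelumab", "durvalumab"}
)
#: Anti-CTLA-4 agents; any co-mention (any role) excludes the report.
EXCLUSION_DRUGS = frozenset({"ipilimumab", "tremelimumab"})

#: Default reporting window (inclusive endpoints).
DEFAULT_WINDOW = (datetime.date(2014, 7, 1), datetime.date(2019, 6, 30))

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lower-case and collapse internal whitespace of an AE preferred term."""
    return _WS.sub(" ", term.strip()).lower()


class SchemaError(ValueError):
    """A mandatory column could not be resolved in a report table."""


class RecordError(ValueError):
    """A report-level inconsistency (conflicting fields, bad date, overlap)."""


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous AE report (one patient record)."""

    report_id: str
    receipt_date: datetime.date
    indication: str
    drugs: tuple[tuple[str, str], ...]  # (normalized drug name, role)
    reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: drugs must be non-empty")
        for name, role in self.drugs:
            if role not in _ALLOWED_ROLES:
                raise ValueError(
                    f"report {self.report_id}: invalid drug role {role!r}"
                )

    def drug_names(self, role: str | None = None) -> set[str]:
        return {n for n, r in self.drugs if role is None or r == role}


@dataclass(frozen=True)
class IrAETermSet:
    """Curated irAE preferred terms with their clinical category.

    Matching is case-insensitive after whitespace normalization; every term
    maps to exactly one category.
    """

    category_of: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IrAETermSet":
        mapping: dict[str, str] = {}
        for term, category in pairs:
            key = normalize_term(term)
            if key in mapping and mapping[key] != category:
                raise ValueError(f"term {term!r} mapped to two categories")
            mapping[key] = category
        return cls(category_of=mapping)

    @classmethod
    def from_tsv(cls, path) -> "IrAETermSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns)
        if len(cols) < 2:
            raise SchemaError("term file needs two columns: term, category")
        return cls.from_pairs(zip(df[cols[0]], df[cols[1]]))

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.category_of)

    def __len__(self) -> int:
        return len(self.category_of)


#: Compact irAE term list drawn from clinical irAE management practice,
#: keyed by organ-system category.  Extend or replace via IrAETermSet.
DEFAULT_IRAE_TERMS: tuple[tuple[str, str], ...] = (
    ("pneumonitis", "pneumonitis"),
    ("interstitial lung disease", "pneumonitis"),
    ("organising pneumonia", "pneumonitis"),
    ("colitis", "colitis"),
    ("autoimmune colitis", "colitis"),
    ("enterocolitis", "colitis"),
    ("diarrhoea haemorrhagic", "colitis"),
    ("hepatitis", "hepatitis"),
    ("autoimmune hepatitis", "hepatitis"),
    ("hepatitis fulminant", "hepatitis"),
    ("hypothyroidism", "thyroid"),
    ("hyperthyroidism", "thyroid"),
    ("thyroiditis", "thyroid"),
    ("autoimmune thyroiditis", "thyroid"),
    ("hypophysitis", "hypophysitis"),
    ("adrenal insufficiency", "adrenal"),
    ("myocarditis", "myocarditis"),
    ("autoimmune myocarditis", "myocarditis"),
    ("nephritis", "nephritis"),
    ("tubulointerstitial nephritis", "nephritis"),
    ("rash maculo-papular", "skin"),
    ("dermatitis bullous", "skin"),
    ("vitiligo", "skin"),
    ("pruritus", "skin"),
    ("uveitis", "ocular"),
    ("myositis", "musculoskeletal"),
    ("polymyalgia rheumatica", "musculoskeletal"),
    ("arthritis", "musculoskeletal"),
    ("myasthenia gravis", "neurologic"),
    ("guillain-barre syndrome", "neurologic"),
    ("encephalitis", "neurologic"),
    ("type 1 diabetes mellitus", "endocrine"),
    ("diabetic ketoacidosis", "endocrine"),
    ("pancreatitis", "pancreatitis"),
)


def default_irae_terms() -> IrAETermSet:
    """The packaged irAE term list as an :class:`IrAETermSet`."""
    return IrAETermSet.from_pairs(DEFAULT_IRAE_TERMS)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 disproportionality counts for one stratum.

    a/b: study-drug reports with / without an irAE term;
    c/d: comparator reports with / without an irAE term.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    def as_dict(self) -> dict[str, int]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


@dataclass(frozen=True)
class RORResult:
    cancer_type: str
    ror: float
    ci_low: float
    ci_high: float
    counts: ContingencyTable
    correction_applied: bool
    alpha: float = 0.05

    def as_dict(self) -> dict:
        d = {
            "cancer_type": self.cancer_type,
            "ror": self.ror,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "correction_applied": self.correction_applied,
            "alpha": self.alpha,
        }
        d.update(self.counts.as_dict())
        return d


# ---------------------------------------------------------------------------
# Parsing

#: Canonical long-format column names.
CANONICAL_COLUMNS = (
    "report_id", "receipt_date", "indication", "drug_name", "drug_role", "reaction",
)


def parse_reports(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SafetyReport]:
    """Read a long-format delimited report table into ``SafetyReport`` records.

    One input row carries one (drug, reaction) mention; all rows sharing a
    ``report_id`` are merged into a single report.  ``schema`` maps canonical
    column names (``report_id``, ``receipt_date``, ``indication``,
    ``drug_name``, ``drug_role``, ``reaction``) to the file's actual headers.
    Dates must be ISO-8601.  Conflicting indications or dates within one
    report id raise :class:`RecordError`.
    """
    schema = dict(schema or {})
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [c for canon, c in colmap.items() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    if df.empty:
        return []

    rid_col = colmap["report_id"]
    grouped = df.groupby(rid_col, sort=False)
    for field in ("indication", "receipt_date"):
        n_distinct = grouped[colmap[field]].nunique()
        bad = n_distinct.index[n_distinct > 1]
        if len(bad):
            raise RecordError(
                f"report {bad[0]}: conflicting {field} values "
                f"{sorted(set(df.loc[df[rid_col] == bad[0], colmap[field]]))}"
            )
    head = grouped[[colmap["receipt_date"], colmap["indication"]]].first()

    dates: dict[str, datetime.date] = {}
    for rid, raw in zip(head.index, head[colmap["receipt_date"]]):
        try:
            dates[rid] = datetime.date.fromisoformat(raw)
        except ValueError as exc:
            raise RecordError(f"report {rid}: unparseable date {raw!r}") from exc

    drug_rows = df.loc[df[colmap["drug_name"]] != "",
                       [rid_col, colmap["drug_name"], colmap["drug_role"]]]
    drugs_of: dict[str, dict[tuple[str, str], None]] = {}
    for rid, name, role in drug_rows.itertuples(index=False):
        name, role = name.strip().lower(), role.strip().lower()
        if role not in _ALLOWED_ROLES:
            raise RecordError(f"report {rid}: invalid drug role {role!r}")
        drugs_of.setdefault(rid, {})[(name, role)] = None

    rx_rows = df.loc[df[colmap["reaction"]] != "", [rid_col, colmap["reaction"]]]
    reactions_of: dict[str, dict[str, None]] = {}
    for rid, rx in rx_rows.itertuples(index=False):
        reactions_of.setdefault(rid, {})[rx.strip()] = None

    return [
        SafetyReport(
            report_id=str(rid),
            receipt_date=dates[rid],
            indication=indication,
            drugs=tuple(drugs_of.get(rid, {})),
            reactions=tuple(reactions_of.get(rid, {})),
        )
        for rid, indication in zip(head.index, head[colmap["indication"]])
    ]


def reports_to_frame(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Inverse of :func:`parse_reports`: long-format frame, one row per mention."""
    rows = []
    for r in reports:
        reactions = r.reactions or ("",)
        n = max(len(r.drugs), len(reactions))
        for i in range(n):
            drug, role = r.drugs[i] if i < len(r.drugs) else ("", "")
            rows.append(
                {
                    "report_id": r.report_id,
                    "receipt_date": r.receipt_date.isoformat(),
                    "indication": r.indication,
                    "drug_name": drug,
                    "drug_role": role,
                    "reaction": reactions[i] if i < len(reactions) else "",
                }
            )
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# Filtering and classification

def _in_window(report: SafetyReport, window) -> bool:
    start, end = window
    return start <= report.receipt_date <= end


def _passes_drug_filter(report, study_drugs, exclusion_drugs) -> bool:
    if report.drug_names() & exclusion_drugs:
        return False
    return bool(report.drug_names(ROLE_SUSPECT) & study_drugs)


def filter_reports(
    reports: Sequence[SafetyReport],
    window=DEFAULT_WINDOW,
    study_drugs: frozenset[str] | set[str] = STUDY_DRUGS,
    exclusion_drugs: frozenset[str] | set[str] = EXCLUSION_DRUGS,
) -> list[SafetyReport]:
    """Study-stratum filter: in-window, >=1 suspect study drug, no excluded drug."""
    study_drugs = frozenset(study_drugs)
    exclusion_drugs = frozenset(exclusion_drugs)
    return [
        r
        for r in reports
        if _in_window(r, window) and _passes_drug_filter(r, study_drugs, exclusion_drugs)
    ]


def split_study_comparator(
    reports: Sequence[SafetyReport],
    window=DEFAULT_WINDOW,
    study_drugs=STUDY_DRUGS,
    exclusion_drugs=EXCLUSION_DRUGS,
) -> tuple[list[SafetyReport], list[SafetyReport]]:
    """Partition in-window reports into (study, comparator).

    The comparator is the rest of the database: every in-window report that
    does not pass the study-drug filter, regardless of indication.
    """
    study_drugs = frozenset(study_drugs)
    exclusion_drugs = frozenset(exclusion_drugs)
    study, comparator = [], []
    for r in reports:
        if not _in_window(r, window):
            continue
        (study if _passes_drug_filter(r, study_drugs, exclusion_drugs) else comparator).append(r)
    return study, comparator


def classify_irae(
    report: SafetyReport, term_set: IrAETermSet
) -> tuple[bool, set[str]]:
    """Return (is irAE report, matched categories) for one report."""
    if not len(term_set):
        raise ValueError("term_set must be non-empty")
    matched = {
        term_set.category_of[t]
        for t in map(normalize_term, report.reactions)
        if t in term_set.category_of
    }
    return bool(matched), matched


def build_contingency(
    study_reports: Sequence[SafetyReport],
    comparator_reports: Sequence[SafetyReport],
    term_set: IrAETermSet,
) -> dict[str, ContingencyTable]:
    """Per-cancer-type 2x2 tables against a shared full-database comparator.

    a/b are counted within each indication's study reports; c/d over ALL
    comparator reports.  A report counts once in `a` no matter how many irAE
    terms it lists.  Study and comparator ids must be disjoint.
    """
    overlap = {r.report_id for r in study_reports} & {
        r.report_id for r in comparator_reports
    }
    if overlap:
        raise RecordError(
            f"study/comparator overlap on report ids: {sorted(overlap)[:10]}"
        )
    c = sum(classify_irae(r, term_set)[0] for r in comparator_reports)
    d = len(comparator_reports) - c
    tables: dict[str, ContingencyTable] = {}
    by_type: dict[str, list[SafetyReport]] = {}
    for r in study_reports:
        by_type.setdefault(r.indication, []).append(r)
    for cancer_type in sorted(by_type):
        grp = by_type[cancer_type]
        a = sum(classify_irae(r, term_set)[0] for r in grp)
        tables[cancer_type] = ContingencyTable(a=a, b=len(grp) - a, c=c, d=d)
    return tables


# ---------------------------------------------------------------------------
# ROR

def compute_ror(
    table: ContingencyTable,
    cancer_type: str = "",
    alpha: float = 0.05,
    zero_cell_correction: bool = True,
) -> RORResult:
    """ROR = (a*d)/(b*c) with a Wald CI on the log-odds-ratio scale.

    With any zero cell and ``zero_cell_correction``, 0.5 is added to all four
    cells (Haldane–Anscombe) before both the point estimate and the CI.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("both strata must contain at least one report")
    corrected = False
    if min(a, b, c, d) == 0:
        if not zero_cell_correction:
            raise ZeroDivisionError(
                "zero cell with correction disabled: ROR undefined"
            )
        corrected = True
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_ror = math.log(ror)
    return RORResult(
        cancer_type=cancer_type,
        ror=ror,
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        counts=table,
        correction_applied=corrected,
        alpha=alpha,
    )


def ror_by_cancer_type(
    reports: Sequence[SafetyReport],
    term_set: IrAETermSet,
    window=DEFAULT_WINDOW,
    study_drugs=STUDY_DRUGS,
    exclusion_drugs=EXCLUSION_DRUGS,
    alpha: float = 0.05,
    zero_cell_correction: bool = True,
) -> list[RORResult]:
    """Full disproportionality pipeline: filter, stratify, estimate per type."""
    study, comparator = split_study_comparator(
        reports, window=window, study_drugs=study_drugs, exclusion_drugs=exclusion_drugs
    )
    tables = build_contingency(study, comparator, term_set)
    return [
        compute_ror(tbl, cancer_type=ct, alpha=alpha, zero_cell_correction=zero_cell_correction)
        for ct, tbl in tables.items()
    ]


def ror_results_to_frame(results: Sequence[RORResult]) -> pd.DataFrame:
    cols = ["cancer_type", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
            "correction_applied"]
    return pd.DataFrame([r.as_dict() for r in results])[cols]


def write_ror_results(results: Sequence[RORResult], prefix: str) -> None:
    """Write ``<prefix>.json`` (full records) and ``<prefix>.tsv`` (summary)."""
    with open(f"{prefix}.json", "w") as fh:
        json.dump([r.as_dict() for r in results], fh, indent=2)
        fh.write("\n")
    ror_results_to_frame(results).to_csv(f"{prefix}.tsv", sep="\t", index=False)
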