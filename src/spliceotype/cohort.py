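"""Hotspot-resolved clinical cohort statistics.

Covers the registry side of the analysis: how SF3B1 variants partition
across WHO 2016 diagnosis classes (with pairwise Fisher exact tests),
the WHO ring-sideroblast criteria, co-mutation landscapes with
Benjamini-Hochberg correction, rank-based clinical comparisons, and
Kaplan-Meier / log-rank survival.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

DIAGNOSES = ("MDS-RS", "MDS-SLD/MLD", "MDS-EB", "AML")

UNKNOWN = None


@dataclass
class CaseRecord:
    """One patient: diagnosis, SF3B1 variant, co-mutations, labs, survival."""

    case_id: str
    diagnosis: str
    sf3b1_variant: str
    sf3b1_exon: int | None = None
    comutations: list[tuple[str, float]] = field(default_factory=list)
    rs_percent: float | None = None
    blast_percent: float | None = None
    platelets: float | None = None
    hemoglobin: float | None = None
    anc: float | None = None
    ipss_r: float | None = None
    panel_genes: frozenset[str] = frozenset()
    os_time: float = 0.0
    os_event: bool = False
    lfs_time: float = 0.0
    lfs_event: bool = False

    def __post_init__(self) -> None:
        if self.os_time < 0 or self.lfs_time < 0:
            raise ValueError(f"{self.case_id}: survival times must be >= 0")
        for gene, vaf in self.comutations:
            if not 0 <= vaf <= 1:
                raise ValueError(f"{self.case_id}: VAF of {gene} outside [0, 1]")
        if self.rs_percent is not None and not 0 <= self.rs_percent <= 100:
            raise ValueError(f"{self.case_id}: rs_percent outside [0, 100]")
        self.panel_genes = frozenset(self.panel_genes)

    def mutated_genes(self) -> set[str]:
        return {g for g, _ in self.comutations}


# ---------------------------------------------------------------------------
# Percent formatting (1 decimal, 2 decimals below 0.1%)

def format_percent(numerator: int, denominator: int) -> tuple[float, str]:
    """Round half-up to 1 decimal, or 2 decimals below 0.1%."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    raw = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal("0.01") if 0 < raw < Decimal("0.1") else Decimal("0.1")
    rounded = raw.quantize(quantum, rounding=ROUND_HALF_UP)
    return float(rounded), f"{rounded}%"


# ---------------------------------------------------------------------------
# Fisher exact

@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float  # sample ad/bc; conditional MLE if any cell is 0
    odds_ratio_haldane: float  # 0.5-continuity-corrected
    degenerate: bool = False


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one. A
    zero margin makes the test degenerate: p = 1.0 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    (a, b), (c, d) = t
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return FisherResult(1.0, math.nan, haldane, degenerate=True)
    if min(a, b, c, d) == 0:
        odds = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(float(p), odds, haldane)


# ---------------------------------------------------------------------------
# Variant x diagnosis partitioning

@dataclass
class PartitionTest:
    variant: str
    diagnosis_a: str
    diagnosis_b: str
    table: list[list[int]]
    p_value: float
    odds_ratio: float


@dataclass
class PartitionResult:
    counts: pd.DataFrame  # variant x diagnosis
    totals: pd.Series  # per-diagnosis totals
    percent: pd.DataFrame  # rounded percentage of the diagnosis column
    percent_text: pd.DataFrame
    tests: list[PartitionTest]


def partition_distribution(
    cases: Sequence[CaseRecord],
    variants_of_interest: Sequence[str],
    diagnoses: Sequence[str] = DIAGNOSES,
) -> PartitionResult:
    """How each variant distributes over diagnosis classes.

    Percentages are variant count / diagnosis total, rounded half-up to
    one decimal (two below 0.1%). Each (variant, diagnosis pair) gets a
    two-sided Fisher exact test of variant-vs-all-other-variants against
    diagnosis A vs B.
    """
    counts = pd.DataFrame(0, index=list(variants_of_interest), columns=list(diagnoses))
    totals = pd.Series(0, index=list(diagnoses))
    for case in cases:
        if case.diagnosis not in totals.index:
            continue
        totals[case.diagnosis] += 1
        if case.sf3b1_variant in counts.index:
            counts.loc[case.sf3b1_variant, case.diagnosis] += 1
    percent = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    percent_text = pd.DataFrame("", index=counts.index, columns=counts.columns)
    for v in counts.index:
        for dgn in counts.columns:
            if totals[dgn] == 0:
                percent_text.loc[v, dgn] = "undefined"
                continue
            val, txt = format_percent(int(counts.loc[v, dgn]), int(totals[dgn]))
            percent.loc[v, dgn] = val
            percent_text.loc[v, dgn] = txt
    tests: list[PartitionTest] = []
    for v in counts.index:
        for i, da in enumerate(diagnoses):
            for db in diagnoses[i + 1 :]:
                if totals[da] == 0 or totals[db] == 0:
                    continue
                na, nb = int(counts.loc[v, da]), int(counts.loc[v, db])
                table = [
                    [na, int(totals[da]) - na],
                    [nb, int(totals[db]) - nb],
                ]
                res = fisher_exact_two_sided(table)
                tests.append(PartitionTest(v, da, db, table, res.p_value, res.odds_ratio))
    return PartitionResult(counts, totals, percent, percent_text, tests)


# ---------------------------------------------------------------------------
# Co-mutation landscape

def _stars(p: float) -> str:
    for cut, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return mark
    return "ns"


def comutation_landscape(
    cases: Sequence[CaseRecord],
    min_panel: Iterable[str],
    predicate_a: Callable[[CaseRecord], bool],
    predicate_b: Callable[[CaseRecord], bool],
    genes: Sequence[str] | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-gene mutation frequencies in two cohorts with exact tests.

    Only cases whose sequencing panel covers the whole ``min_panel`` are
    analyzed; within those, a case enters a gene's denominator only if
    that gene is on its panel. Raw Fisher p-values carry figure-style
    star tiers; Benjamini-Hochberg q-values are reported alongside.
    """
    min_panel = frozenset(min_panel)
    eligible = [c for c in cases if min_panel <= c.panel_genes]
    cohort_a = [c for c in eligible if predicate_a(c)]
    cohort_b = [c for c in eligible if predicate_b(c)]
    if not cohort_a or not cohort_b:
        which = labels[0] if not cohort_a else labels[1]
        raise ValueError(
            f"cohort {which!r} is empty after requiring the {len(min_panel)}-gene panel"
        )
    genes = sorted(min_panel) if genes is None else list(genes)
    la, lb = labels
    rows = []
    for gene in genes:
        ga = [c for c in cohort_a if gene in c.panel_genes]
        gb = [c for c in cohort_b if gene in c.panel_genes]
        ma = sum(1 for c in ga if gene in c.mutated_genes())
        mb = sum(1 for c in gb if gene in c.mutated_genes())
        if ga and gb:
            res = fisher_exact_two_sided(
                [[ma, len(ga) - ma], [mb, len(gb) - mb]]
            )
            p, odds = res.p_value, res.odds_ratio
        else:
            p, odds = math.nan, math.nan
        rows.append(
            {
                "gene": gene,
                f"n_{la}": len(ga),
                f"mut_{la}": ma,
                f"freq_{la}": format_percent(ma, len(ga))[0] if ga else math.nan,
                f"n_{lb}": len(gb),
                f"mut_{lb}": mb,
                f"freq_{lb}": format_percent(mb, len(gb))[0] if gb else math.nan,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    tested = out["p_value"].notna()
    out["q_value"] = math.nan
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    out["stars"] = [
        _stars(p) if not math.isnan(p) else "" for p in out["p_value"]
    ]
    return out


def oncoprint_matrix(
    cases: Sequence[CaseRecord], genes: Sequence[str]
) -> pd.DataFrame:
    """Genes x cases presence matrix (NaN when the gene was not sequenced)."""
    data = {}
    for c in cases:
        col = []
        for g in genes:
            if g not in c.panel_genes:
                col.append(math.nan)
            else:
                col.append(1.0 if g in c.mutated_genes() else 0.0)
        data[c.case_id] = col
    return pd.DataFrame(data, index=list(genes))


# ---------------------------------------------------------------------------
# Ring-sideroblast criteria and summaries

@dataclass
class RsEligibility:
    """WHO 2016 MDS-RS eligibility flags (None when RS% is unknown)."""

    mutated_pathway: bool | None  # SF3B1-mutated and RS > 5%
    unmutated_pathway: bool | None  # RS > 15% regardless of genotype


def apply_rs_criterion(case: CaseRecord) -> RsEligibility:
    if case.rs_percent is None:
        return RsEligibility(None, None)
    sf3b1_mutated = case.sf3b1_variant not in ("", "WT", "wt", None)
    return RsEligibility(
        mutated_pathway=sf3b1_mutated and case.rs_percent > 5,
        unmutated_pathway=case.rs_percent > 15,
    )


@dataclass
class RsSummary:
    mean: float | None
    n: int
    defined: bool


def summarize_rs(
    cases: Sequence[CaseRecord], predicate: Callable[[CaseRecord], bool]
) -> RsSummary:
    """Mean ring-sideroblast percentage among matching cases with known RS."""
    values = [c.rs_percent for c in cases if predicate(c) and c.rs_percent is not None]
    if not values:
        return RsSummary(None, 0, False)
    return RsSummary(float(np.mean(values)), len(values), True)


# ---------------------------------------------------------------------------
# Clinical parameter comparison

@dataclass
class ClinicalComparison:
    field: str
    n_a: int
    n_b: int
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    p_value: float
    degenerate: bool = False


def compare_clinical(
    cases: Sequence[CaseRecord],
    predicate_a: Callable[[CaseRecord], bool],
    predicate_b: Callable[[CaseRecord], bool],
    field: str,
) -> ClinicalComparison:
    """Two-sided Mann-Whitney rank comparison of one clinical field.

    Exact null distribution for small untied samples, normal
    approximation with tie correction otherwise. Groups where every
    value ties are degenerate (p = 1.0).
    """
    a = [getattr(c, field) for c in cases if predicate_a(c)]
    b = [getattr(c, field) for c in cases if predicate_b(c)]
    a = [v for v in a if v is not None and not (isinstance(v, float) and math.isnan(v))]
    b = [v for v in b if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 known values of {field!r} per group")

    def med_iqr(v):
        return float(np.median(v)), (
            float(np.percentile(v, 25)),
            float(np.percentile(v, 75)),
        )

    ma, qa = med_iqr(a)
    mb, qb = med_iqr(b)
    if len(set(a) | set(b)) == 1:
        return ClinicalComparison(field, len(a), len(b), ma, qa, mb, qb, 1.0, True)
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ClinicalComparison(field, len(a), len(b), ma, qa, mb, qb, float(p))


# ---------------------------------------------------------------------------
# Survival

@dataclass
class SurvivalCurve:
    """Product-limit estimate with its risk table.

    ``median`` follows the convention: smallest observed time at which
    survival is <= 0.5, or None when the curve never reaches it.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    timeline = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(timeline).to_numpy(dtype=float)
    keep = timeline > 0 if 0 not in times else np.ones_like(timeline, dtype=bool)
    timeline, surv = timeline[keep], surv[keep]
    at_risk = table["at_risk"].to_numpy(dtype=float)[keep]
    below = timeline[surv <= 0.5]
    median = float(below.min()) if below.size else None
    return SurvivalCurve(timeline, surv, at_risk, median)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """One-degree-of-freedom log-rank (Mantel-Cox) test."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea = np.asarray(events_a, bool)
    eb = np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return LogrankResult(math.nan, math.nan, degenerate=True)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Cohort table I/O

_COLUMNS = [
    "case_id",
    "diagnosis",
    "sf3b1_variant",
    "sf3b1_exon",
    "comutations",
    "rs_percent",
    "blast_percent",
    "platelets",
    "hemoglobin",
    "anc",
    "ipss_r",
    "panel_genes",
    "os_time",
    "os_event",
    "lfs_time",
    "lfs_event",
]


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return "NA" if math.isnan(v) else repr(v)
    return str(v)


def write_cohort_table(
    cases: Sequence[CaseRecord], path: str | os.PathLike, header: str | None = None
) -> None:
    """Write the cohort TSV (column dictionary in ``docs/methods.md``)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for c in cases:
            comut = ";".join(f"{g}:{repr(v)}" for g, v in c.comutations)
            row = [
                c.case_id,
                c.diagnosis,
                c.sf3b1_variant,
                _fmt(c.sf3b1_exon),
                comut,
                _fmt(c.rs_percent),
                _fmt(c.blast_percent),
                _fmt(c.platelets),
                _fmt(c.hemoglobin),
                _fmt(c.anc),
                _fmt(c.ipss_r),
                ",".join(sorted(c.panel_genes)),
                _fmt(c.os_time),
                _fmt(c.os_event),
                _fmt(c.lfs_time),
                _fmt(c.lfs_event),
            ]
            fh.write("\t".join(row) + "\n")


def _parse_opt_float(s: str) -> float | None:
    return None if s == "NA" else float(s)


def read_cohort_table(path: str | os.PathLike) -> list[CaseRecord]:
    cases = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    head = lines[0].split("\t")
    if head != _COLUMNS:
        raise ValueError(f"{path}: unexpected cohort columns {head}")
    for ln in lines[1:]:
        f = dict(zip(_COLUMNS, ln.split("\t")))
        comut = [
            (part.split(":")[0], float(part.split(":")[1]))
            for part in f["comutations"].split(";")
            if part
        ]
        cases.append(
            CaseRecord(
                case_id=f["case_id"],
                diagnosis=f["diagnosis"],
                sf3b1_variant=f["sf3b1_variant"],
                sf3b1_exon=None if f["sf3b1_exon"] == "NA" else int(f["sf3b1_exon"]),
                comutations=comut,
                rs_percent=_parse_opt_float(f["rs_percent"]),
                blast_percent=_parse_opt_float(f["blast_percent"]),
                platelets=_parse_opt_float(f["platelets"]),
                hemoglobin=_parse_opt_float(f["hemoglobin"]),
                anc=_parse_opt_float(f["anc"]),
                ipss_r=_parse_opt_float(f["ipss_r"]),
                panel_genes=frozenset(
                    g for g in f["panel_genes"].split(",") if g
                ),
                os_time=float(f["os_time"]),
                os_event=f["os_event"] == "1",
                lfs_time=float(f["lfs_time"]),
                lfs_event=f["lfs_event"] == "1",
            )
        )
    return cases
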