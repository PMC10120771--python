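"""Stage orchestration: simulate → psi → diff → classify → cohort → report.

Each stage persists its result as files under the run directory so any
stage can be rerun or tested in isolation; a manifest (config, seeds,
content hashes) makes a run reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_fasta, read_gtf, synthesize_genome
from .cohort import (
    comutation_landscape,
    km_estimate,
    logrank_test,
    oncoprint_matrix,
    partition_distribution,
    read_cohort_table,
    summarize_rs,
)
from .events import (
    DifferentialResult,
    SpecificityConfig,
    call_specificity,
    classify_event,
    delta_psi,
    predict_ptc_nmd,
    rank_events,
)
from .junctions import (
    JunctionKey,
    QuantConfig,
    build_anchor_groups,
    compute_psi,
    counts_frame,
    read_junction_table,
)
from .simdata import (
    default_cohort_config,
    default_splice_config,
    read_genotype_map,
    simulate_cohort,
    simulate_junction_counts,
    toy_annotation,
    write_fixtures,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "psi", "diff", "classify", "cohort", "report")


class StageError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class RunConfig:
    out_dir: str = "spliceotype_run"
    log_level: str = "INFO"
    seed: int = 0
    cohort_seed: int | None = None  # defaults to seed + 1
    n_samples_per_genotype: int = 4
    depth_per_anchor: float = 200.0
    dispersion: float = 0.01
    n_cases: int = 400
    min_coverage: int = 15
    min_samples_per_group: int = 2
    reference_genotype: str = "WT"
    t_present: float = 0.10
    t_absent: float = 0.05
    top_k: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage {stage!r} needs {path.name} (run the {produced_by!r} stage first)"
        )
    return path


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    annotation = toy_annotation()
    sim_cfg = default_splice_config(
        seed=cfg.seed,
        n_samples_per_genotype=cfg.n_samples_per_genotype,
        depth_per_anchor=cfg.depth_per_anchor,
        dispersion=cfg.dispersion,
    )
    sim = simulate_junction_counts(annotation, sim_cfg)
    cohort_seed = cfg.seed + 1 if cfg.cohort_seed is None else cfg.cohort_seed
    cases = simulate_cohort(default_cohort_config(seed=cohort_seed, n_cases=cfg.n_cases))
    genome = synthesize_genome(annotation, seed=cfg.seed)
    write_fixtures(annotation, sim, cases, out / "fixtures", genome=genome)


def stage_psi(cfg: RunConfig, out: Path) -> None:
    fixtures = out / "fixtures"
    gtf = _need(fixtures / "annotation.gtf", "psi", "simulate")
    jdir = _need(fixtures / "junctions", "psi", "simulate")
    annotation = read_gtf(gtf)
    records = []
    for p in sorted(jdir.glob("*.SJ.out.tab")):
        records.extend(read_junction_table(p, sample_id=p.name.split(".")[0]))
    groups = build_anchor_groups(records, annotation)
    counts = counts_frame(records)
    psi = compute_psi(
        groups,
        counts,
        QuantConfig(cfg.min_coverage, cfg.min_samples_per_group),
    )
    pdir = out / "psi"
    pdir.mkdir(exist_ok=True)
    psi.to_tsv(pdir / "psi_matrix.tsv", header=f" min_coverage={cfg.min_coverage}")
    tot = psi.total.copy()
    tot.index = pd.MultiIndex.from_tuples(
        psi.total.index, names=["chrom", "intron_start", "intron_end", "strand"]
    )
    tot.reset_index().to_csv(pdir / "totals.tsv", sep="\t", index=False)


def _load_psi_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    df = df.set_index(["chrom", "intron_start", "intron_end", "strand"])
    return df


def stage_diff(cfg: RunConfig, out: Path) -> None:
    psi_path = _need(out / "psi" / "psi_matrix.tsv", "diff", "psi")
    gmap_path = _need(out / "fixtures" / "genotypes.tsv", "diff", "simulate")
    frame = _load_psi_frame(psi_path)
    genotype_map = read_genotype_map(gmap_path)

    from .junctions import PsiMatrix

    matrix = PsiMatrix(psi=frame, total=frame.notna().astype(int))
    results = delta_psi(
        matrix,
        genotype_map,
        cfg.reference_genotype,
        QuantConfig(cfg.min_coverage, cfg.min_samples_per_group),
    )
    genotypes = sorted({genotype_map[s] for s in matrix.samples})
    mutants = [g for g in genotypes if g != cfg.reference_genotype]
    rows = []
    for r in results:
        row = {
            "chrom": r.junction.chrom,
            "intron_start": r.junction.start,
            "intron_end": r.junction.end,
            "strand": r.junction.strand,
        }
        for g in genotypes:
            row[f"mean_{g}"] = r.group_means[g]
            row[f"n_{g}"] = r.n_informative[g]
        for g in mutants:
            row[f"delta_{g}"] = r.delta_psi[g]
        row["score"] = r.score
        row["informative"] = int(r.informative)
        rows.append(row)
    ddir = out / "diff"
    ddir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ddir / "differential.tsv", sep="\t", index=False, na_rep="NA")


def _results_from_tsv(path: Path) -> list[DifferentialResult]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    mean_cols = [c for c in df.columns if c.startswith("mean_")]
    delta_cols = [c for c in df.columns if c.startswith("delta_")]
    results = []
    for _, row in df.iterrows():
        key = JunctionKey(
            row["chrom"], int(row["intron_start"]), int(row["intron_end"]), row["strand"]
        )
        means = {c[len("mean_"):]: float(row[c]) for c in mean_cols}
        n_inf = {c[len("mean_"):]: int(row[f"n_{c[len('mean_'):]}"]) for c in mean_cols}
        deltas = {c[len("delta_"):]: float(row[c]) for c in delta_cols}
        score = float(row["score"]) if not pd.isna(row["score"]) else math.nan
        results.append(
            DifferentialResult(key, means, n_inf, deltas, score, bool(row["informative"]))
        )
    return results


def stage_classify(cfg: RunConfig, out: Path) -> None:
    diff_path = _need(out / "diff" / "differential.tsv", "classify", "diff")
    gtf = _need(out / "fixtures" / "annotation.gtf", "classify", "simulate")
    annotation = read_gtf(gtf)
    genome_path = out / "fixtures" / "genome.fa"
    genome = read_fasta(genome_path) if genome_path.exists() else None
    results = _results_from_tsv(diff_path)
    calls, jaccard = call_specificity(
        results, SpecificityConfig(cfg.t_present, cfg.t_absent)
    )
    ranked = {r.junction for r in rank_events(results, cfg.top_k)}
    by_gene = {t.gene_id: t for t in annotation.transcripts}
    rows = []
    for call in calls:
        cls = classify_event(call.junction, annotation)
        ptc_pos, nmd = None, None
        if genome is not None and cls.gene_id in by_gene and cls.event_class not in (
            "degenerate",
        ):
            ptc = predict_ptc_nmd(
                call.junction, cls.canonical, by_gene[cls.gene_id], genome
            )
            ptc_pos, nmd = ptc.ptc_position, ptc.nmd_predicted
        row = {
            "chrom": call.junction.chrom,
            "intron_start": call.junction.start,
            "intron_end": call.junction.end,
            "strand": call.junction.strand,
            "gene": cls.gene_id,
            "event_class": cls.event_class,
            "canonical": str(cls.canonical) if cls.canonical else "NA",
            "inserted_or_deleted_nt": cls.inserted_or_deleted_nt,
            "frame_shift": cls.frame_shift,
            "ptc_position": ptc_pos,
            "nmd_predicted": nmd,
            "score": call.score,
            "label": call.label,
            "top_ranked": int(call.junction in ranked),
        }
        for g, status in sorted(call.specificity.items()):
            row[f"status_{g}"] = status
        rows.append(row)
    cdir = out / "classify"
    cdir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(cdir / "events.tsv", sep="\t", index=False, na_rep="NA")
    with open(cdir / "overlap.json", "w") as fh:
        json.dump(
            {f"{a}|{b}": j for (a, b), j in sorted(jaccard.items())},
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(cdir / "events.bed", "w") as fh:
        for call in sorted(calls, key=lambda c: c.junction):
            k = call.junction
            score = 0 if math.isnan(call.score) else min(1000, int(1000 * call.score))
            fh.write(
                f"{k.chrom}\t{k.start - 1}\t{k.end}\t{call.label}\t{score}\t{k.strand}\n"
            )


def stage_cohort(cfg: RunConfig, out: Path) -> None:
    cohort_path = _need(out / "fixtures" / "cohort.tsv", "cohort", "simulate")
    cases = read_cohort_table(cohort_path)
    cdir = out / "cohort"
    cdir.mkdir(exist_ok=True)
    variants = sorted({c.sf3b1_variant for c in cases})
    part = partition_distribution(cases, variants)
    _write_df(part.counts, cdir / "partition_counts.tsv")
    _write_df(part.percent, cdir / "partition_percent.tsv")
    pd.DataFrame(
        [
            {
                "variant": t.variant,
                "diagnosis_a": t.diagnosis_a,
                "diagnosis_b": t.diagnosis_b,
                "p_value": t.p_value,
                "odds_ratio": t.odds_ratio,
            }
            for t in part.tests
        ]
    ).to_csv(cdir / "partition_tests.tsv", sep="\t", index=False, na_rep="NA")

    panel = sorted({g for c in cases for g in c.panel_genes})
    is_e592k = lambda c: c.sf3b1_variant == "E592K"
    is_canonical = lambda c: c.sf3b1_exon in (14, 15, 16)
    if any(is_e592k(c) for c in cases) and any(is_canonical(c) for c in cases):
        land = comutation_landscape(
            cases, panel, is_e592k, is_canonical, labels=("e592k", "exon14_16")
        )
        _write_df(land, cdir / "comutation.tsv")
    _write_df(oncoprint_matrix(cases, panel), cdir / "oncoprint.tsv")

    rs = summarize_rs(
        cases,
        lambda c: is_canonical(c)
        and (c.blast_percent is not None and c.blast_percent < 5),
    )
    pd.DataFrame(
        [{"group": "exon14_16_low_blast", "mean_rs": rs.mean, "n": rs.n}]
    ).to_csv(cdir / "rs_summary.tsv", sep="\t", index=False, na_rep="NA")

    for endpoint in ("os", "lfs"):
        rows = []
        for name, pred in (("E592K", is_e592k), ("exon14_16", is_canonical)):
            grp = [c for c in cases if pred(c)]
            if not grp:
                continue
            curve = km_estimate(
                [getattr(c, f"{endpoint}_time") for c in grp],
                [getattr(c, f"{endpoint}_event") for c in grp],
            )
            for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
                rows.append({"group": name, "time": t, "survival": s, "at_risk": n})
        pd.DataFrame(rows).to_csv(
            cdir / f"survival_{endpoint}.tsv", sep="\t", index=False
        )
        a = [c for c in cases if is_e592k(c)]
        b = [c for c in cases if is_canonical(c)]
        if a and b:
            lr = logrank_test(
                [getattr(c, f"{endpoint}_time") for c in a],
                [getattr(c, f"{endpoint}_event") for c in a],
                [getattr(c, f"{endpoint}_time") for c in b],
                [getattr(c, f"{endpoint}_event") for c in b],
            )
            with open(cdir / f"logrank_{endpoint}.json", "w") as fh:
                json.dump(
                    {"statistic": lr.statistic, "p_value": lr.p_value}, fh, indent=2
                )


def stage_report(cfg: RunConfig, out: Path) -> None:
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "files": {},
    }
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


_STAGE_FN = {
    "simulate": stage_simulate,
    "psi": stage_psi,
    "diff": stage_diff,
    "classify": stage_classify,
    "cohort": stage_cohort,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages in dependency order; returns the run dir."""
    stages = list(STAGES) if stages is None else stages
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FN[stage](config, out)
    return out
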