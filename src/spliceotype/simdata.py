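"""Seeded generators for toy annotations, junction counts, and cohorts.

The splice simulator emulates the isogenic-clone design used to profile
SF3B1 hotspot missplicing: a handful of independent clones per genotype
(WT, K700E, E592K by default), beta-binomially dispersed split-read
counts at shared donor/acceptor anchors, and planted hotspot-specific
cryptic junctions whose true PSI per genotype is exported as a truth
table. The cohort simulator draws diagnosis, co-mutations,
ring-sideroblast percentages, blood counts, and exponential survival
conditionally on the SF3B1 variant.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import ToyAnnotation, Transcript, synthesize_genome, write_fasta, write_gtf
from .cohort import CaseRecord, write_cohort_table
from .junctions import JunctionKey, JunctionRecord, write_junction_table

#: genes misspliced by the canonical K700E hotspot vs genes affected by
#: E592K, used to name the planted fixtures; the last four stay neutral
K700E_TARGET_GENES = [
    "MAP3K7", "ZDHHC16", "TMEM14C", "ABCB7", "SLTM",
    "DLST", "UQCC1", "DPH5", "ORAI2", "MED6",
]
E592K_TARGET_GENES = [
    "EZH2", "RAVER2", "CEP43", "NUTM2A_AS1", "COQ5",
    "PPOX", "ANKRD36", "MTA3", "PIGQ", "ZNF91",
]
NEUTRAL_GENES = ["ACTB", "GAPDH", "TUBB", "RPL13A"]


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# Toy annotation

def toy_annotation(
    gene_names: Sequence[str] | None = None,
    chrom: str = "chrT",
    minus_strand: Sequence[str] = ("TUBB", "RPL13A"),
) -> ToyAnnotation:
    """Four-exon single-transcript genes laid out along one chromosome.

    Each gene: exons of 90 nt separated by 210-nt introns, CDS from
    +30 in exon 1 to +59 of exon 4 (300 coding nt, a multiple of 3).
    """
    if gene_names is None:
        gene_names = K700E_TARGET_GENES + E592K_TARGET_GENES + NEUTRAL_GENES
    transcripts = []
    for i, gene in enumerate(gene_names):
        b = 1000 + i * 3000
        exons = ((b, b + 89), (b + 300, b + 389), (b + 600, b + 689), (b + 900, b + 989))
        strand = "-" if gene in minus_strand else "+"
        transcripts.append(
            Transcript(
                transcript_id=f"{gene}_t1",
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=(b + 30, b + 959),
            )
        )
    return ToyAnnotation(transcripts)


# ---------------------------------------------------------------------------
# Splice simulation

@dataclass(frozen=True)
class PlantedEvent:
    """A cryptic junction planted at a canonical anchor.

    ``psi_by_genotype`` is the true fraction of the anchor's split reads
    taken by the cryptic junction in each genotype; genotypes not listed
    fall back to ``baseline_psi`` of the config.
    """

    event_id: str
    chrom: str
    canonical: tuple[int, int]
    cryptic: tuple[int, int]
    strand: str
    psi_by_genotype: Mapping[str, float]


@dataclass(frozen=True)
class SpliceSimConfig:
    genotypes: tuple[str, ...] = ("WT", "K700E", "E592K")
    n_samples_per_genotype: int = 4
    depth_per_anchor: float = 200.0
    dispersion: float = 0.01  # beta-binomial rho in [0, 1)
    baseline_psi: float = 0.02  # cryptic PSI where psi_by_genotype is silent
    planted_events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_genotype < 1:
            raise ConfigurationError("n_samples_per_genotype must be positive")
        if self.depth_per_anchor <= 0:
            raise ConfigurationError("depth_per_anchor must be positive")
        if not 0 <= self.dispersion < 1:
            raise ConfigurationError("dispersion must lie in [0, 1)")
        if not 0 <= self.baseline_psi <= 0.05:
            raise ConfigurationError("baseline_psi must be a small fraction (<= 0.05)")
        for ev in self.planted_events:
            for g, psi in ev.psi_by_genotype.items():
                if not 0 <= psi <= 1:
                    raise ConfigurationError(
                        f"{ev.event_id}: PSI for {g} outside [0, 1]"
                    )


def default_planted_events(
    annotation: ToyAnnotation,
    mutant_psi: float = 0.50,
    baseline_psi: float = 0.02,
    shift_nt: int = 20,
) -> tuple[PlantedEvent, ...]:
    """One alternative 3' acceptor per target gene, in intron 1.

    The acceptor moves ``shift_nt`` bases into the intron, so the mature
    transcript gains ``shift_nt`` nt (a frameshift for the default 20).
    """
    events = []
    by_gene = {t.gene_id: t for t in annotation.transcripts}
    for gene_list, hot in ((K700E_TARGET_GENES, "K700E"), (E592K_TARGET_GENES, "E592K")):
        for gene in gene_list:
            t = by_gene.get(gene)
            if t is None:
                continue
            s, e = t.introns()[0]
            cryptic = (s, e - shift_nt) if t.strand == "+" else (s + shift_nt, e)
            events.append(
                PlantedEvent(
                    event_id=f"{gene}_alt3p",
                    chrom=t.chrom,
                    canonical=(s, e),
                    cryptic=cryptic,
                    strand=t.strand,
                    psi_by_genotype={hot: mutant_psi, "WT": baseline_psi},
                )
            )
    return tuple(events)


def default_splice_config(seed: int = 0, **overrides) -> SpliceSimConfig:
    annotation = toy_annotation()
    events = default_planted_events(annotation)
    return SpliceSimConfig(planted_events=events, seed=seed, **overrides)


@dataclass
class SpliceSim:
    """Simulated junction tables plus the planted truth."""

    records_by_sample: dict[str, list[JunctionRecord]]
    genotype_map: dict[str, str]
    truth: pd.DataFrame  # event_id, genotype, true_psi, junction coords
    config: SpliceSimConfig


def _beta_binomial_p(rng: np.random.Generator, psi: float, rho: float) -> float:
    if rho == 0 or psi in (0.0, 1.0):
        return psi
    scale = (1 - rho) / rho
    return float(rng.beta(psi * scale, (1 - psi) * scale))


def simulate_junction_counts(
    annotation: ToyAnnotation, config: SpliceSimConfig
) -> SpliceSim:
    """Draw per-sample split-read counts at every annotated anchor.

    Per anchor and sample the total count is Poisson around
    ``depth_per_anchor`` and is split between the canonical junction and
    any planted cryptic junctions by a beta-binomial draw whose mean is
    the genotype's true PSI and whose overdispersion is ``dispersion``.
    """
    introns = annotation.annotated_introns()
    events_by_canonical: dict[tuple[str, int, int], list[PlantedEvent]] = {}
    for ev in config.planted_events:
        key = (ev.chrom, *ev.canonical)
        if key not in introns:
            raise ConfigurationError(
                f"{ev.event_id}: canonical intron {key} is not annotated"
            )
        cs, ce = ev.cryptic
        if cs != ev.canonical[0] and ce != ev.canonical[1]:
            raise ConfigurationError(
                f"{ev.event_id}: cryptic junction shares no anchor with its canonical"
            )
        events_by_canonical.setdefault(key, []).append(ev)

    rng = np.random.default_rng(config.seed)
    anchors = sorted(introns)
    samples: dict[str, list[JunctionRecord]] = {}
    genotype_map: dict[str, str] = {}
    for genotype in config.genotypes:
        for clone in range(1, config.n_samples_per_genotype + 1):
            sample = f"{genotype}_c{clone}"
            genotype_map[sample] = genotype
            records: list[JunctionRecord] = []
            for chrom, s, e in anchors:
                strand = introns[(chrom, s, e)]
                total = int(rng.poisson(config.depth_per_anchor))
                planted = sorted(
                    events_by_canonical.get((chrom, s, e), ()),
                    key=lambda ev: ev.event_id,
                )
                ps = [
                    _beta_binomial_p(
                        rng,
                        ev.psi_by_genotype.get(genotype, config.baseline_psi),
                        config.dispersion,
                    )
                    for ev in planted
                ]
                if sum(ps) > 1:
                    raise ConfigurationError(
                        f"planted PSIs at {(chrom, s, e)} exceed 1 for {genotype}"
                    )
                counts = (
                    rng.multinomial(total, ps + [1 - sum(ps)])
                    if planted
                    else np.array([total])
                )
                for ev, n in zip(planted, counts[: len(planted)]):
                    records.append(
                        JunctionRecord(chrom, ev.cryptic[0], ev.cryptic[1], strand, int(n), sample)
                    )
                records.append(
                    JunctionRecord(chrom, s, e, strand, int(counts[-1]), sample)
                )
            samples[sample] = records
    truth = pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "genotype": g,
                "true_psi": ev.psi_by_genotype.get(g, config.baseline_psi),
                "chrom": ev.chrom,
                "cryptic_start": ev.cryptic[0],
                "cryptic_end": ev.cryptic[1],
                "strand": ev.strand,
            }
            for ev in sorted(config.planted_events, key=lambda ev: ev.event_id)
            for g in config.genotypes
        ]
    )
    return SpliceSim(samples, genotype_map, truth, config)


def truth_junction(ev_row: pd.Series) -> JunctionKey:
    return JunctionKey(
        ev_row["chrom"], int(ev_row["cryptic_start"]), int(ev_row["cryptic_end"]), ev_row["strand"]
    )


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass(frozen=True)
class CohortSimConfig:
    n_cases: int = 400
    variant_probs: Mapping[str, float] = field(default_factory=dict)
    diagnosis_probs_by_variant: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    comutation_probs_by_variant: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    rs_percent_model: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    clinical_models: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    survival_hazards: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    censor_rate: float = 0.3
    panel_dropout_rate: float = 0.1  # chance a case was sequenced on a narrower panel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError("n_cases must be non-negative")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        def check_dist(name, dist):
            vals = list(dist.values())
            if any(not 0 <= p <= 1 for p in vals):
                raise ConfigurationError(f"{name}: probabilities outside [0, 1]")
            if abs(sum(vals) - 1) > 1e-9:
                raise ConfigurationError(f"{name}: probabilities must sum to 1")
        if self.variant_probs:
            check_dist("variant_probs", self.variant_probs)
        for v, dist in self.diagnosis_probs_by_variant.items():
            check_dist(f"diagnosis_probs[{v}]", dist)
        for v, probs in self.comutation_probs_by_variant.items():
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigurationError(f"comutation_probs[{v}]: outside [0, 1]")
        for v, hz in self.survival_hazards.items():
            if any(h <= 0 for h in hz.values()):
                raise ConfigurationError(f"survival_hazards[{v}]: hazards must be > 0")


_VARIANT_EXON = {"E592K": 13, "E622D": 14, "K666N": 14, "K666R": 14, "K700E": 15}

_DEFAULT_COMUT = {
    "E592K": {
        "ASXL1": 0.83, "DNMT3A": 0.029, "RUNX1": 0.51, "STAG2": 0.29,
        "TET2": 0.30, "SRSF2": 0.15, "EZH2": 0.0,
    },
    "canonical": {
        "ASXL1": 0.09, "DNMT3A": 0.21, "RUNX1": 0.11, "STAG2": 0.03,
        "TET2": 0.25, "SRSF2": 0.10, "EZH2": 0.04,
    },
}

_DEFAULT_CLINICAL = {
    "E592K": {"platelets": (120.0, 60.0), "hemoglobin": (9.5, 1.5),
              "anc": (1.8, 1.0), "ipss_r": (5.5, 1.5)},
    "canonical": {"platelets": (250.0, 100.0), "hemoglobin": (9.5, 1.5),
                  "anc": (1.8, 1.0), "ipss_r": (3.5, 1.5)},
}

_BLAST_RANGE = {
    "MDS-RS": (0.0, 4.0),
    "MDS-SLD/MLD": (0.0, 4.0),
    "MDS-EB": (5.0, 19.0),
    "AML": (20.0, 60.0),
}


def default_cohort_config(seed: int = 0, n_cases: int = 400) -> CohortSimConfig:
    """Cohort conditions mirroring the observed hotspot asymmetries.

    Diagnosis distributions per variant are the empirical fractions of
    the pooled 2,234-case variant x WHO-class table (per-diagnosis
    totals 1327 / 242 / 266 / 399, with the exon 14-16 remainder pooled
    under K700E, the dominant hotspot). Co-mutation odds, RS means, and
    survival hazards follow the reported E592K-vs-canonical contrasts.
    """
    diag_counts = {
        "K666N": (28, 21, 46, 103),
        "E592K": (1, 9, 9, 10),
        "E622D": (92, 7, 1, 2),
        "K666R": (72, 3, 3, 7),
        "K700E": (1134, 202, 207, 277),
    }
    classes = ("MDS-RS", "MDS-SLD/MLD", "MDS-EB", "AML")
    total = sum(sum(v) for v in diag_counts.values())
    variant_probs = {v: sum(c) / total for v, c in diag_counts.items()}
    diagnosis_probs = {
        v: {cls: n / sum(c) for cls, n in zip(classes, c)}
        for v, c in diag_counts.items()
    }
    comut = {
        v: _DEFAULT_COMUT["E592K" if v == "E592K" else "canonical"]
        for v in diag_counts
    }
    clinical = {
        v: _DEFAULT_CLINICAL["E592K" if v == "E592K" else "canonical"]
        for v in diag_counts
    }
    rs_model = {v: ((2.0, 3.0) if v == "E592K" else (37.0, 15.0)) for v in diag_counts}
    hazards = {
        v: (
            {"os": 0.45, "lfs": 0.60}
            if v == "E592K"
            else {"os": 0.09, "lfs": 0.07}
        )
        for v in diag_counts
    }
    return CohortSimConfig(
        n_cases=n_cases,
        variant_probs=variant_probs,
        diagnosis_probs_by_variant=diagnosis_probs,
        comutation_probs_by_variant=comut,
        rs_percent_model=rs_model,
        clinical_models=clinical,
        survival_hazards=hazards,
        seed=seed,
    )


def simulate_cohort(config: CohortSimConfig) -> list[CaseRecord]:
    """Draw ``n_cases`` patients conditionally on their SF3B1 variant."""
    rng = np.random.default_rng(config.seed)
    variants = sorted(config.variant_probs)
    vprobs = [config.variant_probs[v] for v in variants]
    full_panel = sorted(
        {g for probs in config.comutation_probs_by_variant.values() for g in probs}
    )
    cases: list[CaseRecord] = []
    for i in range(config.n_cases):
        variant = variants[rng.choice(len(variants), p=vprobs)] if variants else "K700E"
        diag_dist = config.diagnosis_probs_by_variant.get(variant, {})
        if diag_dist:
            classes = sorted(diag_dist)
            diagnosis = classes[rng.choice(len(classes), p=[diag_dist[c] for c in classes])]
        else:
            diagnosis = "other"
        comut_probs = config.comutation_probs_by_variant.get(variant, {})
        comutations = [
            (gene, float(np.round(rng.uniform(0.05, 0.5), 4)))
            for gene in sorted(comut_probs)
            if rng.random() < comut_probs[gene]
        ]
        panel = set(full_panel)
        if full_panel and rng.random() < config.panel_dropout_rate:
            dropped = rng.choice(full_panel, size=min(2, len(full_panel)), replace=False)
            panel -= set(dropped)
            comutations = [(g, v) for g, v in comutations if g in panel]
        mean_rs, sd_rs = config.rs_percent_model.get(variant, (10.0, 10.0))
        rs = float(np.clip(rng.normal(mean_rs, sd_rs), 0.0, 100.0))
        lo, hi = _BLAST_RANGE.get(diagnosis, (0.0, 10.0))
        blast = float(np.round(rng.uniform(lo, hi), 1))
        clin = config.clinical_models.get(
            variant, _DEFAULT_CLINICAL["canonical"]
        )
        def draw(fld, lo=0.0):
            m, s = clin[fld]
            return float(np.round(max(lo, rng.normal(m, s)), 2))
        surv: dict[str, tuple[float, bool]] = {}
        hz = config.survival_hazards.get(variant, {"os": 0.1, "lfs": 0.1})
        for endpoint in ("os", "lfs"):
            t = float(rng.exponential(1.0 / hz[endpoint]))
            if rng.random() < config.censor_rate:
                surv[endpoint] = (float(rng.uniform(0, t)), False)
            else:
                surv[endpoint] = (t, True)
        cases.append(
            CaseRecord(
                case_id=f"case{i:04d}",
                diagnosis=diagnosis,
                sf3b1_variant=variant,
                sf3b1_exon=_VARIANT_EXON.get(variant, 15),
                comutations=comutations,
                rs_percent=round(rs, 1),
                blast_percent=blast,
                platelets=draw("platelets"),
                hemoglobin=draw("hemoglobin"),
                anc=draw("anc"),
                ipss_r=min(10.0, draw("ipss_r")),
                panel_genes=frozenset(panel),
                os_time=round(surv["os"][0], 4),
                os_event=surv["os"][1],
                lfs_time=round(surv["lfs"][0], 4),
                lfs_event=surv["lfs"][1],
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Fixture writing

def write_fixtures(
    annotation: ToyAnnotation,
    sim: SpliceSim | None,
    cases: Sequence[CaseRecord] | None,
    out_dir: str | os.PathLike,
    genome: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Write GTF, per-sample SJ tables, cohort TSV, and the truth table.

    With no samples, no junction directory is created (documented
    behavior); the returned mapping names every file written. All
    writers stamp the generating seed into a header comment.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths: dict[str, str] = {}
    seed = sim.config.seed if sim is not None else 0
    stamp = f" spliceotype simdata seed={seed}"
    gtf = out / "annotation.gtf"
    write_gtf(annotation, gtf, header=stamp)
    paths["annotation"] = str(gtf)
    if genome is not None:
        fa = out / "genome.fa"
        write_fasta(genome, fa)
        paths["genome"] = str(fa)
    if sim is not None and sim.records_by_sample:
        jdir = out / "junctions"
        jdir.mkdir(exist_ok=True)
        for sample, records in sorted(sim.records_by_sample.items()):
            p = jdir / f"{sample}.SJ.out.tab"
            write_junction_table(records, p, header=stamp)
            paths[f"junctions/{sample}"] = str(p)
        gmap = out / "genotypes.tsv"
        with open(gmap, "w") as fh:
            fh.write(f"#{stamp}\nsample_id\tgenotype\n")
            for sample, genotype in sorted(sim.genotype_map.items()):
                fh.write(f"{sample}\t{genotype}\n")
        paths["genotypes"] = str(gmap)
    if sim is not None and not sim.truth.empty:
        tpath = out / "truth.tsv"
        with open(tpath, "w") as fh:
            fh.write(f"#{stamp}\n")
            sim.truth.to_csv(fh, sep="\t", index=False)
        paths["truth"] = str(tpath)
    if cases is not None:
        cpath = out / "cohort.tsv"
        write_cohort_table(cases, cpath, header=stamp)
        paths["cohort"] = str(cpath)
    return paths


def read_genotype_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["sample_id"], df["genotype"]))
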