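"""Differential splicing between genotypes and cryptic-event interpretation.

The unit of analysis is a junction's ΔPSI: the difference between its
mean PSI in a mutant genotype group and in the wild-type reference,
taken over samples that survived the coverage filter. Events are ranked
by the largest |ΔPSI| across mutants, classified against the annotation
(alternative 3' acceptor, alternative 5' donor, exon skip, ...),
checked for reading-frame disruption and premature termination codons,
and labeled hotspot-specific when present in exactly one genotype and
affirmatively absent in the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import ToyAnnotation, Transcript
from .junctions import (
    JunctionKey,
    PsiMatrix,
    QuantConfig,
    acceptor_site,
    donor_site,
)

ALT_3P_ACCEPTOR = "alt_3p_acceptor"
ALT_5P_DONOR = "alt_5p_donor"
EXON_SKIP = "exon_skip"
INTRON_RETENTION_PROXY = "intron_retention_proxy"
OTHER = "other"
DEGENERATE = "degenerate"

PRESENT = "present"
ABSENT = "absent"
INDETERMINATE = "indeterminate"


@dataclass
class DifferentialResult:
    """Per-junction group means and signed ΔPSI versus the reference."""

    junction: JunctionKey
    group_means: dict[str, float]
    n_informative: dict[str, int]
    delta_psi: dict[str, float]  # mutant genotype -> mean - reference mean
    score: float  # max |ΔPSI| over informative mutants; NaN if indeterminate
    informative: bool


def delta_psi(
    psi: PsiMatrix,
    genotype_map: Mapping[str, str],
    reference_genotype: str,
    config: QuantConfig = QuantConfig(),
) -> list[DifferentialResult]:
    """ΔPSI of every junction for each mutant genotype vs the reference.

    A junction is informative when the reference and at least one other
    genotype each contribute >= ``config.min_samples_per_group``
    non-missing samples; otherwise it is marked indeterminate (score
    NaN), never silently zero.
    """
    missing = [s for s in psi.samples if s not in genotype_map]
    if missing:
        raise ValueError(f"samples absent from genotype_map: {missing}")
    genotypes = sorted(set(genotype_map[s] for s in psi.samples))
    if reference_genotype not in genotypes:
        raise ValueError(f"reference genotype {reference_genotype!r} has no samples")
    cols = {g: [s for s in psi.samples if genotype_map[s] == g] for g in genotypes}
    min_n = config.min_samples_per_group

    results = []
    for key in psi.junctions:
        vals = psi.psi.loc[tuple(key)]
        means: dict[str, float] = {}
        n_inf: dict[str, int] = {}
        for g in genotypes:
            v = vals[cols[g]].astype(float)
            n_inf[g] = int(v.notna().sum())
            means[g] = float(v.mean()) if n_inf[g] else math.nan
        ref_ok = n_inf[reference_genotype] >= min_n
        deltas: dict[str, float] = {}
        for g in genotypes:
            if g == reference_genotype:
                continue
            if ref_ok and n_inf[g] >= min_n:
                deltas[g] = means[g] - means[reference_genotype]
            else:
                deltas[g] = math.nan
        finite = [abs(d) for d in deltas.values() if not math.isnan(d)]
        informative = bool(finite)
        score = max(finite) if finite else math.nan
        results.append(
            DifferentialResult(key, means, n_inf, deltas, score, informative)
        )
    return results


def rank_events(
    results: Sequence[DifferentialResult], top_k: int
) -> list[DifferentialResult]:
    """Highest-scoring junctions first; coordinate order breaks ties."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    scored = [r for r in results if r.informative and not math.isnan(r.score)]
    scored.sort(key=lambda r: (-r.score, r.junction))
    return scored[:top_k]


# ---------------------------------------------------------------------------
# Classification

@dataclass
class EventClassification:
    cryptic: JunctionKey
    event_class: str
    canonical: JunctionKey | None
    inserted_or_deleted_nt: int | None
    frame_shift: bool | None
    gene_id: str

    def __post_init__(self) -> None:
        nt = self.inserted_or_deleted_nt
        if nt is not None and self.frame_shift != bool(nt % 3):
            raise ValueError("frame_shift inconsistent with inserted_or_deleted_nt")


def _intron_len(key: JunctionKey) -> int:
    return key.end - key.start + 1


def classify_event(
    cryptic: JunctionKey, annotation: ToyAnnotation
) -> EventClassification:
    """Classify a cryptic junction against annotated introns.

    Shares the donor with an annotated intron -> alternative 3'
    acceptor; shares the acceptor -> alternative 5' donor; joins the
    donor of intron i to the acceptor of a later intron j of the same
    transcript -> exon skip; strictly inside an annotated intron ->
    intron-retention proxy; otherwise "other". The signed
    mature-transcript length change is positive when intronic sequence
    becomes exonic (e.g. an acceptor shifted into the intron).
    """
    introns = annotation.annotated_introns()
    owners = annotation.intron_owners()
    gene_for = _gene_lookup(annotation)

    if (cryptic.chrom, cryptic.start, cryptic.end) in introns:
        return EventClassification(
            cryptic, DEGENERATE, cryptic, 0, False, gene_for(cryptic)
        )

    # exon skip: both ends are annotated splice sites of non-adjacent
    # introns within one transcript
    for t in sorted(annotation.transcripts, key=lambda t: t.transcript_id):
        if t.chrom != cryptic.chrom or t.strand != cryptic.strand:
            continue
        t_introns = [
            JunctionKey(t.chrom, s, e, t.strand) for s, e in t.introns()
        ]
        exon_order = list(t.exons)
        if t.strand == "-":  # 5'→3' transcript order
            t_introns = t_introns[::-1]
            exon_order = exon_order[::-1]
        donor_idx = {donor_site(k).pos: i for i, k in enumerate(t_introns)}
        acceptor_idx = {acceptor_site(k).pos: i for i, k in enumerate(t_introns)}
        i = donor_idx.get(donor_site(cryptic).pos)
        j = acceptor_idx.get(acceptor_site(cryptic).pos)
        if i is not None and j is not None and j > i:
            skipped = exon_order[i + 1 : j + 1]
            delta = -sum(e - s + 1 for s, e in skipped)
            return EventClassification(
                cryptic, EXON_SKIP, t_introns[i], delta, bool(delta % 3), t.gene_id
            )

    same_chrom = [
        JunctionKey(c, s, e, st)
        for (c, s, e), st in introns.items()
        if c == cryptic.chrom and st == cryptic.strand
    ]

    def partner(site_fn) -> JunctionKey | None:
        hits = [k for k in same_chrom if site_fn(k).pos == site_fn(cryptic).pos]
        if not hits:
            return None
        return min(
            hits, key=lambda k: (abs(_intron_len(k) - _intron_len(cryptic)), k)
        )

    donor_partner = partner(donor_site)
    if donor_partner is not None:
        delta = _intron_len(donor_partner) - _intron_len(cryptic)
        return EventClassification(
            cryptic,
            ALT_3P_ACCEPTOR,
            donor_partner,
            delta,
            bool(delta % 3),
            _owner_gene(owners, donor_partner),
        )
    acceptor_partner = partner(acceptor_site)
    if acceptor_partner is not None:
        delta = _intron_len(acceptor_partner) - _intron_len(cryptic)
        return EventClassification(
            cryptic,
            ALT_5P_DONOR,
            acceptor_partner,
            delta,
            bool(delta % 3),
            _owner_gene(owners, acceptor_partner),
        )
    for k in sorted(same_chrom):
        if k.start < cryptic.start and cryptic.end < k.end:
            return EventClassification(
                cryptic, INTRON_RETENTION_PROXY, None, None, None, _owner_gene(owners, k)
            )
    return EventClassification(cryptic, OTHER, None, None, None, gene_for(cryptic))


def _owner_gene(owners, key: JunctionKey) -> str:
    hits = owners.get((key.chrom, key.start, key.end), [])
    return hits[0][0].gene_id if hits else "intergenic"


def _gene_lookup(annotation: ToyAnnotation):
    spans = annotation.gene_spans()

    def lookup(key: JunctionKey) -> str:
        hits = sorted(
            gid
            for gid, (chrom, lo, hi, strand) in spans.items()
            if chrom == key.chrom and lo <= key.start and key.end <= hi
        )
        return hits[0] if hits else "intergenic"

    return lookup


# ---------------------------------------------------------------------------
# PTC / NMD

@dataclass
class PtcResult:
    ptc_position: int | None  # 1-based transcript coordinate of the stop codon
    nmd_predicted: bool | None  # None = not applicable (no PTC / outside CDS)


def _modified_exonic_positions(
    transcript: Transcript, cryptic: JunctionKey, canonical: JunctionKey | None
) -> list[int]:
    """Genomic positions of the mature transcript after the cryptic swap.

    The canonical intron's bases rejoin the exonic set (they may be
    retained by the cryptic choice of splice sites) and the cryptic
    intron's bases are excised.
    """
    exonic = set()
    for s, e in transcript.exons:
        exonic.update(range(s, e + 1))
    if canonical is not None:
        exonic.update(range(canonical.start, canonical.end + 1))
    exonic.difference_update(range(cryptic.start, cryptic.end + 1))
    pos = sorted(exonic)
    return pos[::-1] if transcript.strand == "-" else pos


def _transcript_sequence(
    positions: Sequence[int], chrom_seq: str, strand: str
) -> str:
    seq = "".join(chrom_seq[p - 1] for p in positions)
    if strand == "-":
        seq = seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))
    return seq


def _last_junction_offset(positions: Sequence[int], strand: str) -> int | None:
    """0-based transcript offset of the first base of the last exon."""
    breaks = [
        i + 1
        for i in range(len(positions) - 1)
        if abs(positions[i + 1] - positions[i]) != 1
    ]
    return breaks[-1] if breaks else None


def predict_ptc_nmd(
    cryptic: JunctionKey,
    canonical: JunctionKey | None,
    transcript: Transcript,
    genome: Mapping[str, str],
    nmd_min_distance: int = 50,
) -> PtcResult:
    """Translate the cryptic transcript and apply the 50-nt NMD rule.

    The mature mRNA is rebuilt with the cryptic junction replacing its
    canonical partner, translated from the annotated start codon, and
    the first in-frame stop upstream of the canonical stop is reported.
    NMD is predicted when that stop ends more than ``nmd_min_distance``
    nt upstream of the transcript's final exon-exon junction.
    """
    if transcript.cds is None:
        return PtcResult(None, None)
    cds_lo, cds_hi = transcript.cds
    if cryptic.end < cds_lo or cryptic.start > cds_hi:
        return PtcResult(None, None)  # event outside the CDS

    chrom_seq = genome[transcript.chrom]
    positions = _modified_exonic_positions(transcript, cryptic, canonical)
    seq = _transcript_sequence(positions, chrom_seq, transcript.strand)

    start_genomic = cds_lo if transcript.strand == "+" else cds_hi
    stop_genomic = transcript.exonic_positions(transcript.cds)[-3]
    try:
        start_idx = positions.index(start_genomic)
    except ValueError:
        return PtcResult(None, None)  # start codon excised by the event

    stop_idx = None
    for i in range(start_idx, len(seq) - 2, 3):
        if seq[i : i + 3] in ("TAA", "TAG", "TGA"):
            stop_idx = i
            break
    if stop_idx is None or positions[stop_idx] == stop_genomic:
        return PtcResult(None, None)  # no stop, or the canonical one

    last_junction = _last_junction_offset(positions, transcript.strand)
    if last_junction is None:
        nmd = False
    else:
        nmd = (last_junction - (stop_idx + 3)) > nmd_min_distance
    return PtcResult(ptc_position=stop_idx + 1, nmd_predicted=nmd)


# ---------------------------------------------------------------------------
# Hotspot specificity

@dataclass(frozen=True)
class SpecificityConfig:
    t_present: float = 0.10
    t_absent: float = 0.05

    def __post_init__(self) -> None:
        if self.t_absent >= self.t_present:
            raise ValueError("t_absent must be strictly below t_present")


@dataclass
class SpliceEventCall:
    """A cryptic junction with its full interpretation."""

    junction: JunctionKey
    delta_psi: dict[str, float]
    score: float
    specificity: dict[str, str]  # genotype -> present/absent/indeterminate
    label: str
    event_class: str | None = None
    canonical: JunctionKey | None = None
    inserted_or_deleted_nt: int | None = None
    frame_shift: bool | None = None
    ptc_position: int | None = None
    nmd_predicted: bool | None = None
    gene_id: str = ""


def call_specificity(
    results: Sequence[DifferentialResult],
    config: SpecificityConfig = SpecificityConfig(),
) -> tuple[list[SpliceEventCall], dict[tuple[str, str], float]]:
    """Label events hotspot-specific, shared, or indeterminate.

    A genotype is ``present`` when ΔPSI >= t_present, ``absent`` when
    |ΔPSI| <= t_absent, else indeterminate (including junctions that
    failed the informativeness rule in that genotype). The label is
    "<G>-specific" when exactly one genotype is present and every other
    is affirmatively absent; "shared" when two or more are present.
    Returns the calls plus the pairwise Jaccard index of present-event
    sets.
    """
    genotypes = sorted({g for r in results for g in r.delta_psi})
    if len(genotypes) < 2:
        raise ValueError("specificity needs ΔPSI for at least two mutant genotypes")
    calls: list[SpliceEventCall] = []
    present_sets: dict[str, set[JunctionKey]] = {g: set() for g in genotypes}
    for r in results:
        status: dict[str, str] = {}
        for g in genotypes:
            d = r.delta_psi.get(g, math.nan)
            if math.isnan(d):
                status[g] = INDETERMINATE
            elif d >= config.t_present:
                status[g] = PRESENT
                present_sets[g].add(r.junction)
            elif abs(d) <= config.t_absent:
                status[g] = ABSENT
            else:
                status[g] = INDETERMINATE
        n_present = sum(1 for s in status.values() if s == PRESENT)
        if n_present >= 2:
            label = "shared"
        elif n_present == 1 and all(
            s in (PRESENT, ABSENT) for s in status.values()
        ):
            (only,) = [g for g, s in status.items() if s == PRESENT]
            label = f"{only}-specific"
        elif n_present == 0 and all(s == ABSENT for s in status.values()):
            label = "none"
        else:
            label = INDETERMINATE
        calls.append(
            SpliceEventCall(r.junction, dict(r.delta_psi), r.score, status, label)
        )
    jaccard: dict[tuple[str, str], float] = {}
    for i, a in enumerate(genotypes):
        for b in genotypes[i + 1 :]:
            union = present_sets[a] | present_sets[b]
            inter = present_sets[a] & present_sets[b]
            jaccard[(a, b)] = len(inter) / len(union) if union else 0.0
    return calls, jaccard
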