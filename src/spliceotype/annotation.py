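"""Transcript models and annotation I/O.

Coordinates are 1-based inclusive genomic positions throughout (the
STAR ``SJ.out.tab`` convention). An intron spans the first through the
last intronic base. Donor/acceptor sites are strand-aware: on ``+`` the
donor is the intron start, on ``-`` it is the intron end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import gffutils
import numpy as np

Interval = tuple[int, int]

#: codons that never terminate translation (standard code)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised when a transcript model violates its structural invariants."""


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered exons plus an optional genomic CDS span."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Interval | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start > end:
                raise AnnotationError(f"{self.transcript_id}: exon {start}-{end} inverted")
            if prev_end is not None:
                if start <= prev_end:
                    raise AnnotationError(f"{self.transcript_id}: overlapping exons")
                if start - prev_end - 1 < 4:
                    raise AnnotationError(f"{self.transcript_id}: intron shorter than 4 nt")
            prev_end = end
        if self.cds is not None:
            lo, hi = self.cds
            if lo > hi:
                raise AnnotationError(f"{self.transcript_id}: CDS span inverted")
            for endpoint in (lo, hi):
                if not any(s <= endpoint <= e for s, e in exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS endpoint {endpoint} not exonic"
                    )

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, as (first, last) intronic base."""
        return [
            (e1[1] + 1, e2[0] - 1) for e1, e2 in zip(self.exons, self.exons[1:])
        ]

    def exonic_positions(self, span: Interval | None = None) -> list[int]:
        """Genomic positions of exonic bases in transcript (5'→3') order."""
        lo, hi = span if span is not None else (self.exons[0][0], self.exons[-1][1])
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, lo), min(e, hi) + 1)
        ]
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class ToyAnnotation:
    """A set of transcripts with gene-level lookup tables."""

    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def genes(self) -> list[tuple[str, str, str]]:
        seen: dict[str, tuple[str, str, str]] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, (t.gene_id, t.chrom, t.strand))
        return list(seen.values())

    def gene_spans(self) -> dict[str, tuple[str, int, int, str]]:
        spans: dict[str, tuple[str, int, int, str]] = {}
        for t in self.transcripts:
            lo, hi = t.exons[0][0], t.exons[-1][1]
            if t.gene_id in spans:
                chrom, a, b, strand = spans[t.gene_id]
                spans[t.gene_id] = (chrom, min(a, lo), max(b, hi), strand)
            else:
                spans[t.gene_id] = (t.chrom, lo, hi, t.strand)
        return spans

    def annotated_introns(self) -> dict[tuple[str, int, int], str]:
        """Map (chrom, intron_start, intron_end) -> strand."""
        out: dict[tuple[str, int, int], str] = {}
        for t in self.transcripts:
            for s, e in t.introns():
                out[(t.chrom, s, e)] = t.strand
        return out

    def intron_owners(self) -> dict[tuple[str, int, int], list[tuple[Transcript, int]]]:
        out: dict[tuple[str, int, int], list[tuple[Transcript, int]]] = {}
        for t in self.transcripts:
            for i, (s, e) in enumerate(t.introns()):
                out.setdefault((t.chrom, s, e), []).append((t, i))
        return out

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.gene_id == gene_id]


# ---------------------------------------------------------------------------
# GTF I/O

def write_gtf(annotation: ToyAnnotation, path: str | os.PathLike, header: str | None = None) -> None:
    """Write exon and CDS features with gene_id/transcript_id attributes."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for t in annotation.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tspliceotype\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                lo, hi = t.cds
                for s, e in t.exons:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs <= ce:
                        fh.write(
                            f"{t.chrom}\tspliceotype\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def read_gtf(path: str | os.PathLike) -> ToyAnnotation:
    """Load exon/CDS features from a GTF into transcript models."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start, feat.end))
    transcripts = []
    for tid, (gid, chrom, strand) in sorted(meta.items()):
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        transcripts.append(
            Transcript(tid, gid, chrom, strand, tuple(sorted(exons[tid])), cds_span)
        )
    return ToyAnnotation(transcripts)


# ---------------------------------------------------------------------------
# Toy genome synthesis

def synthesize_genome(
    annotation: ToyAnnotation, seed: int, pad: int = 50
) -> dict[str, str]:
    """Random genome consistent with the annotation's gene models.

    Each CDS is rewritten as ATG + stop-free codons + TAA in the coding
    frame implied by exon order, so translating an unmodified transcript
    stops exactly at the annotated CDS end. Intron ends get GT..AG.
    """
    rng = np.random.default_rng(seed)
    length: dict[str, int] = {}
    for t in annotation.transcripts:
        length[t.chrom] = max(length.get(t.chrom, 0), t.exons[-1][1] + pad)
    genome = {
        chrom: list(rng.choice(list("ACGT"), size=n))
        for chrom, n in sorted(length.items())
    }
    for t in annotation.transcripts:
        seq = genome[t.chrom]
        for s, e in t.introns():
            if t.strand == "+":
                seq[s - 1], seq[s] = "G", "T"
                seq[e - 2], seq[e - 1] = "A", "G"
            else:  # GT..AG on the minus strand reads CT..AC on the plus strand
                seq[s - 1], seq[s] = "C", "T"
                seq[e - 2], seq[e - 1] = "A", "C"
        if t.cds is None:
            continue
        positions = t.exonic_positions(t.cds)
        if len(positions) % 3:
            raise AnnotationError(f"{t.transcript_id}: CDS length not a multiple of 3")
        n_codons = len(positions) // 3
        codons = ["ATG"] + [
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        bases = "".join(codons)
        for pos, base in zip(positions, bases):
            seq[pos - 1] = base if t.strand == "+" else base.translate(_COMPLEMENT)
    return {chrom: "".join(seq) for chrom, seq in genome.items()}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome
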