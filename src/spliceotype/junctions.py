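"""Splice-junction ingestion, anchor grouping, and PSI quantification.

PSI (percent spliced in) of a junction is its split-read count divided
by the total split-read count of all junctions sharing its constitutive
donor or acceptor anchor, with the whole anchor masked in a sample when
that denominator falls below a minimum coverage (default 15 split
reads). Multi-mapping read counts are never used.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .annotation import ToyAnnotation

logger = logging.getLogger(__name__)


class JunctionKey(NamedTuple):
    chrom: str
    start: int  # first intronic base, 1-based
    end: int  # last intronic base, 1-based
    strand: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class JunctionRecord:
    """Split-read evidence for one intron in one sample."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str  # '+', '-' or '?' (unknown)
    unique_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"intron_start must precede intron_end "
                f"({self.chrom}:{self.intron_start}-{self.intron_end})"
            )
        if self.unique_count < 0:
            raise ValueError("unique_count must be non-negative")

    @property
    def key(self) -> JunctionKey:
        return JunctionKey(self.chrom, self.intron_start, self.intron_end, self.strand)


class Anchor(NamedTuple):
    chrom: str
    pos: int
    side: str  # 'donor' | 'acceptor'
    strand: str


@dataclass
class AnchorGroup:
    """Junctions sharing one constitutive donor or acceptor site."""

    anchor: Anchor
    members: list[JunctionKey]
    canonical_member: JunctionKey | None = None


@dataclass(frozen=True)
class QuantConfig:
    min_coverage: int = 15
    min_samples_per_group: int = 2

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_samples_per_group < 1:
            raise ValueError("min_samples_per_group must be >= 1")


# ---------------------------------------------------------------------------
# Readers

_STAR_STRAND = {"0": "?", "1": "+", "2": "-"}


def _read_star_sj(path, sample_id):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, strand_code = fields[0], fields[1], fields[2], fields[3]
            if strand_code not in _STAR_STRAND:
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand code {strand_code!r}"
                )
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    intron_start=int(start),
                    intron_end=int(end),
                    strand=_STAR_STRAND[strand_code],
                    unique_count=int(fields[6]),  # multi-mapping column 8 ignored
                    sample_id=sample_id,
                )
            )
    return records


def _read_bed12(path, sample_id):
    """Junction BED12 (two blocks per line); 0-based half-open on disk."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 BED columns, got {len(fields)}"
                )
            chrom_start = int(fields[1])
            strand = fields[5] if fields[5] in "+-" else "?"
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: junction BED must have exactly 2 blocks"
                )
            records.append(
                JunctionRecord(
                    chrom=fields[0],
                    intron_start=chrom_start + sizes[0] + 1,
                    intron_end=chrom_start + starts[1],
                    strand=strand,
                    unique_count=int(fields[4]),
                    sample_id=sample_id,
                )
            )
    return records


_DIALECTS = {"star_sj": _read_star_sj, "bed12": _read_bed12}


def read_junction_table(
    path: str | os.PathLike,
    dialect: str = "star_sj",
    sample_id: str | None = None,
) -> list[JunctionRecord]:
    """Read one per-sample junction table.

    ``dialect`` selects a registered reader: ``star_sj`` (STAR
    ``SJ.out.tab``, 9 columns, strand coded 0/1/2) or ``bed12``.
    ``sample_id`` defaults to the file name stem.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(_DIALECTS)}")
    if sample_id is None:
        sample_id = os.path.basename(str(path)).split(".")[0]
    return _DIALECTS[dialect](str(path), sample_id)


def write_junction_table(
    records: Iterable[JunctionRecord], path: str | os.PathLike, header: str | None = None
) -> None:
    """Write STAR SJ.out.tab dialect (motif/annotated/multi/overhang zeroed)."""
    code = {"?": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.intron_start, r.intron_end)):
            fh.write(
                f"{r.chrom}\t{r.intron_start}\t{r.intron_end}\t{code[r.strand]}"
                f"\t0\t0\t{r.unique_count}\t0\t0\n"
            )


# ---------------------------------------------------------------------------
# Anchor grouping

def donor_site(key: JunctionKey) -> Anchor:
    pos = key.start if key.strand == "+" else key.end
    return Anchor(key.chrom, pos, "donor", key.strand)


def acceptor_site(key: JunctionKey) -> Anchor:
    pos = key.end if key.strand == "+" else key.start
    return Anchor(key.chrom, pos, "acceptor", key.strand)


def resolve_strands(
    keys: Iterable[JunctionKey], annotation: ToyAnnotation
) -> list[JunctionKey]:
    """Fill unknown strands from the annotation; check declared ones.

    Unknown-strand junctions inherit the strand of the unique gene span
    they overlap; ambiguous or orphan junctions are dropped with a
    warning. A junction exactly matching an annotated intron on the
    opposite strand is a contradiction and raises.
    """
    introns = annotation.annotated_introns()
    spans = list(annotation.gene_spans().values())
    resolved: list[JunctionKey] = []
    conflicts: list[JunctionKey] = []
    for key in keys:
        ann_strand = introns.get((key.chrom, key.start, key.end))
        if key.strand in "+-":
            if ann_strand is not None and ann_strand != key.strand:
                conflicts.append(key)
            else:
                resolved.append(key)
            continue
        if ann_strand is not None:
            resolved.append(key._replace(strand=ann_strand))
            continue
        hits = {
            strand
            for chrom, lo, hi, strand in spans
            if chrom == key.chrom and lo <= key.start and key.end <= hi
        }
        if len(hits) == 1:
            resolved.append(key._replace(strand=hits.pop()))
        else:
            logger.warning("dropping junction %s: strand unresolvable", key)
    if conflicts:
        raise ValueError(
            "strand contradicts annotation for junctions: "
            + ", ".join(map(str, conflicts))
        )
    return resolved


def build_anchor_groups(
    junctions: Iterable[JunctionRecord | JunctionKey],
    annotation: ToyAnnotation,
) -> list[AnchorGroup]:
    """Group junctions at shared donor/acceptor sites.

    A group is emitted for every site shared by >= 2 junctions, or held
    by a single junction when the site belongs to an annotated intron.
    ``canonical_member`` is the member exactly matching an annotated
    intron (smallest coordinates if several transcripts tie).
    """
    keys = sorted(
        {r.key if isinstance(r, JunctionRecord) else r for r in junctions}
    )
    keys = resolve_strands(keys, annotation)
    introns = annotation.annotated_introns()

    annotated_sites: set[Anchor] = set()
    for (chrom, s, e), strand in introns.items():
        k = JunctionKey(chrom, s, e, strand)
        annotated_sites.add(donor_site(k))
        annotated_sites.add(acceptor_site(k))

    by_site: dict[Anchor, list[JunctionKey]] = {}
    for key in keys:
        for site in (donor_site(key), acceptor_site(key)):
            by_site.setdefault(site, []).append(key)

    groups: list[AnchorGroup] = []
    for site in sorted(by_site):
        members = sorted(by_site[site])
        if len(members) < 2 and site not in annotated_sites:
            continue
        canonical = sorted(
            m for m in members if (m.chrom, m.start, m.end) in introns
        )
        groups.append(AnchorGroup(site, members, canonical[0] if canonical else None))
    return groups


# ---------------------------------------------------------------------------
# PSI

@dataclass
class PsiMatrix:
    """Junction x sample PSI values with the coverage filter applied.

    ``psi`` holds fractions in [0, 1] with NaN for cells masked by the
    coverage filter; ``total`` holds the anchor-group denominator that
    produced each cell; ``home_anchor`` records the anchor at which each
    junction was quantified.
    """

    psi: pd.DataFrame
    total: pd.DataFrame
    home_anchor: dict[JunctionKey, Anchor] = field(default_factory=dict)
    groups: list[AnchorGroup] = field(default_factory=list)

    @property
    def junctions(self) -> list[JunctionKey]:
        return [JunctionKey(*idx) for idx in self.psi.index]

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    def to_tsv(self, path: str | os.PathLike, header: str | None = None) -> None:
        out = self.psi.copy()
        out.index = pd.MultiIndex.from_tuples(
            self.psi.index, names=["chrom", "intron_start", "intron_end", "strand"]
        )
        with open(path, "w") as fh:
            if header:
                fh.write(f"#{header}\n")
            out.reset_index().to_csv(fh, sep="\t", index=False, na_rep="NA")


def counts_frame(records: Iterable[JunctionRecord]) -> pd.DataFrame:
    """Pivot records into a junction x sample unique-count matrix.

    A junction absent from a sample's table has count 0 there.
    """
    rows = [
        (r.chrom, r.intron_start, r.intron_end, r.strand, r.sample_id, r.unique_count)
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "intron_start", "intron_end", "strand", "sample_id", "count"],
    )
    if df.empty:
        return pd.DataFrame()
    wide = (
        df.groupby(["chrom", "intron_start", "intron_end", "strand", "sample_id"])[
            "count"
        ]
        .sum()
        .unstack("sample_id", fill_value=0)
        .sort_index()
    )
    wide.columns.name = None
    return wide


def _home_group(
    key: JunctionKey, by_anchor: dict[Anchor, AnchorGroup]
) -> AnchorGroup | None:
    donor = by_anchor.get(donor_site(key))
    acceptor = by_anchor.get(acceptor_site(key))
    # prefer the side holding the canonical partner; donor wins ties
    # (the dominant cryptic class is the alternative 3' acceptor)
    for g in (donor, acceptor):
        if g is not None and g.canonical_member is not None:
            return g
    return donor or acceptor


def compute_psi(
    groups: list[AnchorGroup],
    counts: pd.DataFrame,
    config: QuantConfig = QuantConfig(),
) -> PsiMatrix:
    """PSI per junction at its home anchor group.

    PSI(j, s) = count(j, s) / sum of member counts at j's anchor in s;
    the whole anchor is masked (NaN) in samples where that total is
    below ``config.min_coverage``.
    """
    by_anchor = {g.anchor: g for g in groups}
    for g in groups:
        if not g.members:
            raise RuntimeError(f"anchor group {g.anchor} has no members (construction bug)")

    def row(key: JunctionKey) -> pd.Series:
        return (
            counts.loc[tuple(key)]
            if tuple(key) in counts.index
            else pd.Series(0, index=counts.columns)
        )

    quantified = [
        key
        for g in groups
        for key in g.members
        if _home_group(key, by_anchor) is g
    ]
    quantified = sorted(set(quantified))
    samples = list(counts.columns)
    psi = pd.DataFrame(np.nan, index=pd.Index(quantified), columns=samples)
    total = pd.DataFrame(0, index=pd.Index(quantified), columns=samples, dtype=int)
    group_tot: dict[Anchor, pd.Series] = {
        g.anchor: sum((row(m) for m in g.members), pd.Series(0, index=samples))
        for g in groups
    }
    for key in quantified:
        g = _home_group(key, by_anchor)
        tot = group_tot[g.anchor]
        ok = tot >= config.min_coverage
        vals = row(key).astype(float) / tot.where(tot > 0)
        psi.loc[[key]] = vals.where(ok).to_numpy()
        total.loc[[key]] = tot.to_numpy()
    home = {k: _home_group(k, by_anchor).anchor for k in quantified}
    return PsiMatrix(psi=psi, total=total, home_anchor=home, groups=groups)
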