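"""Gene-annotation handling: GTF parsing, intron inference, overlap filters.

Introns are not annotated explicitly in GENCODE/Ensembl GTFs; they are the
gaps between consecutive exons of a transcript. This module parses exon
features, infers introns per transcript, collapses coordinate-identical
introns of the same gene across isoforms, attaches the two splice junctions
(5' = transcription-upstream, oriented by gene strand), and applies the
tiered overlap filters:

level 1  keep every intron;
level 2  drop introns whose splice junctions overlap an exon of a
         *different* gene;
level 3  additionally drop introns whose body overlaps *any* exon,
         including other isoforms of the same gene.

All coordinates here are GTF-style: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .errors import AnnotationParseError, ConfigError, InputError

logger = logging.getLogger("sefq")

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    gene_id: str
    transcript_id: str
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SpliceJunction:
    """One exon|intron boundary.

    ``exon_base`` is the genomic position of the last exonic base adjacent
    to the intron and ``intron_base`` the first intronic base next to it;
    the two are always adjacent. ``side`` is '5' or '3' relative to the
    direction of transcription.
    """

    side: str        # '5' or '3'
    exon_base: int
    intron_base: int

    def __post_init__(self) -> None:
        if abs(self.exon_base - self.intron_base) != 1:
            raise ValueError("junction bases must be adjacent")
        if self.side not in ("5", "3"):
            raise ValueError(f"invalid junction side {self.side!r}")

    @property
    def is_intron_start(self) -> bool:
        """True when intron_base is the lower-coordinate end of the intron."""
        return self.exon_base < self.intron_base


@dataclass(frozen=True)
class Intron:
    """A collapsed intronic interval of one gene.

    ``start``/``end`` are the first and last intronic base (1-based,
    inclusive). ``flank_left``/``flank_right`` are the exonic intervals
    immediately adjacent in coordinate order, each the union of the
    adjacent exons over all supporting transcripts (they share the
    junction-side endpoint by construction, so the union is an interval).
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: frozenset
    gene_name: Optional[str] = None
    flank_left: Optional[Tuple[int, int]] = None
    flank_right: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("intron start > end")
        if not self.transcript_ids:
            raise ValueError("intron must have supporting transcripts")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def sj5(self) -> SpliceJunction:
        """Donor-side junction: at the intron start for '+' genes, at the
        intron end for '-' genes."""
        if self.strand == "+":
            return SpliceJunction("5", self.start - 1, self.start)
        return SpliceJunction("5", self.end + 1, self.end)

    @property
    def sj3(self) -> SpliceJunction:
        if self.strand == "+":
            return SpliceJunction("3", self.end + 1, self.end)
        return SpliceJunction("3", self.start - 1, self.start)

    @property
    def junctions(self) -> Tuple[SpliceJunction, SpliceJunction]:
        return (self.sj5, self.sj3)

    def sort_key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.gene_id)


VALID_LEVELS = (1, 2, 3)


class GeneAnnotation:
    """Exons grouped by transcript and gene, as parsed from a GTF."""

    def __init__(self, exons: Sequence[Exon]):
        self.exons: List[Exon] = list(exons)
        self.transcripts: Dict[str, List[Exon]] = {}
        self.transcript_gene: Dict[str, str] = {}
        self.genes: Dict[str, List[str]] = {}
        for ex in self.exons:
            self.transcripts.setdefault(ex.transcript_id, []).append(ex)
            self.transcript_gene[ex.transcript_id] = ex.gene_id
            tids = self.genes.setdefault(ex.gene_id, [])
            if ex.transcript_id not in tids:
                tids.append(ex.transcript_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def chromosomes(self) -> List[str]:
        return sorted({ex.chrom for ex in self.exons})


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

# `key "value";` (GENCODE/Ensembl) or unquoted `key value;`, with arbitrary
# spacing around the separator.
_ATTR_RE = re.compile(r'\s*(\S+)\s+(?:"([^"]*)"|([^;\s]+))\s*')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        if not chunk.strip():
            continue
        m = _ATTR_RE.match(chunk)
        if m is None:
            continue
        key = m.group(1)
        value = m.group(2) if m.group(2) is not None else m.group(3)
        # first occurrence wins (GTF tag duplication, e.g. multiple 'tag')
        attrs.setdefault(key, value)
    return attrs


def parse_annotation(gtf_path: str) -> GeneAnnotation:
    """Parse exon features from a GTF file (plain or gzip).

    Non-exon feature lines are ignored. Both GENCODE and Ensembl attribute
    dialects are accepted. Raises :class:`InputError` for a missing file,
    :class:`AnnotationParseError` (naming the line number) for an exon line
    lacking gene_id/transcript_id, and an "empty annotation" error when no
    exon feature is present.
    """
    opener = gzip.open if str(gtf_path).endswith(".gz") else open
    exons: List[Exon] = []
    try:
        handle = opener(gtf_path, "rt")
    except OSError as exc:
        raise InputError(f"cannot open annotation file {gtf_path!r}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[6]
            if strand not in STRANDS:
                raise AnnotationParseError(
                    f"{gtf_path}: line {lineno}: invalid strand {strand!r}"
                )
            attrs = _parse_attributes(fields[8])
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationParseError(
                    f"{gtf_path}: line {lineno}: exon feature lacks "
                    "gene_id/transcript_id attribute"
                )
            exons.append(
                Exon(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=attrs["gene_id"],
                    transcript_id=attrs["transcript_id"],
                    gene_name=attrs.get("gene_name"),
                )
            )
    if not exons:
        raise AnnotationParseError(f"{gtf_path}: empty annotation (no exon features)")
    logger.info(
        "parsed %d exons, %d transcripts, %d genes from %s",
        len(exons), len({e.transcript_id for e in exons}),
        len({e.gene_id for e in exons}), gtf_path,
    )
    return GeneAnnotation(exons)


# ---------------------------------------------------------------------------
# Intron inference
# ---------------------------------------------------------------------------

def infer_introns(annotation: GeneAnnotation) -> List[Intron]:
    """Infer introns as inter-exon gaps, collapsed across isoforms.

    For each transcript the exons are sorted by start; each gap between
    consecutive exons becomes an intron [prev.end+1, next.start-1]. Introns
    identical in (chrom, start, end, strand, gene_id) are collapsed into a
    single record carrying the union of supporting transcript ids and the
    union flanking-exon intervals. Transcripts with internally overlapping
    exons are skipped with a warning; single-exon transcripts simply
    contribute nothing. The result is sorted by (chrom, start, end, gene_id).
    """
    collected: Dict[Tuple[str, int, int, str, str], dict] = {}
    for tid, exons in annotation.transcripts.items():
        ordered = sorted(exons, key=lambda e: (e.start, e.end))
        if any(a.end >= b.start for a, b in zip(ordered, ordered[1:])):
            logger.warning(
                "transcript %s has overlapping exons; skipping it", tid
            )
            continue
        for left, right in zip(ordered, ordered[1:]):
            start, end = left.end + 1, right.start - 1
            if start > end:  # abutting exons, zero-length gap
                continue
            key = (left.chrom, start, end, left.strand, left.gene_id)
            rec = collected.setdefault(
                key,
                {
                    "tids": set(),
                    "left": [],
                    "right": [],
                    "gene_name": left.gene_name,
                },
            )
            rec["tids"].add(tid)
            rec["left"].append((left.start, left.end))
            rec["right"].append((right.start, right.end))
    introns = [
        Intron(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            gene_id=gene_id,
            transcript_ids=frozenset(rec["tids"]),
            gene_name=rec["gene_name"],
            flank_left=(min(s for s, _ in rec["left"]), start - 1),
            flank_right=(end + 1, max(e for _, e in rec["right"])),
        )
        for (chrom, start, end, strand, gene_id), rec in collected.items()
    ]
    introns.sort(key=Intron.sort_key)
    return introns


# ---------------------------------------------------------------------------
# Overlap filters
# ---------------------------------------------------------------------------

def _exon_trees(annotation: GeneAnnotation) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for ex in annotation.exons:
        tree = trees.setdefault(ex.chrom, IntervalTree())
        # half-open for intervaltree
        tree.addi(ex.start, ex.end + 1, (ex.gene_id, ex.strand))
    return trees


def _junction_conflict(
    intron: Intron, tree: IntervalTree, stranded: bool
) -> bool:
    """Does either 2-base junction window touch an exon of another gene?"""
    for lo, hi in ((intron.start - 1, intron.start), (intron.end, intron.end + 1)):
        for hit in tree.overlap(lo, hi + 1):
            gene_id, strand = hit.data
            if gene_id == intron.gene_id:
                continue
            if stranded and strand != intron.strand:
                continue
            return True
    return False


def _body_conflict(intron: Intron, tree: IntervalTree, stranded: bool) -> bool:
    """Does the intron body [start, end] intersect any exon at all?"""
    for hit in tree.overlap(intron.start, intron.end + 1):
        _, strand = hit.data
        if stranded and strand != intron.strand:
            continue
        return True
    return False


def filter_by_level(
    introns: Iterable[Intron],
    annotation: GeneAnnotation,
    level: int,
    stranded: bool = True,
) -> List[Intron]:
    """Apply one of the three restrictiveness levels.

    Level 1 keeps everything. Level 2 drops introns whose junction windows
    (the exon_base/intron_base pair at either end) overlap an exon of a
    different gene. Level 3 drops, in addition, introns whose body overlaps
    any exon — including other isoforms of the intron's own gene; adjacent
    flanking exons end exactly at the junction and never intersect the body.
    Level 3 retains the level-2 junction condition so the levels are nested
    for every annotation.

    With ``stranded`` (the default, appropriate for strand-specific
    libraries) only same-strand exons create a conflict.
    """
    introns = list(introns)
    if level not in VALID_LEVELS:
        raise ConfigError(f"invalid restrictiveness level {level!r}; must be 1, 2 or 3")
    if level == 1:
        return introns
    trees = _exon_trees(annotation)
    kept: List[Intron] = []
    for intron in introns:
        tree = trees.get(intron.chrom)
        if tree is None:
            kept.append(intron)
            continue
        if _junction_conflict(intron, tree, stranded):
            continue
        if level == 3 and _body_conflict(intron, tree, stranded):
            continue
        kept.append(intron)
    return kept


def filter_by_length(introns: Iterable[Intron], min_length: int) -> List[Intron]:
    """Keep introns with length >= ``min_length`` bases (inclusive bound)."""
    if min_length < 0:
        raise ConfigError(f"min_length must be >= 0, got {min_length}")
    return [i for i in introns if i.length >= min_length]
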