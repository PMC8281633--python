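"""Junction read counting and per-base coverage from a sorted, indexed BAM.

A *split* read carries a reference-skip gap (CIGAR N) whose intron-side
boundary coincides exactly with a junction's first/last intronic base; the
gap's other end may land anywhere, so reads documenting the excision of
more than one intron (exon skipping) still count as split for each intron
whose boundary they match. An *unsplit* read covers both the exonic and the
intronic base of a junction with contiguous aligned match bases (a deletion
at the boundary breaks contiguity and disqualifies the read).

CIGAR interpretation follows the SAM specification: M/=/X consume the
reference as aligned match, D consumes the reference without providing
coverage, N is a splice gap, I/S consume only the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from intervaltree import IntervalTree

from .annotation import Intron, SpliceJunction
from .errors import ConfigError, InputError

logger = logging.getLogger("sefq")

PROTOCOLS = ("forward", "reverse", "unstranded")

_OP_MATCH = frozenset((0, 7, 8))  # M, =, X
_OP_DEL = 2
_OP_SKIP = 3


# ---------------------------------------------------------------------------
# Read filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadFilterConfig:
    """Which alignment records participate in counting and coverage.

    A read is *uniquely mapped* when its NH tag equals 1; records without
    an NH tag fall back to ``mapq >= mapq_min``. Secondary, supplementary,
    duplicate and QC-fail records are always dropped when the respective
    flag is set. ``protocol`` names the library strandedness: in a
    reverse-stranded (dUTP-style) protocol a single-end read or first mate
    maps to the strand opposite the transcript; forward-stranded is the
    mirror image; unstranded disables strand matching.
    """

    unique_only: bool = True
    mapq_min: int = 30
    protocol: str = "reverse"
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = True
    exclude_qcfail: bool = True
    min_overhang: int = 1

    def __post_init__(self) -> None:
        if self.mapq_min < 0:
            raise ConfigError("mapq_min must be >= 0")
        if self.protocol not in PROTOCOLS:
            raise ConfigError(
                f"unknown protocol {self.protocol!r}; choose from {PROTOCOLS}"
            )
        if self.min_overhang < 1:
            raise ConfigError("min_overhang must be >= 1")


def read_passes_filter(read: "pysam.AlignedSegment", cfg: ReadFilterConfig) -> bool:
    if read.is_unmapped:
        return False
    if cfg.exclude_secondary and read.is_secondary:
        return False
    if cfg.exclude_supplementary and read.is_supplementary:
        return False
    if cfg.exclude_duplicates and read.is_duplicate:
        return False
    if cfg.exclude_qcfail and read.is_qcfail:
        return False
    if cfg.unique_only:
        if read.has_tag("NH"):
            if read.get_tag("NH") != 1:
                return False
        elif read.mapping_quality < cfg.mapq_min:
            return False
    return True


def read_transcript_strand(
    read: "pysam.AlignedSegment", protocol: str
) -> Optional[str]:
    """Strand of the transcript a read derives from, or None if unknowable.

    Mate-aware: in paired data the second mate reports the opposite of the
    first. Returns None for the unstranded protocol (matches everything).
    """
    if protocol == "unstranded":
        return None
    sense = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        sense = "-" if sense == "+" else "+"
    if protocol == "reverse":
        sense = "-" if sense == "+" else "+"
    return sense


# ---------------------------------------------------------------------------
# CIGAR geometry
# ---------------------------------------------------------------------------

def reference_layout(
    read: "pysam.AlignedSegment",
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Match blocks and skip gaps of a read in 1-based inclusive coordinates.

    Blocks are maximal runs of M/=/X bases; a deletion splits blocks (it
    consumes reference but yields no coverage). Gaps are the N intervals.
    """
    blocks: List[Tuple[int, int]] = []
    gaps: List[Tuple[int, int]] = []
    pos = read.reference_start + 1  # to 1-based
    for op, length in read.cigartuples or ():
        if op in _OP_MATCH:
            if blocks and blocks[-1][1] == pos - 1:
                blocks[-1] = (blocks[-1][0], pos + length - 1)
            else:
                blocks.append((pos, pos + length - 1))
            pos += length
        elif op == _OP_DEL:
            pos += length
        elif op == _OP_SKIP:
            gaps.append((pos, pos + length - 1))
            pos += length
        # I (1), S (4), H (5), P (6): no reference advance
    return blocks, gaps


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class JunctionCounts:
    """Split (S) and unsplit (N) read tallies at the two junctions."""

    S5: int = 0
    S3: int = 0
    N5: int = 0
    N3: int = 0

    def add(self, side: str, category: str) -> None:
        attr = ("S" if category == "split" else "N") + side
        setattr(self, attr, getattr(self, attr) + 1)

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.S5, self.N5, self.S3, self.N3)


def classify_read_at_junction(
    read: "pysam.AlignedSegment",
    junction: SpliceJunction,
    intron: Intron,
    min_overhang: int = 1,
) -> str:
    """Classify one read at one splice junction: 'split', 'unsplit' or 'none'.

    Split: some reference-skip gap starts at the intron's first base (for
    the lower-coordinate junction) or ends at its last base (for the
    higher-coordinate junction); the gap's other end is unconstrained.
    Unsplit: one contiguous match block covers both junction bases with at
    least ``min_overhang`` aligned bases on each side.
    """
    try:
        blocks, gaps = reference_layout(read)
    except (TypeError, ValueError):
        logger.warning("malformed CIGAR for read %s; skipped", read.query_name)
        return "none"
    if junction.is_intron_start:
        if any(g_start == junction.intron_base for g_start, _ in gaps):
            return "split"
    else:
        if any(g_end == junction.intron_base for _, g_end in gaps):
            return "split"
    lo = min(junction.exon_base, junction.intron_base)
    hi = lo + 1
    for b_start, b_end in blocks:
        if (
            b_start <= lo - (min_overhang - 1)
            and b_end >= hi + (min_overhang - 1)
            and b_start <= lo
            and b_end >= hi
        ):
            return "unsplit"
    return "none"


# ---------------------------------------------------------------------------
# Counting over a BAM
# ---------------------------------------------------------------------------

def _junction_tree(
    introns: Sequence[Intron],
) -> Dict[str, IntervalTree]:
    """Interval tree of 2-base junction windows, per chromosome."""
    trees: Dict[str, IntervalTree] = {}
    for idx, intron in enumerate(introns):
        tree = trees.setdefault(intron.chrom, IntervalTree())
        for junction in intron.junctions:
            lo = min(junction.exon_base, junction.intron_base)
            tree.addi(lo, lo + 2, (idx, junction))
    return trees


def count_junction_reads(
    bam: "pysam.AlignmentFile",
    introns: Sequence[Intron],
    cfg: ReadFilterConfig,
    chrom_map: Optional[Mapping[str, str]] = None,
) -> Dict[Intron, JunctionCounts]:
    """Tally split/unsplit reads at both junctions of every intron.

    Each retained read is classified at every junction whose window its
    reference span (including gaps) overlaps; a read spanning both
    junctions of an intron contributes to both tallies. ``chrom_map``
    translates annotation chromosome names to BAM reference names.
    Chromosomes absent from the BAM header yield zero counts with a
    warning.
    """
    introns = list(introns)
    counts: Dict[Intron, JunctionCounts] = {i: JunctionCounts() for i in introns}
    trees = _junction_tree(introns)
    bam_refs = set(bam.references)
    for chrom, tree in trees.items():
        ref = (chrom_map or {}).get(chrom, chrom)
        if ref not in bam_refs:
            logger.warning(
                "chromosome %s absent from alignment header; counts left at 0", chrom
            )
            continue
        lo = min(iv.begin for iv in tree) - 1
        hi = max(iv.end for iv in tree) + 1
        for read in bam.fetch(ref, max(0, lo - 1), hi):
            if not read_passes_filter(read, cfg):
                continue
            strand = read_transcript_strand(read, cfg.protocol)
            span_lo = read.reference_start + 1
            span_hi = read.reference_end  # 1-based inclusive end
            for hit in tree.overlap(span_lo, span_hi + 1):
                idx, junction = hit.data
                intron = introns[idx]
                if strand is not None and strand != intron.strand:
                    continue
                category = classify_read_at_junction(
                    read, junction, intron, cfg.min_overhang
                )
                if category != "none":
                    counts[intron].add(junction.side, category)
    return counts


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageStats:
    """Median per-base depths of an intron body and its flanking exons.

    ``exon5_median``/``exon3_median`` follow coordinate order (left/right
    flank), matching the symmetric role they play in the expression-ratio
    denominator.
    """

    intron_median: float
    exon5_median: float
    exon3_median: float


def interval_depth(
    bam: "pysam.AlignmentFile",
    ref: str,
    start: int,
    end: int,
    cfg: ReadFilterConfig,
    strand: Optional[str] = None,
) -> np.ndarray:
    """Per-base depth over [start, end] (1-based inclusive) from aligned
    match bases of reads passing the filter; gaps and deletions contribute
    zero. ``strand`` restricts to reads of that transcript strand."""
    depth = np.zeros(end - start + 1, dtype=np.int64)
    if ref not in set(bam.references):
        return depth
    for read in bam.fetch(ref, start - 1, end):
        if not read_passes_filter(read, cfg):
            continue
        if strand is not None:
            read_strand = read_transcript_strand(read, cfg.protocol)
            if read_strand is not None and read_strand != strand:
                continue
        blocks, _ = reference_layout(read)
        for b_start, b_end in blocks:
            lo = max(b_start, start)
            hi = min(b_end, end)
            if lo <= hi:
                depth[lo - start : hi - start + 1] += 1
    return depth


def compute_coverage_stats(
    bam: "pysam.AlignmentFile",
    intron: Intron,
    flanking_exons: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None,
    cfg: ReadFilterConfig = ReadFilterConfig(),
    chrom_map: Optional[Mapping[str, str]] = None,
) -> CoverageStats:
    """Median per-base coverage of the intron body and both flanking exons.

    Medians are taken over every base of each interval, zero-depth bases
    included. Flanking intervals default to the ones recorded on the
    intron at inference time.
    """
    if flanking_exons is None:
        if intron.flank_left is None or intron.flank_right is None:
            raise ValueError("intron carries no flanking-exon intervals")
        flanking_exons = (intron.flank_left, intron.flank_right)
    for lo, hi in flanking_exons:
        if hi < lo:
            raise ValueError("zero-length flanking exon interval")
    ref = (chrom_map or {}).get(intron.chrom, intron.chrom)
    strand = intron.strand if cfg.protocol != "unstranded" else None
    medians = []
    for lo, hi in ((intron.start, intron.end), flanking_exons[0], flanking_exons[1]):
        depth = interval_depth(bam, ref, lo, hi, cfg, strand)
        medians.append(float(np.median(depth)))
    return CoverageStats(*medians)
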