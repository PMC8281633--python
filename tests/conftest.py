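"""Shared builders: in-memory reads, tiny BAM files, randomized annotations,
and the brute-force overlap-filter oracle."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
import pytest

from sefq.annotation import Exon, GeneAnnotation


DEFAULT_HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1_000_000}]}


def make_header(lengths: Optional[Dict[str, int]] = None) -> pysam.AlignmentHeader:
    if lengths is None:
        return pysam.AlignmentHeader.from_dict(DEFAULT_HEADER)
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": k, "LN": v} for k, v in sorted(lengths.items())]}
    )


def make_read(
    blocks: Sequence[Tuple[int, int]],
    gaps: Sequence[Tuple[int, int]] = (),
    deletions: Sequence[Tuple[int, int]] = (),
    name: str = "read1",
    chrom: str = "chr1",
    is_reverse: bool = False,
    mapq: int = 60,
    nh: Optional[int] = 1,
    header: Optional[pysam.AlignmentHeader] = None,
    **flags,
) -> pysam.AlignedSegment:
    """Build an aligned read from 1-based inclusive match blocks plus
    optional skip gaps (N) and deletions (D)."""
    header = header or make_header()
    rd = pysam.AlignedSegment(header)
    rd.query_name = name
    rd.reference_id = header.get_tid(chrom)
    events = sorted(
        [(lo, hi, 0) for lo, hi in blocks]
        + [(lo, hi, 3) for lo, hi in gaps]
        + [(lo, hi, 2) for lo, hi in deletions]
    )
    rd.reference_start = events[0][0] - 1
    rd.cigartuples = [(op, hi - lo + 1) for lo, hi, op in events]
    qlen = sum(hi - lo + 1 for lo, hi, op in events if op == 0)
    rd.query_sequence = "A" * qlen
    rd.mapping_quality = mapq
    rd.is_reverse = is_reverse
    if nh is not None:
        rd.set_tag("NH", nh)
    for key, value in flags.items():
        setattr(rd, key, value)
    return rd


def write_bam(path, reads: Sequence[pysam.AlignedSegment],
              header: Optional[pysam.AlignmentHeader] = None) -> str:
    header = header or make_header()
    ordered = sorted(reads, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rd in ordered:
            bam.write(rd)
    pysam.index(str(path))
    return str(path)


# ---------------------------------------------------------------------------
# Randomized toy annotations and the brute-force level oracle
# ---------------------------------------------------------------------------


def random_annotation(rng: np.random.Generator, max_genes: int = 4) -> GeneAnnotation:
    """Small annotation with random exon structures; genes may overlap each
    other (both strands) to exercise the restrictiveness filters."""
    exons: List[Exon] = []
    n_genes = int(rng.integers(1, max_genes + 1))
    for g in range(n_genes):
        gene_id = f"G{g}"
        strand = "+" if rng.random() < 0.7 else "-"
        n_tx = int(rng.integers(1, 3))
        gene_start = int(rng.integers(1, 2000))
        for t in range(n_tx):
            pos = gene_start + int(rng.integers(0, 200))
            n_exons = int(rng.integers(1, 5))
            for _ in range(n_exons):
                elen = int(rng.integers(10, 120))
                exons.append(Exon("chr1", pos, pos + elen - 1, strand,
                                  gene_id, f"G{g}.t{t}"))
                pos += elen + int(rng.integers(20, 300))
    return GeneAnnotation(exons)


def _intersects(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 <= b1 and b0 <= a1


def brute_force_level_filter(introns, annotation: GeneAnnotation, level: int,
                             stranded: bool = True):
    """All-pairs interval-intersection reference for the level filters."""
    if level == 1:
        return list(introns)
    kept = []
    for intron in introns:
        junction_hit = False
        body_hit = False
        for ex in annotation.exons:
            if ex.chrom != intron.chrom:
                continue
            if stranded and ex.strand != intron.strand:
                continue
            if ex.gene_id != intron.gene_id and (
                _intersects(ex.start, ex.end, intron.start - 1, intron.start)
                or _intersects(ex.start, ex.end, intron.end, intron.end + 1)
            ):
                junction_hit = True
            if _intersects(ex.start, ex.end, intron.start, intron.end):
                body_hit = True
        if junction_hit or (level == 3 and body_hit):
            continue
        kept.append(intron)
    return kept


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
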