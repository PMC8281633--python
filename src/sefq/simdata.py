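"""Seeded synthetic fixtures: a toy GTF plus an aligned-read BAM with a
known, per-intron spliced fraction.

The generator emulates strand-specific RNA-seq over a small multi-gene
annotation. Each intron is assigned a true spliced fraction ``f`` and a
junction read depth ``n``. Reads are emitted per *fragment*, mirroring the
molecule picture behind junction counting: a spliced molecule exposes a
single junction-crossing site (the ligated exon-exon boundary), so a
spliced fragment yields one split read whose gap is exactly the intron and
which is therefore counted at both junctions; an unspliced molecule
exposes two intron-exon boundaries, so an unspliced fragment yields one
unsplit read at each junction. Drawing ``n`` fragments per intron with
splice probability ``f`` then gives exactly ``n`` junction-informative
reads at each junction and an expected splicing efficiency of ``f``.

Exon and intron bodies are additionally tiled with contiguous match reads
at configurable uniform depths (intron depth defaults to
``round(exon_depth * (1 - f))``, the coverage an unspliced fraction of
``1 - f`` molecules would leave behind), so expression-ratio scores are
informative and track ``f``. Optional opposite-strand contaminant reads
exercise the strand filter.

Every read's reference layout (match blocks, skip gaps, transcript
strand) is recorded at generation time; :func:`oracle_counts` re-derives
junction tallies from that bookkeeping with a naive double loop, giving a
bitwise reference for the BAM-based counting path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .annotation import Intron
from .counting import JunctionCounts
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptLayout:
    """One transcript: alternating exon/intron lengths from ``start``.

    Multi-isoform genes are expressed as several layouts sharing a
    ``gene_id``. ``spliced_fractions`` gives the true f per intron (one
    value per gap, ignored when the transcript has a single exon).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    exon_lengths: Tuple[int, ...]
    spliced_fractions: Tuple[float, ...] = ()
    intron_lengths: Tuple[int, ...] = ()
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ConfigError("transcript start must be >= 1")
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise ConfigError("exon/intron lengths must be positive")
        n_gaps = len(self.exon_lengths) - 1
        if len(self.intron_lengths) != n_gaps:
            raise ConfigError(
                f"{self.transcript_id}: need {n_gaps} intron lengths, "
                f"got {len(self.intron_lengths)}"
            )
        if len(self.spliced_fractions) != n_gaps:
            raise ConfigError(
                f"{self.transcript_id}: need {n_gaps} spliced fractions"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.spliced_fractions):
            raise ConfigError("spliced fractions must lie in [0, 1]")

    @property
    def exons(self) -> List[Tuple[int, int]]:
        out, pos = [], self.start
        for i, elen in enumerate(self.exon_lengths):
            out.append((pos, pos + elen - 1))
            pos += elen
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return out

    @property
    def introns(self) -> List[Tuple[int, int]]:
        ex = self.exons
        return [(a[1] + 1, b[0] - 1) for a, b in zip(ex, ex[1:])]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic dataset."""

    transcripts: Tuple[TranscriptLayout, ...]
    seed: int = 0
    junction_depth: int = 200
    exon_depth: int = 30
    intron_depth: Optional[int] = None  # None -> round(exon_depth * (1 - f))
    read_length: int = 80
    min_anchor: int = 8
    protocol: str = "reverse"
    paired: bool = False
    contaminants_per_junction: int = 0

    def __post_init__(self) -> None:
        if self.junction_depth < 0 or self.exon_depth < 0:
            raise ConfigError("depths must be >= 0")
        if self.read_length < 2 * self.min_anchor:
            raise ConfigError("read length too short for the junction anchors")


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """Reference layout of one emitted read, 1-based inclusive."""

    name: str
    chrom: str
    tx_strand: Optional[str]  # transcript strand the read reports, None=unstranded
    blocks: Tuple[Tuple[int, int], ...]
    gaps: Tuple[Tuple[int, int], ...]
    category: str  # 'split' | 'unsplit' | 'body' | 'contaminant' | 'mate'


@dataclass(frozen=True)
class IntronTruth:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    f: float
    flank_left: Tuple[int, int]
    flank_right: Tuple[int, int]

    @property
    def key(self) -> Tuple[str, int, int, str, str]:
        return (self.chrom, self.start, self.end, self.strand, self.gene_id)


@dataclass
class SimTruth:
    spec: SimSpec
    introns: List[IntronTruth]
    reads: List[ReadRecord]


@dataclass(frozen=True)
class SimFixture:
    gtf_path: str
    bam_path: str
    truth_path: str
    truth: SimTruth


# ---------------------------------------------------------------------------
# Convenience layouts
# ---------------------------------------------------------------------------


def graded_transcripts(
    fractions: Sequence[float],
    n_genes: int = 1,
    chrom: str = "chr1",
    exon_length: int = 200,
    intron_length: int = 300,
    gap: int = 5000,
    strand: str = "+",
    prefix: str = "G",
) -> Tuple[TranscriptLayout, ...]:
    """``n_genes`` single-isoform genes, each with one intron per requested
    fraction; genes are spaced ``gap`` bases apart."""
    out = []
    pos = 1000
    for g in range(n_genes):
        n_introns = len(fractions)
        out.append(
            TranscriptLayout(
                gene_id=f"{prefix}{g + 1}",
                transcript_id=f"{prefix}{g + 1}.t1",
                chrom=chrom,
                strand=strand,
                start=pos,
                exon_lengths=(exon_length,) * (n_introns + 1),
                intron_lengths=(intron_length,) * n_introns,
                spliced_fractions=tuple(fractions),
                gene_name=f"gene{g + 1}",
            )
        )
        pos = out[-1].end + gap
    return tuple(out)


def overlap_transcripts() -> Tuple[Tuple[TranscriptLayout, ...], Dict[str, set]]:
    """Annotation layouts with known restrictiveness-level membership.

    Returns the layouts plus the expected set of intron keys
    (chrom, start, end, strand, gene_id) surviving each level.
    """
    # gene A: clean two-intron gene
    a = TranscriptLayout("GA", "GA.t1", "chr1", "+", 1000,
                         (200, 200, 200), (0.5, 0.5), (300, 300))
    # gene B: exon straddling gene A's second intron's downstream junction
    a_introns = a.introns
    j3 = a_introns[1][1]  # last base of A's intron 2
    b = TranscriptLayout("GB", "GB.t1", "chr1", "+", j3 - 49,
                         (150,), (), ())
    # gene C isoform 1: one intron; isoform 2 retains it as exonic sequence
    c1 = TranscriptLayout("GC", "GC.t1", "chr1", "+", 20000,
                          (200, 200), (0.5,), (300,))
    c2 = TranscriptLayout("GC", "GC.t2", "chr1", "+", 20000,
                          (700,), (), ())
    keys = {
        "A1": ("chr1", a.introns[0][0], a.introns[0][1], "+", "GA"),
        "A2": ("chr1", a.introns[1][0], a.introns[1][1], "+", "GA"),
        "C1": ("chr1", c1.introns[0][0], c1.introns[0][1], "+", "GC"),
    }
    expected = {
        "level1": {keys["A1"], keys["A2"], keys["C1"]},
        "level2": {keys["A1"], keys["C1"]},          # A2's junction hits GB's exon
        "level3": {keys["A1"]},                      # C1's body hits GC.t2's exon
    }
    return (a, b, c1, c2), expected


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def _is_reverse_flag(tx_strand: str, protocol: str, mate: int) -> bool:
    """SAM reverse flag for a read reporting transcript strand ``tx_strand``
    under the given protocol; ``mate`` is 1 or 2."""
    if protocol == "reverse":
        rev = tx_strand == "+"
    else:  # forward or unstranded (emit forward-stranded geometry)
        rev = tx_strand == "-"
    if mate == 2:
        rev = not rev
    return rev


class _Emitter:
    def __init__(self, spec: SimSpec):
        self.spec = spec
        self.reads: List[ReadRecord] = []
        self.segments: List[dict] = []
        self._n = 0

    def emit(
        self,
        chrom: str,
        tx_strand: str,
        blocks: Sequence[Tuple[int, int]],
        gaps: Sequence[Tuple[int, int]],
        category: str,
        flip_strand: bool = False,
        mate: int = 0,
        mate_of: Optional[int] = None,
    ) -> int:
        """Record one read; returns its index. ``flip_strand`` emits the
        read with flags reporting the opposite transcript strand
        (contaminants). ``mate`` 1/2 marks paired records."""
        self._n += 1
        if mate_of is not None:
            name = self.segments[mate_of]["name"]
        else:
            name = f"r{self._n:07d}" if mate == 0 else f"p{self._n:07d}"
        reported = tx_strand
        if flip_strand:
            reported = "-" if tx_strand == "+" else "+"
        effective = None if self.spec.protocol == "unstranded" else reported
        self.reads.append(
            ReadRecord(
                name=name,
                chrom=chrom,
                tx_strand=effective,
                blocks=tuple(blocks),
                gaps=tuple(gaps),
                category=category,
            )
        )
        self.segments.append(
            {
                "name": name,
                "chrom": chrom,
                "blocks": tuple(blocks),
                "gaps": tuple(gaps),
                "is_reverse": _is_reverse_flag(
                    reported, self.spec.protocol, mate if mate else 1
                ),
                "mate": mate,
                "mate_of": mate_of,
            }
        )
        return len(self.segments) - 1


def _emit_junction_reads(
    em: _Emitter,
    t: TranscriptLayout,
    intron_idx: int,
    rng: np.random.Generator,
) -> None:
    spec = em.spec
    L, anchor = spec.read_length, spec.min_anchor
    i_start, i_end = t.introns[intron_idx]
    ex_left, ex_right = t.exons[intron_idx], t.exons[intron_idx + 1]
    f = t.spliced_fractions[intron_idx]
    left_len = ex_left[1] - ex_left[0] + 1
    right_len = ex_right[1] - ex_right[0] + 1
    a_lo = max(anchor, L - right_len)
    a_hi = min(L - anchor, left_len)
    if a_lo > a_hi:
        raise ConfigError(
            f"{t.transcript_id}: exons too short for read length {L}"
        )
    for _ in range(spec.junction_depth):
        spliced = rng.random() < f
        if spliced:
            a = int(rng.integers(a_lo, a_hi + 1))
            blocks = [(i_start - a, i_start - 1), (i_end + 1, i_end + (L - a))]
            idx = em.emit(t.chrom, t.strand, blocks, [(i_start, i_end)], "split")
            if spec.paired:
                _emit_mate(em, t, ex_right, blocks[-1][1] + 1, idx)
        else:
            a = int(rng.integers(a_lo, a_hi + 1))
            lower = [(i_start - a, i_start - a + L - 1)]
            b = int(rng.integers(a_lo, a_hi + 1))
            upper = [(i_end - (L - b) + 1, i_end + b)]
            if spec.paired:
                i1 = em.emit(t.chrom, t.strand, lower, [], "unsplit", mate=1)
                em.emit(t.chrom, t.strand, upper, [], "unsplit", mate=2, mate_of=i1)
            else:
                em.emit(t.chrom, t.strand, lower, [], "unsplit")
                em.emit(t.chrom, t.strand, upper, [], "unsplit")
    for _ in range(spec.contaminants_per_junction):
        a = int(rng.integers(a_lo, a_hi + 1))
        em.emit(t.chrom, t.strand, [(i_start - a, i_start - a + L - 1)], [],
                "contaminant", flip_strand=True)
        b = int(rng.integers(a_lo, a_hi + 1))
        em.emit(t.chrom, t.strand, [(i_end - (L - b) + 1, i_end + b)], [],
                "contaminant", flip_strand=True)


def _emit_mate(
    em: _Emitter,
    t: TranscriptLayout,
    exon: Tuple[int, int],
    want_start: int,
    mate_of: int,
) -> None:
    """Pure-match mate placed inside ``exon`` at/after ``want_start``."""
    L = em.spec.read_length
    start = min(want_start, exon[1] - L + 1)
    start = max(start, exon[0])
    end = min(start + L - 1, exon[1])
    em.emit(t.chrom, t.strand, [(start, end)], [], "mate", mate=2,
            mate_of=mate_of)
    em.segments[mate_of]["mate"] = 1
    em.segments[mate_of]["mate_of"] = len(em.segments) - 1


def _emit_body_reads(em: _Emitter, t: TranscriptLayout) -> None:
    spec = em.spec
    L = spec.read_length
    intervals: List[Tuple[Tuple[int, int], int]] = [
        (ex, spec.exon_depth) for ex in t.exons
    ]
    for idx, iv in enumerate(t.introns):
        depth = (
            spec.intron_depth
            if spec.intron_depth is not None
            else round(spec.exon_depth * (1.0 - t.spliced_fractions[idx]))
        )
        intervals.append((iv, depth))
    for (lo, hi), depth in intervals:
        for _ in range(depth):
            pos = lo
            while pos <= hi:
                end = min(pos + L - 1, hi)
                em.emit(t.chrom, t.strand, [(pos, end)], [], "body")
                pos = end + 1


# ---------------------------------------------------------------------------
# File writing
# ---------------------------------------------------------------------------


def write_gtf(transcripts: Sequence[TranscriptLayout], path: str) -> None:
    """Write a GENCODE-dialect GTF with gene/transcript/exon features."""
    with open(path, "w") as out:
        out.write("#!genome synthetic\n")
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.gene_name:
                attrs += f' gene_name "{t.gene_name}";'
            span = (t.start, t.end)
            for feature, (lo, hi) in (("gene", span), ("transcript", span)):
                out.write(
                    f"{t.chrom}\tsim\t{feature}\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )
            for lo, hi in t.exons:
                out.write(
                    f"{t.chrom}\tsim\texon\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _segment_to_aligned(seg: dict, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    rd = pysam.AlignedSegment(header)
    rd.query_name = seg["name"]
    rd.reference_id = header.get_tid(seg["chrom"])
    rd.reference_start = seg["blocks"][0][0] - 1  # to 0-based
    rd.mapping_quality = 60
    # interleave match blocks with N gaps / D-free geometry
    events = sorted(
        [(lo, hi, "M") for lo, hi in seg["blocks"]]
        + [(lo, hi, "N") for lo, hi in seg["gaps"]]
    )
    cigar = [(0 if kind == "M" else 3, hi - lo + 1) for lo, hi, kind in events]
    rd.cigartuples = cigar
    qlen = sum(l for op, l in cigar if op == 0)
    rd.query_sequence = "A" * qlen
    rd.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    rd.is_reverse = seg["is_reverse"]
    rd.set_tag("NH", 1)
    if seg["mate"]:
        rd.is_paired = True
        rd.is_proper_pair = True
        rd.is_read1 = seg["mate"] == 1
        rd.is_read2 = seg["mate"] == 2
        rd.mate_is_reverse = not seg["is_reverse"]
    return rd


def generate_fixture(spec: SimSpec, out_dir: str, prefix: str = "sim") -> SimFixture:
    """Write <prefix>.gtf, a sorted+indexed <prefix>.bam and a truth TSV.

    Fully reproducible from ``spec.seed``.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    em = _Emitter(spec)
    intron_truth: List[IntronTruth] = []
    for t in spec.transcripts:
        for idx, (i_start, i_end) in enumerate(t.introns):
            intron_truth.append(
                IntronTruth(
                    chrom=t.chrom,
                    start=i_start,
                    end=i_end,
                    strand=t.strand,
                    gene_id=t.gene_id,
                    transcript_id=t.transcript_id,
                    f=t.spliced_fractions[idx],
                    flank_left=t.exons[idx],
                    flank_right=t.exons[idx + 1],
                )
            )
            if spec.junction_depth or spec.contaminants_per_junction:
                _emit_junction_reads(em, t, idx, rng)
        if spec.exon_depth or spec.intron_depth:
            _emit_body_reads(em, t)

    gtf_path = os.path.join(out_dir, f"{prefix}.gtf")
    write_gtf(spec.transcripts, gtf_path)

    chrom_lengths: Dict[str, int] = {}
    for t in spec.transcripts:
        chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.end + 1000)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": length}
                for chrom, length in sorted(chrom_lengths.items())
            ],
        }
    )
    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    ordered = sorted(
        range(len(em.segments)),
        key=lambda i: (
            header.get_tid(em.segments[i]["chrom"]),
            em.segments[i]["blocks"][0][0],
            em.segments[i]["name"],
        ),
    )
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i in ordered:
            bam.write(_segment_to_aligned(em.segments[i], header))
    pysam.index(bam_path)

    truth = SimTruth(spec=spec, introns=intron_truth, reads=em.reads)
    truth_path = os.path.join(out_dir, f"{prefix}.truth.tsv")
    oracle = oracle_counts(truth)
    with open(truth_path, "w") as out:
        out.write("#chrom\tstart\tend\tstrand\tgene_id\ttranscript_id\tf\t"
                  "S5\tN5\tS3\tN3\n")
        for it in intron_truth:
            c = oracle[it.key]
            out.write(
                f"{it.chrom}\t{it.start}\t{it.end}\t{it.strand}\t{it.gene_id}\t"
                f"{it.transcript_id}\t{it.f}\t{c.S5}\t{c.N5}\t{c.S3}\t{c.N3}\n"
            )
    return SimFixture(gtf_path=gtf_path, bam_path=bam_path,
                      truth_path=truth_path, truth=truth)


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------


def oracle_counts(
    truth: SimTruth, min_overhang: int = 1
) -> Dict[Tuple[str, int, int, str, str], JunctionCounts]:
    """Exact junction tallies implied by the emitted reads.

    Naive double loop over (intron, read) pairs operating on the
    generation-time layout records, independent of any alignment-file
    round trip.
    """
    out: Dict[Tuple[str, int, int, str, str], JunctionCounts] = {}
    for it in truth.introns:
        tally = out.setdefault(it.key, JunctionCounts())
        lower_side = "5" if it.strand == "+" else "3"
        upper_side = "3" if it.strand == "+" else "5"
        for rd in truth.reads:
            if rd.chrom != it.chrom:
                continue
            if rd.tx_strand is not None and rd.tx_strand != it.strand:
                continue
            for side, boundary, is_start in (
                (lower_side, it.start, True),
                (upper_side, it.end, False),
            ):
                if is_start and any(g[0] == boundary for g in rd.gaps):
                    tally.add(side, "split")
                    continue
                if not is_start and any(g[1] == boundary for g in rd.gaps):
                    tally.add(side, "split")
                    continue
                exon_base = boundary - 1 if is_start else boundary + 1
                lo, hi = min(boundary, exon_base), max(boundary, exon_base)
                if any(
                    b0 <= lo - (min_overhang - 1) and b1 >= hi + (min_overhang - 1)
                    for b0, b1 in rd.blocks
                ):
                    tally.add(side, "unsplit")
    return out


def true_fractions(truth: SimTruth) -> Dict[Tuple[str, int, int, str, str], float]:
    return {it.key: it.f for it in truth.introns}
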