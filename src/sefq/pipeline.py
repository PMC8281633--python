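"""End-to-end orchestration: annotation -> introns -> filters -> counts ->
scores -> TSV.

The workflow is deterministic and seed-free: parse the GTF, infer and
collapse introns, apply the restrictiveness level and the minimum-length
filter, count split/unsplit junction reads, apply the per-junction
minimum-coverage filter, compute SE (and, at level 3 on request, coverage
medians and IER), then write one row per surviving intron sorted by
(chrom, start, end, gene_id). Counting is partitioned by chromosome and may
run in worker processes; results are merged and globally sorted before
writing, so the output is byte-identical for any worker count.
"""

from __future__ import annotations

import gzip
import logging
import multiprocessing
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pysam

from .annotation import (
    Intron,
    VALID_LEVELS,
    filter_by_length,
    filter_by_level,
    infer_introns,
    parse_annotation,
)
from .counting import (
    CoverageStats,
    JunctionCounts,
    ReadFilterConfig,
    compute_coverage_stats,
    count_junction_reads,
)
from .errors import ConfigError, InputError
from .metrics import compute_IER, compute_SE

logger = logging.getLogger("sefq")

MISSING = "NA"
FLOAT_DIGITS = 6

BASE_COLUMNS = (
    "chrom", "start", "end", "strand", "gene_id", "gene_name",
    "transcript_ids", "S5", "N5", "S3", "N3", "SE",
)
IER_COLUMNS = ("IER", "intron_median", "exon5_median", "exon3_median")


@dataclass(frozen=True)
class RunConfig:
    gtf_path: str
    bam_path: str
    output_path: str
    level: int = 3
    min_coverage: int = 10
    min_intron_length: int = 30
    compute_ier: bool = False
    processes: int = 1
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    stranded_overlap: bool = True

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise ConfigError(f"invalid restrictiveness level {self.level!r}")
        if self.compute_ier and self.level != 3:
            raise ConfigError(
                "the inverse intron expression ratio is only available with "
                "filtering level 3"
            )
        if self.processes < 1:
            raise ConfigError("processes must be >= 1")
        if self.min_coverage < 0:
            raise ConfigError("min_coverage must be >= 0")
        if self.min_intron_length < 0:
            raise ConfigError("min_intron_length must be >= 0")


@dataclass
class IntronResult:
    """One output row."""

    intron: Intron
    counts: JunctionCounts
    SE: Optional[float]
    IER: Optional[float] = None
    coverage: Optional[CoverageStats] = None


# ---------------------------------------------------------------------------
# Chromosome-name reconciliation
# ---------------------------------------------------------------------------

def _normalize(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def reconcile_chromosomes(
    gtf_chroms: Sequence[str], bam_refs: Sequence[str]
) -> Dict[str, str]:
    """Map annotation chromosome names onto BAM reference names, tolerating
    a 'chr' prefix on either side. Fatal when not a single annotation
    chromosome can be matched."""
    by_norm = {}
    for ref in bam_refs:
        by_norm.setdefault(_normalize(ref), ref)
    mapping: Dict[str, str] = {}
    for chrom in gtf_chroms:
        ref = by_norm.get(_normalize(chrom))
        if ref is not None:
            mapping[chrom] = ref
    if gtf_chroms and not mapping:
        raise InputError(
            "no annotation chromosome matches the alignment header even after "
            f"'chr'-prefix normalization; annotation: {sorted(gtf_chroms)}, "
            f"alignment: {sorted(bam_refs)}"
        )
    return mapping


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

def apply_coverage_filter(
    results: Sequence[Tuple[Intron, JunctionCounts]], min_coverage: int
) -> List[Tuple[Intron, JunctionCounts]]:
    """Keep introns with >= min_coverage reads at *each* junction
    (split + unsplit, inclusive bound)."""
    return [
        (intron, counts)
        for intron, counts in results
        if counts.S5 + counts.N5 >= min_coverage
        and counts.S3 + counts.N3 >= min_coverage
    ]


# ---------------------------------------------------------------------------
# Per-chromosome work unit
# ---------------------------------------------------------------------------

def _process_chromosome(
    args: Tuple[str, str, List[Intron], ReadFilterConfig, Mapping[str, str], int, bool]
) -> List[Tuple[Intron, JunctionCounts, Optional[CoverageStats]]]:
    (bam_path, chrom, introns, read_filter, chrom_map, min_coverage,
     want_ier) = args
    out: List[Tuple[Intron, JunctionCounts, Optional[CoverageStats]]] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        counts = count_junction_reads(bam, introns, read_filter, chrom_map)
        surviving = apply_coverage_filter(
            [(i, counts[i]) for i in introns], min_coverage
        )
        for intron, tally in surviving:
            cov = None
            if want_ier:
                cov = compute_coverage_stats(
                    bam, intron, cfg=read_filter, chrom_map=chrom_map
                )
            out.append((intron, tally, cov))
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _fmt_float(value: Optional[float]) -> str:
    return MISSING if value is None else f"{value:.{FLOAT_DIGITS}f}"


def format_row(result: IntronResult, with_ier: bool) -> str:
    intron = result.intron
    fields = [
        intron.chrom,
        str(intron.start),
        str(intron.end),
        intron.strand,
        intron.gene_id,
        intron.gene_name or MISSING,
        ",".join(sorted(intron.transcript_ids)),
        str(result.counts.S5),
        str(result.counts.N5),
        str(result.counts.S3),
        str(result.counts.N3),
        _fmt_float(result.SE),
    ]
    if with_ier:
        cov = result.coverage
        fields += [
            _fmt_float(result.IER),
            _fmt_float(cov.intron_median if cov else None),
            _fmt_float(cov.exon5_median if cov else None),
            _fmt_float(cov.exon3_median if cov else None),
        ]
    return "\t".join(fields)


def write_results(
    results: Sequence[IntronResult], output_path: str, with_ier: bool
) -> None:
    header = "#" + "\t".join(
        BASE_COLUMNS + (IER_COLUMNS if with_ier else ())
    )
    opener = gzip.open if str(output_path).endswith(".gz") else open
    with opener(output_path, "wt") as out:
        out.write(header + "\n")
        for result in results:
            out.write(format_row(result, with_ier) + "\n")


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> List[IntronResult]:
    """Run the full workflow and write the results table.

    Returns the result rows (in output order) for programmatic use.
    """
    logger.info("step 1/5: parsing annotation %s", cfg.gtf_path)
    annotation = parse_annotation(cfg.gtf_path)

    logger.info("step 2/5: inferring introns")
    introns = infer_introns(annotation)
    logger.info("inferred %d collapsed introns", len(introns))

    logger.info("step 3/5: filtering (level %d, min length %d)",
                cfg.level, cfg.min_intron_length)
    introns = filter_by_level(introns, annotation, cfg.level,
                              stranded=cfg.stranded_overlap)
    introns = filter_by_length(introns, cfg.min_intron_length)
    logger.info("%d introns retained after level/length filters", len(introns))

    try:
        with pysam.AlignmentFile(cfg.bam_path, "rb") as bam:
            if not bam.has_index():
                raise InputError(
                    f"alignment file {cfg.bam_path!r} has no index; "
                    "run samtools index first"
                )
            bam_refs = list(bam.references)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open alignment file {cfg.bam_path!r}: {exc}") from exc

    chrom_map = reconcile_chromosomes(
        sorted({i.chrom for i in introns}) or annotation.chromosomes, bam_refs
    )

    logger.info("step 4/5: counting junction reads (%d process(es))",
                cfg.processes)
    by_chrom: Dict[str, List[Intron]] = {}
    for intron in introns:
        by_chrom.setdefault(intron.chrom, []).append(intron)
    jobs = [
        (cfg.bam_path, chrom, chrom_introns, cfg.read_filter, chrom_map,
         cfg.min_coverage, cfg.compute_ier)
        for chrom, chrom_introns in sorted(by_chrom.items())
    ]
    if cfg.processes > 1 and len(jobs) > 1:
        with multiprocessing.Pool(min(cfg.processes, len(jobs))) as pool:
            chunks = pool.map(_process_chromosome, jobs)
    else:
        chunks = [_process_chromosome(job) for job in jobs]

    logger.info("step 5/5: computing scores and writing %s", cfg.output_path)
    results: List[IntronResult] = []
    for chunk in chunks:
        for intron, tally, cov in chunk:
            ier = compute_IER(cov) if cov is not None else None
            results.append(
                IntronResult(intron=intron, counts=tally, SE=compute_SE(tally),
                             IER=ier, coverage=cov)
            )
    results.sort(key=lambda r: r.intron.sort_key())
    if not results:
        logger.warning("no intron passed the filters; writing header-only output")
    write_results(results, cfg.output_path, cfg.compute_ier)
    logger.info("wrote %d rows", len(results))
    return results
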