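"""Splicing-efficiency (SE) and inverse intron expression ratio (IER).

SE for an intron i is the fraction of junction-informative reads that are
split:

    SE_i = (S5 + S3) / (S5 + S3 + N5 + N3),        0 <= SE_i <= 1

where S/N are split/unsplit read counts at the 5' and 3' junctions. SE = 1
means the intron was excised from every observed transcript; SE = 0 means
it was retained in all of them.

IER compares the intron's median per-base coverage I_x with that of its
flanking exons E_x, E_{x+1}:

    IER = 1 - min(1, I_x / (0.5 * (E_x + E_{x+1}))),   0 <= IER <= 1

Both are undefined (returned as None, emitted as "NA") when their
denominator is zero; an undefined score is never silently collapsed to 0.
"""

from __future__ import annotations

from typing import Optional

from .counting import CoverageStats, JunctionCounts


def compute_SE(counts: JunctionCounts) -> Optional[float]:
    """Splicing efficiency from junction tallies; None when no
    junction-informative read was observed."""
    for value in counts.as_tuple():
        if value < 0:
            raise ValueError(f"negative junction count in {counts}")
    split = counts.S5 + counts.S3
    total = split + counts.N5 + counts.N3
    if total == 0:
        return None
    return split / total


def compute_IER(cov: CoverageStats) -> Optional[float]:
    """Inverse intron expression ratio; None when both flanking-exon
    medians are zero."""
    if min(cov.intron_median, cov.exon5_median, cov.exon3_median) < 0:
        raise ValueError(f"negative median coverage in {cov}")
    denom = 0.5 * (cov.exon5_median + cov.exon3_median)
    if denom == 0:
        return None
    return 1.0 - min(1.0, cov.intron_median / denom)
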