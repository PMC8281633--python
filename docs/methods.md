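# Methods

## Model and procedure

`sefq` treats splicing efficiency as an intron-local, read-level quantity.
For each intron the evidence is the set of reads overlapping its two
splice junctions, partitioned into split reads (reference-skip gap whose
intron-side boundary matches the intron start/end exactly) and unsplit
reads (contiguous aligned match covering both the last exonic and the
first intronic base). SE is the split fraction over both junctions
pooled; it estimates the fraction of transcript molecules from which the
intron has been excised, under the assumptions that (i) read sampling is
uniform across junction-crossing sites, (ii) split and unsplit
configurations are detected with equal efficiency at the same site, and
(iii) the library is strand-specific, so antisense reads from overlapping
genes can be excluded.

A molecule that has spliced intron *i* exposes one junction-crossing site
(the ligated exon–exon boundary); an unspliced molecule exposes two (one
per junction). A split read whose gap is exactly the intron is therefore
tallied at *both* junctions, while each unsplit read is tallied at the
junction it covers (a read covering a very short intron entirely can
legitimately count at both). Under uniform sampling these conventions make
SE an unbiased estimator of the spliced molecule fraction. Gaps
documenting the excision of more than one intron (exon skipping) count as
split wherever their boundary matches, because they still document that
intron's removal.

The workflow is: parse exon features from the GTF → infer introns as
inter-exon gaps per transcript and collapse identical (chrom, start, end,
strand, gene) records across isoforms → apply the restrictiveness level
and minimum-length filter → stream the BAM once per chromosome, classify
reads at every junction window their span overlaps → apply the
per-junction minimum-coverage filter → compute SE (and per-base coverage
medians and IER when requested) → write rows sorted by (chrom, start,
end, gene). Nothing in the pipeline is stochastic.

## Overlap filters

Levels: 1 = keep all introns; 2 = both 2-base junction windows
({last exonic base, first intronic base} at either end) must be free of
exons of *other* genes; 3 = additionally the intron body [start, end]
must be free of *any* exon, including other isoforms of the same gene.
Two choices here were genuinely open:

- **Junction window width.** The minimal window — the boundary base pair
  itself — is used for the level-2 test. Any exon that interferes with
  classifying reads at a junction must cover at least one of those two
  bases.
- **Level nesting.** Level 3 is implemented as the level-2 junction
  condition *plus* the body condition, so level-3 ⊆ level-2 ⊆ level-1
  holds for every annotation. A body-only reading would admit the corner
  case of a foreign exon touching only the junction's exonic base, making
  the "strictest" level keep an intron level 2 rejects, which contradicts
  the tiered-restrictiveness intent.
- **Strand awareness.** By default only same-strand exons create a
  conflict (`stranded_overlap`), because with strand-specific libraries
  opposite-strand overlaps are resolved by the read-strand filter at
  counting time; a strand-agnostic mode is available for unstranded data.
- **Cross-gene identical introns** are keyed per gene and remain separate
  records; the overlap filters usually remove them anyway.

Adjacent flanking exons for the coverage ratio are the exonic intervals
immediately bordering the collapsed intron, unioned over its supporting
isoforms (they share the junction endpoint, so the union is an interval).
Under level 3 these regions are exon-overlap-free, so no further
disambiguation is needed.

## Read-level conventions

- *Uniquely mapped*: NH tag equal to 1 when present, otherwise mapping
  quality ≥ `mapq_min` (default 30). This covers the conventions of the
  common spliced aligners, which either emit NH or encode uniqueness in
  MAPQ.
- *Unsplit overhang*: ≥ 1 aligned base on each side of the junction by
  default (`min_overhang`); raise it for stringency. CIGAR deletions (D)
  break contiguity, so a deletion at the boundary disqualifies an unsplit
  call and contributes no coverage.
- *Mates* are classified independently (no fragment reconstruction);
  strand inference is mate-aware (the second mate reports the opposite of
  the first).
- Secondary, supplementary, duplicate and QC-fail records are excluded.
- Each gap of a multi-gap read is evaluated independently against every
  junction.

Coverage for IER is per-base depth of aligned match bases from reads
passing the same filter (same-strand only, unless unstranded); the median
is taken over every base of the interval, zeros included.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `--filter-level` | 3 | intron restrictiveness tier (IER requires 3) |
| `--min-coverage` | 10 reads | minimum split+unsplit reads at *each* junction |
| `--min-intron-length` | 30 nt | shorter introns are discarded before counting |
| `--protocol` | reverse | library strandedness (dUTP-style default) |
| `--mapq-min` | 30 | uniqueness fallback when no NH tag |
| `--processes` | 1 | chromosome-partitioned workers; output independent of it |

Scores are printed with 6 decimals; undefined scores as `NA`, never 0.
Zero surviving introns yields a header-only table with a warning.

## Synthetic data

The generator (`sefq.simdata`) emulates strand-specific RNA-seq over a
toy multi-gene annotation with known per-intron spliced fraction *f*.
Per intron it draws `junction_depth` fragments (default 200, a depth at
which binomial error on SE is ~±0.05 at f = 0.5): a spliced fragment
emits one split read whose gap is exactly the intron; an unspliced one
emits an unsplit read at each junction — mirroring the one-vs-two
crossing-site asymmetry above and giving exactly `junction_depth`
informative reads per junction with E[SE] = f. Exon bodies are tiled at
uniform depth (default 30×, a typical bulk exonic coverage) and intron
bodies at `round(exon_depth·(1−f))`, the residue an unspliced fraction
would leave, so IER increases with f. Reads are 80 nt (default), emitted
single-end (paired behind a flag) with NH:i:1 and MAPQ 60, written as a
coordinate-sorted, indexed BAM plus a GENCODE-dialect GTF; everything is
reproducible from the seed. Layout helpers provide graded-f gene panels
and an annotation with known level-1/2/3 membership (a foreign exon on a
junction; an isoform retaining an intron as exonic sequence).

Every emitted read's match blocks, gaps and reported strand are recorded,
and `oracle_counts` recomputes junction tallies from that bookkeeping
with a naive double loop — an exact, read-identity-level reference for
the BAM-based counting path (no sampling slack).

What the generator does *not* emulate: sequencing errors and quality
variation, coverage biases (GC, 3′ bias), soft-clipping, multi-mappers,
alternative-isoform read mixtures beyond exon-skipping gaps, or intronic
reads from unannotated features. Passing tests therefore demonstrate the
correctness of inference, classification, filtering and arithmetic on
idealized alignments — not robustness to aligner artifacts in real data.

## Numerical and degenerate-input choices

- SE/IER with zero denominator are `None`/`NA` (an intron with no
  junction-informative reads is *unobserved*, not unspliced); the
  default coverage filter removes such introns unless set to 0.
- All thresholds are inclusive (length ≥ 30, coverage ≥ 10).
- Tied or abutting exons (zero-length gap) produce no intron; transcripts
  with internally overlapping exons are skipped with a warning rather
  than aborting, tolerating malformed real-world annotations.
- Chromosome naming: `chr` prefixes are normalized between GTF and BAM;
  a total mismatch after normalization is fatal and lists both name sets;
  individual unmatched chromosomes get zero counts with a warning.
- Counting is order-independent by construction; parallel results are
  merged and globally sorted before writing, so repeated runs and any
  worker count give byte-identical output.

## Verification problem sizes

The test suite and acceptance script run entirely on generated fixtures:
randomized toy annotations of ≤ ~50 exons for the filter oracle (100
draws), counting fixtures of ≤ 500 reads for bitwise oracle comparison,
and recovery/concordance datasets of 2 genes × 5–10 introns at 200
junction reads per junction (20 seeds for recovery, 200 intron-seed
pairs). These sizes give sub-minute runtimes while leaving the binomial
recovery bound and the rank correlation well-powered.

## Known limitations

- No de-novo junction discovery: introns come from the annotation only.
- Read-level counting; no fragment-level deduplication of mate pairs
  (a pair straddling the same junction twice counts twice).
- No soft-clip rescue or realignment; reads must be spliced-aligned
  upstream.
- IER is only defined under level 3, where flanking-exon coverage is
  unambiguous.
- Single-sample tool: cross-sample intersection of surviving introns is
  a downstream step (filter each sample's table, then join on
  chrom/start/end/strand/gene_id).
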