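# Methods

This note documents the models, rules and numerical choices implemented in
smorfkit, and what the synthetic benchmark does and does not establish.

## Coordinate model

All analysis is in 0-based, half-open transcript coordinates on the sense
strand. Genome-side annotations are collapsed onto contiguous transcript
coordinates by the GTF reader (exons concatenated in strand order, CDS
features mapped through the exon chain); everything downstream is
single-“exon” by construction. The model's CDS interval includes the stop
codon; a GTF whose CDS excludes it is absorbed on input when the next three
bases form a stop. ORF spans `[start, end)` likewise include the stop
codon, while `length_codons` and peptides exclude it.

## Candidate ORFs

Enumeration reports every ATG with an in-frame stop before the transcript
end, in all three frames; ORFs running off the end are discarded, as are
near-cognate starts. Defaults bound ORFs to 5–300 codons — small enough to
include short uORFs, capped where translated lncRNA ORFs are expected to
end. Classification against the annotation is strict: only an exact CDS
match is `canonical`; uORFs must end at or before `cds_start` and dORFs
start at or after `cds_end`; ORFs overlapping the CDS (including in-frame
extensions) are `other`, since their footprints cannot be attributed
unambiguously. Any ORF on a lncRNA is a `lncRNA_smORF`.

## P-site calibration

For each read length, 5′-end distances to annotated start codons are
histogrammed in a ±30 nt window (configurable). Candidate offsets (3 to
length − 3) are scored by the frame-0 fraction of shifted 5′ ends that land
inside the CDS. Because offsets in one mod-3 class shift the same reads
onto the same frame, the fraction identifies the offset only up to phase;
candidates within two binomial standard deviations of the best fraction are
treated as tied and resolved by the initiation peak — the candidate whose
negation indexes the tallest upstream 5′-end bin — then by the smaller
offset. This is the same information a start-codon metaplot provides and is
robust to single stray background reads, which can otherwise flip a strict
argmax between in-phase offsets. A read length is selected when its best
fraction reaches `min_in_frame` (default 0.6; a uniform-frame library
scores ≈ 1/3). Calibration is per replicate by default, since digestion
and size selection vary between libraries; a pooled mode exists for sparse
data. P-site assignment drops reads of unselected lengths and logs P-sites
falling past transcript ends.

## Translation calling

The calling unit is the chain of in-frame ATGs sharing one stop. Start
selection runs first, per replicate, on the replicate's P-site pool: the
most upstream ATG with ≥ 5 P-sites before the next in-frame ATG, else the
most downstream ATG. (Whether framing should be assessed before or after
start selection is genuinely open; selecting first is the default and the
order is configurable via `CallThresholds.select_start_first`.) Gates on
`[selected_start, end)`:

- **count**: strictly more than 5 P-sites;
- **framing**: in-frame fraction ≥ 0.5;
- **periodicity**: one-sided exact binomial test of the in-frame count
  against p = 1/3, significant at α = 0.05 — this guards high-count ORFs
  whose 50% framing could still arise by chance at small n, and is used in
  place of spectral periodicity tests because the operative rule is stated
  as an in-frame fraction, which the binomial models exactly;
- **multimapping**: the fraction of covered positions supported only by
  multimapping reads must not exceed 0.30 (strictly greater discards).
  The fraction is over covered positions, not reads, reading "coverage
  supported by multimapping" literally.

A condition calls an ORF when ≥ 2 replicates pass (configurable); the
consensus start is the most upstream start among passing replicates. Set
identity for cross-condition comparisons is the chain `(transcript, stop,
frame)`, so a start disagreement between conditions does not double-count
a translation event.

## Quantification

Translational efficiency follows the median-normalized ratio given in the
README; medians are taken per replicate over the ORF set being reported
(normalizing within the reported set keeps the statistic self-contained;
whether medians should instead be taken per ORF class is not determinable
and the set is the caller's to choose). Replicates with zero median cannot
be normalized and are dropped with a warning; ORFs with zero RNA signal
have undefined TE and are excluded (but counted) in summaries. "RNA sites"
are RNA-seq read 5′ ends inside the ORF — symmetric with P-site counting
and insensitive to read length.

Metagene profiles count P-sites at signed positions in `[-75, +75]` around
the selected start and around the first base of the stop codon, scale both
windows jointly to unit mass per ORF (so each transcript contributes
equally regardless of expression), and average positionwise. The window is
interpreted as ±75 nt; a 75-nt total span is available via `half_width`.
Positions beyond transcript bounds contribute zeros; zero-signal ORFs are
excluded and counted. The stop drop-off ratio compares mean signal at
stop-window positions ≥ +3 with the in-ORF mean.

## Synthetic data

The generator emulates the data structure the caller assumes: random-
sequence transcripts (400–1200 nt) with planted CDSs (60–250 codons behind
a ≥ 20 nt 5′ UTR) and planted lncRNA smORFs (30–90 codons, median ≈ 60);
footprints of 31/33 nt (equal mix) with true offsets 12/13 nt — the
conventional 5′→P-site distance, since the real offsets are library
properties, not constants; per-ORF footprint counts Poisson with mean 50
per replicate; P-sites uniform over codons except an initiation-pause
fraction (0.15) placed in frame on the start codon, matching the universal
start-codon peak of real metagenes; in-frame probability 0.85 elsewhere
(remainder split over frames 1/2); background footprints at 1 per 100 nt
with uniform position and frame; multimapping flags i.i.d. at 0.05; RNA-seq
5′ ends uniform over every transcript at mean 100 per replicate; three
replicates in each of two conditions, with planted smORFs cycled through
condition patterns (first-only, second-only, both). Counts can be switched
to negative binomial (`nb_size`) for overdispersion. Everything derives
from one seed and reruns are byte-identical.

Deliberately not modelled: sequence error, rRNA/contaminant reads,
fragment-length and nucleotide-composition bias, UMIs, isoform sharing of
reads, and reinitiation/overlapping translation. Passing the benchmark
therefore shows the pipeline's rules are implemented correctly and recover
planted signal under realistic counting noise — not that real libraries
meet these assumptions; on real data the multimapping and background
structure in particular will be less benign.

## Benchmark sizes and observed behavior

The default benchmark transcriptome is 20 coding plus 30 lncRNA
transcripts (15 planted smORFs, 15 untranslated controls); performance
metrics average 10 such simulations, and offset recovery uses 20
single-replicate simulations with ≥ 500 CDS reads per read length. These
sizes keep each full pipeline run around a third of a second while leaving
every rate estimated from ≥ 150 Bernoulli trials. The acceptance script
(`scripts/acceptance.py`) recomputes all of it from a single seed.

## Reference data

The expected-by-chance amino-acid frequencies ship as an editable TSV
(`smorfkit/data/expected_aa_freqs.tsv`), computed as codon multiplicity
over the 61 sense codons of the standard code — the classical random-
expectation null for composition comparisons. It is reference data, not a
constant of the method; pass `--expected-freqs` (CLI) or `expected=`
(API) to substitute another table. Composition averaging is per-peptide
(unweighted) by default so short peptides are not swamped; a residue-pooled
mode is provided and the mode is recorded in the output. Reported
percentages round half away from zero to match integer reporting
conventions.

## Known limitations

- Exon-level prefiltering is meaningless under the collapsed transcript
  model; the count gate applies at the ORF level.
- Overlapping ORFs sharing P-sites are scored independently; no
  deconvolution is attempted.
- The start-selection rule can settle on a downstream in-frame ATG when
  in-frame ATGs are closely spaced (fewer than five P-sites fit between
  neighbors); recovery bookkeeping therefore matches on the ORF chain, not
  the exact start.
- Stop-codon readthrough and stopless ORFs are out of scope.
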