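# Methods

## The model

Animal mitochondrial genomes are transcribed strand-wise: the heavy (H) and
light (L) strands each yield a single polycistronic primary transcript.
Maturation follows the tRNA-punctuation model — the ~22 tRNA genes
interspersed among the coding genes fold into cloverleaves inside the
precursor and are excised, releasing the intervening fragments as mature
transcripts (cistrons).  Two structural consequences drive everything this
package computes:

1. **Gene content of mature transcripts.**  Coding genes not separated by a
   tRNA remain on one mature transcript.  This is *forced* wherever coding
   sequences overlap on the genome (atp8/atp6 by 7 bp, nd4/nd4L by 1 bp in
   the packaged lepidopteran annotation): cleaving inside the overlap would
   destroy a reading frame.  tRNA-free intergenic spacers (e.g. the 336 bp
   between nd6 and cytb) likewise stay inside a single cistron.
2. **Truncated stop codons.**  A gene whose 3' end abuts the downstream
   tRNA may keep only a T or TA of its TAA stop at the genomic level;
   polyadenylation of the mature mRNA supplies the missing A's.  EST reads
   whose alignments end at such a CDS terminus with a poly(A) soft clip are
   direct evidence for the mechanism.

## Punctuation cleavage as implemented

Cleavage is modelled on the genome axis.  Punctuating tRNA intervals are
merged; the maximal uncovered intervals are candidate fragments; every
same-strand PCG/rRNA is assigned to the fragment it overlaps most (ties to
the earlier fragment); a cistron is a fragment with at least one assigned
coding gene, its span extended to cover those genes; antisense-only
fragments are discarded.  On a linear (partial) genome the sequence ends
also terminate fragments; on a circular genome the coordinate origin plays
that role after linearization.

Majority-overlap assignment is load-bearing.  Real annotations contain
small gene/tRNA overlaps (cox1 strays 5 bp into trnL-UUR, trnD overlaps
atp8's first base, nd4L runs 27 bp into trnT): treating any such overlap as
a reason not to cleave collapses the prediction (a cox1..cox3 pentacistron,
an nd5/nd4/nd4L tricistron), while cleaving everywhere and letting each
gene follow its majority fragment reproduces the observed transcript table
with no special cases.

Which tRNAs punctuate is configurable (`rule`):

* `all` (default) — every tRNA locus cleaves both strands' transcripts;
  the antisense copy of a tRNA is assumed recognizable.
* `same-strand-only` — only sense tRNAs cleave (the classical reading).
  On the packaged annotation this yields the same cistron contents as
  `all`; the two hypotheses differ only in span boundaries.
* `all-except-overlapping` — every tRNA cleaves except one overlapping a
  PCG on the strand being processed.  Provided for comparison; on the
  packaged annotation it merges cistrons that are observed separately, so
  it is not the default.

**Predicted vs observed cistron count.**  On the packaged annotation the
model predicts 11 sense cistrons.  Ten match the observed EST contig table
row for row; the eleventh is an nd3 monocistron (nd3 sits alone between
trnG and trnA).  The study's EST library recovered no nd3 contig, so the
observed table has 10 rows; the package reports the model's honest 11 and
the synthetic transcriptome gives the nd3 cistron zero weight by default
(an unobserved species under the reference study conditions).

## Codon analytics

Translation uses the invertebrate mitochondrial code (NCBI table 5:
AGA/AGG = Ser, ATA = Met, TGA = Trp) with the start-codon set extended by
CGA, the arginine initiator documented for lepidopteran and dipteran cox1.
Annotated start codons are rendered as M regardless of their table value
(the standard reporting convention for non-ATG initiators); a CGA that is
not an annotated start still translates as R.  Truncated stops are
completed to TAA before translation when requested.

RSCU (relative synonymous codon usage) is a codon's count divided by its
synonymous-family mean under the mitochondrial families (Leu 6 codons, Ser
8 including AGA/AGG); the stop codons TAA/TAG form their own two-codon
family so they too receive relative values.  Families with zero total
count get RSCU 0 for all members; codons containing ambiguity letters are
excluded from tallies and counted separately.  The positional AT-bias test
is the plain Pearson 2x2 chi-square on [AT, GC] x [position i, position j]
without continuity correction, with p from chi-square(1).  (The published
chi-square values for this comparison are not reproducible from the
published counts by any standard 2x2 construction; the statistic here is
the textbook one and is cross-checked against an independent
implementation in the tests.)

The packaged codon-count table carries one internally inconsistent row as
published (UCA count 12.0 against an RSCU of 2.06); a corrected count
(~75, reconstructed from the family's published RSCU values) travels in a
separate column and is opt-in.

## Read processing and quantification

* **QC** (published thresholds): drop reads < 50 nt and reads in which one
  nucleotide makes up >= 60% of the length.
* **Mapping**: exact k-mer seeding (k = 11, non-overlapping sampling) on
  both strands; best seed diagonals are extended by edit-distance
  alignment (edlib) inside a window padded by 15% of the read length.  The
  trailing read suffix is soft-clipped by a local-score trim (+1 match,
  -2 mismatch/indel, keep the longest best-scoring prefix), which is where
  poly(A) tails land.  An alignment is reported only with >= 8 matching
  bases and >= 70% matching fraction over aligned columns (published
  thresholds); ties break by more matches, then lower genome coordinate,
  then H strand.  k, band and scoring are this package's choices, made so
  error-free reads are recovered exactly (verified against exhaustive
  placement on toy genomes) and 454-typical indel rates stay within band.
* **Poly(A)**: the run at the start of the 3' clip, allowing one non-A per
  ten bases, minimum 5 nt.
* **Assignment**: a read goes to the same-strand cistron of maximal span
  overlap; ties to the earlier cistron; no same-strand overlap leaves it
  unassigned.  Assignment is strand-specific, so the simulator emits reads
  in transcript (sense) orientation by default; a mixed-orientation mode
  exists but halves the assignable fraction by construction.
* **Quantification**: per cistron, read count, total aligned nucleotides
  (aligned bases, not read lengths), mean depth = total nt / cistron
  length, and proportion = read count / library total.  The library total
  is an explicit input; without it proportions are over assigned
  mitochondrial reads and labelled as such.
* **Stop verification**: reads covering a truncated CDS terminus whose
  aligned 3' end lies within 10 bp of it and whose clip is poly(A) count
  as support if the tail supplies the A's completing TAA.  The 10 bp
  tolerance absorbs tail bases that spuriously align into A-rich genomic
  sequence immediately downstream of the cleavage point — a real
  ambiguity at ~80% A+T.
* **Consensus**: per-position majority vote of aligned read bases over the
  cistron span, genome base (lowercase) where coverage is zero, ties
  resolved toward the genome base.

## Synthetic data

The generator realizes a gene layout (order, strands, lengths, signed
gaps; negative gaps are overlaps) as an AT-rich genome.  Defaults are the
reference study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `at_target` | 0.80 | background A+T fraction (per-base binomial) |
| `at_by_position` | 0.73 / 0.698 / 0.94 | PCG codon-position A+T targets |
| layout | `GenomeSpec.table2()` | 34 genes, published coordinates, 14,139 bp |
| abundances | published proportions | 0.1%–32.1% of library, ~321-fold spread |
| `n_reads` | 7,608 | the study's mitochondrial read count |
| read length | Normal(350, 50), clipped to [50, 600] | a 454-era stand-in; the study reports no distribution |
| errors | sub 0.5%, ins 0.25%, del 0.25%, homopolymer-extension 2%/run>=3 | invented, 454-like |
| poly(A) | cox2 and atp8/atp6/cox3 cistrons, p=1, length ~ Normal(30, 8) | the two cistrons observed with tails |

PCG interiors are sampled codon-wise from the positional model with
in-frame stops rejected; start codons and (possibly truncated) stops are
written last and frozen; a repair pass resamples any in-frame stop that
overlap-overwriting reintroduced, honouring frozen positions.  Overlapping
genes share bases positionally only — no dual-frame coding validity is
attempted, and tRNA "genes" are plain background sequence (no cloverleaf).
Everything is deterministic under the spec seed, and truth tables record
each read's source transcript, interval, orientation and tail content, so
every mapper/assignment decision is scorable.

What passing synthetic tests does *not* show: performance on real 454 data
with flowgram-specific error structure, chimeras or adapter remnants;
correctness of the punctuation rule for taxa with different gene orders;
tissue-level biology behind the abundance spread (the weights are imposed,
not modelled).

## Numerical choices and edge cases

* Coordinates are 1-based inclusive on the forward axis with a strand
  flag; transcription-orientation input rows are normalized at read time.
  Published declared lengths that disagree with coordinates (every
  descending L-strand row in the reference table is short by 2) are
  warnings; coordinates are authoritative.
* Genome length for the reference layout is 14,139 bp (the last feature
  end); the published assembly-size figures (14,052/14,054 bp) are
  inconsistent with the published coordinates and are not used.
* Zero-length punctuation gaps (overlapping tRNAs) produce no fragment;
  an annotation without tRNAs returns the whole strand as one cistron
  with a warning.
* Depth uses aligned bases so mean_depth x length == total_nt holds
  exactly for every computed row.  (Two rows of the published table
  violate this identity; consistency checks exclude them.)
* The expression-profile proportion denominator of the reference study
  (its whole-library size) was never published; only proportion *ratios*
  are compared.

## Limitations

* The mapper is a purpose-built short-read tool for small (mitochondrial)
  references; its k-mer index and per-read Python orchestration do not
  target nuclear-genome scale.
* No de novo assembly: cistron spans come from the punctuation model, not
  from read overlap layouts.
* The nd1 cistron's 3' boundary (and rRNA termini generally) follow the
  fragment definition; where the mechanism is genuinely unresolved the
  span is one consistent hypothesis, not a claim.
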