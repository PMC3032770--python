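# mitocistron

Mitogenome annotation geometry, tRNA-punctuation transcript prediction,
and EST-based expression profiling for insect mitochondrial genomes.

Animal mitochondria transcribe each genome strand as one long polycistronic
precursor and cleave it at the interspersed tRNA genes (the *tRNA
punctuation* model), releasing mature transcripts — *cistrons* — that carry
one, two or three protein-coding/rRNA genes.  Where coding sequences
overlap on the genome (atp8/atp6, nd4/nd4L) the genes are forced onto a
shared transcript, and genes cut flush against a tRNA may keep only a
truncated stop (a bare `T` or `TA`) that polyadenylation completes to
`TAA`.  This package turns that model into a tested pipeline for a
lepidopteran study system (the legume pod borer mitogenome, 13 PCGs +
2 rRNAs + 19 tRNAs, ~80% A+T), and ships the study's annotation,
codon-usage and expression tables so everything runs without downloads.

It provides, as a library plus a thin `mitocistron` CLI:

* **Annotation model & geometry** — FASTA/GFF3/feature-table I/O with
  normalization of transcription-orientation coordinates, lengths,
  overlaps, gaps, and a validator that surfaces the reference table's own
  internal inconsistencies.
* **Codon analytics** — invertebrate mitochondrial translation (AGR=Ser,
  AUA=Met, UGA=Trp, permissive initiators incl. CGA), truncated-stop
  completion, RSCU under the mitochondrial synonymous families, positional
  AT-bias with a 2x2 chi-square.
* **Cistron prediction** — configurable punctuation cleavage reproducing
  the observed mono-/bi-/tricistronic transcript table.
* **EST mapping & quantification** — read QC (>=50 nt, <60% single-base),
  seed-and-extend mapping (>=8 matching bases, >=70% identity), poly(A)
  soft-clip detection, strand-aware cistron assignment, per-cistron read
  counts / total nt / mean depth / proportions, fold-difference summaries,
  consensus building, SAM/BED/TSV output.
* **Synthetic data** — genomes, transcripts and 454-style reads with full
  ground truth at the study's conditions (7,608 reads, ~321-fold abundance
  spread).

## Worked example

Predict the mature transcripts of the packaged annotation
(`python examples/predict_cistrons.py`):

```
MtD_01  H      1-1006   monocistronic nd2
MtD_02  H   1200-2739   monocistronic cox1
MtD_03  H   2802-3486   monocistronic cox2
MtD_04  H   3624-5251   tricistronic  atp8,atp6,cox3
MtD_05  H   5318-5672   monocistronic nd3
MtD_06  L   6070-7805   monocistronic nd5
MtD_07  L   7872-9491   bicistronic   nd4L,nd4
MtD_08  H   9592-11366  bicistronic   nd6,cytb
MtD_09  L  11433-12387  monocistronic nd1
MtD_10  L  12456-13803  monocistronic rrnL
MtD_11  L  13853-14139  monocistronic rrnS

11 sense cistrons, 3 multi-gene
consistency: OK
```

Ten of these match the observed EST contigs gene-for-gene (the tricistron
and the two bicistrons are the multi-gene transcripts); the eleventh, nd3,
is a genuine model prediction for which the study's EST library recovered
no contig.  The `consistency` line checks that overlapping coding genes
always share a cistron.

Codon usage from the packaged counts (`python examples/codon_usage_rscu.py`):

```
RSCU(UUA) = 5.26   count = 426
RSCU(UUU) = 1.82   count = 315
...
```

UUA at 5.26 means leucine is encoded by UUA more than five times as often
as its six-codon family average — the A/T wobble bias of an 80% A+T genome.

An end-to-end synthetic run (`python examples/simulate_map_quantify.py`)
simulates 1,500 reads at the published abundance weights, maps and
quantifies them, and verifies the cox2 truncated stop:

```
1500 reads: 1500 kept, 1500 mapped, 0 unmapped
cistron_id          genes  length  total_nt  mean_depth  read_count  proportion ...
    MtD_03           cox2     685     57209   83.516788         167    0.111333
    MtD_10           rrnL    1348    289546  214.796736         826    0.550667
...
stop completion cox2: confirmed (24/31 reads with poly(A))
```

The rrnL cistron dominates the library and the rarest cistrons draw a
handful of reads, matching the imposed ~321-fold abundance range; reads
ending at cox2's genomic `...T` carry poly(A) soft clips that complete the
`TAA` stop.

The same stages are available as CLI subcommands (`mitocistron
annotate-qc | cistrons | simulate | map | quantify | report`), each a thin
wrapper over the functions above.

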