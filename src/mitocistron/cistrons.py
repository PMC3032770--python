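"""tRNA-punctuation prediction of mature mitochondrial transcripts.

Both mitochondrial strands are transcribed end-to-end as polycistronic
primary transcripts.  Processing cleaves each primary transcript at the
interspersed tRNA loci (whose cloverleaf fold marks the cut sites), leaving
mature cistrons that carry one, two or three protein-coding/rRNA genes:
genes not separated by a tRNA stay on one transcript, which is forced
whenever neighbouring coding sequences overlap on the genome.

The cleavage geometry is modelled on the genome axis: punctuating tRNA
intervals are removed, the maximal uncovered intervals are the candidate
fragments, and every same-strand PCG/rRNA is assigned to the fragment it
overlaps most (a gene whose edge strays a few bp into a flanking tRNA locus
— overlaps of 1-7 bp between genes and tRNAs occur in real annotations —
still belongs to its main fragment).  Fragments with no same-strand coding
gene are antisense noise and are discarded.  Which tRNAs punctuate is a
configurable rule; see :data:`PUNCTUATION_RULES`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .model import Annotation, GeneFeature, gene_overlap

__all__ = [
    "Cistron",
    "PUNCTUATION_RULES",
    "punctuate",
    "predict_cistrons",
    "punctuation_fragments",
    "multigene_cistrons",
    "overlap_implies_cocistronic_check",
    "write_cistron_bed",
    "write_cistron_tsv",
]

#: Supported punctuation rules.
#:
#: ``all``
#:     every tRNA locus cleaves both strands' transcripts (default: the
#:     antisense copy of a tRNA is assumed recognizable/cleavable too);
#: ``same-strand-only``
#:     only tRNAs encoded on the strand being processed cleave it (the
#:     classical reading: only a sense tRNA folds into a cloverleaf);
#: ``all-except-overlapping``
#:     every tRNA cleaves except one whose locus overlaps a PCG encoded on
#:     the strand being processed.
PUNCTUATION_RULES = ("all", "same-strand-only", "all-except-overlapping")


@dataclass(frozen=True)
class Cistron:
    """A predicted mature (poly)cistronic transcript.

    ``span`` is on the forward genome axis (1-based inclusive); ``genes``
    are same-strand feature names in transcription order (decreasing genome
    coordinate for the L strand); ``arity`` counts PCGs + rRNAs.
    """

    id: str
    strand: str
    start: int
    end: int
    genes: tuple[str, ...]
    arity: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return {1: "monocistronic", 2: "bicistronic", 3: "tricistronic"}.get(
            self.arity, f"{self.arity}-cistronic"
        )


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _punctuating_trnas(
    ann: Annotation, strand: str, rule: str
) -> list[GeneFeature]:
    trnas = ann.trnas
    if rule == "all":
        return trnas
    if rule == "same-strand-only":
        return [t for t in trnas if t.strand == strand]
    if rule == "all-except-overlapping":
        sense_pcgs = [f for f in ann.pcgs if f.strand == strand]
        return [
            t for t in trnas if not any(gene_overlap(t, p) > 0 for p in sense_pcgs)
        ]
    raise ValueError(f"unknown punctuation rule {rule!r}; choose from {PUNCTUATION_RULES}")


def punctuation_fragments(
    ann: Annotation,
    strand: str,
    rule: str = "all",
    genome_length: Optional[int] = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(punctuating tRNA intervals merged, uncovered fragments) for one strand.

    Together the two lists partition ``[1, genome_length]`` exactly.  On a
    linear (partial) genome the transcript ends also terminate fragments;
    zero-length gaps between overlapping tRNAs produce no fragment.
    """
    length = genome_length or ann.span_end
    cuts = _merge_intervals([t.interval() for t in _punctuating_trnas(ann, strand, rule)])
    frags: list[tuple[int, int]] = []
    pos = 1
    for s, e in cuts:
        if s > pos:
            frags.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= length:
        frags.append((pos, length))
    return cuts, frags


def punctuate(
    ann: Annotation,
    strand: str,
    rule: str = "all",
    genome_length: Optional[int] = None,
    id_prefix: str = "Mt",
) -> list[Cistron]:
    """Cleave one strand's primary transcript at tRNA loci; emit sense cistrons.

    Fragments (maximal intervals not covered by punctuating tRNAs) that
    carry at least one same-strand PCG or rRNA are retained; each such gene
    goes to the fragment of maximal overlap (ties to the earlier fragment)
    and the cistron span is the fragment extended to cover its genes.
    Antisense-only fragments are discarded.  With no tRNA in the annotation
    the whole strand is returned as a single cistron, with a warning.
    """
    if strand not in ("H", "L"):
        raise ValueError(f"strand must be H or L, got {strand!r}")
    length = genome_length or ann.span_end
    if not ann.trnas:
        warnings.warn(
            "annotation contains no tRNA: returning the whole strand as one cistron"
        )
        frags = [(1, length)]
    else:
        _, frags = punctuation_fragments(ann, strand, rule, length)

    sense = [f for f in ann.features if f.strand == strand]
    coding = [f for f in sense if f.ftype in ("PCG", "rRNA")]
    # assign every same-strand feature to its best fragment
    assigned: dict[int, list[GeneFeature]] = {i: [] for i in range(len(frags))}
    for f in sense:
        best_i, best_ov = None, 0
        for i, (s, e) in enumerate(frags):
            ov = max(0, min(e, f.end) - max(s, f.start) + 1)
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i is not None:
            assigned[best_i].append(f)
        elif f in coding:
            warnings.warn(f"{f.name}: no fragment overlap; feature not in any cistron")

    cistrons: list[Cistron] = []
    order = range(len(frags)) if strand == "H" else range(len(frags) - 1, -1, -1)
    for i in order:
        feats = assigned[i]
        n_coding = sum(1 for f in feats if f.ftype in ("PCG", "rRNA"))
        if n_coding == 0:
            continue
        s, e = frags[i]
        s = min([s] + [f.start for f in feats])
        e = max([e] + [f.end for f in feats])
        feats_tx = sorted(feats, key=lambda f: f.start, reverse=(strand == "L"))
        cistrons.append(
            Cistron(
                id=f"{id_prefix}{strand}_{len(cistrons) + 1:02d}",
                strand=strand,
                start=s,
                end=e,
                genes=tuple(f.name for f in feats_tx),
                arity=n_coding,
            )
        )
    return cistrons


def predict_cistrons(
    ann: Annotation,
    rule: str = "all",
    genome_length: Optional[int] = None,
    id_prefix: str = "Mt",
) -> list[Cistron]:
    """Punctuate both strands; cistrons renumbered by genome position.

    The combined ids follow the contig-style scheme ``<prefix>D_<ordinal>``
    so that e.g. the first cistron on the genome is ``MtD_01``.
    """
    both = punctuate(ann, "H", rule, genome_length) + punctuate(
        ann, "L", rule, genome_length
    )
    both.sort(key=lambda c: (c.start, c.end))
    return [
        Cistron(
            id=f"{id_prefix}D_{i + 1:02d}",
            strand=c.strand,
            start=c.start,
            end=c.end,
            genes=c.genes,
            arity=c.arity,
        )
        for i, c in enumerate(both)
    ]


def multigene_cistrons(cistrons: Iterable[Cistron]) -> list[Cistron]:
    """Cistrons carrying two or more PCG/rRNA genes (bi-/tricistronic...)."""
    return [c for c in cistrons if c.arity >= 2]


@dataclass
class CocistronicReport:
    """Outcome of the overlap => co-cistronic consistency check."""

    violations: list[str] = field(default_factory=list)
    checked_pairs: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations


def overlap_implies_cocistronic_check(
    ann: Annotation, cistrons: Iterable[Cistron]
) -> CocistronicReport:
    """Verify that same-strand overlapping PCGs always share a cistron.

    Overlapping coding sequences cannot be separated without destroying one
    reading frame, so a sound cleavage prediction must keep them on one
    mature transcript.
    """
    rep = CocistronicReport()
    gene_to_cistron: dict[str, str] = {}
    for c in cistrons:
        for g in c.genes:
            gene_to_cistron[g.lower()] = c.id
    pcgs = ann.pcgs
    for i, a in enumerate(pcgs):
        for b in pcgs[i + 1 :]:
            if a.strand != b.strand or gene_overlap(a, b) == 0:
                continue
            rep.checked_pairs += 1
            ca = gene_to_cistron.get(a.key)
            cb = gene_to_cistron.get(b.key)
            if ca is None or cb is None or ca != cb:
                rep.violations.append(
                    f"{a.name} and {b.name} overlap by {gene_overlap(a, b)} bp "
                    f"but are in cistrons {ca} / {cb}"
                )
    return rep


def write_cistron_bed(cistrons: Iterable[Cistron], path: str | Path) -> None:
    """BED6 (0-based half-open; strand H -> '+', L -> '-')."""
    lines = []
    for c in cistrons:
        lines.append(
            "\t".join(
                [
                    "genome",
                    str(c.start - 1),
                    str(c.end),
                    c.id,
                    str(c.arity),
                    "+" if c.strand == "H" else "-",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cistron_tsv(cistrons: Iterable[Cistron], path: str | Path) -> None:
    lines = ["cistron_id\tstrand\tstart\tend\tlength\tarity\tgenes"]
    for c in cistrons:
        lines.append(
            f"{c.id}\t{c.strand}\t{c.start}\t{c.end}\t{c.length}\t{c.arity}\t"
            + ",".join(c.genes)
        )
    Path(path).write_text("\n".join(lines) + "\n")
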