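"""Synthetic mitogenomes, mature transcripts and 454-style EST reads.

Every pipeline stage can be exercised against data with known ground truth:

* :func:`generate_genome` builds an AT-rich genome realizing a requested
  gene layout (order, strands, lengths, signed intergenic gaps — negative
  gaps are overlaps).  Protein-coding genes get a valid start codon, a stop
  (full TAA/TAG or a truncated T/TA at the genomic level) and an interior
  free of in-frame stop codons; interiors follow a positional nucleotide
  model in which the third codon position is far more AT-rich than the
  first two, as in real insect mitogenomes.  Overlapping genes share bases
  positionally (no attempt at dual-frame coding validity).
* :func:`generate_transcripts` applies tRNA-punctuation cleavage and emits
  the mature cistron sequences (strand-correct), appending sampled poly(A)
  tails to the configured cistrons.
* :func:`simulate_reads` samples reads from the transcript pool with
  per-cistron abundances spanning orders of magnitude, a truncated-normal
  length distribution, and a 454-like error model (substitutions, indels,
  homopolymer-run extension).

Default parameters are the study conditions of the packaged reference
tables: the table2 layout, 80% A+T, Table 4 abundance weights over 7,608
reads, and poly(A) tails on the two cistrons observed to carry them (the
cox2 monocistron and the atp8/atp6/cox3 tricistron).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cistrons import Cistron, predict_cistrons
from .codons import invertebrate_mito_code, translate_cds
from .datasets import load_expression_profile, load_mitogenome_annotation
from .model import Annotation, GeneFeature, GenomeSequence

__all__ = [
    "GeneSpec",
    "GenomeSpec",
    "TranscriptomeSpec",
    "Transcript",
    "generate_genome",
    "generate_transcripts",
    "simulate_reads",
    "cistron_label",
    "write_truth_table",
]


@dataclass(frozen=True)
class GeneSpec:
    """Layout entry for one gene: what to place, where placement is implied
    by order and gaps."""

    name: str
    ftype: str
    strand: str
    length: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic mitogenome.

    ``gaps`` has one signed entry per adjacent gene pair: positive values
    are intergenic spacers, negative values overlap the next gene into the
    previous one (e.g. -7 reproduces a 7 bp coding overlap).  ``at_target``
    is the background A+T fraction; PCG interiors instead follow
    ``at_by_position`` per codon position.
    """

    genes: tuple[GeneSpec, ...]
    gaps: tuple[int, ...]
    at_target: float = 0.80
    at_by_position: tuple[float, float, float] = (0.73, 0.698, 0.94)
    leading_gap: int = 0
    trailing_gap: int = 0
    topology: str = "linear"
    seed: int = 0
    genome_id: str = "synthetic_mito"

    def __post_init__(self) -> None:
        if len(self.gaps) != max(len(self.genes) - 1, 0):
            raise ValueError("need exactly one gap per adjacent gene pair")
        if not (0.0 < self.at_target < 1.0):
            raise ValueError("at_target must be in (0, 1)")
        for g, gap in zip(self.genes[:-1], self.gaps):
            if gap < 0 and -gap >= g.length:
                raise ValueError(f"overlap {-gap} bp not smaller than gene {g.name}")

    @property
    def overlaps(self) -> list[tuple[str, str, int]]:
        out = []
        for i, gap in enumerate(self.gaps):
            if gap < 0:
                out.append((self.genes[i].name, self.genes[i + 1].name, -gap))
        return out

    @classmethod
    def table2(cls, seed: int = 0) -> "GenomeSpec":
        """The packaged reference layout: 34 genes, published coordinates.

        Gene lengths and signed gaps are derived from the packaged
        annotation so the generated annotation reproduces its coordinates
        exactly; genome length is the last feature end (14,139 bp).
        """
        ann = load_mitogenome_annotation()
        genes = []
        gaps = []
        prev: Optional[GeneFeature] = None
        for f in ann.features:
            stop = f.stop_codon
            if f.ftype == "PCG" and stop is None:
                stop = {0: "TAA", 1: "T", 2: "TA"}[f.length % 3]
            genes.append(
                GeneSpec(
                    name=f.name,
                    ftype=f.ftype,
                    strand=f.strand,
                    length=f.length,
                    start_codon=f.start_codon if f.ftype == "PCG" else None,
                    stop_codon=stop if f.ftype == "PCG" else None,
                )
            )
            if prev is not None:
                gaps.append(f.start - prev.end - 1)
            prev = f
        return cls(
            genes=tuple(genes),
            gaps=tuple(gaps),
            leading_gap=0,
            trailing_gap=0,
            seed=seed,
            genome_id="synthetic_mito_table2",
        )


def _sample_bases(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _sample_codon(
    rng: np.random.Generator, at_by_pos: Sequence[float], forbid_stops: bool = True
) -> str:
    while True:
        codon = "".join(
            rng.choice(["A", "T"] if rng.random() < at_by_pos[p] else ["C", "G"])
            for p in range(3)
        )
        if not forbid_stops or codon not in ("TAA", "TAG"):
            return codon


def _gene_sense_positions(f: GeneFeature) -> list[int]:
    """Genome positions (1-based) of the gene, 5'->3' in gene sense."""
    if f.strand == "H":
        return list(range(f.start, f.end + 1))
    return list(range(f.end, f.start - 1, -1))


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _write_gene_sense(
    seq: list[str], f: GeneFeature, content: str, frozen: Optional[np.ndarray] = None
) -> None:
    for pos, base in zip(_gene_sense_positions(f), content):
        if frozen is not None and frozen[pos - 1]:
            continue
        seq[pos - 1] = base if f.strand == "H" else _COMP[base]


def _read_gene_sense(seq: list[str], f: GeneFeature) -> str:
    out = []
    for pos in _gene_sense_positions(f):
        b = seq[pos - 1]
        out.append(b if f.strand == "H" else _COMP[b])
    return "".join(out)


def generate_genome(
    spec: GenomeSpec, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeSequence, Annotation, dict]:
    """Realize a :class:`GenomeSpec` as (genome, annotation, truth manifest).

    Deterministic under ``spec.seed``.  PCG start/stop codons are frozen
    and interiors are repaired until no in-frame stop codon remains in any
    gene (overlapping genes constrain each other; a handful of repair
    passes suffices for realistic layouts).
    """
    rng = rng or np.random.default_rng(spec.seed)
    # ---- coordinates from lengths and signed gaps
    feats: list[GeneFeature] = []
    pos = 1 + spec.leading_gap
    for i, g in enumerate(spec.genes):
        start, end = pos, pos + g.length - 1
        feats.append(
            GeneFeature(
                name=g.name,
                ftype=g.ftype,
                strand=g.strand,
                start=start,
                end=end,
                start_codon=g.start_codon,
                stop_codon=g.stop_codon,
                declared_length=g.length,
            )
        )
        if i < len(spec.gaps):
            pos = end + 1 + spec.gaps[i]
        else:
            pos = end + 1
    length = max(f.end for f in feats) + spec.trailing_gap
    ann = Annotation(genome_id=spec.genome_id, features=feats)

    # ---- background sequence at the target A+T fraction
    seq = [b.decode() for b in _sample_bases(rng, length, spec.at_target)]
    frozen = np.zeros(length, dtype=bool)

    pcgs = [f for f in ann.features if f.ftype == "PCG"]
    # pass 1: interiors (later genes overwrite earlier in shared bases)
    for f in pcgs:
        n_full = f.length // 3
        codons = [_sample_codon(rng, spec.at_by_position) for _ in range(n_full)]
        content = "".join(codons) + "T" * (f.length % 3)  # placeholder tail
        _write_gene_sense(seq, f, content)
    # pass 2: start codons and stops, frozen against repair
    for f in pcgs:
        start_codon = f.start_codon or "ATG"
        stop = f.stop_codon or {0: "TAA", 1: "T", 2: "TA"}[f.length % 3]
        _write_gene_sense(seq, f, start_codon)
        positions = _gene_sense_positions(f)
        for p in positions[:3]:
            frozen[p - 1] = True
        # write the stop (or its truncated prefix) at the gene's 3' end
        for p, base in zip(positions[-len(stop) :], stop):
            seq[p - 1] = base if f.strand == "H" else _COMP[base]
            frozen[p - 1] = True
    # pass 3: repair in-frame stops introduced by overlaps/overwrites
    for _ in range(100):
        dirty = False
        for f in pcgs:
            content = _read_gene_sense(seq, f)
            n_full = f.length // 3
            has_full_stop = f.length % 3 == 0 and (f.stop_codon or "TAA") in ("TAA", "TAG")
            last_internal = n_full - 1 if has_full_stop else n_full
            for j in range(1, last_internal):
                codon = content[3 * j : 3 * j + 3]
                if codon in ("TAA", "TAG"):
                    dirty = True
                    positions = _gene_sense_positions(f)[3 * j : 3 * j + 3]
                    if all(frozen[p - 1] for p in positions):
                        raise RuntimeError(
                            f"{f.name}: frozen in-frame stop at codon {j + 1}; "
                            "layout infeasible"
                        )
                    new = _sample_codon(rng, spec.at_by_position)
                    for p, base in zip(positions, new):
                        if not frozen[p - 1]:
                            seq[p - 1] = base if f.strand == "H" else _COMP[base]
        if not dirty:
            break
    else:  # pragma: no cover - pathological layouts only
        raise RuntimeError("could not remove all in-frame stops")

    genome = GenomeSequence(
        id=spec.genome_id, residues="".join(seq), topology=spec.topology
    )
    # sanity: every PCG translates without internal stops
    code = invertebrate_mito_code()
    for f in pcgs:
        cds = genome.subseq(f.start, f.end, f.strand)
        if f.length % 3:
            cds = cds + "A" * (3 - f.length % 3)
        translate_cds(cds, code, is_annotated_start=True)
    manifest = {
        "seed": spec.seed,
        "genome_id": spec.genome_id,
        "length": length,
        "at_target": spec.at_target,
        "n_features": len(feats),
        "overlaps": spec.overlaps,
    }
    return genome, ann, manifest


# ---------------------------------------------------------------------------
# Transcripts


def cistron_label(c: Cistron, ann: Annotation) -> str:
    """Canonical content label of a cistron: sorted coding genes joined by '+'."""
    coding = [g for g in c.genes if ann.get(g).ftype in ("PCG", "rRNA")]
    return "+".join(sorted(coding))


#: Published relative abundances (library proportions, %) by cistron content.
TABLE4_WEIGHTS: dict[str, float] = {
    "nd2": 0.2,
    "cox1": 6.9,
    "cox2": 6.0,
    "atp6+atp8+cox3": 4.2,
    "nd5": 0.6,
    "nd4+nd4L": 2.2,
    "cytb+nd6": 2.7,
    "nd1": 2.1,
    "rrnL": 32.1,
    "rrnS": 0.1,
}


@dataclass(frozen=True)
class TranscriptomeSpec:
    """Recipe for mature transcripts and a simulated read library.

    ``abundances`` maps cistron content labels (see :func:`cistron_label`)
    to relative weights; labels absent or weighted 0 yield no transcript
    species.  ``polyA`` maps labels to (probability, mean tail length, sd).
    ``error_rates`` is (substitution, insertion, deletion,
    homopolymer-extension-per-run) per base/run.
    """

    abundances: dict[str, float] = field(
        default_factory=lambda: dict(TABLE4_WEIGHTS)
    )
    polyA: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "cox2": (1.0, 30.0, 8.0),
            "atp6+atp8+cox3": (1.0, 30.0, 8.0),
        }
    )
    n_reads: int = 7608
    read_length: tuple[float, float, int, int] = (350.0, 50.0, 50, 600)
    error_rates: tuple[float, float, float, float] = (0.005, 0.0025, 0.0025, 0.02)
    both_orientations: bool = False
    punctuation_rule: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not any(w > 0 for w in self.abundances.values()):
            raise ValueError("at least one abundance weight must be positive")
        if any(w < 0 for w in self.abundances.values()):
            raise ValueError("abundance weights must be non-negative")


@dataclass(frozen=True)
class Transcript:
    """A mature transcript species with its truth (cistron, tail)."""

    id: str
    cistron_id: str
    label: str
    strand: str
    start: int
    end: int
    seq: str
    tail_len: int

    @property
    def length(self) -> int:
        return len(self.seq)


def generate_transcripts(
    genome: GenomeSequence,
    ann: Annotation,
    spec: Optional[TranscriptomeSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Transcript]:
    """Mature transcripts from punctuation cleavage, with sampled poly(A) tails.

    One species per predicted cistron whose content label has a positive
    abundance weight; the sequence is the exact cistron span in
    strand-correct orientation plus any appended tail.
    """
    spec = spec or TranscriptomeSpec()
    rng = rng or np.random.default_rng(spec.seed)
    cistrons = predict_cistrons(
        ann, rule=spec.punctuation_rule, genome_length=genome.length
    )
    out = []
    for c in cistrons:
        label = cistron_label(c, ann)
        if spec.abundances.get(label, 0.0) <= 0.0:
            continue
        body = genome.subseq(c.start, c.end, c.strand)
        tail_len = 0
        prob, mean, sd = spec.polyA.get(label, (0.0, 0.0, 0.0))
        if prob > 0 and rng.random() < prob:
            tail_len = max(5, int(round(rng.normal(mean, sd))))
        out.append(
            Transcript(
                id=f"tx_{c.id}",
                cistron_id=c.id,
                label=label,
                strand=c.strand,
                start=c.start,
                end=c.end,
                seq=body + "A" * tail_len,
                tail_len=tail_len,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reads


def _apply_errors(
    frag: str, rng: np.random.Generator, rates: tuple[float, float, float, float]
) -> str:
    p_sub, p_ins, p_del, p_hp = rates
    bases = "ACGT"
    out: list[str] = []
    for b in frag:
        if p_del and rng.random() < p_del:
            continue
        if p_ins and rng.random() < p_ins:
            out.append(bases[rng.integers(4)])
        if p_sub and rng.random() < p_sub:
            out.append(bases[(bases.index(b) + 1 + rng.integers(3)) % 4])
        else:
            out.append(b)
    if p_hp:
        # extend homopolymer runs of length >= 3 with an extra copy
        s = "".join(out)
        res: list[str] = []
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            run = s[i:j]
            if len(run) >= 3 and rng.random() < p_hp:
                run += s[i]
            res.append(run)
            i = j
        return "".join(res)
    return "".join(out)


def simulate_reads(
    transcripts: Sequence[Transcript],
    spec: Optional[TranscriptomeSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Sample a read library from the transcript pool; (reads, truth table).

    Reads are drawn from transcripts with probability proportional to the
    abundance weights, start positions uniform, lengths truncated-normal; a
    sampled length exceeding the transcript is resampled (the event is
    counted in the truth table attrs).  Deterministic under ``spec.seed``.
    """
    spec = spec or TranscriptomeSpec()
    rng = rng or np.random.default_rng(spec.seed)
    if not transcripts:
        raise ValueError("no transcripts to sample from")
    weights = np.array(
        [spec.abundances.get(t.label, 0.0) for t in transcripts], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("no transcript has positive abundance")
    weights = weights / weights.sum()
    mean, sd, lo, hi = spec.read_length
    reads: list[SeqRecord] = []
    truth_rows = []
    n_resampled = 0
    for i in range(spec.n_reads):
        ti = int(rng.choice(len(transcripts), p=weights))
        t = transcripts[ti]
        for _ in range(100):
            ln = int(round(rng.normal(mean, sd)))
            ln = min(max(ln, lo), hi)
            if ln <= t.length:
                break
            n_resampled += 1
        else:
            ln = t.length
        start = int(rng.integers(0, t.length - ln + 1))
        frag = t.seq[start : start + ln]
        tail_in_read = max(0, (start + ln) - (t.length - t.tail_len))
        reverse = bool(spec.both_orientations and rng.random() < 0.5)
        if reverse:
            frag = str(Seq(frag).reverse_complement())
        read_seq = _apply_errors(frag, rng, spec.error_rates)
        rid = f"simread_{i:06d}"
        rec = SeqRecord(Seq(read_seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [30] * len(read_seq)
        reads.append(rec)
        truth_rows.append(
            {
                "read_id": rid,
                "transcript_id": t.id,
                "cistron_id": t.cistron_id,
                "label": t.label,
                "t_start": start,
                "t_end": start + ln - 1,
                "reverse": reverse,
                "tail_bases": tail_in_read,
                "read_len": len(read_seq),
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_resampled_lengths"] = n_resampled
    return reads, truth


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
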