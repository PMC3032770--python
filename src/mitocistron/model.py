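"""Genome sequence and feature-annotation model for insect mitogenomes.

Coordinates are stored 1-based inclusive on the forward (heavy, H) axis with
an explicit strand flag.  Published feature tables for mitogenomes are often
written in *transcription* orientation — light (L) strand rows list their
5' start at the higher genome coordinate — so :func:`read_annotation_table`
normalizes every interval to ``start = min, end = max`` at read time.  This
keeps all interval arithmetic (lengths, overlaps, gaps) strand-free while
the strand flag preserves orientation for sequence extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "GeneFeature",
    "Annotation",
    "ValidationReport",
    "AnnotationParseError",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_feature_table",
    "write_gff3",
    "feature_length",
    "gene_overlap",
    "gene_gap",
    "validate_annotation",
]

#: Nucleotide letters accepted in a genome sequence (IUPAC DNA + N).
IUPAC_DNA = frozenset("ACGTUNRYSWKMBDHV")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA")
STRANDS = ("H", "L")

#: Bounds on a plausible mitochondrial tRNA gene length (bp).
TRNA_MIN_LEN = 40
TRNA_MAX_LEN = 100


class AnnotationParseError(ValueError):
    """Raised for malformed annotation input; names the offending line."""


@dataclass(frozen=True)
class GenomeSequence:
    """A mitochondrial genome (or fragment thereof).

    Parameters
    ----------
    id :
        Sequence identifier (FASTA header word).
    residues :
        Uppercase IUPAC DNA string.
    topology :
        ``"linear"`` for partial assemblies (e.g. one lacking the AT-rich
        control region) or ``"circular"`` for complete mitogenomes.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        seq = self.residues.upper().replace("U", "T")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC residues in genome: {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    def subseq(self, start: int, end: int, strand: str = "H") -> str:
        """Extract ``[start, end]`` (1-based inclusive); revcomp if strand L."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval [{start}, {end}] outside genome (1..{self.length})")
        s = self.residues[start - 1 : end]
        if strand == "L":
            s = str(Seq(s).reverse_complement())
        return s


def read_fasta(path: str | Path, topology: str = "linear") -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AnnotationParseError(f"{path}: no FASTA records")
    rec = records[0]
    return GenomeSequence(id=rec.id, residues=str(rec.seq), topology=topology)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    # wrapped at 70 columns
    lines = [f">{genome.id}"]
    for i in range(0, genome.length, 70):
        lines.append(genome.residues[i : i + 70])
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated mitochondrial gene (PCG, tRNA or rRNA).

    ``start <= end`` always holds (normalized coordinates); ``strand`` alone
    carries orientation.  ``declared_length`` is the length as published in
    the source table, which may disagree with ``end - start + 1``.
    """

    name: str
    ftype: str
    strand: str
    start: int
    end: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None
    declared_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.name}: invalid interval [{self.start}, {self.end}] "
                "(need 1 <= start <= end)"
            )
        if self.stop_codon is not None and self.stop_codon not in ("TAA", "TAG", "T", "TA"):
            raise ValueError(f"{self.name}: invalid stop codon {self.stop_codon!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        """Normalized lookup name (lowercase token + modifier)."""
        return self.name.lower()

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def feature_length(f: GeneFeature) -> int:
    """Length in bp of the genomic interval (end - start + 1)."""
    return f.length


def gene_overlap(f1: GeneFeature, f2: GeneFeature) -> int:
    """Size (bp) of the interval intersection of two features; strand-agnostic."""
    return max(0, min(f1.end, f2.end) - max(f1.start, f2.start) + 1)


def gene_gap(f1: GeneFeature, f2: GeneFeature) -> int:
    """Intergenic distance in bp (0 if the features touch or overlap)."""
    if gene_overlap(f1, f2) > 0:
        return 0
    lo, hi = sorted([f1, f2], key=lambda f: f.start)
    return max(0, hi.start - lo.end - 1)


@dataclass
class Annotation:
    """An ordered set of gene features on one genome."""

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        key = name.lower()
        for f in self.features:
            if f.key == key:
                return f
        raise KeyError(name)

    def by_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.by_type("PCG")

    @property
    def trnas(self) -> list[GeneFeature]:
        return self.by_type("tRNA")

    @property
    def rrnas(self) -> list[GeneFeature]:
        return self.by_type("rRNA")

    def counts_by_type(self) -> dict[str, int]:
        return {t: len(self.by_type(t)) for t in FEATURE_TYPES}

    @property
    def span_end(self) -> int:
        return max((f.end for f in self.features), default=0)

    def overlapping_pairs(self, same_strand_only: bool = False) -> list[tuple[str, str, int]]:
        """All feature pairs with a positive interval intersection."""
        out = []
        feats = self.features
        for i, a in enumerate(feats):
            for b in feats[i + 1 :]:
                if b.start > a.end:
                    break
                if same_strand_only and a.strand != b.strand:
                    continue
                ov = gene_overlap(a, b)
                if ov > 0:
                    out.append((a.name, b.name, ov))
        return out


# ---------------------------------------------------------------------------
# Table dialect I/O

TABLE_COLUMNS = [
    "name",
    "ftype",
    "strand",
    "start5",
    "stop3",
    "length",
    "start_codon",
    "stop_codon",
    "anticodon",
]


def _missing(v: str) -> Optional[str]:
    v = v.strip()
    return None if v in ("", ".", "-", "NA") else v


def _parse_table_row(fields: dict[str, str], lineno: int, path: str) -> GeneFeature:
    try:
        start5 = int(fields["start5"])
        stop3 = int(fields["stop3"])
    except (KeyError, ValueError) as exc:
        raise AnnotationParseError(f"{path}:{lineno}: bad coordinates ({exc})") from None
    declared = _missing(fields.get("length", "."))
    try:
        return GeneFeature(
            name=fields["name"],
            ftype=fields["ftype"],
            strand=fields["strand"],
            start=min(start5, stop3),
            end=max(start5, stop3),
            start_codon=_missing(fields.get("start_codon", ".")),
            stop_codon=_missing(fields.get("stop_codon", ".")),
            anticodon=_missing(fields.get("anticodon", ".")),
            declared_length=int(declared) if declared else None,
        )
    except (KeyError, ValueError) as exc:
        raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None


def _read_table_tsv(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                if cols[0] != "name":
                    raise AnnotationParseError(
                        f"{path}:{lineno}: expected header starting with 'name'"
                    )
                header = cols
                missing = {"name", "ftype", "strand", "start5", "stop3"} - set(header)
                if missing:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}"
                    )
                continue
            if len(cols) < len(header):
                cols = cols + ["."] * (len(header) - len(cols))
            feats.append(_parse_table_row(dict(zip(header, cols)), lineno, str(path)))
    return feats


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    type_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
    feats = []
    for f in db.all_features():
        if f.featuretype not in type_map:
            continue
        attrs = {k: v[0] for k, v in f.attributes.items() if v}
        feats.append(
            GeneFeature(
                name=attrs.get("ID", attrs.get("Name", f.id)),
                ftype=type_map[f.featuretype],
                strand="L" if f.strand == "-" else "H",
                start=f.start,
                end=f.end,
                start_codon=attrs.get("start_codon"),
                stop_codon=attrs.get("stop_codon"),
                anticodon=attrs.get("anticodon"),
                declared_length=int(attrs["declared_length"])
                if "declared_length" in attrs
                else None,
            )
        )
    return feats


def read_annotation_table(
    path: str | Path,
    dialect: str = "table2_tsv",
    genome: Optional[GenomeSequence] = None,
    genome_id: Optional[str] = None,
) -> Annotation:
    """Read an annotation from a feature table.

    Dialects
    --------
    ``table2_tsv``
        Tab-separated with columns ``name ftype strand start5 stop3
        [length start_codon stop_codon anticodon]``.  Rows written in
        transcription orientation (``start5 > stop3``) are normalized to
        forward-axis intervals with ``strand = L`` kept from the strand
        column.
    ``gff3``
        GFF3 (1-based inclusive); feature types CDS/tRNA/rRNA, strand
        ``-`` mapped to L.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if dialect == "table2_tsv":
        feats = _read_table_tsv(p)
    elif dialect == "gff3":
        feats = _read_gff3(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not feats:
        raise AnnotationParseError(f"{path}: no features found")
    ann = Annotation(
        genome_id=genome_id or (genome.id if genome else p.stem), features=feats
    )
    if genome is not None:
        bad = [f for f in ann.features if f.end > genome.length]
        if bad:
            raise AnnotationParseError(
                f"{path}: features beyond genome end ({genome.length} bp): "
                + ", ".join(f.name for f in bad)
            )
    return ann


def write_feature_table(ann: Annotation, path: str | Path) -> None:
    """Write the table dialect; L-strand rows in transcription orientation."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for f in ann.features:
        start5, stop3 = (f.end, f.start) if f.strand == "L" else (f.start, f.end)
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.ftype,
                    f.strand,
                    str(start5),
                    str(stop3),
                    str(f.declared_length) if f.declared_length is not None else ".",
                    f.start_codon or ".",
                    f.stop_codon or ".",
                    f.anticodon or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


_GFF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def write_gff3(ann: Annotation, path: str | Path) -> None:
    """Write GFF3 (version 3, 1-based inclusive; strand H -> '+', L -> '-')."""
    lines = ["##gff-version 3"]
    for f in ann.features:
        attrs = [f"ID={f.name}"]
        if f.start_codon:
            attrs.append(f"start_codon={f.start_codon}")
        if f.stop_codon:
            attrs.append(f"stop_codon={f.stop_codon}")
        if f.anticodon:
            attrs.append(f"anticodon={f.anticodon}")
        if f.declared_length is not None:
            attrs.append(f"declared_length={f.declared_length}")
        lines.append(
            "\t".join(
                [
                    ann.genome_id,
                    "mitocistron",
                    _GFF_TYPE[f.ftype],
                    str(f.start),
                    str(f.end),
                    ".",
                    "+" if f.strand == "H" else "-",
                    "0" if f.ftype == "PCG" else ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_annotation`: hard violations vs warnings."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        parts = [f"{len(self.violations)} violation(s), {len(self.warnings)} warning(s)"]
        parts += [f"VIOLATION: {v}" for v in self.violations]
        parts += [f"warning: {w}" for w in self.warnings]
        return "\n".join(parts)


def validate_annotation(
    ann: Annotation, genome: Optional[GenomeSequence] = None
) -> ValidationReport:
    """Check an annotation for structural problems.

    Hard violations: empty feature list, duplicate names, features beyond
    genome bounds.  Warnings: declared length differing from the coordinate
    span (published tables do contain such rows), tRNA lengths outside
    40-100 bp, PCGs whose length mod 3 is inconsistent with their stop codon
    (full stops need mod 0, a bare T needs mod 1, TA needs mod 2).
    """
    rep = ValidationReport()
    if not ann.features:
        rep.violations.append("no features")
        return rep
    seen: dict[str, int] = {}
    for f in ann.features:
        seen[f.key] = seen.get(f.key, 0) + 1
    for name, n in seen.items():
        if n > 1:
            rep.violations.append(f"duplicate feature name {name!r} (x{n})")
    for f in ann.features:
        if genome is not None and f.end > genome.length:
            rep.violations.append(
                f"{f.name}: end {f.end} beyond genome length {genome.length}"
            )
        if f.declared_length is not None and f.declared_length != f.length:
            rep.warnings.append(
                f"{f.name}: declared length {f.declared_length} != "
                f"coordinate length {f.length}"
            )
        if f.ftype == "tRNA" and not (TRNA_MIN_LEN <= f.length <= TRNA_MAX_LEN):
            rep.warnings.append(
                f"{f.name}: tRNA length {f.length} outside "
                f"[{TRNA_MIN_LEN}, {TRNA_MAX_LEN}]"
            )
        if f.ftype == "PCG" and f.stop_codon is not None:
            need = {"TAA": 0, "TAG": 0, "TA": 2, "T": 1}[f.stop_codon]
            if f.length % 3 != need:
                rep.warnings.append(
                    f"{f.name}: length {f.length} mod 3 = {f.length % 3} inconsistent "
                    f"with stop codon {f.stop_codon!r} (expects {need})"
                )
    return rep
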