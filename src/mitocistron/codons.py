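"""Invertebrate-mitochondrial translation and codon-usage statistics.

The invertebrate mitochondrial code differs from the standard code in ways
that matter for annotation: AGA/AGG encode serine (an eight-codon Ser
family), AUA encodes methionine, and UGA encodes tryptophan.  Initiation is
permissive — besides ATG, insect mitogenomes use ATA/ATT/ATC, TTG/GTG and,
for cox1 in several Lepidoptera and in Drosophila, an arginine CGA codon —
and genes abutting a downstream tRNA may end in a truncated stop (a bare T
or TA at the genomic level) that polyadenylation of the mature mRNA
completes to TAA.

All I/O is in the DNA alphabet; RNA-style input (U for T) is accepted and
an RNA display is available for codon-usage tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "CompositionStats",
    "StopCompletion",
    "FrameError",
    "PrematureStopError",
    "invertebrate_mito_code",
    "translate_cds",
    "complete_truncated_stop",
    "codon_usage",
    "at_composition",
    "position_bias_chi2",
    "write_codon_usage_tsv",
]


class FrameError(ValueError):
    """CDS length not divisible by 3 (after optional stop completion)."""


class PrematureStopError(ValueError):
    """An internal stop codon was encountered; names the codon position."""


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with start and stop codon sets (DNA alphabet)."""

    name: str
    table: Mapping[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) + len(self.stop_codons) != 64:
            raise ValueError("genetic code must cover all 64 codons")

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; '*' for stops, 'X' for ambiguity."""
        codon = _dna(codon)
        if codon in self.stop_codons:
            return "*"
        return self.table.get(codon, "X")

    def families(self) -> dict[str, list[str]]:
        """Synonymous families (amino acid -> codons); stops form family '*'."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.table):
            fams.setdefault(self.table[codon], []).append(codon)
        fams["*"] = sorted(self.stop_codons)
        return fams


def invertebrate_mito_code() -> GeneticCode:
    """The invertebrate mitochondrial genetic code (NCBI table 5) with the
    start-codon set extended by the lepidopteran/dipteran cox1 initiator CGA."""
    t5 = CodonTable.unambiguous_dna_by_id[5]
    return GeneticCode(
        name="invertebrate mitochondrial (+CGA start)",
        table=dict(t5.forward_table),
        start_codons=frozenset(t5.start_codons) | {"CGA"},
        stop_codons=frozenset(t5.stop_codons),
    )


# ---------------------------------------------------------------------------
# Translation and truncated stops


@dataclass(frozen=True)
class StopCompletion:
    """Result of :func:`complete_truncated_stop`.

    ``status`` is ``"already_complete"`` (CDS ended in TAA/TAG),
    ``"completed"`` (A nucleotides appended to finish TAA) or
    ``"not_completable"`` (no truncated stop, or the tail lacks the required
    A residues).  ``cds`` is unchanged when not completable.
    """

    cds: str
    status: str
    added: int = 0

    @property
    def completed(self) -> bool:
        return self.status in ("already_complete", "completed")


def complete_truncated_stop(cds: str, tail: str = "") -> StopCompletion:
    """Complete a genomic CDS ending in a bare T or TA to a full TAA stop.

    Mitochondrial genes cut at an immediately adjacent tRNA may lack one or
    two residues of their stop codon on the genome; polyadenylation of the
    mature transcript supplies the missing A's.  ``tail`` is the observed (or
    hypothetical) 3' tail; it must begin with enough A's to finish TAA.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = _dna(cds)
    tail = _dna(tail)
    r = len(cds) % 3
    if r == 0:
        if cds[-3:] in ("TAA", "TAG"):
            return StopCompletion(cds, "already_complete")
        return StopCompletion(cds, "not_completable")
    need = {1: ("T", "AA"), 2: ("TA", "A")}[r]
    trailing, missing = need
    if cds.endswith(trailing) and tail.startswith(missing):
        return StopCompletion(cds + missing, "completed", added=len(missing))
    return StopCompletion(cds, "not_completable")


def translate_cds(
    seq: str,
    code: Optional[GeneticCode] = None,
    is_annotated_start: bool = False,
    polyA_completed: bool = False,
) -> str:
    """Translate a CDS; trailing stop codons are dropped from the protein.

    With ``is_annotated_start`` the first codon is rendered as 'M' whatever
    the table says — the reporting convention for non-standard initiators
    (ATT, TTG, CGA, ...); a CGA that is not an annotated start still gives R.
    With ``polyA_completed`` a trailing truncated stop (T or TA) is first
    extended to TAA, mimicking polyadenylation of the mature mRNA.
    """
    code = code or invertebrate_mito_code()
    seq = _dna(seq)
    if polyA_completed:
        seq = complete_truncated_stop(seq, "AA").cds
    if len(seq) < 3:
        raise FrameError(f"CDS too short ({len(seq)} nt)")
    if len(seq) % 3:
        raise FrameError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    aas = []
    for i, codon in enumerate(codons):
        aa = code.aa(codon)
        if aa == "*":
            if i != len(codons) - 1:
                raise PrematureStopError(
                    f"internal stop codon {codon} at codon {i + 1} "
                    f"(nt {3 * i + 1}-{3 * i + 3})"
                )
            break
        aas.append(aa)
    if is_annotated_start and aas:
        aas[0] = "M"
    return "".join(aas)


# ---------------------------------------------------------------------------
# Codon usage / RSCU


@dataclass
class CodonUsageTable:
    """Per-codon counts and relative synonymous codon usage (RSCU).

    RSCU of a codon is its count divided by the mean count over its
    synonymous family under the genetic code in use; within a fully counted
    family the RSCU values average to 1.  Stop codons form their own
    two-codon family (TAA/TAG).  Codons containing non-ACGT letters are
    excluded from the tally and counted in ``n_skipped``.
    """

    counts: dict[str, int]
    code: GeneticCode
    n_skipped: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in self._all_codons()}
        full.update({_dna(c): v for c, v in self.counts.items()})
        self.counts = full

    @staticmethod
    def _all_codons() -> list[str]:
        bases = "TCAG"
        return [a + b + c for a in bases for b in bases for c in bases]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def families(self) -> dict[str, list[str]]:
        return self.code.families()

    @property
    def rscu(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for aa, codons in self.families.items():
            fam_total = sum(self.counts[c] for c in codons)
            if fam_total == 0:
                for c in codons:
                    out[c] = 0.0
            else:
                mean = fam_total / len(codons)
                for c in codons:
                    out[c] = self.counts[c] / mean
        return out

    def rscu_of(self, codon: str) -> float:
        return self.rscu[_dna(codon)]

    def count_of(self, codon: str) -> int:
        return self.counts[_dna(codon)]

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], code: Optional[GeneticCode] = None
    ) -> "CodonUsageTable":
        code = code or invertebrate_mito_code()
        return cls(counts={k: int(round(v)) for k, v in counts.items()}, code=code)


def codon_usage(
    cds_list: Iterable[str], code: Optional[GeneticCode] = None
) -> CodonUsageTable:
    """Tally codon usage (stop codons included) over a set of in-frame CDSs."""
    code = code or invertebrate_mito_code()
    counts: dict[str, int] = {}
    skipped = 0
    for idx, cds in enumerate(cds_list):
        seq = _dna(cds)
        if len(seq) % 3:
            raise FrameError(f"CDS #{idx + 1}: length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
            else:
                skipped += 1
    return CodonUsageTable(counts=counts, code=code, n_skipped=skipped)


def write_codon_usage_tsv(
    table: CodonUsageTable, path: str | Path, alphabet: str = "rna"
) -> None:
    """Write codon, amino acid, count and RSCU, one codon per row."""
    conv = _rna if alphabet == "rna" else (lambda c: c)
    rscu = table.rscu
    lines = ["codon\taa\tcount\trscu"]
    for codon in CodonUsageTable._all_codons():
        lines.append(
            f"{conv(codon)}\t{table.code.aa(codon)}\t"
            f"{table.counts[codon]}\t{rscu[codon]:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Composition statistics


@dataclass(frozen=True)
class CompositionStats:
    """A+T composition of a sequence set, optionally per codon position."""

    at_fraction: float
    n_residues: int
    at_by_codon_position: Optional[tuple[float, float, float]] = None
    n_codons: int = 0


def _at_count(seq: str) -> tuple[int, int]:
    """(A+T count, non-N denominator) for one sequence."""
    at = sum(seq.count(b) for b in "AT")
    denom = sum(seq.count(b) for b in "ACGT")
    return at, denom


def at_composition(seqs: str | Sequence[str]) -> CompositionStats:
    """Overall A+T fraction; per-codon-position fractions for CDS input.

    A single string is treated as one unframed sequence (overall fraction
    only); a list of strings is treated as in-frame CDSs, yielding the
    positional breakdown.  N and other ambiguity letters are excluded from
    numerator and denominator.
    """
    if isinstance(seqs, str):
        seq = _dna(seqs)
        if not seq:
            raise ValueError("empty input")
        at, denom = _at_count(seq)
        if denom == 0:
            raise ValueError("no unambiguous residues")
        return CompositionStats(at_fraction=at / denom, n_residues=denom)
    seq_list = [_dna(s) for s in seqs]
    if not seq_list or all(not s for s in seq_list):
        raise ValueError("empty input")
    at_tot = denom_tot = 0
    pos_at = [0, 0, 0]
    pos_denom = [0, 0, 0]
    n_codons = 0
    for seq in seq_list:
        if len(seq) % 3:
            raise FrameError(f"CDS length {len(seq)} not divisible by 3")
        n_codons += len(seq) // 3
        at, denom = _at_count(seq)
        at_tot += at
        denom_tot += denom
        for p in range(3):
            sub = seq[p::3]
            a, d = _at_count(sub)
            pos_at[p] += a
            pos_denom[p] += d
    if denom_tot == 0:
        raise ValueError("no unambiguous residues")
    by_pos = tuple(
        (pos_at[p] / pos_denom[p]) if pos_denom[p] else float("nan") for p in range(3)
    )
    return CompositionStats(
        at_fraction=at_tot / denom_tot,
        n_residues=denom_tot,
        at_by_codon_position=by_pos,  # type: ignore[arg-type]
        n_codons=n_codons,
    )


def position_bias_chi2(
    n_at_i: int, n_i: int, n_at_j: int, n_j: int
) -> tuple[float, float]:
    """Pearson 2x2 chi-square (no continuity correction) for an AT-content
    difference between two codon positions; p from chi2 with 1 df.

    The table is [AT, GC] x [position i, position j] with GC = total - AT.
    """
    if min(n_at_i, n_at_j) < 0 or n_i <= 0 or n_j <= 0:
        raise ValueError("counts must be non-negative with positive totals")
    a, b = n_at_i, n_i - n_at_i
    c, d = n_at_j, n_j - n_at_j
    if min(b, d) < 0:
        raise ValueError("AT count exceeds total")
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        raise ValueError("undefined statistic: zero marginal total")
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return chi2, float(stats.chi2.sf(chi2, df=1))
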