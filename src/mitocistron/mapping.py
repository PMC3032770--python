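"""EST read QC, seed-and-extend mapping, poly(A) detection and quantification.

Reads are filtered with the pyrosequencing-era QC rules (minimum length
50 nt; reject reads in which any single nucleotide makes up >= 60% of the
read), then placed on the genome by exact k-mer seeding on both strands
followed by banded extension (edlib edit-distance alignment within a window
around the best seed diagonal).  An alignment is reported only when it has
at least ``min_match_bases`` matching bases and a matching fraction of at
least ``min_match_pct`` over aligned columns.  The unaligned 3' suffix of
the read is kept as a soft clip, which is where transcript poly(A) tails
end up; per-cistron expression is quantified as read counts, total aligned
nucleotides and mean depth (total nt / cistron length).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cistrons import Cistron
from .codons import complete_truncated_stop
from .model import Annotation, GeneFeature, GenomeSequence

__all__ = [
    "ReadAlignment",
    "CistronExpression",
    "GenomeIndex",
    "read_reads",
    "filter_reads",
    "map_read",
    "map_reads",
    "detect_polyA",
    "assign_to_cistron",
    "expression_table",
    "expression_to_frame",
    "write_expression_tsv",
    "fold_differences",
    "verify_stop_completion",
    "StopVerification",
    "build_consensus",
    "write_sam",
]

ReadLike = Union[SeqRecord, tuple[str, str]]

_CIG_RE = re.compile(r"(\d+)([=XIDSM])")


def _as_id_seq(read: ReadLike) -> tuple[str, str]:
    if isinstance(read, SeqRecord):
        return read.id, str(read.seq).upper()
    rid, seq = read
    return rid, seq.upper()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_reads(path: str | Path, fmt: Optional[str] = None) -> list[SeqRecord]:
    """Load reads from FASTA or FASTQ (format inferred from the suffix)."""
    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    return list(SeqIO.parse(str(p), fmt))


# ---------------------------------------------------------------------------
# Read QC


def filter_reads(
    reads: Iterable[ReadLike],
    min_len: int = 50,
    homopolymer_frac: float = 0.60,
) -> tuple[list[ReadLike], list[tuple[str, str]]]:
    """Apply the read-QC rules; returns (kept, rejected-with-reason).

    A read is rejected when shorter than ``min_len`` or when any single
    nucleotide accounts for at least ``homopolymer_frac`` of its length.
    """
    kept: list[ReadLike] = []
    rejected: list[tuple[str, str]] = []
    for read in reads:
        rid, seq = _as_id_seq(read)
        if len(seq) < min_len:
            rejected.append((rid, f"too short ({len(seq)} < {min_len} nt)"))
            continue
        top = max(seq.count(b) for b in "ACGT")
        if top / len(seq) >= homopolymer_frac:
            rejected.append(
                (rid, f"homopolymer ({top}/{len(seq)} = {top / len(seq):.0%} one base)")
            )
            continue
        kept.append(read)
    return kept, rejected


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class ReadAlignment:
    """A read placed on the genome.

    ``start``/``end`` are 1-based inclusive forward-axis coordinates of the
    aligned span; ``strand`` is H when the read matches the forward genome.
    ``clip3`` is the 3' soft-clipped read suffix in *read* orientation (the
    natural home of a poly(A) tail).  ``cigar`` and ``seq_fwd`` are in
    genome-forward orientation (for SAM and consensus building);
    ``matching_fraction`` is matches over aligned columns only.
    """

    read_id: str
    start: int
    end: int
    strand: str
    matches: int
    aligned_bases: int
    matching_fraction: float
    clip3: str
    cigar: str
    seq_fwd: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class GenomeIndex:
    """Exact k-mer index of the forward genome strand."""

    def __init__(self, genome: GenomeSequence, k: int = 11):
        self.genome = genome
        self.k = k
        index: dict[str, list[int]] = {}
        seq = genome.residues
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = index

    def hits(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])


def _expand_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cigar)]


def _columns(ops: list[tuple[str, int]], query: str, target: str) -> list[str]:
    """Flatten edlib ops into per-column codes '=', 'X', 'I', 'D'."""
    cols: list[str] = []
    qi = ti = 0
    for op, n in ops:
        for _ in range(n):
            if op in ("=", "X", "M"):
                cols.append("=" if query[qi] == target[ti] else "X")
                qi += 1
                ti += 1
            elif op == "I":  # query-consuming
                cols.append("I")
                qi += 1
            elif op == "D":  # target-consuming
                cols.append("D")
                ti += 1
    return cols


def _trim_suffix(cols: list[str]) -> int:
    """Best number of trailing columns to drop (local-score suffix trim).

    Scores +1 per match and -2 per mismatch/indel; returns the column count
    to keep so the kept prefix maximizes the score, preferring the longest
    prefix on ties (so error-free alignments are never trimmed).
    """
    best_score, best_keep, score = 0, 0, 0
    for i, c in enumerate(cols, start=1):
        score += 1 if c == "=" else -2
        if score >= best_score:
            best_score, best_keep = score, i
    return best_keep


def _align_candidate(
    qseq: str, window: str
) -> Optional[tuple[int, int, int, int, int, list[tuple[str, int]]]]:
    """Align query to an oriented window; 3'-trim; summarize.

    Returns (t_start, t_end, matches, aligned_q_bases, aligned_cols, ops)
    with target coordinates 0-based inclusive within the window, or None.
    """
    import edlib

    res = edlib.align(qseq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0, t1 = res["locations"][0]
    ops = _expand_cigar(res["cigar"])
    cols = _columns(ops, qseq, window[t0 : t1 + 1])
    keep = _trim_suffix(cols)
    if keep == 0:
        return None
    kept = cols[:keep]
    matches = kept.count("=")
    q_bases = sum(1 for c in kept if c in ("=", "X", "I"))
    t_bases = sum(1 for c in kept if c in ("=", "X", "D"))
    # rebuild run-length ops for the kept prefix
    new_ops: list[tuple[str, int]] = []
    for c in kept:
        op = {"=": "=", "X": "X", "I": "I", "D": "D"}[c]
        if new_ops and new_ops[-1][0] == op:
            new_ops[-1] = (op, new_ops[-1][1] + 1)
        else:
            new_ops.append((op, 1))
    return t0, t0 + t_bases - 1, matches, q_bases, len(kept), new_ops


def _seed_diagonals(seq: str, index: GenomeIndex) -> dict[int, int]:
    """Vote for placement diagonals from non-overlapping exact k-mer seeds."""
    k = index.k
    votes: dict[int, int] = {}
    offsets = list(range(0, len(seq) - k + 1, k))
    if offsets and offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    for off in offsets:
        for pos in index.hits(seq[off : off + k]):
            d = pos - off
            votes[d] = votes.get(d, 0) + 1
    return votes


def _cluster_diagonals(votes: dict[int, int], band: int, top: int = 4) -> list[int]:
    """Merge nearby diagonals; return up to `top` representatives by votes."""
    merged: dict[int, int] = {}
    for d in sorted(votes):
        placed = False
        for rep in list(merged):
            if abs(d - rep) <= band:
                merged[rep] += votes[d]
                placed = True
                break
        if not placed:
            merged[d] = votes[d]
    return [d for d, _ in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))[:top]]


def _ops_to_cigar(ops: list[tuple[str, int]], clip5: int, clip3: int) -> str:
    parts = []
    if clip5:
        parts.append(f"{clip5}S")
    parts += [f"{n}{op}" for op, n in ops]
    if clip3:
        parts.append(f"{clip3}S")
    return "".join(parts)


def map_read(
    read: ReadLike,
    genome: GenomeSequence,
    k: int = 11,
    min_match_bases: int = 8,
    min_match_pct: float = 0.70,
    band_frac: float = 0.15,
    index: Optional[GenomeIndex] = None,
) -> Optional[ReadAlignment]:
    """Seed-and-extend placement of one read; None when unmapped.

    Exact k-mer seeds are collected on both strands; the best seed diagonals
    are extended by edit-distance alignment inside a window of the seed
    region padded by ``band_frac`` of the read length.  The trailing read
    suffix that does not improve the alignment score is soft-clipped
    (``clip3``).  Candidates are ranked by (matching bases, lowest genome
    coordinate, H before L).
    """
    rid, seq = _as_id_seq(read)
    if len(seq) < k:
        return None
    if index is None:
        index = GenomeIndex(genome, k)
    elif index.k != k:
        raise ValueError(f"index built with k={index.k}, requested k={k}")
    pad = max(8, int(band_frac * len(seq)))
    g = genome.residues
    best: Optional[tuple[tuple[int, int, int], ReadAlignment]] = None
    for strand in ("H", "L"):
        oriented = seq if strand == "H" else _revcomp(seq)
        votes = _seed_diagonals(oriented, index)
        for diag in _cluster_diagonals(votes, band=pad):
            ws = max(0, diag - pad)
            we = min(len(g), diag + len(seq) + pad)
            window = g[ws:we]
            if strand == "L":
                # align the read itself against the reverse-complemented
                # window so its 3' tail is the trailing clip on either strand
                window = _revcomp(window)
            hit = _align_candidate(seq, window)
            if hit is None:
                continue
            t0, t1, matches, q_bases, cols, ops = hit
            frac = matches / cols if cols else 0.0
            if matches < min_match_bases or frac < min_match_pct:
                continue
            clip3_len = len(seq) - q_bases
            clip3 = seq[q_bases:]
            if strand == "H":
                gstart = ws + t0 + 1
                gend = ws + t1 + 1
                cigar = _ops_to_cigar(ops, 0, clip3_len)
                seq_fwd = seq
            else:
                # window was reverse-complemented: oriented column t maps to
                # genome position we - t (1-based)
                gstart = we - t1
                gend = we - t0
                rev_ops = list(reversed(ops))
                cigar = _ops_to_cigar(rev_ops, clip3_len, 0)
                seq_fwd = _revcomp(seq)
            aln = ReadAlignment(
                read_id=rid,
                start=gstart,
                end=gend,
                strand=strand,
                matches=matches,
                aligned_bases=q_bases,
                matching_fraction=frac,
                clip3=clip3,
                cigar=cigar,
                seq_fwd=seq_fwd,
            )
            rank = (-matches, gstart, 0 if strand == "H" else 1)
            if best is None or rank < best[0]:
                best = (rank, aln)
    return best[1] if best else None


def map_reads(
    reads: Iterable[ReadLike],
    genome: GenomeSequence,
    k: int = 11,
    min_match_bases: int = 8,
    min_match_pct: float = 0.70,
    band_frac: float = 0.15,
) -> tuple[list[ReadAlignment], list[tuple[str, str]]]:
    """Map many reads with a shared genome index; (alignments, unmapped)."""
    index = GenomeIndex(genome, k)
    alignments: list[ReadAlignment] = []
    unmapped: list[tuple[str, str]] = []
    for read in reads:
        rid, seq = _as_id_seq(read)
        if len(seq) < k:
            unmapped.append((rid, f"shorter than seed length k={k}"))
            continue
        aln = map_read(
            read,
            genome,
            k=k,
            min_match_bases=min_match_bases,
            min_match_pct=min_match_pct,
            band_frac=band_frac,
            index=index,
        )
        if aln is None:
            unmapped.append((rid, "no acceptable alignment"))
        else:
            alignments.append(aln)
    return alignments, unmapped


# ---------------------------------------------------------------------------
# Poly(A) tails


def detect_polyA(
    aln: ReadAlignment, min_len: int = 5, max_mismatch_per10: int = 1
) -> int:
    """Length of the poly(A) run at the start of the 3' soft clip, or 0.

    The run may contain up to ``max_mismatch_per10`` non-A per 10 bases
    (sequencing errors inside the tail) and must reach ``min_len``.
    """
    clip = aln.clip3
    best = 0
    non_a = 0
    for i, b in enumerate(clip, start=1):
        if b != "A":
            non_a += 1
        if non_a <= (i * max_mismatch_per10) // 10 and b == "A":
            best = i
    return best if best >= min_len else 0


# ---------------------------------------------------------------------------
# Cistron assignment and quantification


def assign_to_cistron(
    aln: ReadAlignment, cistrons: Sequence[Cistron]
) -> Optional[str]:
    """Id of the same-strand cistron with maximal span overlap, or None.

    Ties go to the earlier cistron in list order; reads overlapping no
    cistron on their own strand are unassigned.
    """
    best_id, best_ov = None, 0
    for c in cistrons:
        if c.strand != aln.strand:
            continue
        ov = max(0, min(c.end, aln.end) - max(c.start, aln.start) + 1)
        if ov > best_ov:
            best_id, best_ov = c.id, ov
    return best_id


@dataclass(frozen=True)
class CistronExpression:
    """Per-cistron expression metrics (one table row).

    ``proportion`` is read_count over the library total when one is given
    (``proportion_basis == "library"``), otherwise over the assigned
    mitochondrial reads only (``proportion_basis == "mitochondrial"``).
    """

    cistron_id: str
    genes: tuple[str, ...]
    length: int
    read_count: int
    total_nt: int
    mean_depth: float
    proportion: float
    polyA_read_count: int
    proportion_basis: str


def expression_table(
    assigned: Iterable[tuple[ReadAlignment, Optional[str]]],
    cistrons: Sequence[Cistron],
    library_total_reads: Optional[int] = None,
    polyA_min: int = 5,
) -> list[CistronExpression]:
    """Summarize assigned read alignments into per-cistron expression rows."""
    counts: dict[str, int] = {c.id: 0 for c in cistrons}
    nts: dict[str, int] = {c.id: 0 for c in cistrons}
    tails: dict[str, int] = {c.id: 0 for c in cistrons}
    n_assigned = 0
    for aln, cid in assigned:
        if cid is None or cid not in counts:
            continue
        n_assigned += 1
        counts[cid] += 1
        nts[cid] += aln.aligned_bases
        if detect_polyA(aln, min_len=polyA_min) > 0:
            tails[cid] += 1
    if library_total_reads is not None:
        denom, basis = library_total_reads, "library"
    else:
        denom, basis = max(n_assigned, 1), "mitochondrial"
    rows = []
    for c in cistrons:
        if c.length <= 0:
            raise ValueError(f"{c.id}: zero-length cistron")
        rows.append(
            CistronExpression(
                cistron_id=c.id,
                genes=c.genes,
                length=c.length,
                read_count=counts[c.id],
                total_nt=nts[c.id],
                mean_depth=nts[c.id] / c.length,
                proportion=counts[c.id] / denom,
                polyA_read_count=tails[c.id],
                proportion_basis=basis,
            )
        )
    return rows


def expression_to_frame(rows: Sequence[CistronExpression]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cistron_id": [r.cistron_id for r in rows],
            "genes": [",".join(r.genes) for r in rows],
            "length": [r.length for r in rows],
            "total_nt": [r.total_nt for r in rows],
            "mean_depth": [r.mean_depth for r in rows],
            "read_count": [r.read_count for r in rows],
            "proportion": [r.proportion for r in rows],
            "polyA_read_count": [r.polyA_read_count for r in rows],
        }
    )


def write_expression_tsv(rows: Sequence[CistronExpression], path: str | Path) -> None:
    expression_to_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Fold differences


def _expression_rows(expr) -> list[dict]:
    """Normalize a CistronExpression list or a published-table DataFrame."""
    rows = []
    if hasattr(expr, "iterrows"):  # DataFrame
        prop_col = "proportion_pct" if "proportion_pct" in expr.columns else "proportion"
        for _, r in expr.iterrows():
            genes = r["genes"]
            rows.append(
                {
                    "id": r["cistron_id"],
                    "genes": [g.strip().lower() for g in str(genes).split(",")],
                    "mean_depth": float(r["mean_depth"]),
                    "proportion": float(r[prop_col]),
                }
            )
    else:
        for r in expr:
            rows.append(
                {
                    "id": r.cistron_id,
                    "genes": [g.lower() for g in r.genes],
                    "mean_depth": r.mean_depth,
                    "proportion": r.proportion,
                }
            )
    return rows


def _find_row(rows: list[dict], key: str) -> dict:
    k = key.lower()
    for r in rows:
        if r["id"].lower() == k or k in r["genes"]:
            return r
    raise KeyError(key)


def fold_differences(
    expr, pairs: Iterable[tuple[str, str]] = ()
) -> dict[str, float]:
    """Larger-over-smaller mean-depth ratios for cistron pairs, plus the
    global max/min proportion ratio under key ``"proportion_range"``.

    Pair members may be cistron ids or gene names (resolved to the cistron
    containing the gene).  Zero depths/proportions raise ValueError.
    """
    rows = _expression_rows(expr)
    out: dict[str, float] = {}
    for a, b in pairs:
        ra, rb = _find_row(rows, a), _find_row(rows, b)
        da, db = ra["mean_depth"], rb["mean_depth"]
        if da <= 0 or db <= 0:
            raise ValueError(f"undefined ratio: zero depth for {a} or {b}")
        out[f"{a}/{b}"] = max(da, db) / min(da, db)
    props = [r["proportion"] for r in rows if r["proportion"] > 0]
    if props:
        out["proportion_range"] = max(props) / min(props)
    return out


# ---------------------------------------------------------------------------
# Stop-codon completion from EST evidence


@dataclass(frozen=True)
class StopVerification:
    """Per-gene outcome of poly(A) stop-completion checking.

    ``status``: ``complete_in_genome`` (full TAA/TAG on the genome, no tail
    needed), ``confirmed`` (truncated genomic stop completed to TAA by
    observed poly(A) tails), ``unconfirmed`` (covering reads but no
    supporting tail), or ``inconclusive`` (no read covers the CDS 3' end).
    """

    gene: str
    status: str
    n_covering: int = 0
    n_supporting: int = 0


def verify_stop_completion(
    cistron: Cistron,
    alignments: Iterable[ReadAlignment],
    ann: Annotation,
    genome: GenomeSequence,
    polyA_min: int = 5,
    end_tolerance: int = 10,
) -> list[StopVerification]:
    """Check poly(A) completion of truncated stop codons against mapped reads.

    For every PCG of the cistron, reads on the cistron strand that cover the
    CDS terminus and whose aligned 3' end lies within ``end_tolerance`` of
    it are inspected: a poly(A) soft clip long enough to supply the A
    residues missing from the genomic stop confirms the completion
    mechanism.  The tolerance absorbs tail bases that spuriously align into
    A-rich genomic sequence just downstream of the cleavage point.
    """
    out = []
    alns = [a for a in alignments if a.strand == cistron.strand]
    for name in cistron.genes:
        f = ann.get(name)
        if f.ftype != "PCG":
            continue
        cds = genome.subseq(f.start, f.end, f.strand)
        if len(cds) % 3 == 0 and cds[-3:] in ("TAA", "TAG"):
            out.append(StopVerification(gene=f.name, status="complete_in_genome"))
            continue
        terminus = f.end if f.strand == "H" else f.start
        covering = []
        for a in alns:
            read_3p = a.end if a.strand == "H" else a.start
            if a.start <= terminus <= a.end and abs(read_3p - terminus) <= end_tolerance:
                covering.append(a)
        supporting = 0
        for a in covering:
            tail = detect_polyA(a, min_len=polyA_min)
            if tail and complete_truncated_stop(cds, "A" * tail).status == "completed":
                supporting += 1
        if not covering:
            status = "inconclusive"
        elif supporting:
            status = "confirmed"
        else:
            status = "unconfirmed"
        out.append(
            StopVerification(
                gene=f.name,
                status=status,
                n_covering=len(covering),
                n_supporting=supporting,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Consensus and SAM output

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_consensus(
    alignments: Iterable[ReadAlignment],
    genome: GenomeSequence,
    cistron: Cistron,
) -> str:
    """Majority-vote consensus over the cistron span (forward axis).

    Aligned read bases vote per position; positions with no coverage are
    emitted as the genome base in lowercase.
    """
    span_len = cistron.length
    counts = np.zeros((4, span_len), dtype=np.int32)
    for a in alignments:
        gpos = a.start
        qpos = 0
        for op, n in _expand_cigar(a.cigar):
            if op == "S":
                qpos += n
            elif op in ("=", "X", "M"):
                for i in range(n):
                    p = gpos + i - cistron.start
                    if 0 <= p < span_len:
                        b = a.seq_fwd[qpos + i]
                        if b in _BASE_IDX:
                            counts[_BASE_IDX[b], p] += 1
                gpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op == "D":
                gpos += n
    ref = genome.subseq(cistron.start, cistron.end, "H")
    out = []
    bases = "ACGT"
    for p in range(span_len):
        col = counts[:, p]
        total = int(col.sum())
        if total == 0:
            out.append(ref[p].lower())
            continue
        best = int(col.max())
        winners = [bases[i] for i in range(4) if col[i] == best]
        out.append(ref[p] if ref[p] in winners else winners[0])
    return "".join(out)


def _sam_cigar(cigar: str) -> str:
    """Collapse =/X to M and merge adjacent runs for SAM output."""
    merged: list[tuple[str, int]] = []
    for op, n in _expand_cigar(cigar):
        op = "M" if op in ("=", "X") else op
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return "".join(f"{n}{op}" for op, n in merged)


def write_sam(
    alignments: Iterable[ReadAlignment], genome: GenomeSequence, path: str | Path
) -> None:
    """Write alignments as SAM (soft clips as S operations; L strand flag 16)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": genome.id, "LN": genome.length}],
            "PG": [{"ID": "mitocistron", "PN": "mitocistron"}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.query_sequence = a.seq_fwd
            seg.flag = 0 if a.strand == "H" else 16
            seg.reference_id = 0
            seg.reference_start = a.start - 1
            seg.mapping_quality = 60
            seg.cigarstring = _sam_cigar(a.cigar) or None
            seg.set_tag("NM", a.aligned_bases - a.matches)
            sam.write(seg)
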