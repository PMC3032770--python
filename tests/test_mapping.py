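"""Read QC, seed-and-extend mapping, poly(A), assignment and quantification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocistron.cistrons import Cistron, predict_cistrons
from mitocistron.mapping import (
    ReadAlignment,
    assign_to_cistron,
    build_consensus,
    detect_polyA,
    expression_table,
    filter_reads,
    fold_differences,
    map_read,
    map_reads,
    verify_stop_completion,
    write_sam,
)
from mitocistron.model import Annotation, GeneFeature, GenomeSequence
from mitocistron.simulate import GenomeSpec, GeneSpec, generate_genome


def _revcomp(s):
    return str(Seq(s).reverse_complement())


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=2000))
    return GenomeSequence(id="toy", residues=seq)


class TestFilterReads:
    def test_short_read_rejected(self):
        kept, rej = filter_reads([("r1", "A" * 30 + "C" * 19)])
        assert not kept and "too short" in rej[0][1]

    def test_sixty_percent_single_base_rejected(self):
        seq = "A" * 61 + "CGT" * 13  # 61 A of 100
        kept, rej = filter_reads([("r1", seq)])
        assert not kept and "homopolymer" in rej[0][1]

    def test_balanced_read_kept(self):
        kept, rej = filter_reads([("r1", "ACGT" * 15)])
        assert len(kept) == 1 and not rej


class TestMapRead:
    def test_error_free_read_identity_placement(self, toy_genome):
        p = 501
        read = ("r", toy_genome.residues[p - 1 : p + 119])
        aln = map_read(read, toy_genome)
        assert aln is not None
        assert (aln.start, aln.end, aln.strand) == (p, p + 119, "H")
        assert aln.matching_fraction == 1.0 and aln.clip3 == ""

    def test_reverse_complement_maps_same_span_strand_l(self, toy_genome):
        p = 501
        fwd = toy_genome.residues[p - 1 : p + 119]
        aln = map_read(("r", _revcomp(fwd)), toy_genome)
        assert aln is not None
        assert (aln.start, aln.end, aln.strand) == (p, p + 119, "L")

    def test_heavily_corrupted_read_is_unmapped(self, toy_genome):
        rng = np.random.default_rng(3)
        frag = list(toy_genome.residues[300:420])
        for i in range(len(frag)):
            if rng.random() < 0.35:
                frag[i] = "ACGT"[(("ACGT".index(frag[i])) + 1 + rng.integers(3)) % 4]
        assert map_read(("r", "".join(frag)), toy_genome) is None

    def test_read_shorter_than_seed_is_unmapped(self, toy_genome):
        alns, unmapped = map_reads([("r", "ACGTACGT")], toy_genome)
        assert not alns and "seed" in unmapped[0][1]

    def test_polyA_tail_is_soft_clipped(self, toy_genome):
        read = toy_genome.residues[700:850] + "A" * 25
        aln = map_read(("r", read), toy_genome)
        assert aln is not None and aln.strand == "H"
        assert (aln.start, aln.end) == (701, 850)
        assert aln.clip3.startswith("A" * 20)

    def test_exhaustive_oracle_equivalence_error_free(self, toy_genome):
        """Seed-and-extend equals exhaustive substring placement on a toy
        genome for error-free reads from either strand."""
        g = toy_genome.residues
        rng = np.random.default_rng(7)
        for _ in range(60):
            ln = int(rng.integers(30, 200))
            p = int(rng.integers(0, len(g) - ln))
            frag = g[p : p + ln]
            reverse = bool(rng.random() < 0.5)
            read = _revcomp(frag) if reverse else frag
            # oracle: exact substring occurrences, first (lowest) position
            occ = []
            start = g.find(frag)
            while start != -1:
                occ.append(start)
                start = g.find(frag, start + 1)
            aln = map_read(("r", read), toy_genome)
            assert aln is not None
            assert aln.start - 1 == occ[0]
            assert aln.end - aln.start + 1 == ln
            assert aln.strand == ("L" if reverse else "H")
            assert aln.matching_fraction == 1.0


class TestDetectPolyA:
    def _aln(self, clip):
        return ReadAlignment(
            read_id="r", start=1, end=10, strand="H", matches=10,
            aligned_bases=10, matching_fraction=1.0, clip3=clip,
            cigar="10=", seq_fwd="A" * 10,
        )

    def test_clean_tail(self):
        assert detect_polyA(self._aln("AAAAAAAA")) == 8

    def test_empty_clip(self):
        assert detect_polyA(self._aln("")) == 0

    def test_short_tail_below_min(self):
        assert detect_polyA(self._aln("AAAA")) == 0

    def test_tolerates_one_error_per_ten(self):
        assert detect_polyA(self._aln("AAAAAAAAAACAAAAAAAAA")) == 20

    def test_non_a_clip_rejected(self):
        assert detect_polyA(self._aln("CCCCCCCC")) == 0


@pytest.fixture(scope="module")
def cistrons(table2):
    return predict_cistrons(table2)


class TestAssignment:
    def _aln(self, start, end, strand):
        return ReadAlignment(
            read_id="r", start=start, end=end, strand=strand, matches=end - start + 1,
            aligned_bases=end - start + 1, matching_fraction=1.0, clip3="",
            cigar=f"{end - start + 1}=", seq_fwd="A" * (end - start + 1),
        )

    def test_read_inside_nd3_goes_to_its_monocistron(self, cistrons):
        cid = assign_to_cistron(self._aln(5400, 5600, "H"), cistrons)
        assert "nd3" in next(c.genes for c in cistrons if c.id == cid)

    def test_read_straddling_atp8_atp6_junction_goes_to_tricistron(self, cistrons):
        cid = assign_to_cistron(self._aln(3700, 3900, "H"), cistrons)
        genes = next(c.genes for c in cistrons if c.id == cid)
        assert set(genes) == {"atp8", "atp6", "cox3"}

    def test_h_read_inside_l_cistron_span_is_unassigned(self, cistrons):
        # nd5 lies on L; an H-strand read there has no same-strand cistron
        assert assign_to_cistron(self._aln(6500, 6700, "H"), cistrons) is None


class TestExpression:
    def _cistron(self, cid, length, strand="H", start=1):
        return Cistron(
            id=cid, strand=strand, start=start, end=start + length - 1,
            genes=(cid,), arity=1,
        )

    def _aln(self, rid, start, nt, strand="H", clip=""):
        return ReadAlignment(
            read_id=rid, start=start, end=start + nt - 1, strand=strand,
            matches=nt, aligned_bases=nt, matching_fraction=1.0, clip3=clip,
            cigar=f"{nt}=", seq_fwd="A" * nt,
        )

    def test_published_arithmetic_mean_depth(self):
        # 7829 nt over 1033 bp -> 7.58; 171490 over 2049 -> 83.69
        assert round(7829 / 1033, 2) == 7.58
        assert round(171490 / 2049, 2) == 83.69

    def test_expression_rows_and_depth_identity(self):
        cis = [self._cistron("c1", 100), self._cistron("c2", 200, start=300)]
        assigned = [
            (self._aln("r1", 10, 50), "c1"),
            (self._aln("r2", 20, 60, clip="A" * 10), "c1"),
            (self._aln("r3", 350, 80), "c2"),
        ]
        rows = expression_table(assigned, cis, library_total_reads=10)
        r1, r2 = rows
        assert (r1.read_count, r1.total_nt) == (2, 110)
        assert r1.mean_depth * r1.length == pytest.approx(r1.total_nt)
        assert r1.proportion == pytest.approx(0.2)
        assert r1.polyA_read_count == 1
        assert (r2.read_count, r2.total_nt) == (1, 80)
        assert sum(r.read_count for r in rows) == 3

    def test_no_assigned_reads_gives_zero_row(self):
        rows = expression_table([], [self._cistron("c1", 100)])
        assert rows[0].read_count == 0 and rows[0].mean_depth == 0.0

    def test_fold_differences_on_published_profile(self, table4):
        folds = fold_differences(table4, pairs=[("nd1", "nd2"), ("cox2", "cox3")])
        assert round(folds["nd1/nd2"], 2) == 11.15
        assert round(folds["cox2/cox3"], 2) == 3.59
        assert folds["proportion_range"] == pytest.approx(321.0)

    def test_equal_depths_give_unit_ratio(self):
        cis = [self._cistron("c1", 100), self._cistron("c2", 100, start=300)]
        rows = expression_table(
            [(self._aln("r1", 10, 50), "c1"), (self._aln("r2", 310, 50), "c2")], cis
        )
        folds = fold_differences(rows, pairs=[("c1", "c2")])
        assert folds["c1/c2"] == pytest.approx(1.0)


class TestConsensusAndSam:
    def _tiling_reads(self, genome, start, end, step, ln):
        reads = []
        for i, p in enumerate(range(start, end - ln + 2, step)):
            reads.append((f"t{i}", genome.residues[p - 1 : p - 1 + ln]))
        return reads

    def test_error_free_tiling_reads_reproduce_the_genome_span(self, toy_genome):
        cis = Cistron(id="c", strand="H", start=401, end=900, genes=("g",), arity=1)
        reads = self._tiling_reads(toy_genome, 401, 900, 50, 120)
        alns, un = map_reads(reads, toy_genome)
        assert not un
        cons = build_consensus(alns, toy_genome, cis)
        ref = toy_genome.subseq(401, 900)
        # positions covered by reads agree exactly; uncovered are lowercase ref
        assert cons.upper() == ref
        assert cons[:120].isupper()

    def test_noisy_reads_majority_vote_recovers_reference(self, toy_genome):
        rng = np.random.default_rng(9)
        cis = Cistron(id="c", strand="H", start=401, end=700, genes=("g",), arity=1)
        reads = []
        for i in range(60):  # depth ~ 24
            p = int(rng.integers(401, 700 - 120))
            frag = list(toy_genome.residues[p - 1 : p + 119])
            for j in range(len(frag)):
                if rng.random() < 0.01:
                    frag[j] = "ACGT"[int(rng.integers(4))]
            reads.append((f"n{i}", "".join(frag)))
        alns, _ = map_reads(reads, toy_genome)
        cons = build_consensus(alns, toy_genome, cis)
        ref = toy_genome.subseq(401, 700)
        covered = [i for i, ch in enumerate(cons) if ch.isupper()]
        assert len(covered) > 250
        assert all(cons[i] == ref[i] for i in covered)

    def test_single_read_consensus_is_that_read(self, toy_genome):
        cis = Cistron(id="c", strand="H", start=501, end=600, genes=("g",), arity=1)
        read = ("r", toy_genome.residues[500:600])
        alns, _ = map_reads([read], toy_genome)
        cons = build_consensus(alns, toy_genome, cis)
        assert cons == read[1]

    def test_sam_output_is_readable_by_pysam(self, toy_genome, tmp_path):
        import pysam

        reads = [
            ("f", toy_genome.residues[100:220]),
            ("r", _revcomp(toy_genome.residues[300:420]) ),
            ("tail", toy_genome.residues[500:620] + "A" * 15),
        ]
        alns, _ = map_reads(reads, toy_genome)
        p = tmp_path / "out.sam"
        write_sam(alns, toy_genome, p)
        with pysam.AlignmentFile(str(p)) as sam:
            segs = list(sam)
        assert len(segs) == 3
        by_name = {s.query_name: s for s in segs}
        assert by_name["f"].reference_start == 100
        assert by_name["r"].is_reverse
        assert ("S" in by_name["tail"].cigarstring)


@pytest.fixture(scope="module")
def truncated_gene_world():
    """A tiny genome whose single PCG ends in a bare T (truncated stop)."""
    spec = GenomeSpec(
        genes=(
            GeneSpec("trnA", "tRNA", "H", 60),
            GeneSpec("g1", "PCG", "H", 301, start_codon="ATG", stop_codon="T"),
            GeneSpec("trnB", "tRNA", "H", 60),
        ),
        gaps=(0, 0),
        seed=5,
    )
    genome, ann, _ = generate_genome(spec)
    cis = predict_cistrons(ann, genome_length=genome.length)
    (c,) = cis
    return genome, ann, c


class TestStopVerification:
    def _reads_to_terminus(self, genome, cds_end, tail, n=6, ln=120):
        reads = []
        for i in range(n):
            reads.append((f"e{i}", genome.residues[cds_end - ln : cds_end] + tail))
        return reads

    def test_polyadenylated_reads_confirm_completion(self, truncated_gene_world):
        genome, ann, c = truncated_gene_world
        f = ann.get("g1")
        reads = self._reads_to_terminus(genome, f.end, "A" * 20)
        alns, _ = map_reads(reads, genome)
        (res,) = verify_stop_completion(c, alns, ann, genome)
        assert res.status == "confirmed" and res.n_supporting >= 1

    def test_c_tails_do_not_confirm(self, truncated_gene_world):
        genome, ann, c = truncated_gene_world
        f = ann.get("g1")
        reads = self._reads_to_terminus(genome, f.end, "C" * 20)
        alns, _ = map_reads(reads, genome)
        (res,) = verify_stop_completion(c, alns, ann, genome)
        assert res.status == "unconfirmed"

    def test_no_covering_reads_is_inconclusive(self, truncated_gene_world):
        genome, ann, c = truncated_gene_world
        f = ann.get("g1")
        reads = [("far", genome.residues[f.start : f.start + 120])]
        alns, _ = map_reads(reads, genome)
        (res,) = verify_stop_completion(c, alns, ann, genome)
        assert res.status == "inconclusive"

    def test_genomic_full_stop_is_trivially_complete(self):
        spec = GenomeSpec(
            genes=(
                GeneSpec("trnA", "tRNA", "H", 60),
                GeneSpec("g1", "PCG", "H", 300, start_codon="ATG", stop_codon="TAA"),
                GeneSpec("trnB", "tRNA", "H", 60),
            ),
            gaps=(0, 0),
            seed=6,
        )
        genome, ann, _ = generate_genome(spec)
        (c,) = predict_cistrons(ann, genome_length=genome.length)
        (res,) = verify_stop_completion(c, [], ann, genome)
        assert res.status == "complete_in_genome"
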