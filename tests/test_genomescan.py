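"""Six-frame smORF scanning, filtering, annotation and database emission."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from smorfkit.genomescan import (DEFAULT_CUTOFFS, GenomeCandidate,
                                 annotate_overlap, emit_database,
                                 remove_within_cds, scan_smorfs,
                                 score_and_filter, standardized_ratio,
                                 translate_seps)
from smorfkit.seqdata import CdsIntervalSet, STOP_CODONS, read_cds_intervals
from smorfkit.synth import generate_toy_genome


def brute_force_scan(genome, start_codons, min_codons, max_codons):
    """Oracle: per-start forward walk over both strands and all frames."""
    found = set()
    for chrom, fwd in genome.items():
        n = len(fwd)
        for strand in "+-":
            seq = fwd if strand == "+" else str(Seq(fwd).reverse_complement())
            for i in range(n - 2):
                if seq[i:i + 3] not in start_codons:
                    continue
                for j in range(i + 3, n - 2, 3):
                    if seq[j:j + 3] in STOP_CODONS:
                        ncod = (j + 3 - i) // 3
                        if min_codons <= ncod <= max_codons and \
                                "N" not in seq[i:j + 3]:
                            s, e = (i, j + 3) if strand == "+" else \
                                (n - j - 3, n - i)
                            found.add((chrom, s, e, strand, seq[i:i + 3]))
                        break
    return found


def cand_key(c):
    return (c.chrom, c.start, c.end, c.strand, c.start_codon)


def make_candidate(chrom="c", start=0, end=36, strand="+", score=0.9,
                   start_codon="ATG", orf_seq=None):
    if orf_seq is None:
        orf_seq = start_codon + "AAA" * ((end - start) // 3 - 2) + "TAA"
    return GenomeCandidate(chrom=chrom, start=start, end=end, strand=strand,
                           frame=start % 3, start_codon=start_codon,
                           upstream3="CCA", orf_seq=orf_seq, score=score)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

class TestScanSmorfs:
    def test_planted_forward_orf(self):
        orf = "ATG" + "AAA" * 9 + "TAA"
        contig = "C" * 12 + orf + "C" * 15
        cands = list(scan_smorfs({"c1": contig}, start_codons=["ATG"],
                                 min_codons=11, max_codons=101))
        assert [(c.start, c.end, c.strand) for c in cands] == [(12, 45, "+")]
        assert cands[0].orf_seq == orf and cands[0].upstream3 == "CCC"

    def test_planted_reverse_orf(self):
        orf = "ATG" + "GGG" * 9 + "TAA"
        rc = str(Seq(orf).reverse_complement())
        contig = "C" * 10 + rc + "C" * 10
        cands = list(scan_smorfs({"c1": contig}, start_codons=["ATG"],
                                 min_codons=11, max_codons=101))
        assert [(c.start, c.end, c.strand) for c in cands] == [(10, 43, "-")]
        assert cands[0].orf_seq == orf

    def test_length_filters(self):
        too_long = "ATG" + "AAA" * 100 + "TAA"  # 102 codons
        cands = list(scan_smorfs({"c": too_long}, start_codons=["ATG"],
                                 min_codons=11, max_codons=101))
        assert cands == []

    def test_contig_edge_padding(self):
        contig = "ATG" + "AAA" * 9 + "TAA"
        c, = scan_smorfs({"c": contig}, start_codons=["ATG"], min_codons=11)
        assert c.upstream3 == "NNN"

    def test_nested_starts_share_stop(self):
        contig = "ATG" + "CCC" + "ATG" + "AAA" * 10 + "TAA"
        cands = list(scan_smorfs({"c": contig}, start_codons=["ATG"],
                                 min_codons=2, max_codons=101))
        assert len(cands) == 2
        only = list(scan_smorfs({"c": contig}, start_codons=["ATG"],
                                min_codons=2, max_codons=101,
                                longest_only=True))
        assert len(only) == 1 and only[0].start == 0

    def test_candidates_with_n_discarded(self):
        contig = "ATG" + "AAA" * 4 + "ANA" + "AAA" * 4 + "TAA"
        assert list(scan_smorfs({"c": contig}, start_codons=["ATG"],
                                min_codons=2)) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_equivalence_random_contig(self, seed):
        rng = np.random.default_rng(seed)
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        genome = {"chr": contig}
        starts = {"ATG", "CTG", "GTG"}
        got = {cand_key(c) for c in scan_smorfs(genome, starts, 5, 60)}
        assert got == brute_force_scan(genome, starts, 5, 60)

    def test_streaming_safe_contig_by_contig(self):
        rng = np.random.default_rng(9)
        contigs = {f"c{i}": "".join("ACGT"[j]
                                    for j in rng.integers(0, 4, 1500))
                   for i in range(3)}
        whole = {cand_key(c) for c in scan_smorfs(contigs)}
        parts = set()
        for name, seq in contigs.items():
            parts |= {cand_key(c) for c in scan_smorfs({name: seq})}
        assert whole == parts


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestScoreAndFilter:
    def test_cutoff_boundaries(self):
        cands = [make_candidate(start_codon="ATG", score=0.80),
                 make_candidate(start=36, end=72, start_codon="TTG",
                                score=0.999),
                 make_candidate(start=72, end=108, start_codon="AAG",
                                score=1.0)]
        kept = score_and_filter(cands, cutoffs=DEFAULT_CUTOFFS)
        assert [c.start_codon for c in kept] == ["ATG"]

    def test_exact_tie_kept(self):
        c = make_candidate(start_codon="CTG", score=0.780)
        assert score_and_filter([c], cutoffs=DEFAULT_CUTOFFS) == [c]

    def test_every_kept_candidate_clears_its_cutoff(self):
        rng = np.random.default_rng(1)
        codons = list(DEFAULT_CUTOFFS) + ["AAG", "AGG"]
        cands = [make_candidate(start=i * 36, end=i * 36 + 36,
                                start_codon=codons[i % len(codons)],
                                score=float(rng.random()))
                 for i in range(60)]
        kept = score_and_filter(cands, cutoffs=DEFAULT_CUTOFFS)
        assert all(c.score - DEFAULT_CUTOFFS[c.start_codon] >= 0 for c in kept)
        assert all(c.start_codon not in ("AAG", "AGG") for c in kept)


class TestRemoveWithinCds:
    def _cds(self):
        cds = CdsIntervalSet()
        cds.add("c", "+", 90, 300)
        return cds

    def test_contained_removed(self):
        c = make_candidate(start=100, end=160)
        assert remove_within_cds([c], self._cds()) == []

    def test_opposite_strand_retained(self):
        c = make_candidate(start=100, end=160, strand="-")
        assert remove_within_cds([c], self._cds()) == [c]

    def test_straddling_retained(self):
        c = make_candidate(start=280, end=316)
        assert remove_within_cds([c], self._cds()) == [c]

    def test_random_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        cds = CdsIntervalSet()
        intervals = []
        for _ in range(30):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(30, 400))
            strand = "+-"[rng.integers(2)]
            cds.add("c", strand, s, e)
            intervals.append((strand, s, e))
        cands = []
        for i in range(1000):
            s = int(rng.integers(0, 5200))
            cands.append(make_candidate(start=s, end=s + 36,
                                        strand="+-"[rng.integers(2)]))
        kept = remove_within_cds(cands, cds)
        expected = [c for c in cands
                    if not any(st == c.strand and s <= c.start and c.end <= e
                               for st, s, e in intervals)]
        assert [cand_key(c) for c in kept] == [cand_key(c) for c in expected]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

ANNOT = """##gff-version 3
c\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1;Name=LINC1;gene_biotype=lncRNA
c\tsrc\tgene\t301\t700\t.\t+\t.\tID=g2;Name=PCG1;gene_biotype=protein_coding
c\tsrc\tgene\t1001\t1200\t.\t-\t.\tID=g3;Name=PSG1;gene_biotype=processed_pseudogene
c\tsrc\tgene\t1501\t1600\t.\t+\t.\tID=g4
"""


class TestAnnotateOverlap:
    @pytest.fixture()
    def gff(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(ANNOT)
        return p

    def test_lncrna_overlap(self, gff):
        c, = annotate_overlap([make_candidate(start=120, end=156)], gff)
        assert c.overlap_type == "lncRNA" and c.overlap_gene == "LINC1"

    def test_no_overlap(self, gff):
        c, = annotate_overlap([make_candidate(start=5000, end=5036)], gff)
        assert c.overlap_type == "none" and c.overlap_gene is None

    def test_protein_coding_precedence(self, gff):
        # overlaps both the lncRNA and the protein-coding gene
        c, = annotate_overlap([make_candidate(start=310, end=346)], gff)
        assert c.overlap_type == "protein_coding" and c.overlap_gene == "PCG1"

    def test_pseudogene_normalization(self, gff):
        c, = annotate_overlap([make_candidate(start=1050, end=1086)], gff)
        assert c.overlap_type == "pseudogene"

    def test_missing_biotype_is_other(self, gff):
        c, = annotate_overlap([make_candidate(start=1510, end=1546)], gff)
        assert c.overlap_type == "other"


# ---------------------------------------------------------------------------
# emission / translation / ratios
# ---------------------------------------------------------------------------

class TestEmitDatabase:
    def _three(self):
        return [make_candidate("c1", 0, 36, "+", 0.9),
                make_candidate("c1", 100, 136, "-", 0.85),
                make_candidate("c2", 50, 86, "+", 0.999)]

    def test_files_consistent(self, tmp_path):
        paths = emit_database(self._three(), tmp_path / "db")
        fasta = paths["fasta"].read_text()
        bed = paths["bed"].read_text().strip().split("\n")
        tsv = paths["tsv"].read_text().strip().split("\n")
        assert fasta.count(">") == 3 and len(bed) == 3 and len(tsv) == 4
        ids_fa = [l[1:] for l in fasta.split("\n") if l.startswith(">")]
        ids_bed = [l.split("\t")[3] for l in bed]
        ids_tsv = [l.split("\t")[0] for l in tsv[1:]]
        assert ids_fa == ids_bed == ids_tsv
        assert bed[0].split("\t")[4] == "900"  # round(1000 * 0.9)

    def test_bed_round_trip(self, tmp_path):
        cands = self._three()
        paths = emit_database(cands, tmp_path / "db")
        back = []
        for line in paths["bed"].read_text().strip().split("\n"):
            f = line.split("\t")
            back.append((f[0], int(f[1]), int(f[2]), f[5]))
        assert sorted(back) == sorted((c.chrom, c.start, c.end, c.strand)
                                      for c in cands)

    def test_empty_set(self, tmp_path):
        paths = emit_database([], tmp_path / "db")
        assert paths["fasta"].read_text() == ""
        assert paths["tsv"].read_text().startswith("id\t")


class TestTranslateSeps:
    def test_atg(self):
        c = make_candidate(orf_seq="ATGAAATAA", end=9)
        assert translate_seps([c]) == ["MK"]

    def test_non_atg_start_becomes_met(self):
        c = make_candidate(orf_seq="CTGAAATAA", start_codon="CTG", end=9)
        assert translate_seps([c]) == ["MK"]

    def test_length_law(self):
        rng = np.random.default_rng(0)
        from conftest import random_orf_record
        recs = [random_orf_record(rng, rec_id=f"r{i}") for i in range(20)]
        for rec, pep in zip(recs, translate_seps(recs)):
            assert len(pep) == rec.n_codons - 1

    def test_internal_stop_errors(self):
        c = make_candidate(orf_seq="ATGTAATAA", end=9)
        with pytest.raises(ValueError):
            translate_seps([c])


class TestStandardizedRatio:
    def test_identity(self):
        assert standardized_ratio(7, 7, 100, 100) == 1

    def test_hand_arithmetic(self):
        v = standardized_ratio(5188, 2, 218709, 20112)
        assert v == pytest.approx((5188 / 2) * (20112 / 218709))
        assert v == pytest.approx(238.6, abs=0.5)

    def test_linearity(self):
        assert standardized_ratio(10, 3, 50, 60) == \
            pytest.approx(2 * standardized_ratio(5, 3, 50, 60))

    def test_zero_denominators(self):
        with pytest.raises(ValueError):
            standardized_ratio(1, 0, 10, 10)
        with pytest.raises(ValueError):
            standardized_ratio(1, 1, 0, 10)
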