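import random
from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from homeoprime.alignment_snp import (MultipleAlignment, align,
                                      load_user_alignment,
                                      locate_input_region, pairwise_global,
                                      scan_snps)
from homeoprime.homology import ExtractedSequence
from homeoprime.io_formats import SequenceRecord
from homeoprime.synthetic_fixtures import FixtureSpec, generate_fixture

MATCH, MISMATCH, OPEN, EXTEND = 5.0, -4.0, 10.0, 0.5


def oracle_score(a: str, b: str) -> float:
    """Independent affine-gap global alignment optimum by exhaustive
    state-space recursion over the last alignment column, permitting every
    state transition (including gap-to-opposite-gap openings)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state of the LAST column: 0 substitution, 1 gap-in-b, 2 gap-in-a
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i == 0 or j == 0:
                return NEG
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            return max(best(i - 1, j - 1, s) for s in (0, 1, 2)) + sub
        if state == 1:
            if i == 0:
                return NEG
            return max(best(i - 1, j, 0) - OPEN,
                       best(i - 1, j, 1) - EXTEND,
                       best(i - 1, j, 2) - OPEN)
        if j == 0:
            return NEG
        return max(best(i, j - 1, 0) - OPEN,
                   best(i, j - 1, 2) - EXTEND,
                   best(i, j - 1, 1) - OPEN)

    return max(best(len(a), len(b), s) for s in (0, 1, 2))


class TestPairwiseGlobal:
    def test_single_gap_example(self):
        ga, gb, score = pairwise_global("ACGTACGT", "ACGACGT")
        assert ga.replace("-", "") == "ACGTACGT"
        assert gb.replace("-", "") == "ACGACGT"
        assert gb.count("-") - ga.count("-") == 1
        assert score == 7 * MATCH - OPEN

    def test_identical_sequences_no_gaps(self):
        ga, gb, score = pairwise_global("ACGTAC", "ACGTAC")
        assert ga == gb == "ACGTAC"
        assert score == 6 * MATCH

    @pytest.mark.parametrize("seed", range(20))
    def test_score_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        _, _, score = pairwise_global(a, b)
        assert score == pytest.approx(oracle_score(a, b))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=10),
           st.text(alphabet="ACGT", min_size=1, max_size=10))
    def test_score_matches_oracle_property(self, a, b):
        _, _, score = pairwise_global(a, b)
        assert score == pytest.approx(oracle_score(a, b))

    def test_alignment_score_consistent_with_rows(self):
        rng = random.Random(4)
        a = "".join(rng.choice("ACGT") for _ in range(200))
        b = list(a)
        for pos in rng.sample(range(200), k=14):
            b[pos] = rng.choice([x for x in "ACGT" if x != a[pos]])
        del b[50:53]
        b = "".join(b)
        ga, gb, score = pairwise_global(a, b)
        # recompute the score from the gapped rows
        total, i = 0.0, 0
        while i < len(ga):
            if ga[i] == "-" or gb[i] == "-":
                which = ga if ga[i] == "-" else gb
                j = i
                while j < len(ga) and which[j] == "-":
                    j += 1
                total -= OPEN + (j - i - 1) * EXTEND
                i = j
            else:
                total += MATCH if ga[i] == gb[i] else MISMATCH
                i += 1
        assert total == pytest.approx(score)


def mk_ext(label, residues, role):
    return ExtractedSequence(label=label, genome_label="g", chrom=label,
                             start=0, end=len(residues), strand="+",
                             residues=residues, role=role)


class TestAlign:
    def test_target_alone(self):
        msa = align([mk_ext("t", "ACGTACGT", "target_locus")])
        assert msa.n_columns == 8 and "-" not in msa.target_gapped

    def test_rows_roundtrip_at_93_and_80_identity(self):
        rng = random.Random(12)
        base = "".join(rng.choice("ACGT") for _ in range(800))

        def mutate(seq, rate):
            out = list(seq)
            for pos in range(len(seq)):
                if rng.random() < rate:
                    out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            return "".join(out)

        seqs = [mk_ext("t", base, "target_locus"),
                mk_ext("h1", mutate(base, 0.07), "homologue"),
                mk_ext("h2", mutate(base, 0.20), "homologue")]
        msa = align(seqs)
        for (label, _, gapped), src in zip(msa.rows, seqs):
            assert gapped.replace("-", "") == src.residues

    def test_first_sequence_must_be_target(self):
        with pytest.raises(ValueError, match="target"):
            align([mk_ext("h", "ACGT", "homologue")])

    def test_missing_backend_binary_is_clear_error(self):
        with pytest.raises(RuntimeError, match="dialign"):
            align([mk_ext("t", "ACGTACGTACGT", "target_locus")],
                  backend="dialign")


class TestLocateInputRegion:
    def test_flank_offsets(self):
        flank = "A" * 20
        gene = "CGCGTTGTCGTACGATCAGG"
        msa = align([mk_ext("t", flank + gene + flank, "target_locus")])
        region = locate_input_region(msa, SequenceRecord("g", "", gene))
        assert region == (20, 40)

    def test_gap_columns_widen_region(self):
        rows = [("t", "target_locus", "AAC--GTTT"),
                ("h", "homologue", "AACGGGTTT")]
        msa = MultipleAlignment(rows=rows)
        region = locate_input_region(msa, SequenceRecord("g", "", "ACGT"))
        # ungapped target AACGTTT; input at positions 1..5 -> columns 1..7
        assert region == (1, 7)

    def test_absent_input_is_error(self):
        msa = align([mk_ext("t", "ACGTACGTACGT", "target_locus")])
        with pytest.raises(ValueError, match="not found"):
            locate_input_region(msa, SequenceRecord("g", "", "TTTTTTT"))

    def test_ambiguous_input_is_error(self):
        msa = align([mk_ext("t", "ACGTACGT", "target_locus")])
        with pytest.raises(ValueError, match="more than once"):
            locate_input_region(msa, SequenceRecord("g", "", "ACGT"))


def mk_msa(target, homologues, extra=()):
    rows = [("t", "target_locus", target)]
    rows += [(f"h{i}", "homologue", h) for i, h in enumerate(homologues)]
    rows += [(f"v{i}", "extra_genome", v) for i, v in enumerate(extra)]
    return MultipleAlignment(rows=rows)


class TestScanSnps:
    def snp_at(self, snps, col):
        return next(s for s in snps if s.column == col)

    def test_all_homologues_differ_is_discriminating(self):
        snps = scan_snps(mk_msa("CATC", ["CGTC", "CGTC"]))
        assert self.snp_at(snps, 1).discriminating

    def test_one_matching_homologue_blocks(self):
        snps = scan_snps(mk_msa("CATC", ["CGTC", "CATC"]))
        assert not self.snp_at(snps, 1).discriminating

    def test_varietal_conflict_marks_unusable(self):
        snps = scan_snps(mk_msa("CATC", ["CGTC"], extra=["CTTC"]))
        col = self.snp_at(snps, 1)
        assert col.discriminating and col.varietal_conflict and not col.usable

    def test_matching_variety_keeps_usable(self):
        snps = scan_snps(mk_msa("CATC", ["CGTC"], extra=["CATC"]))
        assert self.snp_at(snps, 1).usable

    def test_n_in_homologue_vetoes(self):
        snps = scan_snps(mk_msa("CATC", ["CNTC"]))
        assert not self.snp_at(snps, 1).discriminating

    def test_internal_gap_discriminates_with_flag(self):
        snps = scan_snps(mk_msa("CATTC", ["CA-TC"]))
        col = self.snp_at(snps, 2)
        assert col.discriminating and col.gap_discriminated

    def test_leading_trailing_gaps_abstain(self):
        # homologue h0 covers only columns 2..5; columns outside must not
        # become discriminating on the strength of its absence alone
        snps = scan_snps(mk_msa("CATTCG", ["--TTC-", "GGGGGA"]))
        # column 0: h0 abstains, h1 differs -> discriminating
        assert self.snp_at(snps, 0).discriminating
        # column 2: h0 matches -> blocked
        assert not self.snp_at(snps, 2).discriminating

    def test_no_evidence_anywhere_is_not_discriminating(self):
        snps = scan_snps(mk_msa("CATTCG", ["--TT--"]))
        assert not self.snp_at(snps, 0).discriminating
        assert not self.snp_at(snps, 5).discriminating

    def test_homologue_row_order_invariant(self):
        a = scan_snps(mk_msa("CATC", ["CGTC", "CTTC"]))
        b = scan_snps(mk_msa("CATC", ["CTTC", "CGTC"]))
        assert [(s.column, s.discriminating) for s in a] == \
               [(s.column, s.discriminating) for s in b]

    def test_target_gap_columns_skipped(self):
        snps = scan_snps(mk_msa("CA-TC", ["CAGTC"]))
        assert [s.column for s in snps] == [0, 1, 3, 4]
        assert [s.target_pos for s in snps] == [0, 1, 2, 3]


class TestFixtureRecovery:
    def test_planted_discriminating_snps_recovered(self):
        """>=90% of ground-truth discriminating positions must survive
        alignment and SNP scanning on a substitution-only polyploid."""
        spec = FixtureSpec(seed=5, gene_length=1200, chrom_length=8000,
                           homeologue_identities=(0.93, 0.93),
                           homeologous_flank=500)
        fx = generate_fixture(spec)
        seqs = [mk_ext("t", fx.unit, "target_locus")]
        for label, hseq in fx.homeologue_units.items():
            seqs.append(mk_ext(label, hseq, "homologue"))
        msa = align(seqs)
        snps = scan_snps(msa)
        found = {s.target_pos for s in snps if s.discriminating}
        truth = set(fx.truth_discriminating_positions())
        recovered = len(truth & found) / len(truth)
        assert recovered >= 0.90
        # precision: nearly every reported column is a real difference
        precision = len(truth & found) / len(found)
        assert precision >= 0.95

    def test_terminal_mismatch_property(self):
        """Every discriminating column re-checked against the raw sequences
        shows a terminal mismatch for a 20-mer ending at the SNP."""
        spec = FixtureSpec(seed=6, gene_length=800, chrom_length=6000,
                           homeologue_identities=(0.93,),
                           homeologous_flank=300)
        fx = generate_fixture(spec)
        label, hseq = next(iter(fx.homeologue_units.items()))
        msa = align([mk_ext("t", fx.unit, "target_locus"),
                     mk_ext(label, hseq, "homologue")])
        tgt_gapped = msa.target_gapped
        hom_gapped = msa.rows[1][2]
        for s in scan_snps(msa):
            if not s.discriminating or s.gap_discriminated:
                continue
            assert tgt_gapped[s.column] != hom_gapped[s.column]
            assert tgt_gapped[s.column] == fx.unit[s.target_pos]


class TestUserAlignment:
    def test_valid_alignment_loads(self, tmp_path):
        p = tmp_path / "user.fa"
        p.write_text(">bare\n----CGTACGATGCA----\n"
                     ">flanked\nTTAGCGTACGATGCAGGTC\n"
                     ">hom\nTTAGCATACGTTGCAGGTC\n")
        msa, region = load_user_alignment(p)
        assert [r[1] for r in msa.rows] == ["target_locus", "homologue"]
        assert region == (4, 15)

    def test_misordered_rows_cite_required_order(self, tmp_path):
        p = tmp_path / "user.fa"
        p.write_text(">flanked\nTTAGCGTACGATGCAGGTC\n"
                     ">bare\n----CGTACGATGCA----\n"
                     ">hom\nTTAGCATACGTTGCAGGTC\n")
        with pytest.raises(ValueError, match="sequence to be cloned"):
            load_user_alignment(p)
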