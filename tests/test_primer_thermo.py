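import math
import random

import pytest

from homeoprime.alignment_snp import SnpColumn
from homeoprime.homology import ExtractedSequence
from homeoprime.io_formats import reverse_complement
from homeoprime.parameters import DesignParameters
from homeoprime.primer_thermo import (INIT_AT, INIT_GC, NN_TABLE, PAIR_WEIGHT,
                                      R_GAS, PrimerCandidate, PrimerPair,
                                      complementarity_scores, cross_dimer,
                                      generate_candidates, melting_temperature,
                                      pair_penalty, primer_penalty,
                                      score_candidate)

PARAMS = DesignParameters()


def random_primer(rng, lo=18, hi=27):
    return "".join(rng.choice("ACGT") for _ in range(rng.randint(lo, hi)))


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("A" * 20) < melting_temperature("GC" * 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stack_sum_oracle(self, seed):
        """Tm equals an independently coded sum over the dinucleotide
        stacks, initiation terms and entropy salt correction."""
        rng = random.Random(seed)
        seq = random_primer(rng, 20, 20)
        dh = ds = 0.0
        for a, b in zip(seq, seq[1:]):          # the 19 stacks
            h, s = NN_TABLE[a + b]
            dh += h
            ds += s
        for t in (seq[0], seq[-1]):
            h, s = INIT_GC if t in "GC" else INIT_AT
            dh += h
            ds += s
        ds += 0.368 * 19 * math.log(0.05)
        expected = dh * 1000 / (ds + R_GAS * math.log(500e-9 / 4)) - 273.15
        assert melting_temperature(seq, 50.0, 500.0) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_symmetry(self, seed):
        rng = random.Random(100 + seed)
        seq = random_primer(rng)
        assert melting_temperature(seq) == \
            pytest.approx(melting_temperature(reverse_complement(seq)))

    def test_biopython_cross_check(self):
        """Independent thermodynamic oracle: Biopython's nearest-neighbor Tm
        with the same unified table, concentrations and salt correction."""
        from Bio.SeqUtils import MeltingTemp as mt
        rng = random.Random(42)
        for _ in range(20):
            seq = random_primer(rng)
            ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50,
                           dnac1=250, dnac2=250, saltcorr=5)
            assert melting_temperature(seq, 50.0, 500.0) == \
                pytest.approx(ref, abs=1.0)

    def test_rejects_n_and_short(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            melting_temperature("ACGTNACGTACG")
        with pytest.raises(ValueError, match="< 8"):
            melting_temperature("ACGTA")


def oracle_dimer(a: str, other: str, end_only: bool = False) -> float:
    """Exhaustive enumeration over every ungapped antiparallel offset and
    every contiguous run, written independently of the implementation."""
    b = other[::-1]
    n, m = len(a), len(b)
    best = 0.0
    for offset in range(-(m - 1), n):
        lo, hi = max(0, offset), min(n, offset + m)
        for start in range(lo, hi):
            for stop in range(start + 1, hi + 1):
                idxs = range(start, stop)
                ws = [PAIR_WEIGHT.get((a[i], b[i - offset]), 0) for i in idxs]
                if 0 in ws:
                    continue
                if end_only and (n - 1) not in idxs:
                    continue
                best = max(best, sum(ws))
    return best


def oracle_hairpin(seq: str) -> int:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    best = 0
    n = len(seq)
    for i in range(n):           # innermost stem pair (i, j), loop >= 3
        for j in range(i + 4, n):
            stem, x, y = 0, i, j
            while x >= 0 and y < n and comp[seq[x]] == seq[y]:
                stem += 1
                x -= 1
                y += 1
            best = max(best, stem)
    return best


class TestComplementarityScores:
    def test_poly_a_scores_zero(self):
        assert complementarity_scores("A" * 18) == (0.0, 0.0, 0)

    def test_palindromic_stem_hairpin(self):
        _, _, hairpin = complementarity_scores("GCGCGCGCATATGCGCGCGC")
        assert hairpin >= 8

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(25):
            seq = random_primer(rng)
            self_any, self_end, hairpin = complementarity_scores(seq)
            assert self_any == oracle_dimer(seq, seq)
            assert self_end == oracle_dimer(seq, seq, end_only=True)
            assert hairpin == oracle_hairpin(seq)

    def test_cross_dimer_matches_oracle(self):
        rng = random.Random(77)
        for _ in range(20):
            a, b = random_primer(rng), random_primer(rng)
            assert cross_dimer(a, b) == oracle_dimer(a, b)

    def test_self_end_never_exceeds_self_any(self):
        rng = random.Random(13)
        for _ in range(30):
            seq = random_primer(rng)
            self_any, self_end, _ = complementarity_scores(seq)
            assert self_end <= self_any


def mk_candidate(**overrides):
    cand = PrimerCandidate(sequence_5to3="A" * 20, direction="F", start=0,
                           end=20, anchor=None)
    cand.tm = overrides.pop("tm", PARAMS.tm_opt)
    cand.gc = overrides.pop("gc", 50.0)
    cand.self_any = overrides.pop("self_any", 0.0)
    cand.self_end = overrides.pop("self_end", 0.0)
    cand.hairpin_score = overrides.pop("hairpin", 0.0)
    for k, v in overrides.items():
        setattr(cand, k, v)
    return cand


class TestPenalties:
    def test_zero_at_optimum(self):
        assert primer_penalty(mk_candidate(), PARAMS) == 0.0

    def test_hand_computed_weighted_sum(self):
        cand = mk_candidate(tm=61.5, gc=25.0, self_any=4.0, self_end=2.0,
                            hairpin=3.0)
        cand.sequence_5to3 = "A" * 22  # length 22 -> |22-20| = 2
        cand.end = 22
        expected = (abs(61.5 - 60.0) + 1.0 * 2 + 0.5 * (30.0 - 25.0)
                    + 0.1 * 4.0 + 0.2 * 2.0 + 0.1 * 3.0)
        assert primer_penalty(cand, PARAMS) == pytest.approx(expected)

    def test_monotone_in_tm_distance(self):
        close = primer_penalty(mk_candidate(tm=60.5), PARAMS)
        far = primer_penalty(mk_candidate(tm=62.5), PARAMS)
        assert close < far

    def test_gap_discriminated_anchor_penalized(self):
        snp = SnpColumn(column=0, target_pos=0, target_base="A",
                        homologue_bases=("-",), discriminating=True,
                        gap_discriminated=True)
        plain = mk_candidate()
        flagged = mk_candidate()
        flagged.anchor = snp
        assert primer_penalty(flagged, PARAMS) == \
            primer_penalty(plain, PARAMS) + PARAMS.w_gap

    def test_penalty_nonnegative_on_random_primers(self):
        rng = random.Random(3)
        for _ in range(30):
            cand = score_candidate(
                PrimerCandidate(random_primer(rng), "F", 0, 20, None), PARAMS)
            assert cand.penalty >= 0.0

    def test_pair_penalty_hand_sum_and_symmetry(self):
        rng = random.Random(9)
        f = score_candidate(PrimerCandidate(random_primer(rng), "F", 0, 20, None),
                            PARAMS)
        r = score_candidate(PrimerCandidate(random_primer(rng), "R", 500, 520,
                                            None), PARAMS)
        pair = PrimerPair(f, r, 0, 520)
        expected = (f.penalty + r.penalty + PARAMS.w_tmdiff * abs(f.tm - r.tm)
                    + PARAMS.w_cross * cross_dimer(f.sequence_5to3,
                                                   r.sequence_5to3))
        assert pair_penalty(pair, PARAMS) == pytest.approx(expected)
        swapped = PrimerPair(r, f, 0, 520)
        assert pair_penalty(swapped, PARAMS) == \
            pytest.approx(pair_penalty(pair, PARAMS))


def mk_target(residues):
    return ExtractedSequence(label="t", genome_label="g", chrom="c", start=0,
                             end=len(residues), strand="+", residues=residues,
                             role="target_locus")


def mk_snp(pos, base):
    return SnpColumn(column=pos, target_pos=pos, target_base=base,
                     homologue_bases=("G",), discriminating=True)


class TestGenerateCandidates:
    def setup_method(self):
        rng = random.Random(21)
        self.seq = "".join(rng.choice("ACGT") for _ in range(400))
        self.target = mk_target(self.seq)

    def test_candidate_count_bounded_by_length_range(self):
        snps = [mk_snp(200, self.seq[200])]
        cands = generate_candidates(snps, self.target, PARAMS)
        fwd = [c for c in cands if c.direction == "F"]
        rev = [c for c in cands if c.direction == "R"]
        assert len(fwd) == len(rev) == 10  # lengths 18..27

    def test_near_start_snp_has_no_forward(self):
        snps = [mk_snp(5, self.seq[5])]
        cands = generate_candidates(snps, self.target, PARAMS)
        assert all(c.direction == "R" for c in cands)

    def test_forward_three_prime_base_is_anchor(self):
        snps = [mk_snp(150, self.seq[150]), mk_snp(300, self.seq[300])]
        for c in generate_candidates(snps, self.target, PARAMS):
            if c.direction == "F":
                assert c.sequence_5to3[-1] == self.seq[c.anchor.target_pos]
                assert c.end == c.anchor.target_pos + 1
            else:
                # reverse primer 3' base is the complement of the anchor base
                assert c.sequence_5to3[-1] == \
                    reverse_complement(self.seq[c.anchor.target_pos])
                assert c.start == c.anchor.target_pos

    def test_unusable_snps_skipped(self):
        snp = mk_snp(200, self.seq[200])
        snp.varietal_conflict = True
        assert generate_candidates([snp], self.target, PARAMS) == []

    def test_candidates_with_n_dropped(self):
        seq = self.seq[:190] + "N" + self.seq[191:]
        snps = [mk_snp(200, seq[200])]
        cands = generate_candidates(snps, mk_target(seq), PARAMS)
        # forward candidates of length >= 11 would span the N at 190
        fwd = [c for c in cands if c.direction == "F"]
        assert all(c.start > 190 for c in fwd)
        assert len(fwd) < 10
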