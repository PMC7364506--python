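"""Candidate primer generation and thermodynamic scoring.

Candidates are anchored with their 3'-terminal base on a discriminating SNP
(forward primers end at the SNP on the plus strand; reverse primers are the
reverse complement of a window starting at the SNP, so their 3' end sits on
the SNP on the minus strand). Each candidate is scored for melting
temperature (nearest-neighbor thermodynamics with entropy salt correction),
GC content, self-complementarity and hairpin propensity, and folded into a
single non-negative penalty; pairs add a Tm-difference and cross-dimer term.
Lower penalty is better; a candidate at every optimum with no
self-structure scores exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .alignment_snp import SnpColumn
from .homology import ExtractedSequence
from .io_formats import reverse_complement
from .parameters import DesignParameters

R_GAS = 1.987  # cal / (K mol)

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K),
# 5'->3' dinucleotide on the top strand; the table is already symmetric
# under reverse complement.
NN_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation per terminal base pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# complementary-pair weights for dimer/hairpin scoring
PAIR_WEIGHT = {("A", "T"): 1, ("T", "A"): 1, ("G", "C"): 2, ("C", "G"): 2}


def melting_temperature(sequence: str, monovalent_mM: float = 50.0,
                        primer_nM: float = 500.0) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Tm = dH*1000 / (dS_salt + R ln(C/4)) - 273.15, where dH and dS are the
    sum over dinucleotide stacks plus the two terminal initiation terms, the
    salt correction dS_salt = dS + 0.368*(N-1)*ln[Na+] uses the monovalent
    concentration, and C is the total primer concentration (excess primer
    over template, hence C/4).
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("melting temperature undefined for primers < 8 bases")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"cannot compute Tm with non-ACGT residues {sorted(bad)}")
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM * 1e-3)
    c = primer_nM * 1e-9
    return dh * 1000.0 / (ds + R_GAS * math.log(c / 4.0)) - 273.15


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _max_weighted_run(a: str, other: str, require_index: Optional[int] = None
                      ) -> float:
    """Best contiguous complementary run between two antiparallel strands.

    ``a`` and ``other`` are both written 5'->3'; annealing is antiparallel,
    so ``a`` is slid along the reverse of ``other`` at every ungapped offset
    and contiguous complementary pairings are summed with G:C counting 2 and
    A:T counting 1. If ``require_index`` is set, only runs in which that
    position of ``a`` is itself paired count (3'-end restriction).
    """
    n, m = len(a), len(other)
    b = other[::-1]
    best = 0.0
    for offset in range(-(m - 1), n):
        run = 0.0
        run_has = False
        cur = 0.0
        cur_has = False
        lo = max(0, offset)
        hi = min(n, offset + m)
        for i in range(lo, hi):
            j = i - offset
            w = PAIR_WEIGHT.get((a[i], b[j]), 0)
            if w:
                cur += w
                cur_has = cur_has or (i == require_index)
            else:
                if cur > run and (require_index is None or cur_has):
                    run, run_has = cur, cur_has
                cur, cur_has = 0.0, False
            if cur > run and (require_index is None or cur_has):
                run, run_has = cur, cur_has
        if run > best:
            best = run
    return best


def complementarity_scores(sequence: str) -> Tuple[float, float, int]:
    """(self_any, self_end, hairpin_score) for one primer.

    ``self_any`` is the best weighted complementary run over all ungapped
    antiparallel self-alignments; ``self_end`` the same restricted to runs
    covering the 3' terminus; ``hairpin_score`` the maximum stem length
    (paired-base count) over all fold points with a loop of at least 3.
    """
    seq = sequence.upper()
    self_any = _max_weighted_run(seq, seq)
    self_end = _max_weighted_run(seq, seq, require_index=len(seq) - 1)
    hairpin = 0
    n = len(seq)
    for i in range(n):
        for j in range(i + 4, n):  # loop between i and j must be >= 3
            stem = 0
            x, y = i, j
            while x >= 0 and y < n and y - x - 1 >= 3 \
                    and COMPLEMENT.get(seq[x]) == seq[y]:
                stem += 1
                x -= 1
                y += 1
            hairpin = max(hairpin, stem)
    return self_any, self_end, hairpin


def cross_dimer(seq_a: str, seq_b: str) -> float:
    """Best weighted complementary run between two different primers."""
    return _max_weighted_run(seq_a.upper(), seq_b.upper())


@dataclass
class PrimerCandidate:
    """A scored oligo on the flanked target's forward coordinate system."""

    sequence_5to3: str
    direction: str            # F | R
    start: int                # 0-based half-open on the flanked target
    end: int
    anchor: Optional[SnpColumn]   # None => sequencing primer
    tm: float = 0.0
    gc: float = 0.0
    hairpin_score: float = 0.0
    self_any: float = 0.0
    self_end: float = 0.0
    penalty: float = 0.0
    split_index: Optional[int] = None  # set for Sanger sequencing primers

    def __len__(self) -> int:
        return len(self.sequence_5to3)


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_start: int
    product_end: int
    pair_penalty: float = 0.0

    @property
    def product_size(self) -> int:
        return self.product_end - self.product_start


def primer_penalty(candidate: PrimerCandidate, params: DesignParameters) -> float:
    """Weighted single-primer penalty; zero only at the documented optimum."""
    gc_viol = max(0.0, params.gc_min - candidate.gc, candidate.gc - params.gc_max)
    pen = (abs(candidate.tm - params.tm_opt)
           + params.w_len * abs(len(candidate) - params.len_opt)
           + params.w_gc * gc_viol
           + params.w_self * candidate.self_any
           + params.w_end * candidate.self_end
           + params.w_hairpin * candidate.hairpin_score)
    if candidate.anchor is not None and candidate.anchor.gap_discriminated:
        pen += params.w_gap
    return pen


def score_candidate(candidate: PrimerCandidate, params: DesignParameters
                    ) -> PrimerCandidate:
    candidate.tm = melting_temperature(candidate.sequence_5to3,
                                       params.monovalent_mM, params.primer_nM)
    candidate.gc = gc_percent(candidate.sequence_5to3)
    candidate.self_any, candidate.self_end, candidate.hairpin_score = \
        complementarity_scores(candidate.sequence_5to3)
    candidate.penalty = primer_penalty(candidate, params)
    return candidate


def pair_penalty(pair: PrimerPair, params: DesignParameters) -> float:
    """Penalty of a primer pair: both single penalties, the Tm mismatch
    between the two primers, and their cross-dimer propensity."""
    return (pair.forward.penalty + pair.reverse.penalty
            + params.w_tmdiff * abs(pair.forward.tm - pair.reverse.tm)
            + params.w_cross * cross_dimer(pair.forward.sequence_5to3,
                                           pair.reverse.sequence_5to3))


def generate_candidates(snps: Sequence[SnpColumn], target: ExtractedSequence,
                        params: DesignParameters) -> List[PrimerCandidate]:
    """All SNP-anchored candidates over the configured length range.

    For each usable SNP and each length, one forward candidate whose last
    base sits on the SNP and one reverse candidate whose 3' end sits on the
    SNP on the minus strand. Candidates containing N or running off the
    sequence are dropped; survivors are fully scored.
    """
    seq = target.residues
    n = len(seq)
    out: List[PrimerCandidate] = []
    for snp in snps:
        if not (snp.discriminating and not snp.varietal_conflict):
            continue
        pos = snp.target_pos
        for length in range(params.len_min, params.len_max + 1):
            # forward: [pos-length+1, pos+1), 3' base at pos
            a = pos - length + 1
            if a >= 0:
                s = seq[a:pos + 1]
                if "N" not in s:
                    out.append(score_candidate(
                        PrimerCandidate(s, "F", a, pos + 1, snp), params))
            # reverse: revcomp of [pos, pos+length), 3' base at pos
            b = pos + length
            if b <= n:
                s = reverse_complement(seq[pos:b])
                if "N" not in s:
                    out.append(score_candidate(
                        PrimerCandidate(s, "R", pos, b, snp), params))
    return out
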