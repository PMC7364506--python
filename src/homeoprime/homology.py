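"""Locate the target locus and its close homologues in one or more genomes.

Local-alignment searches report fragmented high-scoring pairs (HSPs); one
genomic locus therefore appears as several tabular hits that must be chained
back together before ranking. Hits sharing query, subject and strand are
chained into a :class:`HitGroup` whenever consecutive subject intervals are
within ``max_group_gap`` bases (default 1000). The highest-ranking group is
taken as the genomic copy of the input sequence itself; the next few groups
are candidate homologues, kept only while their within-group average
bitscore clears a floor (default 200). Selected loci are extracted with
flanking buffers so primers may sit outside the gene proper.

"Most closely related" is operationalized as highest *total* bitscore
(a locus should dominate on both identity and length); the *mean* bitscore
is reserved for the >200 homologue floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import GenomeIndex, SequenceRecord, TabularHit, reverse_complement
from .parameters import DesignParameters


@dataclass
class HitGroup:
    """A chained cluster of local-alignment hits representing one locus."""

    subject_id: str
    strand: str
    hits: List[TabularHit]
    s_min: int = 0        # 0-based half-open subject span
    s_max: int = 0
    mean_bitscore: float = 0.0
    total_bitscore: float = 0.0
    query_coverage: float = 0.0

    def finalize(self, query_length: int) -> "HitGroup":
        spans = [h.s_span for h in self.hits]
        self.s_min = min(a for a, _ in spans)
        self.s_max = max(b for _, b in spans)
        scores = [h.bitscore for h in self.hits]
        self.total_bitscore = float(sum(scores))
        self.mean_bitscore = self.total_bitscore / len(scores)
        if query_length > 0:
            ivs = sorted(h.q_span for h in self.hits)
            covered = 0
            cur_a, cur_b = ivs[0]
            for a, b in ivs[1:]:
                if a > cur_b:
                    covered += cur_b - cur_a
                    cur_a, cur_b = a, b
                else:
                    cur_b = max(cur_b, b)
            covered += cur_b - cur_a
            self.query_coverage = covered / query_length
        return self


@dataclass
class ExtractedSequence:
    """A genomic slice with provenance, oriented to read in query direction."""

    label: str
    genome_label: str
    chrom: str
    start: int            # 0-based half-open on the forward strand
    end: int
    strand: str
    residues: str
    role: str             # target_locus | homologue | extra_genome
    clamped: bool = False

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HomologySelection:
    target: ExtractedSequence
    homologues: List[ExtractedSequence]
    extra_variety: List[ExtractedSequence]
    discarded_groups: List[Tuple[HitGroup, str]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def group_hits(hits: Sequence[TabularHit], max_group_gap: int = 1000,
               query_length: Optional[int] = None) -> List[HitGroup]:
    """Chain hits into per-(subject, strand) groups.

    Within a bucket, hits sorted by subject start are chained while the gap
    from the end of one subject interval to the start of the next is at most
    ``max_group_gap``. The result is a partition of the input hits.
    """
    if not hits:
        return []
    qids = {h.query_id for h in hits}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple query ids: {sorted(qids)}")
    if query_length is None:
        query_length = max(h.q_end for h in hits)

    buckets: Dict[Tuple[str, str], List[TabularHit]] = {}
    for h in hits:
        buckets.setdefault((h.subject_id, h.strand), []).append(h)

    groups: List[HitGroup] = []
    for (subject, strand), bucket in sorted(buckets.items()):
        bucket.sort(key=lambda h: h.s_span)
        current = [bucket[0]]
        reach = bucket[0].s_span[1]
        for h in bucket[1:]:
            a, b = h.s_span
            if a - reach <= max_group_gap:
                current.append(h)
            else:
                groups.append(HitGroup(subject, strand, current).finalize(query_length))
                current = [h]
            reach = max(reach, b)
        groups.append(HitGroup(subject, strand, current).finalize(query_length))
    return groups


def rank_groups(groups: Sequence[HitGroup]) -> List[HitGroup]:
    """Order groups best-first: total bitscore, then query coverage, then
    (subject_id, s_min) lexicographically so ties are deterministic."""
    return sorted(
        groups,
        key=lambda g: (-g.total_bitscore, -g.query_coverage, g.subject_id, g.s_min),
    )


def select_loci(ranked: Sequence[HitGroup], n_homologue_groups: int = 3,
                bitscore_floor: float = 200.0,
                ) -> Tuple[HitGroup, List[HitGroup], List[Tuple[HitGroup, str]], List[str]]:
    """Split ranked groups into (target, homologues, discarded, warnings).

    The best group is the target locus; the next up to ``n_homologue_groups``
    groups whose mean bitscore exceeds ``bitscore_floor`` are homologues.
    """
    if not ranked:
        raise ValueError("no hit groups to select from")
    target = ranked[0]
    homologues: List[HitGroup] = []
    discarded: List[Tuple[HitGroup, str]] = []
    warnings: List[str] = []
    for g in ranked[1:]:
        if len(homologues) >= n_homologue_groups:
            discarded.append((g, f"beyond the {n_homologue_groups} best homologue groups"))
        elif g.mean_bitscore <= bitscore_floor:
            discarded.append(
                (g, f"mean bitscore {g.mean_bitscore:.1f} <= floor {bitscore_floor:g}"))
        else:
            homologues.append(g)
    if not homologues:
        warnings.append("no homologues found: every non-target group fell below "
                        "the bitscore floor (primers cannot be made allele-specific)")
    return target, homologues, discarded, warnings


def extract_flanked(group: HitGroup, index: GenomeIndex, start_buffer: int = 1000,
                    end_buffer: int = 1000, label: str = "", genome_label: str = "",
                    role: str = "homologue") -> ExtractedSequence:
    """Extract the group's subject span plus flanking buffers.

    Minus-strand groups are reverse-complemented so the result reads in query
    orientation, and the buffers are swapped so "start" always means the
    query-5' side. Intervals overrunning the chromosome are clamped.
    """
    if group.subject_id not in index:
        raise KeyError(f"subject '{group.subject_id}' absent from {index.fasta_path}")
    if group.strand == "+":
        want_a = group.s_min - start_buffer
        want_b = group.s_max + end_buffer
    else:
        want_a = group.s_min - end_buffer
        want_b = group.s_max + start_buffer
    a, b, clamped = index.clamp(group.subject_id, want_a, want_b)
    residues = index.slice(group.subject_id, a, b)
    if group.strand == "-":
        residues = reverse_complement(residues)
    return ExtractedSequence(
        label=label or f"{group.subject_id}:{a}-{b}({group.strand})",
        genome_label=genome_label, chrom=group.subject_id, start=a, end=b,
        strand=group.strand, residues=residues, role=role, clamped=clamped)


# --- internal seed-and-extend search -------------------------------------
#
# A self-contained local similarity search so the pipeline and its tests
# need no external binary: exact word seeding, ungapped x-drop extension,
# then a greedy gapped merge of overlapping diagonals. Scores use fixed
# Karlin-Altschul-style constants (lambda=0.625, K=0.41; match +2,
# mismatch -3, gap open 5, extend 2). Only the ranking behaviour of the
# scores matters downstream; importing externally produced tabular hits
# remains the fidelity path.

MATCH, MISMATCH = 2, -3
GAP_OPEN, GAP_EXTEND = 5, 2
_LAMBDA, _K = 0.625, 0.41
_LN2 = math.log(2.0)


def _bitscore(raw: int) -> float:
    return (_LAMBDA * raw - math.log(_K)) / _LN2


@dataclass
class _Hsp:
    q_start: int  # 0-based half-open, query forward
    q_end: int
    s_start: int  # 0-based half-open, subject forward strand
    s_end: int
    strand: str
    score: int
    matches: int
    length: int
    gaps: int = 0


def _extend_ungapped(q: str, s: str, qi: int, si: int, word: int,
                     xdrop: int = 20) -> Tuple[int, int, int, int]:
    """X-drop extension of an exact seed; returns (qa, qb, score, matches)."""
    cur = word * MATCH
    cur_m = word
    best, best_m = cur, cur_m
    best_qb = qi + word
    i, j = qi + word, si + word
    while i < len(q) and j < len(s):
        if q[i] == s[j]:
            cur += MATCH
            cur_m += 1
        else:
            cur += MISMATCH
        i += 1
        j += 1
        if cur > best:
            best, best_m, best_qb = cur, cur_m, i
        elif best - cur > xdrop:
            break
    # left extension resumes from the best right checkpoint
    cur, cur_m = best, best_m
    best_qa = qi
    i, j = qi, si
    while i > 0 and j > 0:
        i -= 1
        j -= 1
        if q[i] == s[j]:
            cur += MATCH
            cur_m += 1
        else:
            cur += MISMATCH
        if cur > best:
            best, best_m, best_qa = cur, cur_m, i
        elif best - cur > xdrop:
            break
    return best_qa, best_qb, best, best_m


def _search_one_strand(query: str, subject: str, word_size: int) -> List[_Hsp]:
    seeds: Dict[str, List[int]] = {}
    for i in range(len(query) - word_size + 1):
        seeds.setdefault(query[i:i + word_size], []).append(i)
    hsps: List[_Hsp] = []
    # per diagonal, rightmost query end already covered: skip redundant seeds
    covered: Dict[int, int] = {}
    for j in range(len(subject) - word_size + 1):
        w = subject[j:j + word_size]
        for i in seeds.get(w, ()):  # noqa: B905
            diag = j - i
            if covered.get(diag, -1) >= i:
                continue
            qa, qb, score, matches = _extend_ungapped(query, subject, i, j, word_size)
            covered[diag] = qb
            if score >= 2 * word_size:  # drop bare-seed noise
                hsps.append(_Hsp(qa, qb, qa + diag, qb + diag, "+",
                                 score, matches, qb - qa))
    return hsps


def _merge_gapped(hsps: List[_Hsp], max_diag_drift: int = 30,
                  max_gap: int = 100) -> List[_Hsp]:
    """Greedy chain of co-linear HSPs on nearby diagonals into gapped HSPs."""
    hsps = sorted(hsps, key=lambda h: (h.q_start, h.s_start))
    merged: List[_Hsp] = []
    for h in hsps:
        joined = False
        for m in merged:
            drift = abs((h.s_start - h.q_start) - (m.s_end - m.q_end))
            if (drift <= max_diag_drift
                    and -20 <= h.q_start - m.q_end <= max_gap
                    and -20 <= h.s_start - m.s_end <= max_gap
                    and h.q_end > m.q_end and h.s_end > m.s_end):
                gap = max(abs(h.q_start - m.q_end), abs(h.s_start - m.s_end))
                overlap_penalty = max(0, -(h.q_start - m.q_end)) * MATCH
                m.score += h.score - (GAP_OPEN + GAP_EXTEND * gap) - overlap_penalty
                m.matches += h.matches
                m.gaps += 1 if gap > 0 else 0
                m.length = (h.q_end - m.q_start)
                m.q_end, m.s_end = h.q_end, h.s_end
                joined = True
                break
        if not joined:
            merged.append(_Hsp(h.q_start, h.q_end, h.s_start, h.s_end, h.strand,
                               h.score, h.matches, h.length, h.gaps))
    return [m for m in merged if m.score > 0]


def internal_search(query: SequenceRecord, index: GenomeIndex,
                    word_size: int = 11, min_score: int = 40) -> List[TabularHit]:
    """Search a query against every record of an indexed genome.

    Exact ``word_size``-mer seeding with ungapped x-drop extension and a
    greedy gapped merge; both strands are scanned. Emits standard 12-column
    tabular hits whose bitscores come from the documented fixed constants.
    """
    q = query.residues
    if len(q) < word_size:
        raise ValueError(f"query shorter than word size {word_size}")
    hits: List[TabularHit] = []
    for chrom in index.names:
        subject = index.slice(chrom, 0, index.length(chrom))
        for strand in "+-":
            s = subject if strand == "+" else reverse_complement(subject)
            hsps = _merge_gapped(_search_one_strand(q, s, word_size))
            for h in hsps:
                if h.score < min_score:
                    continue
                aln_len = max(h.q_end - h.q_start, h.s_end - h.s_start)
                mism = max(0, min(h.q_end - h.q_start, h.s_end - h.s_start) - h.matches)
                if strand == "+":
                    s1, s2 = h.s_start + 1, h.s_end
                else:
                    n = len(subject)
                    s1, s2 = n - h.s_start, n - h.s_end + 1  # minus: s_start > s_end
                hits.append(TabularHit(
                    query_id=query.id, subject_id=chrom,
                    pct_identity=round(100.0 * h.matches / max(1, aln_len), 2),
                    aln_length=aln_len, mismatches=mism, gap_opens=h.gaps,
                    q_start=h.q_start + 1, q_end=h.q_end,
                    s_start=s1, s_end=s2,
                    e_value=0.0, bitscore=round(_bitscore(h.score), 1)))
    return hits


# --- multi-genome orchestration -------------------------------------------

def select_homology(query: SequenceRecord,
                    genome_hits: Dict[str, List[TabularHit]],
                    genome_indices: Dict[str, GenomeIndex],
                    primary: str,
                    params: DesignParameters) -> HomologySelection:
    """Full locus selection across a primary genome and extra varieties.

    The primary genome supplies the target locus and homologues; from each
    additional genome only the single best group is extracted (role
    ``extra_genome``, no bitscore floor) to guard against varietal SNPs.
    """
    ranked = rank_groups(group_hits(genome_hits[primary], params.max_group_gap,
                                    query_length=len(query)))
    if not ranked:
        raise ValueError(f"no hits against primary genome '{primary}'")
    tgt_group, hom_groups, discarded, warnings = select_loci(
        ranked, params.n_homologue_groups, params.bitscore_floor)
    idx = genome_indices[primary]
    target = extract_flanked(tgt_group, idx, params.start_buffer, params.end_buffer,
                             label=f"{primary}:{tgt_group.subject_id}",
                             genome_label=primary, role="target_locus")
    homologues = [
        extract_flanked(g, idx, params.start_buffer, params.end_buffer,
                        label=f"{primary}:{g.subject_id}:{g.s_min}",
                        genome_label=primary, role="homologue")
        for g in hom_groups
    ]
    extra: List[ExtractedSequence] = []
    for label, hits in genome_hits.items():
        if label == primary:
            continue
        if not hits:
            warnings.append(f"no hits against extra genome '{label}'")
            continue
        best = rank_groups(group_hits(hits, params.max_group_gap,
                                      query_length=len(query)))[0]
        extra.append(extract_flanked(
            best, genome_indices[label], params.start_buffer, params.end_buffer,
            label=f"{label}:{best.subject_id}", genome_label=label,
            role="extra_genome"))
    return HomologySelection(target=target, homologues=homologues,
                             extra_variety=extra, discarded_groups=discarded,
                             warnings=warnings)
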