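"""Choose overlapping primer pairs that tile the whole input sequence.

Every admissible (forward, reverse) anchor combination within the product
size bounds becomes a candidate product; tiling then picks the set of
products with minimal total pair penalty such that the first product starts
at or before the input region, the last ends at or after it, and every
consecutive pair of products overlaps by at least ``min_overlap`` bases.
The optimization is an exact shortest path over the DAG whose nodes are
products and whose edges are admissible successions; when no full cover
exists a greedy rightmost-reach partial cover is returned with its gaps.

Products longer than one usable Sanger read also receive internal forward
sequencing primers ("split" primers), spaced so consecutive read start
points advance by ``sanger_read - sanger_overlap`` — adjacent reads then
overlap enough to be joined confidently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .homology import ExtractedSequence
from .parameters import DesignParameters
from .primer_thermo import (PrimerCandidate, PrimerPair, pair_penalty,
                            score_candidate)


@dataclass
class TilingSolution:
    pairs: List[PrimerPair]
    sequencing_primers: List[PrimerCandidate] = field(default_factory=list)
    covered: bool = False
    coverage_gaps: List[Tuple[int, int]] = field(default_factory=list)
    total_penalty: float = 0.0
    all_candidates: List[PrimerCandidate] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    _seq_owner: Dict[int, PrimerPair] = field(default_factory=dict)

    def pair_for_sequencing(self, cand: PrimerCandidate) -> PrimerPair:
        return self._seq_owner[id(cand)]

    def register_sequencing(self, pair: PrimerPair,
                            primers: Sequence[PrimerCandidate]) -> None:
        for p in primers:
            self.sequencing_primers.append(p)
            self._seq_owner[id(p)] = pair


def enumerate_pairs(candidates: Sequence[PrimerCandidate],
                    params: DesignParameters,
                    per_anchor_cap: int = 3) -> List[PrimerPair]:
    """All (forward, reverse) anchor combinations within the size bounds.

    For each (forward SNP, reverse SNP) anchor pair only the best-penalty
    length combination is kept, evaluated over the ``per_anchor_cap``
    lowest-penalty candidates of each anchor — the full quadratic sweep over
    every length pair adds nothing but cost. The complete scored candidate
    list remains available to the caller.
    """
    by_anchor_f: Dict[int, List[PrimerCandidate]] = {}
    by_anchor_r: Dict[int, List[PrimerCandidate]] = {}
    for c in candidates:
        if c.anchor is None:
            continue
        d = by_anchor_f if c.direction == "F" else by_anchor_r
        d.setdefault(c.anchor.target_pos, []).append(c)
    for d in (by_anchor_f, by_anchor_r):
        for k in d:
            d[k].sort(key=lambda c: (c.penalty, c.sequence_5to3))
            d[k] = d[k][:per_anchor_cap]

    pairs: List[PrimerPair] = []
    r_positions = sorted(by_anchor_r)
    for fpos, fcands in sorted(by_anchor_f.items()):
        for rpos in r_positions:
            if rpos <= fpos:
                continue
            best: Optional[PrimerPair] = None
            for fc in fcands:
                for rc in by_anchor_r[rpos]:
                    size = rc.end - fc.start
                    if not params.product_min <= size <= params.product_max:
                        continue
                    pp = PrimerPair(fc, rc, fc.start, rc.end)
                    pp.pair_penalty = pair_penalty(pp, params)
                    if best is None or (pp.pair_penalty, pp.forward.sequence_5to3) \
                            < (best.pair_penalty, best.forward.sequence_5to3):
                        best = pp
            if best is not None:
                pairs.append(best)
    pairs.sort(key=lambda p: (p.product_start, p.product_size,
                              p.forward.sequence_5to3))
    return pairs


def _greedy_cover(pairs: Sequence[PrimerPair], region: Tuple[int, int],
                  min_overlap: int) -> Tuple[List[PrimerPair], List[Tuple[int, int]]]:
    """Rightmost-reach greedy partial cover used when no full cover exists."""
    lo, hi = region
    chosen: List[PrimerPair] = []
    gaps: List[Tuple[int, int]] = []
    cursor = lo
    limit = lo  # products must start at or before this to chain
    while cursor < hi:
        feasible = [p for p in pairs if p.product_start <= limit
                    and p.product_end > cursor]
        if not feasible:
            upcoming = [p for p in pairs if p.product_end > cursor]
            if not upcoming:
                gaps.append((cursor, hi))
                break
            nxt = min(upcoming, key=lambda p: (p.product_start, -p.product_end))
            gaps.append((cursor, min(nxt.product_start, hi)))
            chosen.append(nxt)
        else:
            nxt = max(feasible, key=lambda p: (p.product_end, -p.pair_penalty))
            chosen.append(nxt)
        cursor = nxt.product_end
        limit = nxt.product_end - min_overlap
    return chosen, [g for g in gaps if g[0] < g[1]]


def select_tiling(pairs: Sequence[PrimerPair], input_region: Tuple[int, int],
                  params: DesignParameters) -> TilingSolution:
    """Minimal-penalty overlapping cover of the input region.

    Exact shortest path over the product DAG: sources start at or before the
    region, sinks end at or after it, and an edge p -> q exists when q
    starts inside p by at least ``min_overlap`` bases and extends the cover.
    Ties break on (product_start, product_size, forward sequence) so a fixed
    input always yields the same solution.
    """
    lo, hi = input_region
    if not pairs:
        return TilingSolution(pairs=[], covered=False, coverage_gaps=[(lo, hi)],
                              warnings=["no admissible primer pairs"])
    order = sorted(pairs, key=lambda p: (p.product_start, p.product_size,
                                         p.forward.sequence_5to3))
    n = len(order)
    starts = np.array([p.product_start for p in order])
    ends = np.array([p.product_end for p in order])
    pens = np.array([p.pair_penalty for p in order])

    INF = math.inf
    best = np.full(n, INF)
    parent = np.full(n, -1, dtype=int)
    src = starts <= lo
    best[src] = pens[src]
    # nodes sorted by start; a predecessor must end at least min_overlap
    # past our start and we must extend it
    for i in range(n):
        preds = (ends >= starts[i] + params.min_overlap) & (ends < ends[i]) \
                & (starts < starts[i]) & np.isfinite(best)
        if preds.any():
            cand = best[preds] + pens[i]
            j = int(np.argmin(cand))
            idxs = np.nonzero(preds)[0]
            if cand[j] < best[i]:
                best[i] = cand[j]
                parent[i] = idxs[j]

    sinks = (ends >= hi) & np.isfinite(best)
    if sinks.any():
        end_idx = int(np.nonzero(sinks)[0][np.argmin(best[sinks])])
        chain: List[PrimerPair] = []
        k = end_idx
        while k >= 0:
            chain.append(order[k])
            k = int(parent[k])
        chain.reverse()
        sol = TilingSolution(pairs=chain, covered=True,
                             total_penalty=float(best[end_idx]))
        return sol

    chosen, gaps = _greedy_cover(order, input_region, params.min_overlap)
    if starts.size and starts.min() > lo:
        gaps = [(lo, min(int(starts.min()), hi))] + gaps
    return TilingSolution(pairs=sorted(chosen, key=lambda p: p.product_start),
                          covered=False, coverage_gaps=gaps,
                          total_penalty=float(sum(p.pair_penalty for p in chosen)),
                          warnings=["input region could not be fully covered"])


def place_sequencing_primers(pair: PrimerPair, target: ExtractedSequence,
                             params: DesignParameters,
                             warnings: Optional[List[str]] = None
                             ) -> List[PrimerCandidate]:
    """Internal forward primers for Sanger sequencing of a long product.

    A product no longer than one usable read needs none. Otherwise read
    start points advance by ``sanger_read - sanger_overlap`` from the
    product start until the remaining stretch fits one read; each internal
    primer is the lowest-penalty unanchored forward primer inside a window
    around its ideal start point. Primers are numbered split2, split3, ...
    in order (the product's own forward primer is read 1).
    """
    size = pair.product_size
    if size <= params.sanger_read:
        return []
    step = params.sanger_read - params.sanger_overlap
    n_internal = math.ceil(size / step) - 1
    seq = target.residues
    out: List[PrimerCandidate] = []
    # +-50 around the ideal start keeps the worst-case read gap at exactly
    # sanger_read while bounding the per-primer search cost
    half_window = min(50, step // 4)
    for k in range(1, n_internal + 1):
        ideal = pair.product_start + k * step
        chosen = _best_window_primer(seq, ideal, half_window, params)
        if chosen is None:
            chosen = _best_window_primer(seq, ideal, 2 * half_window, params)
            if chosen is None:
                msg = (f"no acceptable sequencing primer near position {ideal} "
                       f"of product {pair.product_start}-{pair.product_end}")
                if warnings is not None:
                    warnings.append(msg)
                continue
        chosen.split_index = k + 1
        out.append(chosen)
    return out


def _best_window_primer(seq: str, ideal: int, half_window: int,
                        params: DesignParameters) -> Optional[PrimerCandidate]:
    best: Optional[PrimerCandidate] = None
    for start in range(max(0, ideal - half_window), ideal + half_window + 1):
        for length in range(params.len_min, params.len_max + 1):
            end = start + length
            if end > len(seq):
                continue
            s = seq[start:end]
            if "N" in s:
                continue
            cand = score_candidate(
                PrimerCandidate(s, "F", start, end, anchor=None), params)
            if cand.tm < params.tm_min or cand.tm > params.tm_max:
                continue
            if best is None or (cand.penalty, cand.start, cand.sequence_5to3) \
                    < (best.penalty, best.start, best.sequence_5to3):
                best = cand
    return best


def build_solution(pairs: Sequence[PrimerPair], input_region: Tuple[int, int],
                   target: ExtractedSequence, params: DesignParameters,
                   all_candidates: Sequence[PrimerCandidate] = ()
                   ) -> TilingSolution:
    """Tile the region, then attach sequencing primers and the full
    candidate table to the solution."""
    sol = select_tiling(pairs, input_region, params)
    sol.all_candidates = list(all_candidates)
    for pair in sol.pairs:
        sol.register_sequencing(
            pair, place_sequencing_primers(pair, target, params, sol.warnings))
    return sol
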