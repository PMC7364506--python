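"""Multiple alignment of target and homologues, and SNP-column mining.

A primer discriminates between near-identical gene copies only through its
3'-terminal base: a single mismatch there suppresses Taq extension by up to
two orders of magnitude. The alignment is therefore scanned column by
column for positions where the target base differs from *every* homologue
that provides evidence at that column; those columns are the admissible 3'
anchors.

Rules, in order:

* a homologue row abstains at columns outside its aligned extent (leading
  or trailing gap run) — a partial homologue neither vetoes nor licenses
  anchors where it simply has no sequence;
* a column with no evidenced homologue at all is never discriminating
  (nothing has been discriminated against);
* an ``N`` in any evidenced homologue vetoes the column;
* an internal gap in a homologue counts as a difference but flags the
  column ``gap_discriminated`` — indel 3' anchors behave unpredictably and
  are deprioritized by a penalty later;
* a same-locus copy from another variety that differs from the target marks
  the column ``varietal_conflict``: the difference may be varietal rather
  than homeologous, so it must not anchor a primer.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .homology import ExtractedSequence
from .io_formats import SequenceRecord, read_alignment, write_fasta

# internal aligner scoring (documented, configurable via align() arguments)
ALN_MATCH = 5.0
ALN_MISMATCH = -4.0
ALN_GAP_OPEN = 10.0   # cost of the first gapped position
ALN_GAP_EXTEND = 0.5  # cost of each further gapped position


@dataclass
class MultipleAlignment:
    """Gapped rows (label, role, residues) with the target row first."""

    rows: List[Tuple[str, str, str]]
    target_row_index: int = 0
    input_region: Optional[Tuple[int, int]] = None  # half-open column interval

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0

    @property
    def target_gapped(self) -> str:
        return self.rows[self.target_row_index][2]

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index][2].replace("-", "")

    def validate(self) -> None:
        lengths = {len(r[2]) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")


@dataclass
class SnpColumn:
    """One alignment column classified for allele-specific anchoring."""

    column: int
    target_pos: int          # 0-based on the ungapped target
    target_base: str
    homologue_bases: Tuple[str, ...]
    discriminating: bool
    varietal_conflict: bool = False
    gap_discriminated: bool = False

    @property
    def usable(self) -> bool:
        return self.discriminating and not self.varietal_conflict


# --- pairwise global alignment (affine gaps) ------------------------------

def pairwise_global(a: str, b: str, match: float = ALN_MATCH,
                    mismatch: float = ALN_MISMATCH, gap_open: float = ALN_GAP_OPEN,
                    gap_extend: float = ALN_GAP_EXTEND) -> Tuple[str, str, float]:
    """Needleman-Wunsch with affine gaps (Gotoh), vectorized per row.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``. Returns the two
    gapped strings and the optimal score. End gaps are charged like any
    other gap; sequences here always share homologous ends after flanked
    extraction, so free end gaps are unnecessary.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return "-" * m or a, "-" * n or b, -(gap_open + (max(n, m) - 1) * gap_extend) if max(n, m) else 0.0
    NEG = -1e12
    bs = np.frombuffer(b.encode(), dtype=np.uint8)
    as_ = np.frombuffer(a.encode(), dtype=np.uint8)

    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)  # gap in b (a aligned to '-')... see below
    Y = np.full(m + 1, NEG)  # gap in a
    M[0] = 0.0
    Y[1:] = -(gap_open + np.arange(m) * gap_extend)
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diagM,1 diagX,2 diagY
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 openM,1 extend,2 openY
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 openM,1 extend,2 openX

    ks = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bs == as_[i - 1], match, mismatch)
        # X: vertical gap (consume a[i-1], gap in b) from the previous row;
        # full Gotoh transitions, so it may also open from a Y gap
        x_open = np.where(M >= Y, M, Y) - gap_open
        x_src = np.where(M >= Y, 0, 2).astype(np.int8)
        x_ext = X - gap_extend
        newX = np.maximum(x_open, x_ext)
        ptr_X[i] = np.where(x_ext > x_open, 1, x_src)
        # M: diagonal from previous row, previous column
        prevM, prevX, prevY = M[:-1], X[:-1], Y[:-1]
        best_prev = np.maximum(np.maximum(prevM, prevX), prevY)
        choice = np.where(prevM >= np.maximum(prevX, prevY), 0,
                          np.where(prevX >= prevY, 1, 2)).astype(np.int8)
        newM = np.full(m + 1, NEG)
        newM[1:] = best_prev + sub
        ptr_M[i, 1:] = choice
        # Y: horizontal gap (consume b[j-1], gap in a), opening from M or X
        # of the current row. Y[j] = max(W[j-1]-open, Y[j-1]-extend) with
        # W = max(M, X) is a prefix-max in z[k] = W[k-1] - open + k*extend.
        w = np.where(newM >= newX, newM, newX)
        w_src = np.where(newM >= newX, 0, 2).astype(np.int8)
        newY = np.full(m + 1, NEG)
        z = w[:-1] - gap_open + ks * gap_extend
        pm = np.maximum.accumulate(z)
        newY[1:] = pm - ks * gap_extend
        extend_mask = np.zeros(m, dtype=bool)
        if m > 1:
            extend_mask[1:] = pm[:-1] > z[1:]
        ptr_Y[i, 1:] = np.where(extend_mask, 1, w_src[:-1])
        M, X, Y = newM, newX, newY

    end_scores = (M[m], X[m], Y[m])
    state = int(np.argmax(end_scores))
    score = float(end_scores[state])
    # traceback
    i, j = n, m
    ga: List[str] = []
    gb: List[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 or j == 0:
                state = 2 if i == 0 else 1
                continue
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            state = int(ptr_M[i, j])
            i -= 1
            j -= 1
        elif state == 1:  # X: a vs gap
            if i == 0:
                state = 2
                continue
            ga.append(a[i - 1])
            gb.append("-")
            p = int(ptr_X[i, j])
            state = 1 if p == 1 else (2 if p == 2 else 0)
            i -= 1
        else:  # Y: gap vs b
            if j == 0:
                state = 1
                continue
            ga.append("-")
            gb.append(b[j - 1])
            p = int(ptr_Y[i, j])
            j -= 1
            state = 2 if p == 1 else (1 if p == 2 else 0)
    return "".join(reversed(ga)), "".join(reversed(gb)), score


def _merge_center_star(center: str,
                       pairs: Sequence[Tuple[str, str]]) -> List[str]:
    """Merge pairwise alignments (center row, other row) on a common center.

    Gap columns inserted into the center by different pairs are reconciled
    by taking, before each center position, the maximum insertion length
    over all pairs (classic center-star merge).
    """
    n = len(center)
    ins = np.zeros(n + 1, dtype=int)  # insertions before center position k
    per_pair_ins: List[np.ndarray] = []
    for gc, _ in pairs:
        cnt = np.zeros(n + 1, dtype=int)
        pos = 0
        run = 0
        for ch in gc:
            if ch == "-":
                run += 1
            else:
                cnt[pos] = run
                run = 0
                pos += 1
        cnt[n] = run
        per_pair_ins.append(cnt)
        ins = np.maximum(ins, cnt)

    def expand(gc: str, row: str, my_ins: np.ndarray) -> str:
        out: List[str] = []
        k = 0  # index into gapped pair columns
        for pos in range(n + 1):
            have = int(my_ins[pos])
            out.append(row[k:k + have])
            out.append("-" * int(ins[pos] - have))
            k += have
            if pos < n:
                out.append(row[k])
                k += 1
        return "".join(out)

    rows: List[str] = []
    # center row itself
    center_ins = np.zeros(n + 1, dtype=int)
    rows.append(expand(center, center, center_ins))
    for (gc, gr), my in zip(pairs, per_pair_ins):
        rows.append(expand(gc, gr, my))
    return rows


def align(sequences: Sequence[ExtractedSequence], backend: str = "internal",
          ) -> MultipleAlignment:
    """Align target (first) and homologues into a MultipleAlignment.

    ``internal`` is a progressive center-star alignment using the target as
    center, built from affine-gap pairwise global alignments. ``muscle`` and
    ``dialign`` shell out to the named binary when present on PATH and raise
    a clear error otherwise; row order is restored afterwards.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    for s in sequences:
        if not s.residues:
            raise ValueError(f"sequence '{s.label}' has no residues")
    if sequences[0].role != "target_locus":
        raise ValueError("first sequence must be the target locus")
    labels = [s.label for s in sequences]
    roles = [s.role for s in sequences]

    if backend == "internal":
        center = sequences[0].residues
        if len(sequences) == 1:
            rows = [center]
        else:
            pairs = []
            for s in sequences[1:]:
                gc, gr, _ = pairwise_global(center, s.residues)
                pairs.append((gc, gr))
            rows = _merge_center_star(center, pairs)
    elif backend in ("muscle", "dialign"):
        rows = _external_align(backend, labels, [s.residues for s in sequences])
    else:
        raise ValueError(f"unknown alignment backend '{backend}'")

    msa = MultipleAlignment(rows=[(l, r, g) for l, r, g in zip(labels, roles, rows)])
    msa.validate()
    for (label, _role, gapped), s in zip(msa.rows, sequences):
        if gapped.replace("-", "") != s.residues:
            raise AssertionError(f"aligner corrupted row '{label}'")
    return msa


def _external_align(backend: str, labels: Sequence[str],
                    seqs: Sequence[str]) -> List[str]:
    binary = shutil.which(backend)
    if binary is None:
        raise RuntimeError(
            f"alignment backend '{backend}' requested but the '{backend}' "
            f"binary is not on PATH; use backend='internal' or install it")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fa"
        fout = Path(td) / "out.fa"
        write_fasta([SequenceRecord(f"s{i}", "", s) for i, s in enumerate(seqs)], fin)
        if backend == "muscle":
            cmd = [binary, "-align", str(fin), "-output", str(fout)]
        else:  # dialign adapter stub: anchor syntax is out of scope
            cmd = [binary, "-fa", "-fn", str(fout.with_suffix("")), str(fin)]
        subprocess.run(cmd, check=True, capture_output=True)
        rows = dict(read_alignment(fout))
    return [rows[f"s{i}"] for i in range(len(seqs))]


# --- input-region location and SNP scanning -------------------------------

def locate_input_region(msa: MultipleAlignment,
                        bare_input: SequenceRecord) -> Tuple[int, int]:
    """Column interval of the bare input inside the (flanked) target row.

    The bare input must occur exactly once in the ungapped target; zero
    occurrences signal a wrong locus, more than one an ambiguous repeat.
    """
    target = msa.ungapped(msa.target_row_index)
    first = target.find(bare_input.residues)
    if first < 0:
        raise ValueError(
            f"input sequence '{bare_input.id}' not found in the extracted "
            "target locus; the homology search likely selected a wrong locus")
    if target.find(bare_input.residues, first + 1) >= 0:
        raise ValueError(
            f"input sequence '{bare_input.id}' occurs more than once in the "
            "target locus; cannot place the input region unambiguously")
    # map ungapped [first, first+len) to columns
    gapped = msa.target_gapped
    pos_to_col = [c for c, ch in enumerate(gapped) if ch != "-"]
    start_col = pos_to_col[first]
    end_col = pos_to_col[first + len(bare_input.residues) - 1] + 1
    region = (start_col, end_col)
    msa.input_region = region
    return region


def _aligned_extent(gapped: str) -> Tuple[int, int]:
    """Half-open column extent between the first and last residue of a row."""
    first = next((i for i, ch in enumerate(gapped) if ch != "-"), 0)
    last = next((i for i in range(len(gapped) - 1, -1, -1) if gapped[i] != "-"), -1)
    return first, last + 1


def scan_snps(msa: MultipleAlignment, warn: Optional[List[str]] = None) -> List[SnpColumn]:
    """Classify every target-base column of the alignment.

    Returns one :class:`SnpColumn` per column where the target row holds a
    plain base. The result is invariant to homologue row order.
    """
    msa.validate()
    target_gapped = msa.target_gapped
    hom_rows = [(r[2], _aligned_extent(r[2])) for r in msa.rows if r[1] == "homologue"]
    var_rows = [(r[2], _aligned_extent(r[2])) for r in msa.rows if r[1] == "extra_genome"]
    if not hom_rows and warn is not None:
        warn.append("alignment has no homologue rows; no column can be "
                    "discriminating and no allele-specific primer will exist")

    out: List[SnpColumn] = []
    tpos = -1
    for col, tbase in enumerate(target_gapped):
        if tbase == "-":
            continue
        tpos += 1
        if tbase not in "ACGT":
            continue
        bases: List[str] = []
        discriminating = len(hom_rows) > 0
        gap_disc = False
        evidenced = 0
        for row, (a, b) in hom_rows:
            if not (a <= col < b):
                bases.append("-")      # outside extent: abstains
                continue
            base = row[col]
            bases.append(base)
            evidenced += 1
            if base == "N":
                discriminating = False
            elif base == "-":
                gap_disc = True        # internal gap: difference, but flagged
            elif base == tbase:
                discriminating = False
        if evidenced == 0:
            discriminating = False
        varietal = False
        for row, (a, b) in var_rows:
            if a <= col < b and row[col] in "ACGT" and row[col] != tbase:
                varietal = True
        out.append(SnpColumn(
            column=col, target_pos=tpos, target_base=tbase,
            homologue_bases=tuple(bases),
            discriminating=discriminating,
            varietal_conflict=varietal,
            gap_discriminated=gap_disc and discriminating))
    return out


# --- user-supplied alignment (-a mode) ------------------------------------

def load_user_alignment(path) -> Tuple[MultipleAlignment, Tuple[int, int]]:
    """Load a user multiple alignment following the documented row order:
    bare input first, the same sequence with flanks second, then homologues.

    Row 1's ungapped content must be a substring of row 2's; violations are
    hard errors quoting the required order.
    """
    rows = read_alignment(path)
    if len(rows) < 2:
        raise ValueError(
            "user alignment needs at least two rows, in the order: sequence "
            "to be cloned, same sequence with flanking regions included, "
            "then any homologues")
    bare_label, bare_gapped = rows[0]
    bare = bare_gapped.replace("-", "")
    flanked_label, flanked_gapped = rows[1]
    flanked = flanked_gapped.replace("-", "")
    if bare not in flanked:
        raise ValueError(
            "row 1 of the user alignment is not contained in row 2; rows "
            "must be ordered: sequence to be cloned, same sequence with "
            "flanking regions included, then any homologues")
    msa_rows: List[Tuple[str, str, str]] = [(flanked_label, "target_locus", flanked_gapped)]
    for label, gapped in rows[2:]:
        msa_rows.append((label, "homologue", gapped))
    msa = MultipleAlignment(rows=msa_rows)
    msa.validate()
    region = locate_input_region(msa, SequenceRecord(bare_label, "", bare))
    return msa, region
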