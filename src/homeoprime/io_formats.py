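"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open on the forward strand everywhere;
1-based inclusive coordinates appear only at I/O edges (BLAST-style tabular
hits on the way in). Oligo names use the half-open product coordinates
directly, so the printed size equals ``product_end - product_start``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from pyfaidx import Fasta

VALID_BASES = set("ACGTN")
GAP_CHARS = {"-", "."}


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on read."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TabularHit:
    """One line of 12-column BLAST-style tabular output.

    Coordinates are kept 1-based inclusive as printed; ``s_start > s_end``
    encodes a minus-strand hit.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bitscore: float

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def s_span(self) -> Tuple[int, int]:
        """Subject span as a 0-based half-open interval on the forward strand."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    @property
    def q_span(self) -> Tuple[int, int]:
        return self.q_start - 1, self.q_end


def read_fasta(path: str | os.PathLike) -> List[SequenceRecord]:
    """Strict FASTA reader.

    Rejects empty files, duplicate ids and residues outside {A,C,G,T,N}
    (case-insensitive), naming the offending line in the error message.
    Multi-line record bodies are concatenated; order is preserved.
    """
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: List[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(
                f"{path}: record '{header}' (line {header_line}) has no residues"
            )
        records.append(SequenceRecord(header, desc, residues))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                parts = line[1:].split(maxsplit=1)
                if not parts:
                    raise FastaParseError(f"{path}: empty header at line {line_no}")
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = line_no
                if header in seen:
                    raise FastaParseError(
                        f"{path}: duplicate id '{header}' at line {line_no}"
                    )
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: residues before any header at line {line_no}"
                    )
                up = line.upper()
                bad = set(up) - VALID_BASES
                if bad:
                    raise FastaParseError(
                        f"{path}: invalid residue(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(up)
    flush(-1)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


class GenomeIndex:
    """Random access into a FASTA assembly via a faidx-style index.

    The .fai file is persisted beside the FASTA and reused when newer than
    its source. Out-of-range slice requests clamp to the record bounds and
    set :attr:`last_clamped` instead of raising, because flank buffers
    routinely overrun chromosome ends.
    """

    def __init__(self, fasta_path: str | os.PathLike):
        self.fasta_path = Path(fasta_path)
        fai = Path(str(fasta_path) + ".fai")
        if fai.exists() and fai.stat().st_mtime < self.fasta_path.stat().st_mtime:
            fai.unlink()  # stale index: rebuild
        self._fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True,
                         rebuild=True)
        self.last_clamped = False

    @property
    def names(self) -> List[str]:
        return list(self._fa.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Return residues of [start, end) (0-based half-open), clamped."""
        if chrom not in self._fa:
            raise KeyError(f"sequence '{chrom}' not present in {self.fasta_path}")
        n = len(self._fa[chrom])
        a, b = max(0, start), min(n, end)
        self.last_clamped = (a != start) or (b != end)
        if a >= b:
            return ""
        return str(self._fa[chrom][a:b])

    def clamp(self, chrom: str, start: int, end: int) -> Tuple[int, int, bool]:
        n = self.length(chrom)
        a, b = max(0, start), min(n, end)
        return a, b, (a != start or b != end)


def build_index(fasta_path: str | os.PathLike) -> GenomeIndex:
    """Index a genome FASTA for random access without loading it whole."""
    return GenomeIndex(fasta_path)


def parse_blast_tabular(path: str | os.PathLike) -> List[TabularHit]:
    """Parse standard 12-column tabular local-alignment output.

    An empty file yields an empty list; a line with the wrong column count
    raises with its line number.
    """
    hits: List[TabularHit] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: expected 12 tab-separated columns at line "
                    f"{line_no}, found {len(cols)}"
                )
            hits.append(TabularHit(
                query_id=cols[0], subject_id=cols[1],
                pct_identity=float(cols[2]), aln_length=int(cols[3]),
                mismatches=int(cols[4]), gap_opens=int(cols[5]),
                q_start=int(cols[6]), q_end=int(cols[7]),
                s_start=int(cols[8]), s_end=int(cols[9]),
                e_value=float(cols[10]), bitscore=float(cols[11]),
            ))
    return hits


def write_blast_tabular(hits: Iterable[TabularHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start,
                h.s_end, f"{h.e_value:.2g}", f"{h.bitscore:.1f}")) + "\n")


PRIMER_CSV_COLUMNS = [
    "oligo_name", "sequence_5to3", "type", "direction", "product_start",
    "product_end", "product_size", "tm_celsius", "gc_percent", "penalty",
]


def oligo_name(prefix: str, product_start: int, product_end: int,
               direction: str, split_index: int | None = None) -> str:
    """Build the ``{prefix}.{start}-{end}.{F|R}`` oligo name.

    Coordinates are the half-open product interval, so the size printed
    elsewhere equals ``product_end - product_start``. Internal sequencing
    primers insert a ``split{k}`` component (k >= 2).
    """
    core = f"{prefix}.{product_start}-{product_end}"
    if split_index is not None:
        return f"{core}.split{split_index}.{direction}"
    return f"{core}.{direction}"


def product_size_from_name(name: str) -> int:
    """Recover the product size from an oligo name's coordinate component."""
    for part in name.split("."):
        if "-" in part:
            a, b = part.split("-")
            if a.isdigit() and b.isdigit():
                return int(b) - int(a)
    raise ValueError(f"no coordinate component in oligo name '{name}'")


def write_primer_csv(solution, path: str | os.PathLike, prefix: str = "primers") -> None:
    """Write the tiling solution as a flat primer CSV.

    One row per PCR primer (two per pair) plus one per sequencing primer.
    An empty solution writes the header only.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PRIMER_CSV_COLUMNS)
        for pair in solution.pairs:
            for cand, direction in ((pair.forward, "F"), (pair.reverse, "R")):
                w.writerow([
                    oligo_name(prefix, pair.product_start, pair.product_end, direction),
                    cand.sequence_5to3, "PCR", direction,
                    pair.product_start, pair.product_end, pair.product_size,
                    f"{cand.tm:.2f}", f"{cand.gc:.1f}", f"{cand.penalty:.3f}",
                ])
        for cand in solution.sequencing_primers:
            pair = solution.pair_for_sequencing(cand)
            w.writerow([
                oligo_name(prefix, pair.product_start, pair.product_end, "F",
                           split_index=cand.split_index),
                cand.sequence_5to3, "Sanger", "F",
                pair.product_start, pair.product_end, pair.product_size,
                f"{cand.tm:.2f}", f"{cand.gc:.1f}", f"{cand.penalty:.3f}",
            ])


def read_alignment(path: str | os.PathLike) -> List[Tuple[str, str]]:
    """Read a gapped FASTA alignment as (label, gapped residues) rows.

    '.' gaps are normalized to '-'; rows must share one gapped length.
    """
    rows: List[Tuple[str, str]] = []
    label: str | None = None
    chunks: List[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    rows.append((label, "".join(chunks)))
                label = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper().replace(".", "-"))
    if label is not None:
        rows.append((label, "".join(chunks)))
    if not rows:
        raise FastaParseError(f"{path}: no alignment rows found")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return rows


def write_alignment(rows: Sequence[Tuple[str, str]], path: str | os.PathLike,
                    dialect: str = "fasta") -> None:
    """Write an alignment in fasta or clustal dialect (gaps as '-')."""
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
    if dialect == "fasta":
        write_fasta([_gapped_record(l, s) for l, s in rows], path)
    elif dialect == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import AlignIO
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=l, description="") for l, s in rows])
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment dialect '{dialect}'")


def _gapped_record(label: str, gapped: str) -> SequenceRecord:
    rec = SequenceRecord.__new__(SequenceRecord)
    rec.id = label
    rec.description = ""
    rec.residues = gapped
    return rec


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")
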