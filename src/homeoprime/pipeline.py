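"""End-to-end pipeline: locate, align, mine SNPs, design, tile, validate.

This is the programmatic entry point the CLI wraps. A run takes the input
gene, a set of genome assemblies (one primary), and design parameters, and
produces a :class:`RunResult` holding every intermediate product plus the
final tiling solution and its in-silico specificity report.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import alignment_snp, homology, insilico_validation, tiling
from .alignment_snp import MultipleAlignment, SnpColumn, load_user_alignment
from .homology import ExtractedSequence, HomologySelection
from .insilico_validation import SpecificityReport
from .io_formats import (GenomeIndex, SequenceRecord, build_index,
                         parse_blast_tabular, read_fasta, write_alignment,
                         write_primer_csv)
from .parameters import DesignParameters
from .primer_thermo import generate_candidates
from .tiling import TilingSolution


@dataclass
class GenomeConfig:
    label: str
    fasta: Path
    primary: bool = False


def load_genome_config(path: str | Path) -> List[GenomeConfig]:
    """Read the genome list: label, fasta path, primary flag.

    Paths are resolved relative to the config file. Exactly one genome must
    be marked primary (a single listed genome is primary implicitly).
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "genomes" not in data:
        raise ValueError(f"{path}: expected a top-level 'genomes' list")
    out: List[GenomeConfig] = []
    for entry in data["genomes"]:
        fasta = Path(entry["fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        out.append(GenomeConfig(label=str(entry["label"]), fasta=fasta,
                                primary=bool(entry.get("primary", False))))
    if not out:
        raise ValueError(f"{path}: no genomes listed")
    primaries = [g for g in out if g.primary]
    if len(out) == 1 and not primaries:
        out[0].primary = True
        primaries = out
    if len(primaries) != 1:
        raise ValueError(f"{path}: exactly one genome must be marked primary")
    return out


@dataclass
class RunResult:
    selection: Optional[HomologySelection]
    msa: MultipleAlignment
    input_region_cols: Tuple[int, int]
    input_region_target: Tuple[int, int]   # on the ungapped flanked target
    snps: List[SnpColumn]
    solution: Optional[TilingSolution]
    report: Optional[SpecificityReport]
    warnings: List[str] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        if self.solution is None:
            return 0  # guided stop
        return 0 if self.solution.covered else 2


def _target_from_msa(msa: MultipleAlignment) -> ExtractedSequence:
    label, _, gapped = msa.rows[msa.target_row_index]
    return ExtractedSequence(label=label, genome_label="", chrom=label,
                             start=0, end=len(gapped.replace("-", "")),
                             strand="+", residues=gapped.replace("-", ""),
                             role="target_locus")


def run_pipeline(input_record: SequenceRecord,
                 genomes: Sequence[GenomeConfig],
                 params: DesignParameters = DesignParameters(),
                 backend: str = "internal",
                 hits_path: Optional[str] = None,
                 guided: bool = False,
                 log=None) -> RunResult:
    """Full run from a bare input gene against configured genomes.

    ``hits_path`` supplies precomputed 12-column tabular hits for the
    primary genome instead of the internal search. ``guided=True`` stops
    after the alignment so the user can curate it and resume with
    :func:`run_from_alignment`.
    """
    def say(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    primary = next(g for g in genomes if g.primary)
    indices: Dict[str, GenomeIndex] = {}
    genome_hits: Dict[str, list] = {}
    for g in genomes:
        say(f"[homology] indexing {g.label}: {g.fasta}")
        indices[g.label] = build_index(g.fasta)
        if g.primary and hits_path is not None:
            say(f"[homology] loading precomputed hits from {hits_path}")
            genome_hits[g.label] = parse_blast_tabular(hits_path)
        else:
            genome_hits[g.label] = homology.internal_search(input_record,
                                                            indices[g.label])
        say(f"[homology] {g.label}: {len(genome_hits[g.label])} hits")

    selection = homology.select_homology(input_record, genome_hits, indices,
                                         primary.label, params)
    say(f"[homology] target locus {selection.target.chrom}:"
        f"{selection.target.start}-{selection.target.end}"
        f"({selection.target.strand}); {len(selection.homologues)} homologues,"
        f" {len(selection.extra_variety)} extra-variety copies,"
        f" {len(selection.discarded_groups)} groups discarded")

    ordered = [selection.target] + selection.homologues + selection.extra_variety
    msa = alignment_snp.align(ordered, backend=backend)
    say(f"[alignment] {len(msa.rows)} rows x {msa.n_columns} columns")

    region_cols = alignment_snp.locate_input_region(msa, input_record)
    t0 = selection.target.residues.find(input_record.residues)
    region_target = (t0, t0 + len(input_record.residues))

    result = RunResult(selection=selection, msa=msa,
                       input_region_cols=region_cols,
                       input_region_target=region_target,
                       snps=[], solution=None, report=None,
                       warnings=list(selection.warnings))
    if guided:
        say("[guided] stopping after alignment; curate it and resume with -a")
        return result

    return _design_from(result, input_record, selection.target, params, say)


def run_from_alignment(alignment_path: str | Path,
                       params: DesignParameters = DesignParameters(),
                       log=None) -> RunResult:
    """Resume from a user-supplied (possibly curated) multiple alignment."""
    def say(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    msa, region_cols = load_user_alignment(alignment_path)
    target = _target_from_msa(msa)
    bare_gapped = None  # row order contract already validated in the loader
    ungapped_target = target.residues
    # reconstruct the bare input from the located region
    col_to_pos = []
    pos = 0
    for ch in msa.target_gapped:
        col_to_pos.append(pos)
        if ch != "-":
            pos += 1
    a_col, b_col = region_cols
    t0 = col_to_pos[a_col]
    t1 = col_to_pos[b_col - 1] + 1
    input_record = SequenceRecord("input", "", ungapped_target[t0:t1])
    result = RunResult(selection=None, msa=msa, input_region_cols=region_cols,
                       input_region_target=(t0, t1), snps=[], solution=None,
                       report=None)
    return _design_from(result, input_record, target, params, say)


def _design_from(result: RunResult, input_record: SequenceRecord,
                 target: ExtractedSequence, params: DesignParameters,
                 say) -> RunResult:
    result.snps = alignment_snp.scan_snps(result.msa, warn=result.warnings)
    usable = [s for s in result.snps if s.usable]
    n_varietal = sum(1 for s in result.snps
                     if s.discriminating and s.varietal_conflict)
    say(f"[snp] {len(usable)} usable discriminating columns "
        f"({n_varietal} discriminating columns vetoed as varietal)")

    candidates = generate_candidates(usable, target, params)
    say(f"[primer] {len(candidates)} scored SNP-anchored candidates")
    pairs = tiling.enumerate_pairs(candidates, params)
    say(f"[tiling] {len(pairs)} admissible primer pairs")
    solution = tiling.build_solution(pairs, result.input_region_target,
                                     target, params, all_candidates=candidates)
    result.solution = solution
    result.warnings.extend(solution.warnings)
    say(f"[tiling] covered={solution.covered} with {len(solution.pairs)} pairs,"
        f" {len(solution.sequencing_primers)} sequencing primers,"
        f" total penalty {solution.total_penalty:.2f}")

    if result.selection is not None:
        result.report = insilico_validation.specificity_report(
            solution, result.selection, params.max_internal_mm,
            params.terminal_exact, params.max_product)
        status = "all PASS" if result.report.all_pass else "FAILURES PRESENT"
        say(f"[validate] in-silico PCR: {status}")
    return result


def write_outputs(result: RunResult, out_dir: str | Path,
                  prefix: str = "primers") -> Dict[str, Path]:
    """Write primer CSV, alignments, candidate table and the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    rows = [(label, gapped) for label, _role, gapped in result.msa.rows]
    paths["alignment_fasta"] = out / "alignment.fa"
    write_alignment(rows, paths["alignment_fasta"], "fasta")
    paths["alignment_clustal"] = out / "alignment.aln"
    write_alignment(rows, paths["alignment_clustal"], "clustal")

    if result.solution is not None:
        paths["primer_csv"] = out / "primers.csv"
        write_primer_csv(result.solution, paths["primer_csv"], prefix=prefix)
        paths["candidates"] = out / "candidates.tsv"
        with open(paths["candidates"], "w") as fh:
            fh.write("anchor_target_pos\tdirection\tsequence_5to3\ttm\tgc"
                     "\tpenalty\tgap_discriminated\n")
            for c in result.solution.all_candidates:
                fh.write(f"{c.anchor.target_pos if c.anchor else -1}\t"
                         f"{c.direction}\t{c.sequence_5to3}\t{c.tm:.2f}\t"
                         f"{c.gc:.1f}\t{c.penalty:.3f}\t"
                         f"{int(bool(c.anchor and c.anchor.gap_discriminated))}\n")

    report_lines: List[str] = ["run report", "=" * 10]
    if result.selection is not None:
        sel = result.selection
        report_lines.append(
            f"target locus: {sel.target.chrom}:{sel.target.start}-"
            f"{sel.target.end}({sel.target.strand})")
        for h in sel.homologues:
            report_lines.append(f"homologue: {h.label}")
        for e in sel.extra_variety:
            report_lines.append(f"extra variety: {e.label}")
        for g, reason in sel.discarded_groups:
            report_lines.append(
                f"discarded group {g.subject_id}:{g.s_min}-{g.s_max} — {reason}")
    usable = sum(1 for s in result.snps if s.usable)
    report_lines.append(f"usable SNP columns: {usable}")
    if result.solution is not None:
        report_lines.append(f"covered: {result.solution.covered}")
        for a, b in result.solution.coverage_gaps:
            report_lines.append(f"coverage gap: {a}-{b}")
    if result.report is not None:
        report_lines.append(result.report.to_text())
    report_lines.extend(f"warning: {w}" for w in result.warnings)
    paths["report"] = out / "run_report.txt"
    paths["report"].write_text("\n".join(report_lines) + "\n")
    return paths
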