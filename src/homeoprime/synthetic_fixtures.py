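"""Synthetic polyploid genomes with known ground truth.

The generator emulates the situation the pipeline is built for: a gene on
one subgenome of a polyploid, with near-identical homeologues on the other
subgenomes, all embedded in larger scaffolds, plus optionally a second
variety's genome carrying a handful of varietal SNPs at the same locus.

Divergence model. Observed differences between a target gene and a
homeologue come from two lineages: mutations on the homeologue's own branch
(private to it) and mutations on the target's branch, which show up as the
*same* difference against every homeologue (all of them retain the
ancestral base). The generator therefore splits each homeologue's total
divergence ``1 - identity`` into a shared component at rate
``lineage_fraction * min(1 - identity)`` — applied at identical positions,
with one common ancestral base, in every homeologue — and a private
remainder. Only the shared component creates columns where the target
differs from all homeologues at once, i.e. usable primer anchors; without
it a polyploid fixture would have essentially no discriminating SNPs at
all. Homeologous similarity extends through a configurable flanking context
(real homeologues sit in homeologous chromosomal neighbourhoods), beyond
which scaffold DNA is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import SequenceRecord, write_fasta

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    seed: int = 0
    gene_length: int = 2400
    homeologue_identities: Tuple[float, ...] = (0.93, 0.93, 0.80)
    # (offset_into_gene, covered_length) for the LAST homeologue; None = full
    partial_homologue: Optional[Tuple[int, int]] = None
    partial_downstream: int = 10   # homology extends this far past the gene
    chrom_length: int = 20000
    gc_target: float = 0.49
    n_varieties: int = 1
    varietal_snp_count: int = 0
    # homeologous context on each side of the gene (0 = gene only)
    homeologous_flank: int = 1000
    # fraction of the smallest divergence attributed to the target lineage
    lineage_fraction: float = 0.5
    indel_rate: float = 0.0
    indel_max_len: int = 3

    def __post_init__(self) -> None:
        for ident in self.homeologue_identities:
            if not 0.5 < ident <= 1.0:
                raise ValueError("homeologue identities must lie in (0.5, 1.0]")
        unit = self.gene_length + 2 * self.homeologous_flank
        if unit > self.chrom_length:
            raise ValueError("gene plus homeologous flanks exceeds chrom_length")


@dataclass
class TruthRow:
    locus: str           # homeologue label or variety label
    unit_pos: int        # position within the homeologous unit
    gene_pos: int        # position within the gene, -1 if in context
    target_base: str
    derived_base: str
    kind: str            # shared | private | varietal | indel


@dataclass
class Locus:
    genome: str
    chrom: str
    start: int
    end: int


@dataclass
class Fixture:
    spec: FixtureSpec
    input_record: SequenceRecord                 # the bare gene
    genomes: Dict[str, List[SequenceRecord]]     # label -> scaffolds
    primary: str
    loci: Dict[str, Locus]                       # unit placements
    unit: str                                    # target homeologous unit
    homeologue_units: Dict[str, str]             # label -> (partial) unit copy
    truth: List[TruthRow] = field(default_factory=list)
    varietal_unit_positions: List[int] = field(default_factory=list)

    @property
    def gene_unit_offset(self) -> int:
        return self.spec.homeologous_flank

    def shared_unit_positions(self) -> List[int]:
        return sorted({r.unit_pos for r in self.truth if r.kind == "shared"})

    def truth_discriminating_positions(self) -> List[int]:
        """Unit positions where the target differs from every homeologue
        covering that position (and at least one covers it) — computed from
        the final sequences, so coincidental all-differ sites are included.
        Only valid for substitution-only fixtures."""
        if self.spec.indel_rate > 0:
            raise ValueError("ground-truth positions undefined with indels")
        out = []
        covers: List[Tuple[int, int, str]] = []
        for label, seq in self.homeologue_units.items():
            off = self._partial_offset(label)
            covers.append((off, off + len(seq), seq))
        for pos, base in enumerate(self.unit):
            seen = 0
            disc = True
            for a, b, seq in covers:
                if a <= pos < b:
                    seen += 1
                    if seq[pos - a] == base:
                        disc = False
                        break
            if seen and disc:
                out.append(pos)
        return out

    def _partial_offset(self, label: str) -> int:
        return self._partial_offsets.get(label, 0)

    _partial_offsets: Dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return BASES[rng.choice(4, size=length, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate_positions(rng: np.random.Generator, seq: np.ndarray,
                      positions: np.ndarray) -> Dict[int, Tuple[str, str]]:
    """Substitute each position with a uniformly different base; returns
    {pos: (old, new)}."""
    changes: Dict[int, Tuple[str, str]] = {}
    for pos in positions:
        old = seq[pos]
        choices = BASES[BASES != old]
        new = choices[rng.integers(0, 3)]
        seq[pos] = new
        changes[int(pos)] = (chr(old), chr(new))
    return changes


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build genomes, the bare input gene and the ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    flank = spec.homeologous_flank
    unit_len = spec.gene_length + 2 * flank
    unit = _random_seq(rng, unit_len, spec.gc_target)
    gene = unit[flank:flank + spec.gene_length]

    min_div = min(1.0 - i for i in spec.homeologue_identities) \
        if spec.homeologue_identities else 0.0
    shared_rate = spec.lineage_fraction * min_div
    shared_mask = rng.random(unit_len) < shared_rate
    shared_pos = np.nonzero(shared_mask)[0]
    # one common ancestral base per shared site, used by every homeologue
    shared_base: Dict[int, np.uint8] = {}
    for pos in shared_pos:
        choices = BASES[BASES != unit[pos]]
        shared_base[int(pos)] = choices[rng.integers(0, 3)]

    truth: List[TruthRow] = []
    hom_units: Dict[str, str] = {}
    partial_offsets: Dict[str, int] = {}
    subgenomes = ["B", "D", "X", "Y", "Z"]
    n_hom = len(spec.homeologue_identities)
    for k, ident in enumerate(spec.homeologue_identities):
        label = f"chr1{subgenomes[k]}"
        hom = unit.copy()
        for pos in shared_pos:
            hom[pos] = shared_base[int(pos)]
            truth.append(TruthRow(label, int(pos), int(pos) - flank
                                  if flank <= pos < flank + spec.gene_length else -1,
                                  chr(unit[pos]), chr(hom[pos]), "shared"))
        private_rate = max(0.0, (1.0 - ident) - shared_rate)
        pmask = (rng.random(unit_len) < private_rate) & ~shared_mask
        changes = _mutate_positions(rng, hom, np.nonzero(pmask)[0])
        for pos, (old, new) in changes.items():
            truth.append(TruthRow(label, pos, pos - flank
                                  if flank <= pos < flank + spec.gene_length else -1,
                                  old, new, "private"))
        a, b = 0, unit_len
        if spec.partial_homologue is not None and k == n_hom - 1:
            off, length = spec.partial_homologue
            a = flank + off
            b = min(unit_len, flank + off + length + spec.partial_downstream)
        if spec.indel_rate > 0:
            hom_seq = _apply_indels(rng, hom[a:b], spec, label, truth, a, flank,
                                    spec.gene_length)
        else:
            hom_seq = _to_str(hom[a:b])
        hom_units[label] = hom_seq
        partial_offsets[label] = a

    # scaffolds: primary genome holds target + homeologues, each on its own
    # chromosome at a random position inside random DNA
    genomes: Dict[str, List[SequenceRecord]] = {}
    loci: Dict[str, Locus] = {}

    def embed(label: str, chrom: str, genome: str, payload: str) -> SequenceRecord:
        pad = spec.chrom_length - len(payload)
        at = int(rng.integers(0, pad + 1)) if pad > 0 else 0
        left = _to_str(_random_seq(rng, at, spec.gc_target))
        right = _to_str(_random_seq(rng, pad - at, spec.gc_target))
        loci[label] = Locus(genome, chrom, at, at + len(payload))
        return SequenceRecord(chrom, "", left + payload + right)

    primary = "reference"
    scaffolds = [embed("target", "chr1A", primary, _to_str(unit))]
    for label, seq in hom_units.items():
        scaffolds.append(embed(label, label, primary, seq))
    genomes[primary] = scaffolds

    varietal_positions: List[int] = []
    for v in range(2, spec.n_varieties + 1):
        vlabel = f"variety{v}"
        vunit = unit.copy()
        if spec.varietal_snp_count:
            vpos = rng.choice(np.arange(flank, flank + spec.gene_length),
                              size=spec.varietal_snp_count, replace=False)
            changes = _mutate_positions(rng, vunit, np.sort(vpos))
            for pos, (old, new) in changes.items():
                truth.append(TruthRow(vlabel, pos, pos - flank, old, new,
                                      "varietal"))
                varietal_positions.append(pos)
        genomes[vlabel] = [embed(f"{vlabel}:target", "chr1A", vlabel,
                                 _to_str(vunit))]

    fx = Fixture(
        spec=spec,
        input_record=SequenceRecord("input_gene", "synthetic fixture gene",
                                    _to_str(gene)),
        genomes=genomes, primary=primary, loci=loci,
        unit=_to_str(unit), homeologue_units=hom_units, truth=truth,
        varietal_unit_positions=sorted(varietal_positions))
    fx._partial_offsets = partial_offsets
    return fx


def _apply_indels(rng: np.random.Generator, hom: np.ndarray, spec: FixtureSpec,
                  label: str, truth: List[TruthRow], unit_offset: int,
                  flank: int, gene_length: int) -> str:
    """Sprinkle short insertions/deletions into a homeologue copy."""
    out: List[str] = []
    i = 0
    n = len(hom)
    while i < n:
        if rng.random() < spec.indel_rate:
            length = int(rng.integers(1, spec.indel_max_len + 1))
            upos = unit_offset + i
            gpos = upos - flank if flank <= upos < flank + gene_length else -1
            if rng.random() < 0.5:  # deletion from the homeologue
                truth.append(TruthRow(label, upos, gpos,
                                      _to_str(hom[i:i + length]), "-", "indel"))
                i += length
            else:                   # insertion into the homeologue
                ins = _to_str(_random_seq(rng, length, spec.gc_target))
                truth.append(TruthRow(label, upos, gpos, "-", ins, "indel"))
                out.append(ins)
        out.append(chr(hom[i]) if i < n else "")
        i += 1
    return "".join(out)


def write_fixture(fx: Fixture, out_dir: str | Path) -> Dict[str, Path]:
    """Write genome FASTAs, the bare input FASTA, a genome config file and
    the truth table; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for label, scaffolds in fx.genomes.items():
        p = out / f"{label}.fa"
        write_fasta(scaffolds, p)
        paths[label] = p
    input_path = out / "input_gene.fa"
    write_fasta([fx.input_record], input_path)
    paths["input"] = input_path

    config_path = out / "genomes.yaml"
    lines = ["genomes:"]
    for label in fx.genomes:
        lines.append(f"  - label: {label}")
        lines.append(f"    fasta: {paths[label].name}")
        if label == fx.primary:
            lines.append("    primary: true")
    config_path.write_text("\n".join(lines) + "\n")
    paths["config"] = config_path

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("locus\tunit_pos\tgene_pos\ttarget_base\tderived_base\tkind\n")
        for r in sorted(fx.truth, key=lambda r: (r.locus, r.unit_pos)):
            fh.write(f"{r.locus}\t{r.unit_pos}\t{r.gene_pos}\t{r.target_base}"
                     f"\t{r.derived_base}\t{r.kind}\n")
    paths["truth"] = truth_path
    return paths
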