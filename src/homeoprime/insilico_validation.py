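"""Simulated PCR against all extracted sequences, with the 3'-mismatch rule.

The specificity of allele-specific primers rests on Taq polymerase's strong
intolerance of a mismatch at the primer's 3'-terminal base (up to a
100-fold drop in efficiency). The model here is deliberately binary: a
primer binds a site when it matches with at most ``max_internal_mm``
internal mismatches, and a bound site supports amplification only when the
``terminal_exact`` 3'-most bases match exactly. Two convergent bound sites
within ``max_product`` bases yield an amplicon call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .homology import HomologySelection
from .io_formats import SequenceRecord, reverse_complement
from .primer_thermo import PrimerPair
from .tiling import TilingSolution


@dataclass
class AmpliconCall:
    template_label: str
    forward_site: int        # 0-based start of the forward primer's site
    reverse_site: int        # 0-based start of the reverse primer's site (fwd strand)
    product_size: int
    forward_3prime_match: bool
    reverse_3prime_match: bool
    internal_mismatches: int
    amplifies: bool


@dataclass
class PairReport:
    pair: PrimerPair
    amplifying_templates: List[str]
    passes: bool             # exactly the target amplifies


@dataclass
class SpecificityReport:
    per_pair: List[PairReport]
    warnings: List[str]

    @property
    def all_pass(self) -> bool:
        return all(p.passes for p in self.per_pair)

    def to_text(self) -> str:
        lines = ["in-silico PCR specificity report", "=" * 34]
        for pr in self.per_pair:
            status = "PASS" if pr.passes else "FAIL"
            lines.append(
                f"{status}  product {pr.pair.product_start}-{pr.pair.product_end}"
                f" ({pr.pair.product_size} bp): amplifies "
                f"{', '.join(pr.amplifying_templates) or 'nothing'}")
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def _binding_sites(primer: str, template: str, max_mm: int, terminal_exact: int
                   ) -> List[Tuple[int, int, bool]]:
    """(start, mismatches, three_prime_ok) for every site on this strand.

    The primer is compared 5'->3' against the template forward strand; the
    3' terminus is the rightmost base of the window.
    """
    m, n = len(primer), len(template)
    if n < m:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    hits = np.nonzero(mism <= max_mm)[0]
    out = []
    tail = windows[:, m - terminal_exact:]
    ptail = p[m - terminal_exact:]
    for i in hits:
        ok = bool((tail[i] == ptail).all())
        out.append((int(i), int(mism[i]), ok))
    return out


def simulate_pcr(pair: PrimerPair, templates: Sequence[SequenceRecord],
                 max_internal_mm: int = 3, terminal_exact: int = 1,
                 max_product: int = 10000) -> List[AmpliconCall]:
    """Exhaustively scan each template on both strands for amplicons.

    Forward-primer sites on the plus strand are combined with reverse-primer
    sites on the minus strand (and vice versa for inverted templates);
    amplification requires convergent orientation, exact 3' matches on both
    sides, and a product within ``max_product`` bases.
    """
    if not templates:
        raise ValueError("no templates to simulate against")
    fwd = pair.forward.sequence_5to3
    rev = pair.reverse.sequence_5to3
    calls: List[AmpliconCall] = []
    for rec in templates:
        template = rec.residues
        n = len(template)
        for f_primer, r_primer in ((fwd, rev), (rev, fwd)):
            f_sites = _binding_sites(f_primer, template, max_internal_mm,
                                     terminal_exact)
            # reverse primer binds the minus strand: its site on the forward
            # strand is the reverse complement of the primer
            r_rc = reverse_complement(r_primer)
            rcsites = _binding_sites(r_primer, reverse_complement(template),
                                     max_internal_mm, terminal_exact)
            r_sites = [(n - s - len(r_primer), mm, ok) for s, mm, ok in rcsites]
            for fs, fmm, fok in f_sites:
                for rs, rmm, rok in r_sites:
                    prod_end = rs + len(r_primer)
                    size = prod_end - fs
                    if size < len(f_primer) + len(r_primer) or size > max_product:
                        continue
                    calls.append(AmpliconCall(
                        template_label=rec.id,
                        forward_site=fs, reverse_site=rs,
                        product_size=size,
                        forward_3prime_match=fok, reverse_3prime_match=rok,
                        internal_mismatches=fmm + rmm,
                        amplifies=fok and rok))
            if f_primer is r_primer:
                break
    return calls


def specificity_report(solution: TilingSolution, selection: HomologySelection,
                       max_internal_mm: int = 3, terminal_exact: int = 1,
                       max_product: int = 10000) -> SpecificityReport:
    """Per-pair PASS/FAIL against the target and every homologue.

    PASS means the target template amplifies and no homologue does. With no
    homologues every pair passes trivially, with a warning.
    """
    templates = [SequenceRecord("target", "", selection.target.residues)]
    templates += [SequenceRecord(h.label, "", h.residues)
                  for h in selection.homologues]
    warnings: List[str] = []
    if not selection.homologues:
        warnings.append("no homologues available: specificity is untestable "
                        "and passes trivially")
    reports: List[PairReport] = []
    for pair in solution.pairs:
        calls = simulate_pcr(pair, templates, max_internal_mm, terminal_exact,
                             max_product)
        amplifying = sorted({c.template_label for c in calls if c.amplifies})
        passes = amplifying == ["target"]
        if not selection.homologues:
            passes = "target" in amplifying
        reports.append(PairReport(pair, amplifying, passes))
    return SpecificityReport(per_pair=reports, warnings=warnings)
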