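"""Design parameters shared across the pipeline.

Every knob a user can reasonably want to turn lives here with its default.
The locus-selection defaults (1000-base hit-group gap, bitscore floor of
200, three homologue groups, 1000-base flank buffers) are the pipeline's
published operating point; the thermodynamic and product-size defaults
follow long-standing primer-design conventions and are all overridable
from the config file or CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class DesignParameters:
    # primer geometry
    len_min: int = 18
    len_max: int = 27
    len_opt: int = 20
    # melting temperature targets, degrees Celsius
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    # GC content, percent
    gc_min: float = 30.0
    gc_max: float = 70.0
    gc_opt: float = 50.0
    # PCR product size bounds, bases
    product_min: int = 500
    product_max: int = 2000
    # genomic flank buffers around the located gene, bases
    start_buffer: int = 1000
    end_buffer: int = 1000
    # locus selection
    n_homologue_groups: int = 3
    bitscore_floor: float = 200.0
    max_group_gap: int = 1000
    # tiling
    min_overlap: int = 50
    # Sanger sequencing: usable read length and required read-join overlap
    sanger_read: int = 700
    sanger_overlap: int = 100
    # thermodynamic conditions
    monovalent_mM: float = 50.0
    primer_nM: float = 500.0
    # penalty weights
    w_len: float = 1.0
    w_gc: float = 0.5
    w_self: float = 0.1
    w_end: float = 0.2
    w_hairpin: float = 0.1
    w_gap: float = 2.0
    w_tmdiff: float = 1.0
    w_cross: float = 0.1
    # in-silico PCR model
    max_internal_mm: int = 3
    terminal_exact: int = 1
    max_product: int = 10000

    def __post_init__(self) -> None:
        for lo, opt, hi, what in (
            (self.len_min, self.len_opt, self.len_max, "primer length"),
            (self.tm_min, self.tm_opt, self.tm_max, "melting temperature"),
            (self.gc_min, self.gc_opt, self.gc_max, "GC content"),
        ):
            if not lo <= opt <= hi:
                raise ValueError(f"{what} bounds must satisfy min <= opt <= max")
        if self.product_min <= self.len_min + self.len_max:
            raise ValueError("product_min must exceed len_min + len_max")
        if not 0 < self.sanger_overlap < self.sanger_read:
            raise ValueError("sanger_overlap must lie in (0, sanger_read)")

    def replace(self, **overrides) -> "DesignParameters":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return DesignParameters(**values)
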