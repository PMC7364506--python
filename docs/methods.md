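# Methods

This note records the models, parameter choices and numerical decisions
behind `homeoprime`, and what the synthetic fixtures do and do not show.

## Locus finding and homologue selection

Local similarity searches report fragmented high-scoring pairs, so hits
sharing query, subject and strand are chained into groups whenever the gap
between consecutive subject intervals (end of one to start of the next,
not midpoints) is at most `max_group_gap` = 1000 bases. Chaining is per
(subject, strand): mixing strands in one group would make extraction
ill-defined.

Groups are ranked by **total** bitscore, ties by query coverage, then by
(subject, position) for determinism. Total — not mean — operationalizes
"most closely related": the genomic copy of the input should dominate on
both identity and aligned length, whereas a short perfect repeat can have
a high mean. The mean is used only for the homologue floor: after the top
group is taken as the target locus, up to `n_homologue_groups` = 3 further
groups qualify as homologues while their within-group mean bitscore
exceeds `bitscore_floor` = 200. From each additional (non-primary) genome
only the single best group is extracted, with no floor: it is the same
locus in another variety and exists to expose varietal SNPs, not to be a
design off-target.

Extraction adds `start_buffer`/`end_buffer` = 1000 bases of flank on each
side (so primers may sit outside the gene proper), clamped to chromosome
ends with a recorded flag rather than an error — buffers routinely overrun
scaffold boundaries. Minus-strand loci are reverse-complemented and the
buffers swapped so "start" always means the query-5' side. Internal
coordinates are 0-based half-open everywhere; 1-based inclusive appears
only at I/O edges (tabular hits in).

The built-in search is exact 11-mer seeding, ungapped x-drop extension
(match +2, mismatch −3, x-drop 20) and a greedy co-linear merge of nearby
diagonals (gap open 5, extend 2). Bitscores use fixed Karlin–Altschul
style constants (λ = 0.625, K = 0.41). Only the *ranking* behaviour of
these scores matters; fidelity to any external tool's scores is a
non-goal, and externally produced 12-column tabular hits can be imported
unchanged.

## Alignment

The internal aligner is a progressive center-star: each homologue is
aligned to the target (the center) by global affine-gap dynamic
programming — match +5, mismatch −4, gap open 10, extend 0.5, a gap of
length L costing `open + (L−1)·extend` — and the pairwise alignments are
merged by taking, before each target position, the maximum insertion
length over all pairs. The DP uses the full three-state Gotoh transition
set, including opening one gap type directly after the other; with cheap
extensions such configurations are genuinely optimal (verified against an
exhaustive oracle), so the commonly used restriction to open-from-match
only would miss optima. End gaps are charged like any other gap: after
flanked extraction the sequences share homologous ends, and free end gaps
would reward sliding a partial homologue around.

`muscle` and `dialign` can be selected as external backends and are
invoked only when the binary is on PATH; the internal backend is the
default and the tested path. Column-level SNP recovery on fixtures — not
fidelity to any particular aligner's output — is the test surface.

## SNP classification

For every column where the target row holds a plain base:

* a homologue row **abstains** at columns outside its aligned extent
  (leading/trailing gap run): a partial homologue neither licenses nor
  vetoes anchors where it has no sequence. Its absence is no evidence of
  discrimination — but with other homologues present the column can still
  qualify against those, which is exactly what makes designs possible
  upstream of a partial homologue's start;
* a column with no evidenced homologue at all is never discriminating;
* `N` in any evidenced homologue vetoes the column (unknown base, unknown
  specificity);
* an internal gap counts as a difference but flags the column
  `gap_discriminated`; indel 3' anchors behave unpredictably, so such
  columns carry a +2.0 penalty surcharge and are chosen only when no
  substitution anchor serves;
* any extra-variety row differing from the target marks the column
  `varietal_conflict` and removes it from use: the difference may be
  varietal rather than homeologous, and a primer anchored there could fail
  in the very variety being cloned.

## Primer scoring

Melting temperature is nearest-neighbor thermodynamics over the unified
dinucleotide parameter set with duplex-initiation terms,
`Tm = ΔH·1000 / (ΔS_salt + R·ln(C/4)) − 273.15`, with the entropy salt
correction `ΔS_salt = ΔS + 0.368·(N−1)·ln[Na+]`. Defaults: 50 mM
monovalent salt, 500 nM primer. Complementarity scores are exact maxima
over all ungapped antiparallel offsets (G:C pairs weigh 2, A:T weigh 1):
`self_any` over all runs, `self_end` over runs pairing the 3' terminus,
and `hairpin` as the longest stem over all fold points with a loop of at
least 3.

The single-primer penalty is
`|Tm − 60| + 1.0·|len − 20| + 0.5·GC-excess + 0.1·self_any +
0.2·self_end + 0.1·hairpin (+ 2.0 if gap-anchored)`; a pair adds
`1.0·|Tm_f − Tm_r| + 0.1·cross_dimer`. Geometry defaults (length 18–27
optimum 20, Tm 57–63 optimum 60 °C, GC 30–70%, product 500–2000 bases)
follow long-standing primer-design conventions; all are config-exposed.
The penalty is zero exactly at the documented optimum and the weights are
deliberately simple — ranking candidates is what matters, not absolute
units.

## Tiling

Every (forward anchor, reverse anchor) combination within the product
bounds yields one candidate product; per anchor pair only the best length
combination is kept (evaluated over the three lowest-penalty candidates
per anchor side), which bounds the otherwise quadratic-times-hundredfold
sweep while the complete per-SNP candidate table is still emitted. Cover
selection is an exact shortest path on the DAG whose nodes are products
and whose edges are admissible successions (successor starts at least
`min_overlap` = 50 bases before the predecessor ends and extends it);
sources start at or before the input region, sinks end at or after it.
Products may extend into the flanks — only the input region itself must be
covered. When no full cover exists the greedy rightmost-reach partial
cover is returned with its gaps listed and exit status 2. Ties break on
(product start, product size, forward sequence), so identical inputs give
byte-identical output.

The 50-base minimum product overlap guarantees that Sanger reads bridge
product junctions; it is a config default, chosen once.

## Sanger split primers

A product no longer than one usable read (`sanger_read` = 700 bases)
needs no internal primer. Longer products get forward-only internal
primers (the amplicon is already allele-pure, so they need no SNP anchor)
with read start points advancing by `sanger_read − sanger_overlap` =
600 bases, so consecutive reads overlap by ≥ 100 bases and assemble
unambiguously; the count is therefore `ceil(size/600) − 1`. This
read-join overlap is what the published split counts of the wheat worked
example imply: plain `ceil(size/700) − 1` spacing would give one internal
primer for its 1331- and 1234-base products where two are printed, while
a 100-base join overlap reproduces all four printed counts (805 → 1,
1234 → 2, 1331 → 2, 1412 → 2). Each primer is the lowest-penalty
unanchored candidate within ±50 bases of its ideal start (widened once,
then a warning is recorded); the ±50 window keeps the worst-case read gap
at exactly one read length. Primers are numbered `split2, split3, …` —
the product's own forward primer is read 1.

Oligo names embed the half-open product interval
(`prefix.start-end.F/R`), so the printed size is `end − start`.

## In-silico PCR

The validation model is deliberately binary rather than thermokinetic: a
primer binds wherever it matches with at most `max_internal_mm` = 3
mismatches (exhaustive scan of both strands), and a bound site supports
extension only when the terminal `terminal_exact` = 1 3'-base matches
exactly — the threshold abstraction of the up-to-100-fold suppression a
3'-terminal mismatch causes in Taq extension. Two convergent productive
sites within `max_product` = 10 000 bases yield an amplicon. A pair
passes when exactly the target template amplifies among the target and
all extracted homologues. `terminal_exact` may be raised to 2–3 for
polymerases with harsher tail requirements.

## Synthetic fixtures

The generator emulates the pipeline's motivating scenario: an ancestral
unit (gene plus homeologous flanking context) embedded on one scaffold
per subgenome inside random DNA, a configurable set of homeologue
identities (default 93/93/80% with the 80% copy partial from 325 bases
into the gene, mirroring a realistic wheat locus), GC content 0.49, and
an optional second-variety genome whose target-locus copy carries planted
varietal SNPs.

Observed divergence is split into two components. A **shared** component
— rate `lineage_fraction × min(1 − identity)`, default 0.5 × 0.07 = 3.5%
— is applied at identical positions in every homeologue, all of which
receive one common (ancestral) base differing from the target: these are
the differences that arose on the target's own lineage, and they are the
only positions where the target differs from *all* homeologues at once,
i.e. the usable anchors. The remainder of each homeologue's divergence is
private, independent per copy. Without the shared component an n-homeologue
fixture would offer essentially no discriminating columns (the
all-copies-hit-at-once probability is the product of the rates), which
matches neither real homeologue phylogeny nor published designs. Total
per-homeologue divergence still equals `1 − identity`.

Substitution-only is the default; an indel option (rate and max length
config-exposed) exercises the gap-anchor path. A single seed governs all
randomness; the same seed reproduces byte-identical FASTA output.

What passing fixture tests do **not** show about real data: fixtures have
uniform base composition, no repeats or gene families beyond the planted
homeologues, no sequencing gaps/N runs, and mutation positions are i.i.d.
rather than clustered into exons/introns. Real genomes add paralogues and
repeat-induced spurious hit groups that the bitscore floor and guided
curation exist to handle.

## Problem sizes

Tests and the acceptance script run the full pipeline on a 2400-base gene
with three homeologues in ~20 kb scaffolds (seconds per run) — large
enough to exercise every stage, including partial-homologue and
varietal-guard behaviour, while keeping the suite fast. Exhaustive
oracles (alignment DP ≤ 12 bases, dimer enumeration 18–27-mers, tiling
subsets ≤ 15 products, grouping 50 hits) bound the regimes where exact
equivalence is asserted.

## Known limitations

* The aligner is center-star progressive; pathological inputs where the
  target is a poor center can misalign low-identity homologues (the 80%
  partial copy is near the practical floor).
* Penalty weights are heuristic ranks, not calibrated free energies; no
  secondary-structure partition function is computed.
* The in-silico PCR model is binary; it cannot grade partial suppression
  or polymerase-specific mismatch tolerances.
* Multiplex compatibility across pairs and nested strategies are out of
  scope.
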