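# homeoprime

Homologue-specific primer design for full-gene cloning in polyploids.

## The problem

Cloning a gene by PCR and Sanger sequencing is routine in diploids but
fragile in polyploids such as bread wheat: every gene typically has
near-identical copies (homeologues on the other subgenomes, sometimes
paralogues) at 80–95% sequence identity, and ordinary primers amplify all
of them at once. The standard remedy is an **allele-specific primer**: a
primer whose 3'-terminal base sits on a position where the target copy
differs from *every* off-target copy. Taq polymerase extends a 3'-terminal
mismatch poorly — efficiency drops by up to two orders of magnitude — so
such a primer amplifies only the intended locus.

`homeoprime` automates the whole design, end to end:

1. **Locate** — search the input gene against one or more genome
   assemblies (built-in seed-and-extend search, or imported 12-column
   tabular hits), chain fragmented local-alignment hits into loci
   (hits within 1000 bases of each other form one group), rank groups by
   total bitscore, and keep the best group as the target locus plus up to
   three further groups with within-group mean bitscore above 200 as
   homologues. Each locus is extracted with 1000-base flanking buffers.
2. **Align & mine** — build a multiple sequence alignment (internal
   affine-gap progressive aligner, or Muscle/Dialign if installed) and
   classify every column: a column is a usable anchor when the target base
   differs from every homologue that has sequence there. Copies of the
   same locus from other varieties' genomes veto columns where they differ
   from the target (varietal SNPs must not anchor primers).
3. **Design & tile** — generate candidate primers of 18–27 bases whose 3'
   ends sit exactly on anchor columns, score them with nearest-neighbor
   melting temperature, GC, hairpin and dimer terms, enumerate all
   (forward, reverse) anchor combinations inside the product-size bounds,
   and pick the minimum-penalty set of products that covers the whole
   input sequence with ≥ 50 bases of overlap between adjacent products
   (exact shortest path over the product DAG). Products longer than one
   usable Sanger read (700 bases) get internal "split" sequencing primers.
4. **Validate** — simulate PCR of every chosen pair against the target and
   all homologues: a primer binds with at most 3 internal mismatches, but
   amplification requires an exact 3'-terminal match on both primers. A
   design passes when exactly the target amplifies.

A synthetic-genome generator (`homeoprime.synthetic_fixtures`) builds
polyploid test genomes with known ground truth, so the entire pipeline is
testable without downloading any assembly.

## Worked example

Generate a synthetic allotetraploid — a 2400 bp gene on chr1A, homeologues
at 93/93/80% identity (the 80% one partial, starting 325 bases into the
gene), and a second variety's genome carrying 10 varietal SNPs — then run
the designer:

```python
from homeoprime.synthetic_fixtures import FixtureSpec, generate_fixture, write_fixture
spec = FixtureSpec(seed=11, gene_length=2400,
                   homeologue_identities=(0.93, 0.93, 0.80),
                   partial_homologue=(325, 2400 - 325),
                   n_varieties=2, varietal_snp_count=10)
write_fixture(generate_fixture(spec), "fixture")
```

```bash
homeoprime --input fixture/input_gene.fa --config fixture/genomes.yaml \
           --prefix T.demo --out design --verbose
```

```
[homology] target locus chr1A:15440-19840(+); 3 homologues, 1 extra-variety copies, 0 groups discarded
[alignment] 5 rows x 4886 columns
[snp] 104 usable discriminating columns (1 discriminating columns vetoed as varietal)
[primer] 2075 scored SNP-anchored candidates
[tiling] 3134 admissible primer pairs
[tiling] covered=True with 2 pairs, 5 sequencing primers, total penalty 10.67
[validate] in-silico PCR: all PASS
```

The pipeline found the gene and all three homeologues, kept 104 alignment
columns where the target differs from every homologue (one further column
was rejected because the second variety disagreed there — a varietal, not
homeologous, difference), and tiled the gene with two overlapping products.
`design/primers.csv` begins:

```
oligo_name,sequence_5to3,type,direction,product_start,product_end,product_size,tm_celsius,gc_percent,penalty
T.demo.323-2097.F,CGTCAGACCCAGGTTCGCA,PCR,F,323,2097,1774,59.80,63.2,2.103
T.demo.323-2097.R,TTGACTCGTTGCTGTCGGCT,PCR,R,323,2097,1774,59.74,55.0,1.257
T.demo.1653-3475.F,GCTGCGGAGTGTTTCGTGAAC,PCR,F,1653,3475,1822,59.90,57.1,2.596
T.demo.1653-3475.R,GCCCCATGGTACTCGCAGTG,PCR,R,1653,3475,1822,60.58,65.0,2.482
T.demo.323-2097.split2.F,CCTTCGTATTGGGGGAGGCG,Sanger,F,323,2097,1774,60.02,65.0,1.622
```

Oligo names embed the half-open product interval on the flanked target, so
`T.demo.323-2097` is a 2097 − 323 = 1774-base product; with 1000-base
flanks the gene occupies positions 1000–3400, so the first product starts
inside the 5' flank and the two products overlap by 444 bases. Each
product longer than one 700-base Sanger read carries numbered internal
`split` primers (`split2`, `split3`, …; the product's own forward primer
is read 1). Exit status is 0 for a fully covered design, 2 for a partial
cover, 1 on error.

`--guided` stops after writing the alignment so it can be inspected and
curated; the run resumes from the edited alignment with `-a` (row order:
bare sequence, flanked sequence, then homologues).

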