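# seloscan

Comparative-genomics toolkit for the **SELO/ydiU selenoprotein family**: a
census of anchored C-terminal Cys/Sec redox motifs with exact binomial
overrepresentation tests, rescue of selenocysteine residues misannotated
as stop codons, representative-set construction by identity-threshold
redundancy removal, gene-neighbourhood COG enrichment, and microbial
lifestyle enrichment — plus seeded synthetic-data generators so that every
stage can be validated against planted ground truth without external
downloads.

## The scientific problem

SELO (selenoprotein O; bacterial ydiU, yeast FMP40) is a widespread but
uncharacterised protein family with a predicted kinase-like domain. Several
independent sequence signals bear on its function:

- many members end with an anchored thioredoxin-like motif
  `C-x-x-[CU]-x-x>` (`>` marks the C-terminus; `U` is selenocysteine), e.g.
  the human terminus `CVTUSS>`. Whether this motif is overrepresented is a
  one-sided exact binomial question: with k observed carriers among n
  family members and a background rate p taken from a reference database,

      P(X ≥ k),  X ~ Binomial(n, p),

  evaluated in log space because the observed tails are extreme;
- because Sec is encoded by UGA (normally a stop), automated gene callers
  truncate selenoproteins at the Sec codon. A family member whose terminus
  aligns exactly three columns short of the family consensus, whose
  annotated stop is TGA, and whose genomic context continues with two sense
  codons and an ordinary stop, is a likely misannotation and can be
  rescued by reading the TGA as `U`;
- genes co-occurring with a focal gene across many genomes hint at shared
  function. For each COG the census counts windows of ±11 kbp around the
  focal gene that contain it, and tests the count against a per-COG
  background window probability (Poisson form `1 − exp(−n_c·W/L)` or
  Monte-Carlo), with Bonferroni correction;
- binary lifestyle traits (aquatic, aerobic, ...) of the organisms carrying
  the focal gene are tested the same way, with pairwise Fisher exact tests
  for independence of the enriched traits.

## Worked example

```python
>>> from seloscan import log10_binomial_tail, classify_terminus, summarize_presence
>>> classify_terminus("MAAAAAACVTUSS")          # the human SELO terminus
TerminalClass(inner=<InnerClass.U_TERM: 'U_TERM'>, outer=<OuterClass.CXXC: 'CXXC'>)
>>> log10_binomial_tail(12, 143, 585 / 500000)  # 12 of 143 carriers vs SwissProt background
-18.265568901376547
>>> [l.percent for l in summarize_presence(
...     [("Eukaryota", 79, 121), ("Bacteria", 1101, 2780), ("Archaea", 3, 107)])]
[65, 40, 3]
```

The tail value says: 12 motif carriers among 143 representative sequences
have a chance probability below 10⁻¹⁸ given 585 motif occurrences in half a
million database sequences — strong evidence the terminus is maintained by
selection. The percentages are the integer presence rates of the family in
the three domains of life.

The numbered scripts under `analysis/` run the full synthetic cohort:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_motif_census.py
python analysis/03_representative_set.py --seed 1
python analysis/04_neighborhood_enrichment.py
python analysis/05_lifestyle_enrichment.py
python analysis/06_sec_rescue.py
```

which prints, among other lines:

```
Cxx[CU]xx>: k = 14, log10 p = -22.16 (7.0E-23) against background 0.00117
clustered family: 50 sequences -> 10 representatives covering 10 planted clusters
  COG0042: k=56/60, p_bg=0.3230, log10 p corrected = -20.76
aquatic: 99/200 observed (50%) vs background 16%, log10 p corrected = -27.09
6 of 143 proteins called LIKELY_SEC (6 planted; recall 1.00, 0 false calls)
```

Each stage is also exposed as a CLI (`seloscan motif-scan|motif-enrich|
repset|neighborhood|lifestyle|sec-rescue|simulate|report|presence`) over
FASTA, gene-table TSV/GFF3, trait TSV and Newick inputs, writing TSV/JSON
results and iTOL colour-strip annotations.

## Layout

```
src/seloscan/     library: motifs, stats, repset, neighborhood,
                  sec_recovery, synth, pipeline, cli, io
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance recomputation
docs/methods.md   models, assumptions, parameter choices, limitations
```
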