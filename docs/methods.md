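# Methods

## Anchored motif grammar and terminal classes

Patterns follow PROSITE conventions: single residues, `[..]` residue
classes, `x` wildcards, `x(m,n)` bounded gaps (inclusive at both ends),
optional `-` separators, and a trailing `>` anchoring the final element at
the C-terminus. Matching is exact-class (no profile scores): a pattern
matches iff some assignment of gap lengths covers a suffix (anchored) or a
substring (unanchored). Selenocysteine `U` satisfies `[CU]` classes but
never a bare `C` — the Cys- and Sec-terminated families are biologically
distinct and counted separately. Matching is case-insensitive; trailing
`*`/`>` stop characters in input FASTA are stripped with a warning.

Terminal classification uses two concentric rings. The inner ring is read
directly off the residue at position −3 from the terminus (U → `U_TERM`,
C → `C_TERM`, else `NONE`). The outer ring is the smallest-gap pattern
among `C-x-x-[CU]-x-x>`, `C-x-[CU]-x-x>`, `C-x(3,10)-[CU]-x-x>` that
matches, assigned only when the inner ring is non-`NONE`; smallest-gap
precedence makes the categories mutually exclusive. The widest pattern
spans 14 residues, so classification depends only on the final 14 (the
minimum accepted sequence length is 13; a 13-mer simply cannot realise the
gap-10 case).

The census counts *sequences* matching each registered pattern, not
occurrences: anchored motifs occur at most once per sequence.

The kinase fingerprint annotator locates the ordered motif series
G-loop `G-x-x-G-x-G`, β3 `K`, αC `E`, catalytic-loop variant
`[HQ]-G-[VNS]` (the family's replacement for the canonical HRD), Mg-binding
`N`, and `D-[YF]-G`. Search is greedy-earliest with slots required in
order and non-overlapping; no tie-breaking beyond "earliest" is defined,
and a slot that cannot be placed after its predecessor is reported ABSENT.
Per-column conservation for logos is information content
`IC = log2(20) − H` with gaps excluded from the column distribution
(clamped to `[0, log2 20]`, since a Sec-containing column nominally has 21
states); columns with >50% gaps are flagged rather than scored.

## Enrichment statistics

`log10_binomial_tail(k, n, p)` evaluates the exact upper tail
`P(X ≥ k) = Σ_{i=k..n} C(n,i) p^i (1−p)^{n−i}` as a log-sum-exp over
log-gamma terms. This is stable far below double underflow (validated to
10⁻¹⁸⁰⁰ against 80-digit summation); results are carried as log10 values
plus a rendered scientific-notation string. The tail is exactly 1 at k=0
and monotone in k and p.

Expected motif counts under a composition model multiply the class
frequencies of the fixed positions (wildcards contribute 1); for bounded
gaps, the per-sequence probability is `1 − Π_g (1 − p_fixed)` treating gap
choices as independent. That independence is an approximation — the gap
instantiations share the anchored `[CU]` position — whose relative error
is second-order in the class frequencies; at database-like Cys frequencies
(~1.4%) it is within Monte-Carlo noise of the truth (tested), but it
overestimates noticeably if class frequencies are pushed to ~10%.

Fisher's exact test is two-sided by the probability-mass rule (sum of
tables, margins fixed, with probability at most the observed table's);
the implementation delegates to scipy and is validated against exact
rational enumeration on all tables with n ≤ 12 (max deviation ~1e-16).
Bonferroni correction is `min(0, log10 p + log10 m)` on the log scale.
Zero-background labels are refused (with a warning) rather than
pseudo-counted, for both trait and COG tests.

Trait (lifestyle) enrichment counts trait-positive organisms in the
selected subset against a supplied background frequency; traits with all
values missing in the subset are skipped. Pairwise Fisher independence
tests are run among traits whose corrected tail is below 0.05.

## Representative sets

Percent identity is defined on an optimal global alignment (match +1,
mismatch 0, linear gap −1; affine available) as 100 × identical columns /
alignment length, gap columns included — a deliberately conservative
denominator. Co-optimal alignments can differ in identity, so the
alignment is chosen to maximise lexicographically
(score, identical columns, −length); this is computed in one pass by
folding the three objectives into a single integer score for the standard
dynamic program (weights 2¹⁴ apart, which bounds sequences at ~8000
residues — ample for protein domains). The greedy reduction visits
sequences longest-first (ties by identifier), assigning each to the
best-matching representative at or above the threshold or founding a new
one; the output invariants (no representative pair at or above threshold,
every member at or above threshold to its representative) are asserted on
every run.

## Genomic neighbourhoods

Windows are anchored at the focal gene's midpoint and extend ±11 kbp by
default (22-kbp window); genes belong to a window if their interval
overlaps it, strand ignored, the focal gene excluded. The census is
presence/absence per window — duplicated neighbours never raise a count —
and the focal COG itself is excluded by default to avoid self-enrichment.
Windows truncate at replicon ends; a circular mode evaluates overlap
modulo the replicon length. The Bonferroni factor defaults to the number
of distinct COGs censused and is overridable.

Backgrounds come in two modes. The Poisson form `p_c = 1 − exp(−n_c·W/L)`
assumes genes placed uniformly and independently; the Monte-Carlo mode
samples windows that fit inside a replicon (centres uniform on
`[W/2, L − W/2]`, replicons chosen length-weighted) and reports empirical
presence. Two systematic effects separate the modes on structured data:
interval overlap widens the effective window by about one gene length
relative to the midpoint model, and — more importantly — a *fixed* set of
reference genomes is one configuration draw, so its empirical presence
deviates from the ensemble-mean Poisson value by a between-genome
configuration noise that does not shrink with more Monte-Carlo windows.
The agreement test therefore compares the modes on uniformly placed genes
with a tolerance combining the Monte-Carlo standard error with the
measured between-genome standard error. A related caveat: densely packed
gene layouts (hard-core spacing) make same-COG genes anti-clustered, which
raises window presence above the Poisson value; backgrounds for structured
genomes are best estimated in Monte-Carlo mode.

## Sec misannotation rescue

A candidate is called `LIKELY_SEC` only if all four conditions hold:
(i) its terminus sits exactly three columns short of the family consensus
terminus (the last alignment column with ≤50% gaps); (ii) its annotated
stop codon is TGA; (iii) reading through the TGA as Sec yields exactly two
further sense codons followed by TAA/TAG (a second TGA is rejected);
(iv) the recoded U falls in the alignment column holding C or U in ≥50% of
non-gap rows. The corrected protein appends `U` plus the two readthrough
residues and re-translates exactly from the CDS with TGA→U (asserted in
tests). Only the `Uxx>` geometry (three-residue truncation) is in scope;
deeper truncations are reported `NOT_CANDIDATE` with a note. The 50%
column-support threshold and the standard genetic code are fixed choices;
no SECIS-element evidence is used.

## Synthetic-data generators

All generators are pure functions of their config; one root seed spawns
per-generator substreams keyed by fixed labels, so adding a generator
never perturbs another's output.

- **Proteomes**: lengths uniform on [50, 120] residues by default (the
  simplest distribution satisfying the 14-residue terminal window);
  residues i.i.d. from a fixed database-average composition (Cys 1.37%)
  unless overridden. Planting overwrites the terminal region required by
  the class — outer-ring classes scrub the full 14-residue window, with
  wildcard positions drawn from the composition minus C/U so a planted
  sequence cannot fall into a second class. The family-census fixture
  plants 12 `CxxCxx>` and 99 further `Cxx>` termini among 143 sequences
  on a zero-Cys background, reproducing the published ring counts
  (12 and 111) exactly by construction.
- **Genomes**: one linear replicon per genome, genes laid left to right
  with exponential lengths (mean 900 bp, floor 90) and intergenic gaps
  (mean 120 bp, floor 1), 1-based inclusive, non-overlapping; one focal
  gene per genome at the middle index; background COGs i.i.d. uniform
  over the vocabulary; each planted COG is written, with its probability,
  onto a random non-focal gene overlapping the focal window. Strand is
  generated but never conditions window membership.
- **Traits**: the designated subset (first `subset_size` organisms) draws
  enriched traits at their enriched frequency, everything else at
  background. Default study conditions mirror the lifestyle analysis:
  backgrounds 0.16 (aquatic) and 0.32 (aerobic), enriched rates 0.47 and
  0.65, subset 200.
- **Readthrough families**: all full-length proteins share one length
  (default 60) and end `[CU]-x-x`; the flagged fraction (default 6/143)
  carries U at −3 with the annotated CDS stopping at that TGA and the
  genomic context continuing with two sense codons and TAA/TAG. The
  C-termini alignment is the trivial gap-padded one. With a truncated
  majority the consensus terminus itself shifts and rescue is not
  expected to work (warned).

What the generators do *not* emulate: phylogenetic correlation among
sequences (i.i.d. only), operon structure or strand bias, overlapping
genes, codon-usage bias, and alignment uncertainty (the C-termini
alignment is exact by construction). Passing tests therefore demonstrate
correctness of the computations under the stated statistical model, not
robustness to misalignment or annotation noise in real data.

## Problem sizes and numerical choices

The default validation runs use 143-sequence proteomes, 50-sequence
cluster fixtures, 100 + 150 genomes for planted-COG recovery, 1000 null
replicates of 10 genomes for calibration, and 40000 Monte-Carlo windows
for backgrounds — sizes at which every planted signal is recovered with
probability ≈ 1 while the whole suite runs in seconds. Ties in enrichment
tables are broken by label to keep output deterministic; all tabular
output is plain TSV and round-trips through the package's readers.

## Known limitations

- The published representative-set size (143 of 859 hits at 70% identity)
  is not reproducible because neither the hit set nor the original tool's
  identity convention is public; the reduction here is validated on
  planted clusters instead.
- The published neighbourhood table and lifestyle p-values require
  genome-database snapshots and unprinted inputs (the lifestyle n, the
  2×2 table, the exact Bonferroni factor); the statistics are therefore
  validated against oracles and planted signals rather than those printed
  values.
- The expected-count composition model is a first-order independence
  approximation for gapped patterns (see above).
- Window membership ignores strand and operon structure by design.
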