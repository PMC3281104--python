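#!/usr/bin/env python
"""Generate the synthetic study cohort used by the downstream analyses.

Writes, under results/data/: a 143-member proteome planted with the
family's terminal-class counts (12 CxxCxx>, 99 further Cxx>), 60 genomes
with one focal gene each and a COG planted nearby at 0.9 co-occurrence,
a 1250-organism trait table with an enriched 200-organism subset, and a
143-member CDS family containing 6 Sec-misannotated stops — each with a
ground-truth sidecar.
"""

import argparse
from pathlib import Path

from seloscan import io as sio
from seloscan import synth

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/data"))
args = ap.parse_args()
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

records, truth = synth.gen_proteome(
    synth.SimProteomeConfig(
        n_seqs=143, terminal_spec={"CxxCxx>": 12 / 143, "Cxx>": 99 / 143}, seed=args.seed
    )
)
sio.write_fasta(records, out / "proteome.fasta")
with open(out / "proteome_truth.tsv", "w") as fh:
    fh.write("seq_id\tplanted_class\n")
    fh.writelines(f"{sid}\t{lab}\n" for sid, lab in truth.items())
print(f"proteome: {len(records)} sequences, "
      f"{sum(1 for v in truth.values() if v != 'none')} planted termini")

# the planted COG is drawn from the shared vocabulary so the reference
# genomes carry an honest background for it
gcfg = synth.SimGenomesConfig(n_genomes=60, planted={"COG0042": 0.9}, seed=args.seed)
genomes, placed = synth.gen_genome_tables(gcfg)
sio.write_gene_table(synth.genomes_to_frame(genomes), out / "genes.tsv")
refs, _ = synth.gen_genome_tables(
    synth.SimGenomesConfig(n_genomes=120, seed=args.seed + 1)
)
sio.write_gene_table(synth.genomes_to_frame(refs), out / "reference_genes.tsv")
with open(out / "genes_truth.tsv", "w") as fh:
    fh.write("genome_id\tplanted_cogs\n")
    fh.writelines(f"{g}\t{','.join(sorted(s)) or '.'}\n" for g, s in placed.items())
print(f"genomes: {len(genomes)} with focal gene, planted in "
      f"{sum(1 for s in placed.values() if s)} of them; {len(refs)} reference genomes")

tcfg = synth.SimTraitConfig(
    n_orgs=1250, trait_freqs={"aquatic": 0.16, "aerobic": 0.32},
    enriched={"aquatic": 0.47, "aerobic": 0.65}, subset_size=200, seed=args.seed,
)
table, subset = synth.gen_trait_table(tcfg)
sio.write_trait_table(table, out / "traits.tsv")
(out / "selected_organisms.txt").write_text("\n".join(subset) + "\n")
print(f"traits: {table.shape[0]} organisms, subset of {len(subset)}")

fx = synth.gen_readthrough_cds(
    synth.SimReadthroughConfig(n_proteins=143, sec_fraction=6 / 143, seed=args.seed)
)
sio.write_fasta(fx.annotated_proteins, out / "family_annotated.fasta")
sio.write_fasta(
    [sio.SequenceRecord(f"{c.protein_id} cds_len={c.cds_len}", c.seq) for c in fx.cds_records],
    out / "family_cds.fasta",
)
sio.write_fasta(
    [sio.SequenceRecord(i, r) for i, r in zip(fx.alignment.ids, fx.alignment.rows)],
    out / "family_ctermini.aln.fasta",
)
with open(out / "family_truth.tsv", "w") as fh:
    fh.write("protein_id\tmisannotated_sec\n")
    fh.writelines(f"{p}\t{int(f)}\n" for p, f in fx.truth_flags.items())
print(f"readthrough family: {len(fx.cds_records)} CDS, "
      f"{sum(fx.truth_flags.values())} misannotated Sec stops")
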