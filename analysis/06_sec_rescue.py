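#!/usr/bin/env python
"""Rescue Sec residues misannotated as stop codons in the CDS family.

Reads the annotated proteins, their CDS records with downstream context,
and the C-termini alignment; writes verdicts and corrected proteins and
compares the calls with the generator's ground truth.
"""

import argparse
from pathlib import Path

from Bio import SeqIO

from seloscan import io as sio
from seloscan.sec_recovery import CdsRecord, TerminusAlignment, call_family

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

proteins = sio.read_fasta(args.data / "family_annotated.fasta")
aln_rows = sio.read_alignment_fasta(args.data / "family_ctermini.aln.fasta")
aln = TerminusAlignment([r.id for r in aln_rows], [r.seq for r in aln_rows])
cds_records = []
for rec in SeqIO.parse(str(args.data / "family_cds.fasta"), "fasta"):
    length = next(int(t.split("=")[1]) for t in rec.description.split() if t.startswith("cds_len="))
    cds_records.append(CdsRecord(rec.id, str(rec.seq), length))

calls = call_family(proteins, cds_records, aln)
rescued = [c for c in calls if c.verdict == "LIKELY_SEC"]
with open(args.outdir / "sec_recovery.tsv", "w") as fh:
    fh.write("protein_id\tverdict\textension\n")
    for c in calls:
        fh.write(f"{c.protein_id}\t{c.verdict}\t{c.extended_protein[-3:] if c.extended_protein else '.'}\n")
sio.write_fasta([sio.SequenceRecord(c.protein_id, c.extended_protein) for c in rescued],
                args.outdir / "sec_corrected.fasta")

truth = {
    line.split("\t")[0]: line.strip().split("\t")[1] == "1"
    for line in open(args.data / "family_truth.tsv").readlines()[1:]
}
called = {c.protein_id for c in rescued}
planted = {p for p, f in truth.items() if f}
print(f"{len(called)} of {len(calls)} proteins called LIKELY_SEC "
      f"({len(planted)} planted; recall {len(called & planted) / len(planted):.2f}, "
      f"{len(called - planted)} false calls)")
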