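"""File I/O: FASTA (protein with Sec 'U', nucleotide), gene tables, trait
tables, GFF3 with COG attributes, Newick leaf lists, and iTOL annotation
files.

All tabular formats are plain TSV so that every artefact of a run is
diffable and round-trips through pandas.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class SequenceRecord(NamedTuple):
    """A named sequence; proteins may contain selenocysteine as 'U'."""

    id: str
    seq: str


GENE_TABLE_COLUMNS = ["genome_id", "gene_id", "start", "end", "strand", "cog_id"]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA; all rows must have equal length."""
    rows = read_fasta(path)
    if rows and len({len(r.seq) for r in rows}) != 1:
        raise ValueError(f"ragged alignment in {path}")
    return rows


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str, "cog_id": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} lacks columns: {missing}")
    return df


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GENE_TABLE_COLUMNS)


_GFF_COG = re.compile(r"(?:^|;)\s*COG=([^;]+)")


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene", "CDS")) -> pd.DataFrame:
    """Read gene records from a GFF3 file into the gene-table schema.

    Coordinates are 1-based inclusive as in GFF3. The COG label is taken
    from a ``COG=`` key in the attributes column; genes without one get a
    null cog_id. The genome id is the seqid column.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in feature_types:
                continue
            m = _GFF_COG.search(attrs)
            gid = None
            for key in ("ID=", "Name=", "locus_tag="):
                if key in attrs:
                    gid = attrs.split(key, 1)[1].split(";", 1)[0]
                    break
            rows.append(
                {
                    "genome_id": seqid,
                    "gene_id": gid or f"{seqid}:{start}-{end}",
                    "start": int(start),
                    "end": int(end),
                    "strand": strand if strand in "+-" else "+",
                    "cog_id": m.group(1) if m else None,
                }
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a binary trait table (organism_id index, one 0/1 column per trait)."""
    df = pd.read_csv(path, sep="\t", dtype={"organism_id": str})
    return df.set_index("organism_id")


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="organism_id")


def newick_leaf_names(path: str | Path) -> list[str]:
    tree = Phylo.read(str(path), "newick")
    return [leaf.name for leaf in tree.get_terminals()]


# default ring colours follow the published phylogram convention:
# inner ring green for Cxx>, red for Uxx>; outer ring magenta/blue/black.
ITOL_INNER_COLOURS = {"C_TERM": "#2ca02c", "U_TERM": "#d62728", "NONE": "#d9d9d9"}
ITOL_OUTER_COLOURS = {
    "CXXC": "#ff00ff",
    "CXC": "#1f77b4",
    "CX_RANGE_C": "#000000",
    "NONE": "#d9d9d9",
}


def write_itol_colorstrip(
    assignments: dict[str, str],
    colours: dict[str, str],
    path: str | Path,
    dataset_label: str = "terminal_class",
) -> None:
    """Write an iTOL COLORSTRIP annotation file keyed by leaf identifier."""
    with open(path, "w") as fh:
        fh.write("DATASET_COLORSTRIP\nSEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\t{dataset_label}\nCOLOR\t#000000\nDATA\n")
        for leaf, label in assignments.items():
            fh.write(f"{leaf}\t{colours.get(label, '#d9d9d9')}\t{label}\n")
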