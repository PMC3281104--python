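"""Selenocysteine stop-codon misannotation rescue.

Selenocysteine is encoded by UGA, normally a stop codon; automated gene
callers therefore often truncate selenoproteins at the Sec position. For
a family whose members end with a ``[CU]-x-x>`` terminus, a truncated
member betrays itself in a C-terminal multiple alignment: its terminus
sits exactly three (non-gap) columns short of the family consensus
terminus, its annotated stop codon is TGA, and reading through that TGA
as Sec yields exactly two further sense codons and then an ordinary
TAA/TAG stop, with the recoded U falling in the alignment column that
holds Cys/Sec in the rest of the family.

A candidate must satisfy all four conditions to be called LIKELY_SEC;
the corrected protein appends ``U`` plus the two readthrough residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from seloscan.io import SequenceRecord

STOPS = {"TAA", "TAG", "TGA"}
_FORWARD = dict(standard_dna_table.forward_table)
GAPS = ("-", ".")

#: required truncation depth: the Uxx> geometry (U + 2 residues)
EXTENSION_LEN = 3
#: minimum fraction of non-gap rows holding C/U in the Sec column
CU_SUPPORT = 0.5


def _translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    codon = codon.upper().replace("U", "T")
    if codon in STOPS:
        return None
    aa = _FORWARD.get(codon)
    if aa is None:
        raise ValueError(f"unrecognised codon {codon!r}")
    return aa


@dataclass(frozen=True)
class CdsRecord:
    """A CDS with trailing genomic context.

    `seq` covers the annotated CDS (stop codon included as the last
    in-frame triplet of the first `cds_len` bases) plus at least 12 bp of
    downstream sequence read in the same frame.
    """

    protein_id: str
    seq: str
    cds_len: int

    def __post_init__(self):
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.protein_id}: CDS length {self.cds_len} not divisible by 3")
        if self.cds_len > len(self.seq):
            raise ValueError(f"{self.protein_id}: cds_len exceeds sequence length")

    @property
    def stop_codon(self) -> str:
        return self.seq[self.cds_len - 3 : self.cds_len].upper().replace("U", "T")

    def codons(self, start: int, count: int) -> list[str]:
        out = []
        for i in range(count):
            a = start + 3 * i
            out.append(self.seq[a : a + 3].upper().replace("U", "T"))
        return out


@dataclass
class TerminusAlignment:
    """A gapped alignment of family C-termini.

    The consensus terminus is the last column with at most 50% gaps; the
    Sec/Cys column sits two columns before it (position -3 from the
    consensus terminus).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged alignment")

    def row(self, protein_id: str) -> str:
        try:
            return self.rows[self.ids.index(protein_id)]
        except ValueError:
            raise KeyError(f"{protein_id} not in alignment") from None

    @property
    def consensus_terminus_col(self) -> int:
        ncol = len(self.rows[0])
        for j in range(ncol - 1, -1, -1):
            gaps = sum(1 for r in self.rows if r[j] in GAPS)
            if gaps / len(self.rows) <= 0.5:
                return j
        raise ValueError("alignment has no column with <=50% gaps")

    @property
    def cu_col(self) -> int:
        return self.consensus_terminus_col - 2

    def cu_support(self) -> float:
        """Fraction of non-gap rows holding C or U in the Sec/Cys column."""
        j = self.cu_col
        col = [r[j].upper() for r in self.rows if r[j] not in GAPS]
        if not col:
            return 0.0
        return sum(1 for c in col if c in "CU") / len(col)

    def last_residue_col(self, protein_id: str) -> int:
        r = self.row(protein_id)
        for j in range(len(r) - 1, -1, -1):
            if r[j] not in GAPS:
                return j
        raise ValueError(f"{protein_id}: all-gap alignment row")


@dataclass
class RecoveryCall:
    protein_id: str
    verdict: str  # "LIKELY_SEC" | "NOT_CANDIDATE"
    extended_protein: str | None = None
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.verdict == "LIKELY_SEC":
            assert self.extended_protein is not None
            assert "U" in self.extended_protein[-EXTENSION_LEN:]


def _check_translation(protein: SequenceRecord, cds: CdsRecord) -> None:
    n_aa = cds.cds_len // 3 - 1
    if len(protein.seq) != n_aa:
        raise ValueError(
            f"{protein.id}: protein length {len(protein.seq)} != CDS-encoded {n_aa}"
        )
    for i, codon in enumerate(cds.codons(0, n_aa)):
        expect = protein.seq[i].upper()
        aa = _translate_codon(codon)
        if aa is None:
            aa = "U" if codon == "TGA" else None  # internal recoded Sec
        if aa != expect:
            raise ValueError(
                f"{protein.id}: codon {i + 1} ({codon}) encodes {aa}, protein has {expect}"
            )


def detect_sec_misannotation(
    protein: SequenceRecord,
    cds: CdsRecord,
    aln: TerminusAlignment,
) -> RecoveryCall:
    """Verdict on one protein: is its annotated stop a misannotated Sec?

    All four conditions must hold — (i) the protein's terminus aligns
    exactly three columns short of the family consensus terminus, (ii)
    the annotated stop codon is TGA, (iii) readthrough yields exactly two
    sense codons then a TAA/TAG stop, (iv) the recoded U lands in the
    family's Cys/Sec column (>=50% non-gap support).
    """
    _check_translation(protein, cds)
    evidence = []
    ok = True

    t_row = aln.last_residue_col(protein.id)
    t_cons = aln.consensus_terminus_col
    if t_row == t_cons - EXTENSION_LEN:
        evidence.append(f"terminus {EXTENSION_LEN} columns short of consensus (col {t_row})")
    else:
        evidence.append(f"terminus at col {t_row}, consensus at {t_cons}: geometry mismatch")
        ok = False

    if cds.stop_codon == "TGA":
        evidence.append("annotated stop is TGA")
    else:
        evidence.append(f"annotated stop is {cds.stop_codon}, not TGA")
        ok = False

    extension = None
    down = cds.codons(cds.cds_len, EXTENSION_LEN)  # 2 sense codons + new stop
    if len(down[-1]) == 3:
        sense = [_translate_codon(c) for c in down[: EXTENSION_LEN - 1]]
        stop2 = down[EXTENSION_LEN - 1]
        if all(a is not None for a in sense) and stop2 in {"TAA", "TAG"}:
            extension = "U" + "".join(sense)  # type: ignore[arg-type]
            evidence.append(f"readthrough extension {extension} ends at {stop2}")
        else:
            evidence.append(
                "readthrough does not give 2 sense codons then TAA/TAG "
                f"(codons {down})"
            )
            ok = False
    else:
        evidence.append("insufficient downstream context")
        ok = False

    # condition (iv): with geometry (i) satisfied the readthrough U lands in
    # cu_col, so what remains to check is the family support in that column
    support = aln.cu_support()
    if support >= CU_SUPPORT:
        evidence.append(f"U lands in [CU] column ({support:.0%} support)")
    else:
        evidence.append(f"[CU] column support only {support:.0%}")
        ok = False

    if ok and extension is not None:
        return RecoveryCall(protein.id, "LIKELY_SEC", protein.seq + extension, evidence)
    return RecoveryCall(protein.id, "NOT_CANDIDATE", None, evidence)


def call_family(
    proteins: Sequence[SequenceRecord],
    cds_records: Iterable[CdsRecord],
    aln: TerminusAlignment,
) -> list[RecoveryCall]:
    """Run misannotation detection across a family; order follows `proteins`."""
    by_id = {c.protein_id: c for c in cds_records}
    calls = []
    for p in proteins:
        if p.id not in by_id:
            raise ValueError(f"no CDS record for {p.id}")
        calls.append(detect_sec_misannotation(p, by_id[p.id], aln))
    return calls
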