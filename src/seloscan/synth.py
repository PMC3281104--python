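"""Seeded synthetic-data generators.

Every downstream stage of the package is exercised against data whose
ground truth is known by construction: proteomes with planted C-terminal
motif classes, genomes with COGs planted near a focal gene at a chosen
co-occurrence rate, binary trait tables with enriched subsets, and CDS
records whose annotated stop is an in-frame TGA standing for Sec.

Each generator is a pure function of its config: one root seed, with
per-generator substreams derived from fixed labels, so adding a new
generator never perturbs an existing one's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from seloscan.io import SequenceRecord
from seloscan.motifs import AMINO_ACIDS
from seloscan.neighborhood import GeneRecord
from seloscan.sec_recovery import CdsRecord, TerminusAlignment

# fixed substream labels (see module docstring)
_STREAMS = {"proteome": 11, "genomes": 22, "traits": 33, "readthrough": 44}


class ConfigError(ValueError):
    pass


def substream(seed: int, label: str) -> np.random.Generator:
    if label not in _STREAMS:
        raise KeyError(f"unknown generator stream {label!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[label],)))


# ---------------------------------------------------------------------------
# proteomes with planted terminal classes

#: plant recipes: (inner residue, upstream gap before the extra Cys; None = no outer Cys)
#: gap is the number of wildcards between the upstream C and the [CU] position
_PLANT_CLASSES = {
    "Cxx>": ("C", None),
    "Uxx>": ("U", None),
    "CxxCxx>": ("C", 2),
    "CxxUxx>": ("U", 2),
    "CxCxx>": ("C", 1),
    "CxUxx>": ("U", 1),
    "Cx(3,10)Cxx>": ("C", "range"),
    "Cx(3,10)Uxx>": ("U", "range"),
}

#: widest scrubbed terminal region: C + 10 gap + [CU] + 2 = 14 residues
_SCRUB = 14


@dataclass(frozen=True)
class SimProteomeConfig:
    n_seqs: int
    length_min: int = 50
    length_max: int = 120
    residue_freqs: Mapping[str, float] = None  # type: ignore[assignment]
    terminal_spec: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.residue_freqs is None:
            object.__setattr__(self, "residue_freqs", swissprot_like_composition())
        total = sum(self.residue_freqs.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.residue_freqs.values()):
            raise ConfigError(f"residue_freqs must be a frequency vector (sum {total})")
        if self.length_min < 12:
            raise ConfigError("length_min must be >= 12 for terminal-window analysis")
        if self.length_min > self.length_max:
            raise ConfigError("length_min > length_max")
        unknown = set(self.terminal_spec) - set(_PLANT_CLASSES)
        if unknown:
            raise ConfigError(f"unknown terminal classes: {sorted(unknown)}")
        fr = list(self.terminal_spec.values())
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise ConfigError("terminal_spec fractions must be >=0 and sum <=1")


def uniform_composition(include_u: bool = False) -> dict[str, float]:
    letters = AMINO_ACIDS + ("U" if include_u else "")
    return {a: 1.0 / len(letters) for a in letters}


def swissprot_like_composition() -> dict[str, float]:
    """A fixed average-composition model with Cys at 1.37%, the order of
    magnitude seen in large protein databases."""
    comp = {a: 0.0 for a in AMINO_ACIDS}
    comp.update(
        A=0.0826, R=0.0553, N=0.0406, D=0.0546, C=0.0137, Q=0.0393, E=0.0674,
        G=0.0708, H=0.0227, I=0.0593, L=0.0965, K=0.0582, M=0.0241, F=0.0386,
        P=0.0472, S=0.0660, T=0.0535, W=0.0110, Y=0.0292, V=0.0687,
    )
    total = sum(comp.values())
    return {a: v / total for a, v in comp.items()}


def _sample_letters(rng: np.random.Generator, letters: list[str], probs: np.ndarray, n: int) -> str:
    return "".join(rng.choice(letters, size=n, p=probs)) if n else ""


def gen_proteome(cfg: SimProteomeConfig) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate a proteome; returns records plus id -> planted-class labels.

    Unplanted termini are i.i.d. from residue_freqs. Planting overwrites
    the terminal region as required by the class pattern, sampling
    wildcard positions from residue_freqs with C and U excluded so a
    planted sequence cannot accidentally fall into a second class.
    Inner-only classes (Cxx>, Uxx>) guarantee the inner ring; outer
    classes scrub the full 14-residue terminal window and guarantee both
    rings.
    """
    rng = substream(cfg.seed, "proteome")
    letters = sorted(cfg.residue_freqs)
    probs = np.array([cfg.residue_freqs[a] for a in letters])
    nc_letters = [a for a in letters if a not in "CU" and cfg.residue_freqs[a] > 0]
    nc_probs = np.array([cfg.residue_freqs[a] for a in nc_letters])
    if len(nc_letters) == 0:
        raise ConfigError("residue_freqs has no mass outside C/U for wildcard planting")
    nc_probs = nc_probs / nc_probs.sum()

    # deterministic planted counts, assigned to a seeded permutation
    labels_for: list[str | None] = [None] * cfg.n_seqs
    counts = {lab: int(round(f * cfg.n_seqs)) for lab, f in cfg.terminal_spec.items()}
    if sum(counts.values()) > cfg.n_seqs:
        raise ConfigError("terminal_spec rounds to more sequences than n_seqs")
    perm = rng.permutation(cfg.n_seqs)
    pos = 0
    for lab in sorted(counts):
        for _ in range(counts[lab]):
            labels_for[perm[pos]] = lab
            pos += 1

    records = []
    truth: dict[str, str] = {}
    width = max(1, len(str(cfg.n_seqs)))
    for i in range(cfg.n_seqs):
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        seq = list(_sample_letters(rng, letters, probs, length))
        lab = labels_for[i]
        if lab is not None:
            inner, gap = _PLANT_CLASSES[lab]
            if gap is None:
                tail = [inner] + list(_sample_letters(rng, nc_letters, nc_probs, 2))
            else:
                g = int(rng.integers(3, 11)) if gap == "range" else gap
                scrub = list(_sample_letters(rng, nc_letters, nc_probs, _SCRUB))
                scrub[-3] = inner
                scrub[-(g + 4)] = "C"
                tail = scrub
            seq[-len(tail):] = tail
        sid = f"seq{i:0{width}d}"
        records.append(SequenceRecord(sid, "".join(seq)))
        truth[sid] = lab if lab is not None else "none"
    return records, truth


def gen_identity_clusters(
    n_clusters: int = 10,
    per_cluster: int = 5,
    length: int = 100,
    within_mut_rate: float = 0.08,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Sequence families for redundancy-reduction tests.

    Each cluster is an i.i.d. random centroid plus members carrying point
    mutations at `within_mut_rate`: members sit at roughly
    100*(1 - rate)% identity to their centroid, while unrelated centroids
    share only chance identity (far below any reduction threshold).
    Returns the records plus id -> true cluster index.
    """
    rng = substream(seed, "proteome")
    letters = list(AMINO_ACIDS)
    records, truth = [], {}
    for c in range(n_clusters):
        centroid = rng.integers(0, len(letters), length)
        for m in range(per_cluster):
            seq = centroid.copy()
            if m > 0:
                hit = rng.random(length) < within_mut_rate
                seq[hit] = (seq[hit] + rng.integers(1, len(letters), hit.sum())) % len(letters)
            sid = f"cl{c:02d}_m{m:02d}"
            records.append(SequenceRecord(sid, "".join(letters[j] for j in seq)))
            truth[sid] = c
    return records, truth


# ---------------------------------------------------------------------------
# genomes with planted neighbourhood COGs


@dataclass(frozen=True)
class SimGenomesConfig:
    n_genomes: int
    genes_per_genome: int = 40
    gene_len_mean: int = 900
    intergenic_len_mean: int = 120
    cog_vocab_size: int = 50
    focal_cog: str = "COG_FOCAL"
    planted: Mapping[str, float] = field(default_factory=dict)
    half_width: int = 11000
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 0 or self.genes_per_genome < 2:
            raise ConfigError("need n_genomes >= 0 and genes_per_genome >= 2")
        if self.genes_per_genome * (self.gene_len_mean + self.intergenic_len_mean) > 2**31:
            raise ConfigError("genome length would overflow the coordinate range")
        if any(not 0.0 <= q <= 1.0 for q in self.planted.values()):
            raise ConfigError("planted probabilities must lie in [0,1]")
        if self.half_width < self.gene_len_mean + self.intergenic_len_mean:
            raise ConfigError("half_width too small to guarantee a neighbour gene")


def cog_vocab(size: int) -> list[str]:
    return [f"COG{i:04d}" for i in range(1, size + 1)]


def gen_genome_tables(
    cfg: SimGenomesConfig,
) -> tuple[dict[str, list[GeneRecord]], dict[str, set[str]]]:
    """Generate per-genome gene tables with exactly one focal gene each.

    Genes are laid out left to right with exponential lengths and
    intergenic gaps (1-based inclusive coordinates, single linear
    replicon, no overlaps). Background COGs are drawn uniformly from the
    vocabulary; each planted COG is, with its probability, written onto a
    randomly chosen non-focal gene overlapping the focal window. Returns
    the genomes and the per-genome set of planted COGs actually placed.
    """
    rng = substream(cfg.seed, "genomes")
    vocab = cog_vocab(cfg.cog_vocab_size)
    genomes: dict[str, list[GeneRecord]] = {}
    placed: dict[str, set[str]] = {}
    gwidth = max(1, len(str(max(cfg.n_genomes, 1))))
    for gi in range(cfg.n_genomes):
        gid = f"g{gi:0{gwidth}d}"
        lens = np.maximum(90, rng.exponential(cfg.gene_len_mean, cfg.genes_per_genome).astype(int))
        gaps = np.maximum(1, rng.exponential(cfg.intergenic_len_mean, cfg.genes_per_genome).astype(int))
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lens[:-1])])
        ends = starts + lens - 1
        strands = rng.choice(["+", "-"], size=cfg.genes_per_genome)
        cogs = [vocab[j] for j in rng.integers(0, len(vocab), cfg.genes_per_genome)]
        focal_idx = cfg.genes_per_genome // 2
        cogs[focal_idx] = cfg.focal_cog
        mid = (starts[focal_idx] + ends[focal_idx]) / 2.0
        lo, hi = mid - cfg.half_width, mid + cfg.half_width
        in_window = [
            j
            for j in range(cfg.genes_per_genome)
            if j != focal_idx and starts[j] <= hi and ends[j] >= lo
        ]
        placed[gid] = set()
        want = [c for c in sorted(cfg.planted) if rng.random() < cfg.planted[c]]
        if len(want) > len(in_window):
            raise ConfigError(
                f"genome {gid}: {len(want)} planted COGs but only {len(in_window)} window genes"
            )
        slots = rng.choice(in_window, size=len(want), replace=False) if want else []
        for c, j in zip(want, slots):
            cogs[int(j)] = c
            placed[gid].add(c)
        genomes[gid] = [
            GeneRecord(gid, f"{gid}_gene{j:03d}", int(starts[j]), int(ends[j]), str(strands[j]), cogs[j])
            for j in range(cfg.genes_per_genome)
        ]
    return genomes, placed


def genomes_to_frame(genomes: Mapping[str, list[GeneRecord]]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": g.genome_id,
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "cog_id": g.cog_id,
        }
        for gid in sorted(genomes)
        for g in genomes[gid]
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait tables


@dataclass(frozen=True)
class SimTraitConfig:
    n_orgs: int
    trait_freqs: Mapping[str, float] = field(default_factory=dict)
    enriched: Mapping[str, float] = field(default_factory=dict)
    subset_size: int = 0
    seed: int = 0

    def __post_init__(self):
        for name, f in {**self.trait_freqs, **self.enriched}.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"frequency for {name!r} outside [0,1]")
        unknown = set(self.enriched) - set(self.trait_freqs)
        if unknown:
            raise ConfigError(f"enriched traits without a background: {sorted(unknown)}")
        if self.subset_size > self.n_orgs:
            raise ConfigError("subset_size exceeds n_orgs")


def gen_trait_table(cfg: SimTraitConfig) -> tuple[pd.DataFrame, list[str]]:
    """Binary trait table plus the designated (first subset_size) organisms.

    Organisms in the designated subset draw enriched traits at the
    enriched frequency, everything else at the background frequency.
    """
    rng = substream(cfg.seed, "traits")
    width = max(1, len(str(max(cfg.n_orgs, 1))))
    orgs = [f"org{i:0{width}d}" for i in range(cfg.n_orgs)]
    subset = orgs[: cfg.subset_size]
    data = {}
    for trait in sorted(cfg.trait_freqs):
        p_bg = cfg.trait_freqs[trait]
        p_sub = cfg.enriched.get(trait, p_bg)
        probs = np.full(cfg.n_orgs, p_bg)
        probs[: cfg.subset_size] = p_sub
        data[trait] = (rng.random(cfg.n_orgs) < probs).astype(int)
    table = pd.DataFrame(data, index=pd.Index(orgs, name="organism_id"))
    return table, subset


# ---------------------------------------------------------------------------
# readthrough CDS records

_SENSE_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _SENSE_CODONS.setdefault(_aa, []).append(_codon)

_NT = ["A", "C", "G", "T"]


@dataclass(frozen=True)
class SimReadthroughConfig:
    n_proteins: int
    sec_fraction: float = 0.0
    tail_len: int = 3  # residues beyond the misannotated stop (U + 2)
    protein_len: int = 60
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sec_fraction <= 1.0:
            raise ConfigError("sec_fraction must lie in [0,1]")
        if self.tail_len != 3:
            raise ConfigError("only the Uxx> geometry (tail_len 3) is supported")
        if self.protein_len < 13:
            raise ConfigError("protein_len must be >= 13")


@dataclass
class ReadthroughFixture:
    cds_records: list[CdsRecord]
    annotated_proteins: list[SequenceRecord]
    full_proteins: list[SequenceRecord]
    alignment: TerminusAlignment
    truth_flags: dict[str, bool]  # id -> annotated stop is a misannotated Sec


def _codon_for(rng: np.random.Generator, aa: str) -> str:
    options = _SENSE_CODONS[aa]
    return options[int(rng.integers(0, len(options)))]


def gen_readthrough_cds(cfg: SimReadthroughConfig) -> ReadthroughFixture:
    """A selenoprotein family with a fraction of Sec-misannotated members.

    Every full-length protein ends [CU]-x-x: flagged members carry Sec (U)
    at position -3 and their annotated CDS stops early at that TGA, with
    two sense codons and a TAA/TAG stop following in the genomic context;
    unflagged members carry Cys there and stop normally at TAA/TAG. The
    C-termini alignment is the trivial one (all full forms share the
    family length, truncated rows are gap-padded).
    """
    rng = substream(cfg.seed, "readthrough")
    n_flag = int(round(cfg.sec_fraction * cfg.n_proteins))
    flagged = set(rng.choice(cfg.n_proteins, size=n_flag, replace=False).tolist())
    width = max(1, len(str(max(cfg.n_proteins, 1))))
    aa_pool = [a for a in AMINO_ACIDS if a != "C"]
    cds_records, annotated, full, rows, ids = [], [], [], [], []
    truth: dict[str, bool] = {}
    L = cfg.protein_len
    for i in range(cfg.n_proteins):
        pid = f"prot{i:0{width}d}"
        is_sec = i in flagged
        core = "".join(aa_pool[int(j)] for j in rng.integers(0, len(aa_pool), L - 3))
        tail2 = "".join(aa_pool[int(j)] for j in rng.integers(0, len(aa_pool), 2))
        full_seq = core + ("U" if is_sec else "C") + tail2
        codons = [
            "TGA" if aa == "U" else _codon_for(rng, aa) for aa in full_seq
        ]
        normal_stop = ["TAA", "TAG"][int(rng.integers(0, 2))]
        pad = "".join(_NT[int(j)] for j in rng.integers(0, 4, 12))
        if is_sec:
            ann_seq = full_seq[:-3]
            cds_proper = "".join(codons[: L - 3]) + "TGA"
            downstream = "".join(codons[L - 2 :]) + normal_stop + pad
        else:
            ann_seq = full_seq
            cds_proper = "".join(codons) + normal_stop
            downstream = pad
        cds_records.append(CdsRecord(pid, cds_proper + downstream, len(cds_proper)))
        annotated.append(SequenceRecord(pid, ann_seq))
        full.append(SequenceRecord(pid, full_seq))
        rows.append(ann_seq + "-" * (L - len(ann_seq)))
        ids.append(pid)
        truth[pid] = is_sec
    if 0 < cfg.sec_fraction and n_flag > cfg.n_proteins // 2:
        warnings.warn(
            "more than half the family is truncated: the consensus terminus "
            "shifts and alignment-based rescue is not expected to work"
        )
    return ReadthroughFixture(cds_records, annotated, full, TerminusAlignment(ids, rows), truth)
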