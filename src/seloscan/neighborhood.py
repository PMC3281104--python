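"""Genomic-neighbourhood COG census and enrichment.

For each genome carrying a focal gene (the SELO/ydiU homologue in the
motivating analysis) a fixed window of +/- half_width bp (default 11 kbp,
a 22-kbp window) is placed around the focal gene's midpoint. The census
records, per COG label, in how many windows at least one gene of that COG
occurs (presence, not gene count). Enrichment is an exact binomial upper
tail of k presences in n windows against a per-COG background window
probability estimated from reference genomes, Bonferroni-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from seloscan.stats import EnrichmentRow, bonferroni, log10_binomial_tail


@dataclass(frozen=True)
class GeneRecord:
    genome_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    cog_id: str | None = None

    def __post_init__(self):
        if not (0 < self.start <= self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}: {self.start}..{self.end}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class NeighbourhoodConfig:
    half_width: int = 11000
    exclude_focal_cog: bool = True
    circular: bool = False

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


def genes_from_frame(df: pd.DataFrame) -> dict[str, list[GeneRecord]]:
    """Group a gene table (see io.read_gene_table) into per-genome records."""
    genomes: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples(index=False):
        cog = None if pd.isna(row.cog_id) else str(row.cog_id)
        genomes.setdefault(str(row.genome_id), []).append(
            GeneRecord(str(row.genome_id), str(row.gene_id), int(row.start), int(row.end), str(row.strand), cog)
        )
    return genomes


def _overlaps(g: GeneRecord, lo: float, hi: float) -> bool:
    return g.start <= hi and g.end >= lo


def extract_neighbourhood(
    genes: Sequence[GeneRecord],
    focal: GeneRecord,
    cfg: NeighbourhoodConfig = NeighbourhoodConfig(),
    replicon_length: int | None = None,
) -> list[GeneRecord]:
    """Genes whose intervals overlap the window around the focal midpoint.

    The focal gene itself is excluded; strand is ignored. Windows are
    truncated at replicon ends unless cfg.circular, in which case overlap
    is evaluated modulo the replicon length.
    """
    if focal not in genes:
        raise ValueError(f"focal gene {focal.gene_id} not among the genome's genes")
    mid = focal.midpoint
    lo, hi = mid - cfg.half_width, mid + cfg.half_width
    members = []
    for g in genes:
        if g is focal or g == focal:
            continue
        hit = _overlaps(g, lo, hi)
        if not hit and cfg.circular:
            if replicon_length is None:
                raise ValueError("circular windows require a replicon length")
            hit = _overlaps(g, lo + replicon_length, hi + replicon_length) or _overlaps(
                g, lo - replicon_length, hi - replicon_length
            )
        if hit:
            members.append(g)
    return members


@dataclass
class WindowCensus:
    n_windows: int
    counts: dict[str, int] = field(default_factory=dict)  # COG -> presence count k

    def __post_init__(self):
        bad = {c: k for c, k in self.counts.items() if not 0 <= k <= self.n_windows}
        if bad:
            raise ValueError(f"presence counts outside [0, n_windows]: {bad}")


def neighbourhood_census(
    genomes: Mapping[str, Sequence[GeneRecord]],
    focal_selector: str | Callable[[GeneRecord], bool],
    cfg: NeighbourhoodConfig = NeighbourhoodConfig(),
) -> WindowCensus:
    """One window per focal gene; per COG, count windows where it occurs.

    `focal_selector` is a COG label or a predicate on GeneRecord. Genomes
    without a focal gene are skipped with a warning. Presence is binary
    per window: duplicated members of a COG never raise its count. The
    focal COG itself is excluded from the census when the config says so
    (only applicable with a label selector).
    """
    if isinstance(focal_selector, str):
        label = focal_selector
        select = lambda g: g.cog_id == label  # noqa: E731
        excluded = {label} if cfg.exclude_focal_cog else set()
    else:
        select = focal_selector
        excluded = set()
    counts: dict[str, int] = {}
    n_windows = 0
    for genome_id in sorted(genomes):
        genes = genomes[genome_id]
        focals = [g for g in genes if select(g)]
        if not focals:
            warnings.warn(f"genome {genome_id} has no focal gene; skipped")
            continue
        for focal in focals:
            n_windows += 1
            present = {
                m.cog_id
                for m in extract_neighbourhood(genes, focal, cfg)
                if m.cog_id is not None and m.cog_id not in excluded
            }
            for cog in present:
                counts[cog] = counts.get(cog, 0) + 1
    return WindowCensus(n_windows, counts)


@dataclass
class CogBackground:
    probs: dict[str, float]  # COG -> window-presence probability
    provenance: str  # "poisson" | "montecarlo"
    n_reference_genomes: int

    def prob(self, cog: str) -> float:
        """Window-presence probability; 0 with a warning for COGs absent
        from the reference genomes."""
        if cog not in self.probs:
            warnings.warn(f"COG {cog} absent from reference genomes: background 0")
            return 0.0
        return self.probs[cog]


def _replicon_lengths(
    genomes: Mapping[str, Sequence[GeneRecord]],
    lengths: Mapping[str, int] | None,
) -> dict[str, int]:
    out = {}
    for gid, genes in genomes.items():
        if lengths and gid in lengths:
            out[gid] = lengths[gid]
        else:
            out[gid] = max(g.end for g in genes)
    return out


def estimate_background(
    reference_genomes: Mapping[str, Sequence[GeneRecord]],
    cfg: NeighbourhoodConfig = NeighbourhoodConfig(),
    mode: str = "poisson",
    replicon_lengths: Mapping[str, int] | None = None,
    mc_reps: int = 10000,
    seed: int = 0,
) -> CogBackground:
    """Per-COG probability of presence in a random window of width 2*half_width.

    poisson: p_c = 1 - exp(-n_c * W / L_total), with n_c the COG's gene
    count across references, W the window width and L_total the summed
    replicon length (a Poisson approximation for uniformly placed genes).

    montecarlo: the empirical fraction of mc_reps seeded random windows
    (genomes chosen length-weighted, centres uniform) containing the COG.
    """
    if not reference_genomes:
        raise ValueError("empty reference genome set")
    lengths = _replicon_lengths(reference_genomes, replicon_lengths)
    l_total = sum(lengths.values())
    width = 2 * cfg.half_width
    if mode == "poisson":
        counts: dict[str, int] = {}
        for genes in reference_genomes.values():
            for g in genes:
                if g.cog_id is not None:
                    counts[g.cog_id] = counts.get(g.cog_id, 0) + 1
        probs = {c: 1.0 - math.exp(-n_c * width / l_total) for c, n_c in counts.items()}
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        gids = sorted(reference_genomes)
        weights = np.array([lengths[g] for g in gids], dtype=float)
        weights /= weights.sum()
        hits: dict[str, int] = {}
        choices = rng.choice(len(gids), size=mc_reps, p=weights)
        centres = rng.random(mc_reps)
        for idx, u in zip(choices, centres):
            gid = gids[idx]
            length = lengths[gid]
            # a region of the given size must fit inside the replicon
            if length > width:
                mid = cfg.half_width + u * (length - width)
            else:
                mid = length / 2.0
            lo, hi = mid - cfg.half_width, mid + cfg.half_width
            present = {
                g.cog_id
                for g in reference_genomes[gid]
                if g.cog_id is not None and _overlaps(g, lo, hi)
            }
            for c in present:
                hits[c] = hits.get(c, 0) + 1
        probs = {c: k / mc_reps for c, k in hits.items()}
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return CogBackground(probs, mode, len(reference_genomes))


def cog_enrichment(
    census: WindowCensus,
    bg: CogBackground,
    m_tested: int | None = None,
) -> tuple[list[EnrichmentRow], list[str]]:
    """Binomial enrichment of censused COGs against window backgrounds.

    Returns Bonferroni-corrected rows sorted by corrected tail, plus the
    list of COGs left unscored because their background is zero/absent
    (zero-background policy: refuse to test rather than pseudo-count).
    m_tested defaults to the number of distinct COGs censused.
    """
    unscored = []
    raw: list[EnrichmentRow] = []
    for cog in sorted(census.counts):
        k = census.counts[cog]
        p_c = bg.probs.get(cog, 0.0)
        if p_c <= 0.0:
            unscored.append(cog)
            continue
        lp = 0.0 if p_c >= 1.0 else log10_binomial_tail(k, census.n_windows, p_c)
        raw.append(EnrichmentRow(cog, k, census.n_windows, p_c, lp, lp, 1))
    if unscored:
        warnings.warn(f"{len(unscored)} COGs unscored (zero background)")
    m = m_tested if m_tested is not None else max(1, len(census.counts))
    rows = bonferroni(raw, max(m, len(raw)))
    rows.sort(key=lambda r: (r.log10_p_corrected, r.label))
    return rows, unscored
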