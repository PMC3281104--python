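"""Pipeline orchestration: stage wiring, presence summaries, manifests.

`run_pipeline` executes the full synthetic-cohort analysis — proteome
simulation, terminal-class census and motif enrichment, representative-set
reduction, neighbourhood COG enrichment, lifestyle enrichment, and Sec
misannotation rescue — writing every artefact as TSV/FASTA/JSON under an
output directory together with a machine-readable manifest of all
resolved parameters. Given the same config and seed the outputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from seloscan import io as sio
from seloscan import motifs, repset, sec_recovery, stats, synth
from seloscan import neighborhood as nbh


@dataclass(frozen=True)
class PresenceLine:
    label: str
    with_homolog: int
    total: int
    percent: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_presence(counts) -> list[PresenceLine]:
    """Integer presence percentages (half-up) from (label, with, total) rows."""
    out = []
    for label, with_homolog, total in counts:
        if total <= 0:
            raise ValueError(f"{label}: total must be positive")
        if not 0 <= with_homolog <= total:
            raise ValueError(f"{label}: count {with_homolog} outside [0, {total}]")
        out.append(PresenceLine(label, with_homolog, total, _round_half_up(100.0 * with_homolog / total)))
    return out


@dataclass
class RunConfig:
    """Resolved parameters for a full synthetic-cohort run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # proteome / motif stage
    n_seqs: int = 143
    terminal_spec: dict[str, float] = field(default_factory=lambda: {"CxxCxx>": 12 / 143, "Cxx>": 99 / 143})
    motif_background_count: int = 585
    motif_background_size: int = 500000
    # repset stage
    repset_threshold: float = 70.0
    # neighbourhood stage
    n_genomes: int = 60
    n_reference_genomes: int = 120
    planted_cogs: dict[str, float] = field(default_factory=lambda: {"COG0005": 0.9})
    half_width: int = 11000
    background_mode: str = "poisson"
    mc_reps: int = 10000
    m_tested: int | None = None
    # lifestyle stage
    n_orgs: int = 1250
    subset_size: int = 200
    trait_freqs: dict[str, float] = field(default_factory=lambda: {"aquatic": 0.16, "aerobic": 0.32})
    enriched: dict[str, float] = field(default_factory=lambda: {"aquatic": 0.47, "aerobic": 0.65})
    # sec rescue stage
    n_family: int = 143
    sec_fraction: float = 6 / 143

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config file (flat or nested one level); CLI overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, val in raw.items():
            if isinstance(val, Mapping) and key not in ("terminal_spec", "planted_cogs", "trait_freqs", "enriched"):
                flat.update(val)
            else:
                flat[key] = val
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


def _json_default(o):
    if isinstance(o, Path):
        return str(o)
    raise TypeError(type(o))


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage on seeded synthetic inputs; return the JSON summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataclasses.asdict(cfg)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    summary: dict[str, Any] = {"seed": cfg.seed}

    # --- proteome simulation + motif census -------------------------------
    pcfg = synth.SimProteomeConfig(
        n_seqs=cfg.n_seqs, terminal_spec=dict(cfg.terminal_spec), seed=cfg.seed
    )
    records, truth = synth.gen_proteome(pcfg)
    sio.write_fasta(records, out / "proteome.fasta")
    cens = motifs.census(records)
    classes = [(r.id, motifs.classify_terminus(r.seq)) for r in records]
    with open(out / "terminal_classes.tsv", "w") as fh:
        fh.write("seq_id\tinner\touter\tplanted\n")
        for (sid, tc) in classes:
            fh.write(f"{sid}\t{tc.inner.value}\t{tc.outer.value}\t{truth[sid]}\n")
    p_bg = stats.background_from_reference(cfg.motif_background_count, cfg.motif_background_size)
    motif_rows = []
    for pat_text in motifs.DEFAULT_CENSUS_PATTERNS:
        k = cens.k(pat_text)
        lp = stats.log10_binomial_tail(k, cens.n, p_bg)
        motif_rows.append(stats.EnrichmentRow(pat_text, k, cens.n, p_bg, lp, lp, 1))
    motif_rows = stats.bonferroni(motif_rows, len(motif_rows))
    stats.rows_to_frame(motif_rows).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    summary["motif"] = {
        "n": cens.n,
        "inner_counts": dict(cens.inner_counts),
        "k_cxxcuxx": cens.k("C-x-x-[CU]-x-x>"),
        "k_cu_xx": cens.k("[CU]-x-x>"),
        "log10_p_cxxcuxx": stats.log10_binomial_tail(cens.k("C-x-x-[CU]-x-x>"), cens.n, p_bg),
    }

    # --- representative set ------------------------------------------------
    rep = repset.greedy_reduce(records, cfg.repset_threshold)
    sio.write_fasta([r for r in records if r.id in set(rep.representatives)], out / "repset.fasta")
    with open(out / "repset_membership.tsv", "w") as fh:
        fh.write("seq_id\trepresentative\tidentity_pct\n")
        for sid, repr_id in sorted(rep.membership.items()):
            fh.write(f"{sid}\t{repr_id}\t{rep.identities[sid]:.2f}\n")
    summary["repset"] = {"n_input": len(records), "n_representatives": len(rep.representatives)}

    # --- neighbourhood enrichment ------------------------------------------
    gcfg = synth.SimGenomesConfig(
        n_genomes=cfg.n_genomes, planted=dict(cfg.planted_cogs), half_width=cfg.half_width, seed=cfg.seed
    )
    genomes, placed = synth.gen_genome_tables(gcfg)
    sio.write_gene_table(synth.genomes_to_frame(genomes), out / "genes.tsv")
    ref_cfg = dataclasses.replace(gcfg, n_genomes=cfg.n_reference_genomes, planted={}, seed=cfg.seed + 1)
    ref_genomes, _ = synth.gen_genome_tables(ref_cfg)
    ncfg = nbh.NeighbourhoodConfig(half_width=cfg.half_width)
    census_w = nbh.neighbourhood_census(genomes, gcfg.focal_cog, ncfg)
    bg = nbh.estimate_background(
        ref_genomes, ncfg, mode=cfg.background_mode, mc_reps=cfg.mc_reps, seed=cfg.seed
    )
    rows, unscored = nbh.cog_enrichment(census_w, bg, cfg.m_tested)
    stats.rows_to_frame(rows).to_csv(out / "neighbourhood_enrichment.tsv", sep="\t", index=False)
    top = rows[0] if rows else None
    summary["neighbourhood"] = {
        "n_windows": census_w.n_windows,
        "n_cogs_tested": len(rows),
        "n_unscored": len(unscored),
        "top_cog": top.label if top else None,
        "top_log10_p_corrected": top.log10_p_corrected if top else None,
        "planted_placed_rate": (
            sum(1 for s in placed.values() if s) / max(1, len(placed)) if cfg.planted_cogs else 0.0
        ),
    }

    # --- lifestyle enrichment ----------------------------------------------
    tcfg = synth.SimTraitConfig(
        n_orgs=cfg.n_orgs,
        trait_freqs=dict(cfg.trait_freqs),
        enriched=dict(cfg.enriched),
        subset_size=cfg.subset_size,
        seed=cfg.seed,
    )
    table, subset = synth.gen_trait_table(tcfg)
    sio.write_trait_table(table, out / "traits.tsv")
    trows, pairwise = stats.trait_enrichment(table, subset, dict(cfg.trait_freqs))
    stats.rows_to_frame(trows).to_csv(out / "lifestyle_enrichment.tsv", sep="\t", index=False)
    summary["lifestyle"] = {
        "top_trait": trows[0].label if trows else None,
        "rows": {r.label: r.log10_p_corrected for r in trows},
        "pairwise_fisher": {f"{a}|{b}": p for (a, b), p in pairwise.items()},
    }

    # --- sec rescue ---------------------------------------------------------
    rcfg = synth.SimReadthroughConfig(n_proteins=cfg.n_family, sec_fraction=cfg.sec_fraction, seed=cfg.seed)
    fixture = synth.gen_readthrough_cds(rcfg)
    calls = sec_recovery.call_family(fixture.annotated_proteins, fixture.cds_records, fixture.alignment)
    with open(out / "sec_recovery.tsv", "w") as fh:
        fh.write("protein_id\tverdict\tstop_codon\textension\n")
        for call, cds in zip(calls, fixture.cds_records):
            ext = call.extended_protein[-3:] if call.extended_protein else "."
            fh.write(f"{call.protein_id}\t{call.verdict}\t{cds.stop_codon}\t{ext}\n")
    rescued = [c for c in calls if c.verdict == "LIKELY_SEC"]
    sio.write_fasta(
        [sio.SequenceRecord(c.protein_id, c.extended_protein) for c in rescued],
        out / "sec_corrected.fasta",
    )
    n_true = sum(fixture.truth_flags.values())
    summary["sec_recovery"] = {
        "n_family": cfg.n_family,
        "n_truth": n_true,
        "n_called": len(rescued),
        "recall": (sum(1 for c in rescued if fixture.truth_flags[c.protein_id]) / n_true) if n_true else 1.0,
        "false_calls": sum(1 for c in rescued if not fixture.truth_flags[c.protein_id]),
    }

    # --- iTOL annotation of terminal classes --------------------------------
    sio.write_itol_colorstrip(
        {sid: tc.inner.value for sid, tc in classes}, sio.ITOL_INNER_COLOURS, out / "itol_inner_ring.tsv",
        dataset_label="inner_ring",
    )

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
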