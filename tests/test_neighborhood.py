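"""Window extraction, COG presence census, background estimation and
neighbourhood enrichment, against brute-force and simulation oracles."""

import math
import warnings

import numpy as np
import pytest

from seloscan import synth
from seloscan.neighborhood import (
    CogBackground,
    GeneRecord,
    NeighbourhoodConfig,
    WindowCensus,
    cog_enrichment,
    estimate_background,
    extract_neighbourhood,
    neighbourhood_census,
)


def g(gid, gene, start, end, cog=None):
    return GeneRecord(gid, gene, start, end, "+", cog)


class TestExtract:
    def test_gene_inside_window_is_member(self):
        focal = g("g", "f", 20000, 21000, "F")
        inside = g("g", "a", 15000, 15900, "A")
        members = extract_neighbourhood([focal, inside], focal)
        assert members == [inside]

    def test_one_bp_edge_overlap_is_member(self):
        focal = g("g", "f", 20000, 21000, "F")  # midpoint 20500, window 9500..31500
        edge = g("g", "a", 31500, 32400, "A")
        outside = g("g", "b", 31501, 32400, "B")
        assert extract_neighbourhood([focal, edge], focal) == [edge]
        assert extract_neighbourhood([focal, outside], focal) == []

    def test_focal_must_be_present(self):
        focal = g("g", "f", 100, 200)
        with pytest.raises(ValueError):
            extract_neighbourhood([g("g", "a", 1, 50)], focal)

    def test_random_layouts_match_bruteforce_overlap(self, rng):
        cfg = NeighbourhoodConfig(half_width=500)
        for _ in range(50):
            starts = np.sort(rng.integers(1, 20000, 30))
            genes = [g("g", f"x{i}", int(s), int(s + rng.integers(50, 400))) for i, s in enumerate(starts)]
            focal = genes[int(rng.integers(0, len(genes)))]
            got = {m.gene_id for m in extract_neighbourhood(genes, focal, cfg)}
            mid = (focal.start + focal.end) / 2
            want = {
                x.gene_id
                for x in genes
                if x is not focal and x.start <= mid + 500 and x.end >= mid - 500
            }
            assert got == want

    def test_circular_wraparound(self):
        cfg = NeighbourhoodConfig(half_width=5000, circular=True)
        focal = g("g", "f", 100, 1100, "F")  # window wraps below 1
        far = g("g", "a", 96000, 96900, "A")
        members = extract_neighbourhood([focal, far], focal, cfg, replicon_length=100000)
        assert members == [far]
        assert extract_neighbourhood([focal, far], focal, NeighbourhoodConfig(half_width=5000)) == []


class TestCensus:
    def test_forced_planting_gives_k_equal_n(self):
        cfg = synth.SimGenomesConfig(n_genomes=15, planted={"COG0007": 1.0}, seed=2)
        genomes, placed = synth.gen_genome_tables(cfg)
        assert all("COG0007" in s for s in placed.values())
        census = neighbourhood_census(genomes, cfg.focal_cog)
        assert census.counts["COG0007"] == census.n_windows == 15

    def test_empty_annotations(self):
        genes = [g("g", "f", 1000, 2000, "F"), g("g", "a", 2500, 3000, None)]
        census = neighbourhood_census({"g": genes}, "F")
        assert census.n_windows == 1 and census.counts == {}

    def test_presence_not_count(self):
        genes = [
            g("g", "f", 10000, 11000, "F"),
            g("g", "a", 12000, 12500, "C1"),
            g("g", "b", 13000, 13500, "C1"),
        ]
        census = neighbourhood_census({"g": genes}, "F")
        assert census.counts["C1"] == 1

    def test_focal_cog_excluded_by_default(self):
        genes = [g("g", "f", 10000, 11000, "F"), g("g", "f2", 12000, 12500, "F")]
        assert "F" not in neighbourhood_census({"g": genes}, "F").counts
        cfg = NeighbourhoodConfig(exclude_focal_cog=False)
        # two focal genes -> two windows, each containing the other focal
        assert neighbourhood_census({"g": genes}, "F", cfg).counts["F"] == 2

    def test_matches_per_window_bruteforce(self):
        cfg = synth.SimGenomesConfig(n_genomes=12, planted={"COG0003": 0.5}, seed=8)
        genomes, _ = synth.gen_genome_tables(cfg)
        ncfg = NeighbourhoodConfig(half_width=cfg.half_width)
        census = neighbourhood_census(genomes, cfg.focal_cog, ncfg)
        recount: dict[str, int] = {}
        for genes in genomes.values():
            focal = next(x for x in genes if x.cog_id == cfg.focal_cog)
            present = {
                x.cog_id
                for x in extract_neighbourhood(genes, focal, ncfg)
                if x.cog_id and x.cog_id != cfg.focal_cog
            }
            for c in present:
                recount[c] = recount.get(c, 0) + 1
        assert census.counts == recount

    def test_missing_focal_warns_and_skips(self):
        genomes = {
            "has": [g("has", "f", 10000, 11000, "F"), g("has", "a", 12000, 12500, "C1")],
            "lacks": [g("lacks", "a", 1000, 2000, "C1")],
        }
        with pytest.warns(UserWarning, match="lacks"):
            census = neighbourhood_census(genomes, "F")
        assert census.n_windows == 1

    def test_genome_order_invariance(self):
        cfg = synth.SimGenomesConfig(n_genomes=8, planted={"COG0002": 0.7}, seed=3)
        genomes, _ = synth.gen_genome_tables(cfg)
        reordered = dict(reversed(list(genomes.items())))
        assert neighbourhood_census(genomes, cfg.focal_cog).counts == \
            neighbourhood_census(reordered, cfg.focal_cog).counts


class TestBackground:
    def test_poisson_closed_form(self):
        # one genome of length L with n_c genes of COG c such that
        # n_c * W / L = ln 2  ->  presence probability exactly 0.5
        hw = 1000
        length = int(40 * 2 * hw / math.log(2))
        genes = [g("g", f"x{i}", 1 + i * (length // 40), 1 + i * (length // 40) + 99, "C1") for i in range(40)]
        bg = estimate_background({"g": genes}, NeighbourhoodConfig(half_width=hw),
                                 mode="poisson", replicon_lengths={"g": length})
        assert bg.probs["C1"] == pytest.approx(0.5, rel=1e-3)

    def test_absent_cog_zero_with_warning(self):
        genes = [g("g", "a", 100, 200, "C1")]
        bg = estimate_background({"g": genes})
        with pytest.warns(UserWarning, match="C9"):
            assert bg.prob("C9") == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            estimate_background({})

    def test_poisson_vs_montecarlo_agree(self):
        # genes placed uniformly at random (the placement model the Poisson
        # form assumes), short relative to the window, replicons much longer
        # than the window. The tolerance combines the Monte-Carlo standard
        # error with the between-genome configuration noise of the fixture:
        # the Poisson value is an ensemble mean, the fixture is one draw.
        rng = np.random.default_rng(42)
        n_genomes, n_genes, rep_len, vocab = 100, 200, 200_000, 25
        genomes = {}
        for gi in range(n_genomes):
            gid = f"u{gi:03d}"
            starts = rng.integers(1, rep_len - 100, n_genes)
            genomes[gid] = [
                g(gid, f"{gid}_{i}", int(s), int(s) + 99, f"C{rng.integers(0, vocab):02d}")
                for i, s in enumerate(np.sort(starts))
            ]
        ncfg = NeighbourhoodConfig(half_width=11000)
        lengths = {gid: rep_len for gid in genomes}
        pois = estimate_background(genomes, ncfg, mode="poisson", replicon_lengths=lengths)
        mc_reps = 30000
        mc = estimate_background(genomes, ncfg, mode="montecarlo",
                                 replicon_lengths=lengths, mc_reps=mc_reps, seed=1)
        for cog in sorted(pois.probs):
            p_mc = mc.probs.get(cog, 0.0)
            se_mc = math.sqrt(max(p_mc * (1 - p_mc), 1e-9) / mc_reps)
            # per-genome presence fractions are i.i.d. configuration draws
            per_genome = []
            for gg in genomes.values():
                centres = np.linspace(11000.0, rep_len - 11000.0, 400)
                cov = np.zeros_like(centres, dtype=bool)
                for x in gg:
                    if x.cog_id == cog:
                        cov |= (centres >= x.start - 11000) & (centres <= x.end + 11000)
                per_genome.append(cov.mean())
            se_cfg = np.std(per_genome, ddof=1) / math.sqrt(n_genomes)
            tol = 3 * math.sqrt(se_mc**2 + se_cfg**2)
            assert abs(pois.probs[cog] - p_mc) <= tol, (cog, pois.probs[cog], p_mc, tol)


class TestEnrichment:
    def test_planted_cog_ranks_first(self):
        cfg = synth.SimGenomesConfig(
            n_genomes=100, cog_vocab_size=400, planted={"PLANTED": 0.9}, seed=5
        )
        genomes, _ = synth.gen_genome_tables(cfg)
        ref_cfg = synth.SimGenomesConfig(n_genomes=150, cog_vocab_size=400, seed=105)
        refs, _ = synth.gen_genome_tables(ref_cfg)
        ncfg = NeighbourhoodConfig(half_width=cfg.half_width)
        census = neighbourhood_census(genomes, cfg.focal_cog, ncfg)
        bg = estimate_background(refs, ncfg, mode="poisson")
        bg.probs.setdefault("PLANTED", 1.0 - math.exp(-0.05))  # absent from refs
        rows, _ = cog_enrichment(census, bg)
        assert rows[0].label == "PLANTED"
        assert 10 ** rows[0].log10_p_corrected < 1e-6

    def test_zero_presence_census_gives_p_one(self):
        census = WindowCensus(10, {"C1": 0, "C2": 0})
        bg = CogBackground({"C1": 0.3, "C2": 0.5}, "poisson", 1)
        rows, _ = cog_enrichment(census, bg)
        assert all(r.log10_p_raw == 0.0 for r in rows)

    def test_zero_background_unscored(self):
        census = WindowCensus(10, {"C1": 4, "C2": 2})
        bg = CogBackground({"C1": 0.3}, "poisson", 1)
        with pytest.warns(UserWarning):
            rows, unscored = cog_enrichment(census, bg)
        assert unscored == ["C2"]
        assert [r.label for r in rows] == ["C1"]

    def test_null_type_i_error_controlled(self):
        # pooled raw p<0.05 rate over null replicates stays within binomial
        # tolerance of the nominal level
        ref_cfg = synth.SimGenomesConfig(n_genomes=100, genes_per_genome=120,
                                         cog_vocab_size=30, seed=999)
        refs, _ = synth.gen_genome_tables(ref_cfg)
        ncfg = NeighbourhoodConfig()
        bg = estimate_background(refs, ncfg, mode="montecarlo", mc_reps=40000, seed=7)
        n_rep, hits, total = 300, 0, 0
        for rep in range(n_rep):
            cfg = synth.SimGenomesConfig(n_genomes=12, genes_per_genome=120,
                                         cog_vocab_size=30, seed=10_000 + rep)
            genomes, _ = synth.gen_genome_tables(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                census = neighbourhood_census(genomes, cfg.focal_cog, ncfg)
                rows, _ = cog_enrichment(census, bg)
            hits += sum(1 for r in rows if 10 ** r.log10_p_raw < 0.05)
            total += len(rows)
        rate = hits / total
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total)
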