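#!/usr/bin/env python
"""Lifestyle enrichment of the focal-gene-bearing organism subset.

Tests each binary trait with the one-sided exact binomial against its
background frequency (aquatic 0.16, aerobic 0.32) and runs pairwise
Fisher independence tests among the significant traits.
"""

import argparse
from pathlib import Path

from seloscan import io as sio
from seloscan import stats

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

table = sio.read_trait_table(args.data / "traits.tsv")
selected = [l.strip() for l in open(args.data / "selected_organisms.txt") if l.strip()]
rows, pairwise = stats.trait_enrichment(
    table, selected, {"aquatic": 0.16, "aerobic": 0.32}
)
stats.rows_to_frame(rows).to_csv(args.outdir / "lifestyle_enrichment.tsv",
                                 sep="\t", index=False)
for r in rows:
    print(f"{r.label}: {r.k}/{r.n} observed ({r.k / r.n:.0%}) vs background "
          f"{r.p_bg:.0%}, log10 p corrected = {r.log10_p_corrected:.2f}")
for (a, b), p in pairwise.items():
    print(f"Fisher independence {a} vs {b}: p = {p:.3f}")
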