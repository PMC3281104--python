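"""Exact enrichment statistics in log space.

The overrepresentation tests are one-sided exact binomial upper tails,
P(X >= k) with X ~ Binomial(n, p_bg). The observed tails are extreme
(down to below 1e-189 for the [CU]xx> census), so everything is evaluated
in log space with a log-sum-exp over log-gamma terms: the result is a
log10 tail probability that is stable far beyond double underflow.

Fisher's exact test (two-sided, probability-mass method) and Bonferroni
correction are provided for the lifestyle analysis, plus a composition
model for expected anchored-motif counts in a reference database.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact as _scipy_fisher

from seloscan.motifs import Fixed, MotifPattern, Range, Wildcard

LOG10_E = math.log10(math.e)


@dataclass(frozen=True)
class BinomTailResult:
    k: int
    n: int
    p_bg: float
    log10_p: float

    def sci(self) -> str:
        """Scientific-notation rendering, e.g. '4.1E-19'."""
        if self.log10_p == 0.0:
            return "1.0E+00"
        exp10 = math.floor(self.log10_p)
        mant = 10 ** (self.log10_p - exp10)
        return f"{mant:.1f}E{exp10:+03d}"


def log10_binomial_tail(k: int, n: int, p_bg: float) -> float:
    """log10 of the exact binomial upper tail P(X >= k), X ~ Bin(n, p_bg).

    Evaluated as a log-sum-exp over per-term log probabilities
    ``lgamma(n+1) - lgamma(i+1) - lgamma(n-i+1) + i log p + (n-i) log1p(-p)``
    so there is no underflow for tails down to 1e-500 and beyond.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p_bg < 1.0):
        raise ValueError(f"background probability must be in (0,1), got {p_bg}")
    if k == 0:
        return 0.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p_bg)
        + (n - i) * math.log1p(-p_bg)
    )
    return float(min(0.0, logsumexp(log_terms) * LOG10_E))


def binomial_tail(k: int, n: int, p_bg: float) -> BinomTailResult:
    return BinomTailResult(k, n, p_bg, log10_binomial_tail(k, n, p_bg))


def background_from_reference(count_in_ref: int, ref_size: int) -> float:
    """Background probability as count / reference-database size.

    A zero count returns 0.0 with a warning; the caller decides any
    pseudo-count policy (the default policy elsewhere is to refuse to
    test zero-background labels).
    """
    if ref_size <= 0:
        raise ValueError("reference size must be positive")
    if not (0 <= count_in_ref <= ref_size):
        raise ValueError("count must be between 0 and the reference size")
    if count_in_ref == 0:
        warnings.warn("zero count in reference: background probability is 0")
        return 0.0
    return count_in_ref / ref_size


@dataclass(frozen=True)
class CompositionModel:
    """Average residue composition of a reference database of N sequences."""

    frequencies: Mapping[str, float]
    n_sequences: int

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative residue frequency")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {total}, not 1")

    def class_prob(self, residues: frozenset) -> float:
        return sum(self.frequencies.get(r, 0.0) for r in residues)


def _match_prob(p: MotifPattern, comp: CompositionModel) -> float:
    """Per-sequence probability of an anchored pattern under i.i.d.
    composition; with bounded gaps, independence across gap choices."""
    ranges = [e for e in p.elements if isinstance(e, Range)]
    base = 1.0
    for e in p.elements:
        if isinstance(e, Fixed):
            base *= comp.class_prob(e.residues)
        # wildcards and ranges contribute 1 to the fixed-position product
    if not ranges:
        return base
    # one miss factor per gap assignment, independence across assignments
    miss = 1.0
    for _combo in itertools.product(*(range(r.min, r.max + 1) for r in ranges)):
        miss *= 1.0 - base
    return 1.0 - miss


def expected_count(p: MotifPattern, comp: CompositionModel) -> float:
    """Expected number of sequences in the reference matching an anchored
    pattern, N x per-sequence match probability."""
    if not p.anchored:
        raise ValueError("expected_count supports anchored patterns only")
    return comp.n_sequences * _match_prob(p, comp)


@dataclass(frozen=True)
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_exact(t: Contingency2x2) -> float:
    """Two-sided Fisher's exact p: the sum of hypergeometric probabilities
    of tables (margins fixed) at most as probable as the observed one."""
    if min(t.margins) <= 0:
        raise ValueError(f"degenerate margins {t.margins}")
    return float(_scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided").pvalue)


def bonferroni_log10(log10_p_raw: float, m_tested: int) -> float:
    """Bonferroni correction on the log10 scale: min(0, log10 p + log10 m)."""
    if m_tested < 1:
        raise ValueError("m_tested must be >= 1")
    return min(0.0, log10_p_raw + math.log10(m_tested))


@dataclass
class EnrichmentRow:
    label: str
    k: int
    n: int
    p_bg: float
    log10_p_raw: float
    log10_p_corrected: float
    m_tested: int


def bonferroni(rows: Iterable[EnrichmentRow], m_tested: int) -> list[EnrichmentRow]:
    """Apply Bonferroni correction to raw rows, on the log scale."""
    rows = list(rows)
    if m_tested < len(rows):
        raise ValueError("m_tested must cover all tested hypotheses")
    return [
        EnrichmentRow(
            r.label, r.k, r.n, r.p_bg, r.log10_p_raw,
            bonferroni_log10(r.log10_p_raw, m_tested), m_tested,
        )
        for r in rows
    ]


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "k": r.k,
                "n": r.n,
                "p_bg": r.p_bg,
                "log10_p_raw": r.log10_p_raw,
                "log10_p_corrected": r.log10_p_corrected,
                "m_tested": r.m_tested,
            }
            for r in rows
        ]
    )


def trait_enrichment(
    traits: pd.DataFrame,
    selected: Iterable[str],
    backgrounds: Mapping[str, float],
    m_tested: int | None = None,
    fisher_alpha: float = 0.05,
) -> tuple[list[EnrichmentRow], dict[tuple[str, str], float]]:
    """Lifestyle-style trait enrichment among a selected organism subset.

    For each trait, k is the number of trait-positive selected organisms
    and n the number of selected organisms with a non-missing value; the
    one-sided binomial upper tail is taken against the supplied background
    frequency. Traits with background 0 are skipped with a warning
    (zero-background policy); background 1 gives a tail of exactly 1.
    Rows are Bonferroni-corrected and sorted by corrected tail; pairwise
    Fisher independence tests are run among significant traits.
    """
    selected = [s for s in selected]
    missing = set(selected) - set(traits.index)
    if missing:
        raise ValueError(f"selected organisms absent from table: {sorted(missing)[:5]}")
    sub = traits.loc[selected]
    raw: list[EnrichmentRow] = []
    for trait, p_bg in backgrounds.items():
        if trait not in traits.columns:
            warnings.warn(f"trait {trait!r} not in table; skipped")
            continue
        col = sub[trait].dropna()
        n = int(col.shape[0])
        if n == 0:
            warnings.warn(f"trait {trait!r} missing for all selected organisms; skipped")
            continue
        k = int((col == 1).sum())
        if p_bg == 0.0:
            warnings.warn(f"trait {trait!r} has zero background; skipped")
            continue
        lp = 0.0 if p_bg >= 1.0 else log10_binomial_tail(k, n, p_bg)
        raw.append(EnrichmentRow(trait, k, n, p_bg, lp, lp, 1))
    m = m_tested if m_tested is not None else max(1, len(raw))
    rows = bonferroni(raw, m)
    rows.sort(key=lambda r: (r.log10_p_corrected, r.label))
    sig = [r.label for r in rows if 10 ** r.log10_p_corrected < fisher_alpha]
    pairwise: dict[tuple[str, str], float] = {}
    for t1, t2 in itertools.combinations(sig, 2):
        both = sub[[t1, t2]].dropna()
        a = int(((both[t1] == 1) & (both[t2] == 1)).sum())
        b = int(((both[t1] == 1) & (both[t2] == 0)).sum())
        c = int(((both[t1] == 0) & (both[t2] == 1)).sum())
        d = int(((both[t1] == 0) & (both[t2] == 0)).sum())
        tab = Contingency2x2(a, b, c, d)
        if min(tab.margins) > 0:
            pairwise[(t1, t2)] = fisher_exact(tab)
    return rows, pairwise
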