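"""Anchored PROSITE-style motif matching and C-terminal class census.

The SELO family carries a thioredoxin-like Cys/Sec motif at the extreme
C-terminus, written in anchored pattern notation with a trailing ``>``
(e.g. ``C-x-x-[CU]-x-x>``, matched by the human terminus ``CVTUSS``).
Sequences are classified into two concentric "ring" categories:

- inner ring: the residue three positions before the terminus is Sec
  (``Uxx>``), Cys (``Cxx>``), or neither;
- outer ring: an additional upstream cysteine forming ``CxxCxx>``,
  ``CxCxx>`` or ``Cx(3,10)Cxx>``, where the bracketed position admits
  Cys or Sec.

A selenocysteine ``U`` satisfies a ``[CU]`` class but never a bare ``C``
element: the census keeps Cys- and Sec-terminated proteins distinct.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from seloscan.io import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "U")

WILDCARD = "WILDCARD"


@dataclass(frozen=True)
class Fixed:
    residues: frozenset

    def __post_init__(self):
        bad = self.residues - ALPHABET
        if bad:
            raise MotifParseError(f"unknown residues in class: {sorted(bad)}")
        if not self.residues:
            raise MotifParseError("empty residue class")


@dataclass(frozen=True)
class Wildcard:
    pass


@dataclass(frozen=True)
class Range:
    min: int
    max: int

    def __post_init__(self):
        if not (0 <= self.min <= self.max):
            raise MotifParseError(f"malformed range x({self.min},{self.max})")


Element = Fixed | Wildcard | Range


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[Element, ...]
    anchored: bool

    def __post_init__(self):
        if not self.elements:
            raise MotifParseError("pattern has no elements")

    @property
    def min_span(self) -> int:
        return sum(e.min if isinstance(e, Range) else 1 for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max if isinstance(e, Range) else 1 for e in self.elements)


def parse_pattern(text: str) -> MotifPattern:
    """Parse a PROSITE-like pattern string.

    Syntax: residue letters (including ``U``), ``[..]`` residue classes,
    ``x`` wildcards, ``x(m,n)`` / ``x(n)`` bounded gaps, optional ``-``
    separators, and a trailing ``>`` anchoring the last element at the
    C-terminus. Case-insensitive.
    """
    if not text or not text.strip():
        raise MotifParseError("empty pattern")
    s = text.strip().upper().replace("-", "")
    anchored = s.endswith(">")
    if anchored:
        s = s[:-1]
    if not s:
        raise MotifParseError(f"pattern {text!r} has no elements")
    elements: list[Element] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise MotifParseError(f"unclosed class in {text!r}")
            elements.append(Fixed(frozenset(s[i + 1 : j])))
            i = j + 1
        elif ch == "X":
            if i + 1 < len(s) and s[i + 1] == "(":
                j = s.find(")", i)
                if j < 0:
                    raise MotifParseError(f"unclosed range in {text!r}")
                body = s[i + 2 : j]
                try:
                    if "," in body:
                        lo, hi = (int(v) for v in body.split(","))
                    else:
                        lo = hi = int(body)
                except ValueError as exc:
                    raise MotifParseError(f"malformed range {body!r} in {text!r}") from exc
                elements.append(Range(lo, hi))
                i = j + 1
            else:
                elements.append(Wildcard())
                i += 1
        elif ch in ALPHABET:
            elements.append(Fixed(frozenset(ch)))
            i += 1
        else:
            raise MotifParseError(f"unknown character {ch!r} in {text!r}")
    return MotifPattern(tuple(elements), anchored)


def render_pattern(p: MotifPattern) -> str:
    """Canonical string form; ``parse_pattern(render_pattern(p)) == p``."""
    parts = []
    for e in p.elements:
        if isinstance(e, Wildcard):
            parts.append("x")
        elif isinstance(e, Range):
            parts.append(f"x({e.min})" if e.min == e.max else f"x({e.min},{e.max})")
        else:
            rs = "".join(sorted(e.residues))
            parts.append(rs if len(rs) == 1 else f"[{rs}]")
    return "-".join(parts) + (">" if p.anchored else "")


def _clean(seq: str) -> str:
    s = seq.upper()
    if s.endswith("*") or s.endswith(">"):
        warnings.warn(f"stripping trailing stop character from sequence ending {s[-5:]!r}")
        s = s.rstrip("*>")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"residues outside the 21-letter alphabet: {sorted(bad)}")
    return s


def _elem_matches(e: Element, residue: str) -> bool:
    if isinstance(e, Wildcard):
        return True
    return residue in e.residues  # Fixed


def _cover_exact(elements: tuple[Element, ...], s: str, j: int, i: int) -> bool:
    """True if elements[j:] can consume exactly s[i:]."""
    if j == len(elements):
        return i == len(s)
    e = elements[j]
    if isinstance(e, Range):
        for g in range(e.min, min(e.max, len(s) - i) + 1):
            if _cover_exact(elements, s, j + 1, i + g):
                return True
        return False
    if i < len(s) and _elem_matches(e, s[i]):
        return _cover_exact(elements, s, j + 1, i + 1)
    return False


def _cover_prefix(elements: tuple[Element, ...], s: str, j: int, i: int) -> bool:
    """True if elements[j:] can consume some prefix of s[i:]."""
    if j == len(elements):
        return True
    e = elements[j]
    if isinstance(e, Range):
        for g in range(e.min, min(e.max, len(s) - i) + 1):
            if _cover_prefix(elements, s, j + 1, i + g):
                return True
        return False
    if i < len(s) and _elem_matches(e, s[i]):
        return _cover_prefix(elements, s, j + 1, i + 1)
    return False


def matches(p: MotifPattern, seq: str) -> bool:
    """True iff the pattern covers a suffix (anchored) or any substring
    (unanchored) of the sequence, for some assignment of range lengths."""
    s = _clean(seq)
    if not s:
        raise ValueError("empty sequence")
    if p.anchored:
        lo = max(0, len(s) - p.max_span)
        hi = len(s) - p.min_span
        return any(_cover_exact(p.elements, s, 0, t) for t in range(lo, hi + 1))
    return any(_cover_prefix(p.elements, s, 0, t) for t in range(0, len(s) - p.min_span + 1))


class InnerClass(str, Enum):
    U_TERM = "U_TERM"
    C_TERM = "C_TERM"
    NONE = "NONE"


class OuterClass(str, Enum):
    CXXC = "CXXC"
    CXC = "CXC"
    CX_RANGE_C = "CX_RANGE_C"
    NONE = "NONE"


@dataclass(frozen=True)
class TerminalClass:
    inner: InnerClass
    outer: OuterClass


# ring patterns; outer precedence is smallest upstream gap first
PAT_INNER_CU = parse_pattern("[CU]-x-x>")
PAT_INNER_C = parse_pattern("C-x-x>")
PAT_INNER_U = parse_pattern("U-x-x>")
PAT_CXXC = parse_pattern("C-x-x-[CU]-x-x>")
PAT_CXC = parse_pattern("C-x-[CU]-x-x>")
PAT_CXRANGEC = parse_pattern("C-x(3,10)-[CU]-x-x>")

_OUTER_ORDER = [
    (OuterClass.CXXC, PAT_CXXC),
    (OuterClass.CXC, PAT_CXC),
    (OuterClass.CX_RANGE_C, PAT_CXRANGEC),
]

#: classify_terminus only inspects this many terminal residues
TERMINAL_WINDOW = 14  # C + x(10) + [CU] + x + x

MIN_CLASSIFY_LEN = 13


def classify_terminus(seq: str) -> TerminalClass:
    """Assign the inner/outer ring category of a protein C-terminus.

    The inner class is read off the residue at position −3 from the
    terminus; the outer class is the smallest-gap upstream-Cys pattern
    that matches, and is only assigned when the inner class is non-NONE.
    """
    s = _clean(seq)
    if len(s) < MIN_CLASSIFY_LEN:
        raise ValueError(f"sequence too short to classify ({len(s)} < {MIN_CLASSIFY_LEN})")
    tail = s[-TERMINAL_WINDOW:]
    res = tail[-3]
    if res == "U":
        inner = InnerClass.U_TERM
    elif res == "C":
        inner = InnerClass.C_TERM
    else:
        inner = InnerClass.NONE
    outer = OuterClass.NONE
    if inner is not InnerClass.NONE:
        for label, pat in _OUTER_ORDER:
            if matches(pat, tail):
                outer = label
                break
    return TerminalClass(inner, outer)


DEFAULT_CENSUS_PATTERNS = (
    "[CU]-x-x>",
    "C-x-x>",
    "U-x-x>",
    "C-x-x-[CU]-x-x>",
    "C-x-[CU]-x-x>",
    "C-x(3,10)-[CU]-x-x>",
)


@dataclass
class MotifCensus:
    n: int
    inner_counts: Counter = field(default_factory=Counter)
    outer_counts: Counter = field(default_factory=Counter)
    pattern_counts: dict[str, int] = field(default_factory=dict)

    def k(self, pattern_text: str) -> int:
        return self.pattern_counts[render_pattern(parse_pattern(pattern_text))]


def census(
    records: Iterable[SequenceRecord],
    patterns: Sequence[str] = DEFAULT_CENSUS_PATTERNS,
) -> MotifCensus:
    """Count terminal-class membership and per-pattern matches.

    Per-pattern counts are counts of *sequences* matching (anchored
    motifs occur at most once per sequence). Input errors are collected
    and reported together with the offending identifiers.
    """
    pats = [(render_pattern(parse_pattern(t)), parse_pattern(t)) for t in patterns]
    out = MotifCensus(n=0, pattern_counts={canon: 0 for canon, _ in pats})
    errors = []
    for rec in records:
        try:
            tc = classify_terminus(rec.seq)
        except ValueError as exc:
            errors.append(f"{rec.id}: {exc}")
            continue
        out.n += 1
        out.inner_counts[tc.inner.value] += 1
        out.outer_counts[tc.outer.value] += 1
        for canon, pat in pats:
            if matches(pat, rec.seq):
                out.pattern_counts[canon] += 1
    if errors:
        raise ValueError("unclassifiable sequences: " + "; ".join(errors))
    return out


# ---------------------------------------------------------------------------
# kinase fingerprint

FINGERPRINT_SLOTS = (
    ("G_LOOP", "G-x-x-G-x-G"),
    ("BETA3_K", "K"),
    ("ALPHAC_E", "E"),
    ("CAT_LOOP", "[HQ]-G-[VNS]"),
    ("MG_N", "N"),
    ("DFG", "D-[YF]-G"),
)

ABSENT = None


@dataclass
class FingerprintReport:
    """Ordered motif hits; positions are 1-based starts, ABSENT (None) when
    a slot cannot be placed after its predecessor."""

    hits: dict[str, tuple[int, int] | None]

    def positions(self) -> list[int]:
        return [h[0] for h in self.hits.values() if h is not None]


@lru_cache(maxsize=64)
def _fixed_elems(text: str) -> tuple[Element, ...]:
    return parse_pattern(text + ">").elements


def _find_earliest(elems: tuple[Element, ...], s: str, start: int) -> tuple[int, int] | None:
    span = len(elems)  # fingerprint motifs are range-free
    for t in range(start, len(s) - span + 1):
        if all(_elem_matches(e, s[t + off]) for off, e in enumerate(elems)):
            return t, t + span
    return None


def annotate_kinase_fingerprint(seq: str) -> FingerprintReport:
    """Locate the ordered kinase-domain fingerprint: glycine-rich loop
    (GxxGxG), β3 lysine, αC glutamate, catalytic-loop variant ([HQ]G[VNS],
    e.g. HGV replacing the canonical HRD), Mg-binding asparagine, and the
    strictly conserved ion-binding D[YF]G.

    Search is greedy-earliest with slots required to appear in order and
    without overlap; a slot that cannot be placed after its predecessor is
    reported ABSENT, as is every later slot that then fails to fit.
    """
    s = _clean(seq)
    if len(s) < 50:
        raise ValueError(f"sequence too short for fingerprint annotation ({len(s)} < 50)")
    hits: dict[str, tuple[int, int] | None] = {}
    cursor = 0
    for name, text in FINGERPRINT_SLOTS:
        found = _find_earliest(_fixed_elems(text), s, cursor)
        if found is None:
            hits[name] = ABSENT
        else:
            hits[name] = (found[0] + 1, found[1])  # 1-based inclusive
            cursor = found[1]
    return FingerprintReport(hits)


# ---------------------------------------------------------------------------
# per-column conservation (logo input)

MAX_IC_BITS = math.log2(20)

GAP_CHARS = frozenset("-.")


@dataclass
class ConservationProfile:
    frequencies: list[dict[str, float]]  # per column, over observed residues
    information_bits: np.ndarray  # log2(20) - Shannon entropy
    gap_fraction: np.ndarray
    flagged_gappy: np.ndarray  # columns with >50% gaps


def column_conservation(alignment: Sequence[str]) -> ConservationProfile:
    """Per-column residue frequencies and information content in bits.

    Gaps are excluded from each column's distribution; columns with more
    than 50% gaps are flagged. IC is clamped to [0, log2(20)] (a column
    containing Sec can nominally exceed 20 states).
    """
    rows = [r.upper() for r in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    ncol = len(rows[0])
    freqs: list[dict[str, float]] = []
    ic = np.zeros(ncol)
    gapf = np.zeros(ncol)
    for j in range(ncol):
        col = [r[j] for r in rows]
        residues = [c for c in col if c not in GAP_CHARS]
        gapf[j] = 1.0 - len(residues) / len(col)
        if not residues:
            freqs.append({})
            ic[j] = 0.0
            continue
        counts = Counter(residues)
        f = {res: c / len(residues) for res, c in counts.items()}
        freqs.append(f)
        entropy = -sum(v * math.log2(v) for v in f.values())
        ic[j] = min(MAX_IC_BITS, max(0.0, MAX_IC_BITS - entropy))
    return ConservationProfile(freqs, ic, gapf, gapf > 0.5)
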