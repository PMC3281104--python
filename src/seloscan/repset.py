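"""Pairwise global percent identity and greedy redundancy reduction.

Representative sets are built the CD-HIT way: sequences are visited
longest-first and become representatives unless they reach the identity
threshold against an existing representative, in which case they are
assigned to the representative they match best.

Percent identity is defined on an optimal global alignment (match +1,
mismatch 0, linear gap -1 by default) as 100 x identical columns /
alignment length, gap columns included in the denominator. Because
co-optimal alignments can differ in their identity, the alignment is
chosen to maximise, lexicographically, (alignment score, identical
columns, -alignment length); this makes the identity value a
well-defined, symmetric function of the sequence pair. The lexicographic
optimum is obtained with a single standard dynamic program by folding
the three objectives into one integer score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from seloscan.io import SequenceRecord

# weights folding (score, identities, -length) into one integer; unique
# decomposition requires alignment length < _BIG2 and |score| bounded
_BIG2 = 1 << 14
_BIG1 = _BIG2 * _BIG2
MAX_LEN = _BIG2 // 2 - 1


@dataclass(frozen=True)
class IdentityParams:
    match: int = 1
    mismatch: int = 0
    gap: int = -1  # linear gap; set gap_open for affine
    gap_open: int | None = None

    def __post_init__(self):
        if self.gap > 0:
            raise ValueError("gap penalty must be <= 0")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")


def _make_aligner(params: IdentityParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # every column also contributes (+_BIG2 if identical, -1 for length)
    aligner.match_score = params.match * _BIG1 + _BIG2 - 1
    aligner.mismatch_score = params.mismatch * _BIG1 - 1
    extend = params.gap * _BIG1 - 1
    if params.gap_open is not None:
        aligner.open_gap_score = params.gap_open * _BIG1 - 1
        aligner.extend_gap_score = extend
    else:
        aligner.gap_score = extend
    return aligner


def global_identity(a: str, b: str, params: IdentityParams = IdentityParams()) -> float:
    """Percent identity of the lexicographically optimal global alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    if max(len(a), len(b)) > MAX_LEN:
        raise ValueError(f"sequences longer than {MAX_LEN} are not supported")
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(a.upper(), b.upper())))
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class RepSetResult:
    representatives: list[str]
    membership: dict[str, str]  # removed id -> representative id
    threshold_pct: float
    identities: dict[str, float] = field(default_factory=dict)  # removed id -> identity


def greedy_reduce(
    records: Sequence[SequenceRecord],
    threshold_pct: float = 70.0,
    params: IdentityParams = IdentityParams(),
) -> RepSetResult:
    """Greedy redundancy removal at an identity threshold.

    Sequences are processed longest-first (ties by identifier); a
    sequence joins the representative with which it shares the highest
    identity >= threshold, otherwise it founds a new representative.
    Output invariants (no over-threshold representative pair; every
    member at or above threshold to its representative) are asserted.
    """
    if not records:
        raise ValueError("need at least one sequence")
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence identifiers")
    order = sorted(records, key=lambda r: (-len(r.seq), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    identities: dict[str, float] = {}
    for rec in order:
        best_rep, best_ident = None, -1.0
        for rep in reps:
            ident = global_identity(rec.seq, rep.seq, params)
            if ident >= threshold_pct and ident > best_ident:
                best_rep, best_ident = rep, ident
        if best_rep is None:
            reps.append(rec)
        else:
            membership[rec.id] = best_rep.id
            identities[rec.id] = best_ident
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            ident = global_identity(reps[i].seq, reps[j].seq, params)
            assert ident < threshold_pct, (
                f"representatives {reps[i].id}/{reps[j].id} at {ident:.1f}% identity"
            )
    assert set(membership) | {r.id for r in reps} == set(ids)
    return RepSetResult([r.id for r in reps], membership, threshold_pct, identities)
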