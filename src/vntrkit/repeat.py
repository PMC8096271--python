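"""Cyclic (wraparound) alignment of sequences against tandem-repeat patterns.

The central primitive is a local alignment of a query sequence against the
infinite cyclic extension ``pattern^∞`` of a short repeat pattern.  The
dynamic-programming matrix has one column per pattern position, indexed
modulo the pattern length, so an alignment may begin at any phase of the
pattern and may wrap around it arbitrarily many times.  The number of
pattern positions consumed along the optimal path, divided by the pattern
length, is the (fractional) number of pattern copies spanned by the query —
the quantity used both to genotype repeat arrays from short reads and to
confirm predicted alleles from long reads.

Scoring is +2 for a match, −5 for a mismatch and −7 per gapped base
(linear gaps).  ``N`` scores as a mismatch against every base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ScoringScheme",
    "WraparoundAlignment",
    "ReadTR",
    "wraparound_align",
    "copy_number",
    "is_genotypable",
    "detectable_cgl_range",
    "canonical_pattern",
    "match_read_to_locus",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: positive match, negative mismatch and per-base gap."""

    match: int = 2
    mismatch: int = -5
    gap: int = -7

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch and 0 > self.gap):
            raise ValueError("require match > 0 > mismatch and 0 > gap")


@dataclass
class WraparoundAlignment:
    """Result of a local wraparound alignment.

    ``path`` is a string over {M, I, D}: M consumes one query and one
    pattern base (match or mismatch), I consumes a query base only (gap in
    the pattern), D consumes a pattern base only (gap in the query).
    ``copies`` is pattern positions consumed (M + D) / pattern length.
    """

    score: int
    copies: float
    seq_start: int
    seq_end: int
    path: str = field(repr=False, default="")

    @property
    def pattern_consumed(self) -> int:
        return sum(1 for op in self.path if op in "MD")


def wraparound_align(
    seq: str, pattern: str, scoring: ScoringScheme = ScoringScheme()
) -> WraparoundAlignment:
    """Optimal local alignment of ``seq`` against the cyclic extension of ``pattern``.

    Columns are indexed modulo the pattern length; the within-row horizontal
    (gap-in-query) recurrence therefore wraps, and is resolved by two
    relaxation sweeps around the row — sufficient because every gapped base
    costs ``scoring.gap`` < 0, so no optimal gap run spans a full pattern
    cycle.  Ties prefer match/mismatch over gaps, and earlier query starts.
    """
    seq = seq.upper()
    pattern = pattern.upper()
    if not seq or not pattern:
        raise ValueError("seq and pattern must be non-empty")
    for s, name in ((seq, "seq"), (pattern, "pattern")):
        if any(c not in "ACGTN" for c in s):
            raise ValueError(f"{name} contains characters outside ACGTN")

    n, p = len(seq), len(pattern)
    ma, mi, g = scoring.match, scoring.mismatch, scoring.gap

    # pointer codes: 0 = start (score floored at 0), 1 = M, 2 = I (vertical),
    # 3 = D (horizontal)
    ptr_rows: list[bytearray] = [bytearray(p)]
    prev = [0] * p
    best_score, best_i, best_j = 0, 0, 0

    for i in range(1, n + 1):
        q = seq[i - 1]
        cur = [0] * p
        ptr = bytearray(p)
        for j in range(p):
            sub = ma if (q == pattern[j] and q != "N") else mi
            diag = prev[j - 1] + sub  # j-1 == -1 wraps to column p-1
            vert = prev[j] + g
            if diag >= vert:
                if diag > 0:
                    cur[j] = diag
                    ptr[j] = 1
            elif vert > 0:
                cur[j] = vert
                ptr[j] = 2
        # horizontal wrap relaxation: two sweeps around the cyclic row
        for _ in range(2):
            changed = False
            for j in range(p):
                cand = cur[j - 1] + g
                if cand > cur[j]:
                    cur[j] = cand
                    ptr[j] = 3
                    changed = True
            if not changed:
                break
        ptr_rows.append(ptr)
        for j in range(p):
            if cur[j] > best_score:
                best_score, best_i, best_j = cur[j], i, j
        prev = cur

    if best_score <= 0:
        return WraparoundAlignment(0, 0.0, 0, 0, "")

    # traceback
    ops: list[str] = []
    i, j = best_i, best_j
    while i > 0:
        code = ptr_rows[i][j]
        if code == 0:
            break
        if code == 1:
            ops.append("M")
            i -= 1
            j = (j - 1) % p
        elif code == 2:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j = (j - 1) % p
    ops.reverse()
    path = "".join(ops)
    consumed = path.count("M") + path.count("D")
    return WraparoundAlignment(
        score=best_score,
        copies=round(consumed / p, 2),
        seq_start=i,
        seq_end=best_i,
        path=path,
    )


def copy_number(aln: WraparoundAlignment, pattern_length: int) -> float:
    """Pattern copies spanned by an alignment: positions consumed / pattern length.

    Reported at 0.01-copy resolution.
    """
    if pattern_length < 1:
        raise ValueError("pattern_length must be >= 1")
    return round(aln.pattern_consumed / pattern_length, 2)


def is_genotypable(array_length: int, read_length: int, min_flank: int = 10) -> bool:
    """Whether a repeat array plus ``min_flank`` bases on each side fits in a read."""
    if array_length < 0 or read_length < 0 or min_flank < 0:
        raise ValueError("lengths must be non-negative")
    return array_length + 2 * min_flank <= read_length


def detectable_cgl_range(
    locus,
    read_length: int,
    min_copies: float = 1.9,
    min_flank: int = 10,
) -> tuple[int, int] | None:
    """Integer copies-gained/lost interval observable at a given read length.

    An allele with ``ref_copies + cgl`` copies is detectable iff it retains at
    least ``min_copies`` pattern copies (the repeat-finder floor) and its
    array plus flanks fits within the read.  Returns ``(cgl_min, cgl_max)``,
    or ``None`` when no integer allele is detectable.
    """
    pat = locus.pattern_length
    ref = locus.ref_copies
    eps = 1e-9
    cgl_min = math.ceil(min_copies - ref - eps)
    cgl_max = math.floor((read_length - 2 * min_flank) / pat - ref + eps)
    if cgl_max < cgl_min:
        return None
    return cgl_min, cgl_max


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_pattern(pattern: str) -> str:
    """Strand- and rotation-canonical form: the lexicographically smallest
    rotation over both the pattern and its reverse complement."""
    pattern = pattern.upper()
    candidates = []
    for s in (pattern, _revcomp(pattern)):
        doubled = s + s
        candidates.extend(doubled[i : i + len(s)] for i in range(len(s)))
    return min(candidates)


@dataclass
class ReadTR:
    """A tandem repeat detected within a read: its pattern, the array
    sequence, and the flanking sequence on each side."""

    pattern: str
    array: str
    left_flank: str
    right_flank: str


def _flank_identity(read_flank: str, ref_flank: str, side: str, max_flank: int) -> tuple[int, float]:
    """Compare the array-adjacent ends of two flanks; returns (bases compared,
    identity fraction)."""
    k = min(len(read_flank), len(ref_flank), max_flank)
    if k == 0:
        return 0, 0.0
    if side == "left":
        a, b = read_flank[-k:], ref_flank[-k:]
    else:
        a, b = read_flank[:k], ref_flank[:k]
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return k, matches / k


def match_read_to_locus(
    read_tr: ReadTR,
    ref_set,
    min_flank: int = 10,
    max_flank: int = 50,
    identity_threshold: float = 0.9,
) -> int | None:
    """Assign a repeat found in a read to a unique reference locus.

    A candidate locus must share the read TR's pattern up to cyclic rotation
    and reverse complement, and both flanks (compared over 10–50 array-
    adjacent bases) must exceed the identity threshold.  Ambiguous matches —
    ties between two loci, or any hit on a locus from an indistinguishable
    family — return ``None``, since such reads cannot be attributed safely.
    """
    if len(read_tr.left_flank) < min_flank or len(read_tr.right_flank) < min_flank:
        raise ValueError(f"read TR flanks must be >= {min_flank} bp on both sides")
    canon = canonical_pattern(read_tr.pattern)
    hits = []
    hit_indistinct = False
    for locus in ref_set:
        if canonical_pattern(locus.pattern) != canon:
            continue
        kl, idl = _flank_identity(read_tr.left_flank, locus.left_flank, "left", max_flank)
        kr, idr = _flank_identity(read_tr.right_flank, locus.right_flank, "right", max_flank)
        if kl < min_flank or kr < min_flank:
            continue
        if idl >= identity_threshold and idr >= identity_threshold:
            if locus.indistinguishable:
                hit_indistinct = True
            else:
                hits.append(locus.locus_id)
    if hit_indistinct or len(hits) != 1:
        return None
    return hits[0]
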