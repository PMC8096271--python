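"""Consistency and validation procedures for predicted VNTR genotypes.

Three independent checks: Mendelian consistency within mother-father-child
trios (with increasingly stringent locus-selection tiers), allele agreement
between two sequencing platforms for the same individual (Jaccard over
detectable non-reference alleles), and confirmation of predicted copy
numbers against long-read measurements within ±0.25 copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genotyping import SampleGenotype
from .reference import ReferenceTRSet
from .repeat import detectable_cgl_range, wraparound_align

__all__ = [
    "TrioGenotypes",
    "ConsistencyReport",
    "mendelian_check",
    "platform_consistency",
    "LongReadReport",
    "longread_copy_estimates",
    "longread_validate",
]

TIERS = ("all", "parents_het", "all_het", "all_het_distinct")


@dataclass
class TrioGenotypes:
    mother: SampleGenotype
    father: SampleGenotype
    child: SampleGenotype

    @property
    def child_sex(self) -> str:
        return self.child.sex


@dataclass
class ConsistencyReport:
    tier: str
    per_locus: dict[int, bool]  # evaluated loci only
    n_unevaluated: int

    @property
    def n_consistent(self) -> int:
        return sum(self.per_locus.values())

    @property
    def n_inconsistent(self) -> int:
        return len(self.per_locus) - self.n_consistent

    @property
    def consistency_rate(self) -> float | None:
        if not self.per_locus:
            return None
        return self.n_consistent / len(self.per_locus)


def _is_het(alleles: list[int]) -> bool:
    return len(set(alleles)) >= 2


def _autosomal_consistent(child: list[int], mother: list[int], father: list[int]) -> bool:
    m, f = set(mother), set(father)
    if len(child) >= 2:
        c1, c2 = child[0], child[1]
        return (c1 in m and c2 in f) or (c2 in m and c1 in f)
    # single detected child allele: lenient — explicable by either parent
    return child[0] in m or child[0] in f


def mendelian_check(
    trio: TrioGenotypes, tier: str = "all", chrom_of: dict[int, str] | None = None
) -> ConsistencyReport:
    """Check each locus for Mendelian consistency within the trio.

    An autosomal locus is consistent when the child's allele pair can be
    split as one allele seen in the mother and one in the father.  A son's X
    allele must appear among the mother's X alleles and his Y allele on the
    father's Y.  Loci lacking a genotype in a required member are
    unevaluated.  Tiers restrict evaluation: ``parents_het`` (both parents
    heterozygous), ``all_het`` (trio heterozygous), ``all_het_distinct``
    (trio heterozygous with three pairwise different genotypes).
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    chrom_of = chrom_of or {}
    universe = (
        set(trio.mother.calls) | set(trio.father.calls) | set(trio.child.calls)
    )
    per_locus: dict[int, bool] = {}
    unevaluated = 0
    for lid in universe:
        chrom = chrom_of.get(lid, "chr1").removeprefix("chr")
        c = trio.child.alleles(lid)
        m = trio.mother.alleles(lid)
        f = trio.father.alleles(lid)
        if chrom == "Y" and trio.child_sex == "M":
            if not (c and f):
                unevaluated += 1
                continue
            if tier != "all":
                unevaluated += 1
                continue
            per_locus[lid] = all(a in set(f) for a in c)
            continue
        if chrom == "Y":
            unevaluated += 1
            continue
        if chrom == "X" and trio.child_sex == "M":
            if not (c and m):
                unevaluated += 1
                continue
            if tier != "all":
                unevaluated += 1
                continue
            per_locus[lid] = all(a in set(m) for a in c)
            continue
        # autosome, or X in a daughter (inherited like an autosome)
        if not (c and m and f):
            unevaluated += 1
            continue
        if tier in ("parents_het", "all_het", "all_het_distinct") and not (
            _is_het(m) and _is_het(f)
        ):
            unevaluated += 1
            continue
        if tier in ("all_het", "all_het_distinct") and not _is_het(c):
            unevaluated += 1
            continue
        if tier == "all_het_distinct":
            genos = {tuple(sorted(x)) for x in (m, f, c)}
            if len(genos) < 3:
                unevaluated += 1
                continue
        per_locus[lid] = _autosomal_consistent(c, m, f)
    return ConsistencyReport(tier=tier, per_locus=per_locus, n_unevaluated=unevaluated)


def platform_consistency(
    geno_a: SampleGenotype,
    geno_b: SampleGenotype,
    read_length_a: int,
    read_length_b: int,
    ref_set: ReferenceTRSet,
    min_copies: float = 1.9,
) -> float | None:
    """Jaccard agreement of non-reference alleles between two call sets.

    Only loci genotyped on both platforms and VNTR in at least one are
    compared.  Alleles that could not have been detected at the shorter read
    length (outside its detectable CGL range) are excluded from both sides,
    so a longer-read platform is not penalised for its extra reach.
    Reference alleles are excluded; an empty union returns ``None``.
    """
    short_len = min(read_length_a, read_length_b)
    shared = set(geno_a.calls) & set(geno_b.calls)
    loci = {
        lid
        for lid in shared
        if any(c != 0 for c in geno_a.alleles(lid) + geno_b.alleles(lid))
    }

    def nonref(geno: SampleGenotype) -> set[tuple[int, int]]:
        out = set()
        for lid in loci:
            rng = detectable_cgl_range(ref_set[lid], short_len, min_copies)
            for cgl in geno.alleles(lid):
                if cgl == 0:
                    continue
                if rng is not None and rng[0] <= cgl <= rng[1]:
                    out.add((lid, cgl))
        return out

    a, b = nonref(geno_a), nonref(geno_b)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


@dataclass
class LongReadReport:
    tolerance: float
    validated: dict[tuple[int, int], bool] = field(default_factory=dict)
    unevaluated_loci: set[int] = field(default_factory=set)

    @property
    def fraction_alleles_validated(self) -> float | None:
        if not self.validated:
            return None
        return sum(self.validated.values()) / len(self.validated)

    @property
    def fraction_loci_all_validated(self) -> float | None:
        by_locus: dict[int, bool] = {}
        for (lid, _), ok in self.validated.items():
            by_locus[lid] = by_locus.get(lid, True) and ok
        if not by_locus:
            return None
        return sum(by_locus.values()) / len(by_locus)


def longread_copy_estimates(
    reads_by_locus: dict[int, list[str]],
    ref_set: ReferenceTRSet,
    min_flank: int = 10,
) -> dict[int, list[float]]:
    """Per-locus copy numbers from long reads pre-assigned to loci.

    Each read's repeat array is localized between the locus flanks (seeded
    on the ``min_flank`` array-adjacent bases) and aligned to the pattern
    with wraparound DP; reads where the flanks cannot be found are aligned
    whole, which may over-count where flanking bases continue the pattern.
    """
    out: dict[int, list[float]] = {}
    for lid, reads in reads_by_locus.items():
        loc = ref_set[lid]
        lseed = loc.left_flank[-min_flank:]
        rseed = loc.right_flank[:min_flank]
        vals = []
        for read in reads:
            lpos = read.find(lseed)
            segment = read
            if lpos >= 0:
                astart = lpos + len(lseed)
                rpos = read.find(rseed, astart)
                if rpos >= 0:
                    segment = read[astart:rpos]
            if segment:
                vals.append(wraparound_align(segment, loc.pattern).copies)
        out[lid] = vals
    return out


def longread_validate(
    predicted: SampleGenotype,
    ref_set: ReferenceTRSet,
    longread_copies: dict[int, list[float]],
    tolerance: float = 0.25,
) -> LongReadReport:
    """Confirm predicted alleles against per-locus long-read copy numbers.

    A predicted allele (reference copies + CGL) is validated when at least
    one long read measures a copy number within ``tolerance`` of it.  Loci
    with no covering long reads are unevaluated.
    """
    report = LongReadReport(tolerance=tolerance)
    for lid, calls in predicted.calls.items():
        reads = longread_copies.get(lid)
        if not reads:
            report.unevaluated_loci.add(lid)
            continue
        ref_copies = ref_set[lid].ref_copies
        for call in calls:
            target = ref_copies + call.cgl
            report.validated[(lid, call.cgl)] = any(
                abs(r - target) <= tolerance for r in reads
            )
    return report
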