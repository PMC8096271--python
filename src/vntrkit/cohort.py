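"""Cohort-level VNTR summaries.

Operates on multi-filtered per-sample genotypes: common/private
classification by cohort carrier counts, per-sample heterozygosity, the
copies-gained/lost spectrum, the fraction of a reference set on which gains
and losses were observable at a given read length, tumor/normal comparison
(loss of heterozygosity, somatic alleles), and generic interval-overlap
annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .genotyping import SampleGenotype, classify_vntr_loci
from .reference import ReferenceTRSet
from .repeat import is_genotypable

__all__ = [
    "CohortGenotypeMatrix",
    "classify_common_private",
    "heterozygosity_fraction",
    "CopySpectrum",
    "copy_spectrum",
    "loss_gain_ratio",
    "detectable_fractions",
    "TumorNormalReport",
    "compare_tumor_normal",
    "overlap_annotations",
]


@dataclass
class CohortGenotypeMatrix:
    """Loci × samples view of a multi-filtered cohort, with sample metadata."""

    cohort: list[SampleGenotype]
    metadata: pd.DataFrame | None = None  # sample_id, population, read_length, coverage
    vntr_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vntr_flags:
            self.vntr_flags = classify_vntr_loci(self.cohort)

    @property
    def n_samples(self) -> int:
        return len(self.cohort)

    @property
    def vntr_loci(self) -> list[int]:
        return sorted(lid for lid, f in self.vntr_flags.items() if f)

    def carrier_count(self, locus_id: int) -> int:
        """Samples carrying at least one non-reference allele at the locus."""
        return sum(
            1 for g in self.cohort if any(c != 0 for c in g.alleles(locus_id))
        )


def classify_common_private(
    matrix: CohortGenotypeMatrix,
    common_frac: float = 0.05,
    private_frac: float = 0.01,
) -> dict[int, str]:
    """Label each VNTR locus common / private / intermediate.

    A locus is common when at least ``ceil(common_frac × n)`` samples carry a
    non-reference allele (126 of 2504 at the 5% default) and private when at
    most ``floor(private_frac × n)`` but at least one do (25 of 2504 at 1%).
    """
    for f in (common_frac, private_frac):
        if not 0 < f < 1:
            raise ValueError("fractions must lie in (0,1)")
    n = matrix.n_samples
    if n < 1:
        raise ValueError("cohort is empty")
    common_min = math.ceil(common_frac * n)
    private_max = math.floor(private_frac * n)
    labels: dict[int, str] = {}
    for lid in matrix.vntr_loci:
        count = matrix.carrier_count(lid)
        if count >= common_min:
            labels[lid] = "common"
        elif 1 <= count <= private_max:
            labels[lid] = "private"
        else:
            labels[lid] = "intermediate"
    return labels


def heterozygosity_fraction(
    genotype: SampleGenotype, denominator: str = "vntr"
) -> float | None:
    """Percentage of per-sample loci with two distinct called alleles.

    With the default denominator the base set is the sample's VNTR loci
    (those where it carries a non-reference allele); ``denominator="all"``
    uses every genotyped locus.  Returns ``None`` when the base set is
    empty.
    """
    if denominator == "vntr":
        base = [lid for lid in genotype.calls if any(c != 0 for c in genotype.alleles(lid))]
    elif denominator == "all":
        base = list(genotype.calls)
    else:
        raise ValueError("denominator must be 'vntr' or 'all'")
    if not base:
        return None
    het = sum(1 for lid in base if genotype.is_heterozygous(lid))
    return 100.0 * het / len(base)


@dataclass
class CopySpectrum:
    histogram: dict[int, int]  # CGL -> occurrences (per sample per locus)
    losses: int
    gains: int
    ratio: float | None  # losses/gains, 1 decimal; None when gains == 0

    @property
    def total(self) -> int:
        return sum(self.histogram.values())


def copy_spectrum(cohort: list[SampleGenotype]) -> CopySpectrum:
    """Histogram of non-reference allele occurrences by copies gained/lost."""
    hist: dict[int, int] = {}
    for g in cohort:
        for lid, calls in g.calls.items():
            for call in calls:
                if call.cgl != 0:
                    hist[call.cgl] = hist.get(call.cgl, 0) + 1
    losses = sum(n for c, n in hist.items() if c < 0)
    gains = sum(n for c, n in hist.items() if c > 0)
    return CopySpectrum(dict(sorted(hist.items())), losses, gains, loss_gain_ratio(losses, gains))


def loss_gain_ratio(losses: int, gains: int) -> float | None:
    """Loss/gain fold ratio at 1-decimal resolution; ``None`` when no gains."""
    return round(losses / gains, 1) if gains else None


def detectable_fractions(
    ref_set: ReferenceTRSet,
    read_length: int,
    min_copies: float = 1.8,
    min_flank: int = 10,
) -> tuple[float, float]:
    """(fraction of loci where a one-copy gain fits in the read, fraction
    where a one-copy loss keeps at least ``min_copies + 1`` reference copies).

    The loss side uses the repeat-finder detection floor: a locus needs
    ``min_copies + 1`` reference copies for the loss allele to retain
    ``min_copies``.
    """
    loci = list(ref_set)
    if not loci:
        raise ValueError("empty reference set")
    gain = sum(
        1
        for loc in loci
        if is_genotypable(
            round(loc.pattern_length * (loc.ref_copies + 1)), read_length, min_flank
        )
    )
    eps = 1e-9
    loss = sum(1 for loc in loci if loc.ref_copies >= min_copies + 1 - eps)
    return gain / len(loci), loss / len(loci)


@dataclass
class TumorNormalReport:
    het_normal: float | None
    het_tumor: float | None
    somatic_alleles: set[tuple[int, int]]  # present in tumor, absent in normal
    loh_loci: list[int]  # heterozygous in normal, single-allele in tumor
    both_allele_loss: list[int]  # genotyped in normal, absent in tumor


def compare_tumor_normal(
    normal: SampleGenotype, tumor: SampleGenotype
) -> TumorNormalReport:
    """Tumor/normal contrast over a shared locus universe."""
    somatic = set()
    for lid, calls in tumor.calls.items():
        if lid not in normal.calls:
            continue
        normal_alleles = set(normal.alleles(lid))
        for call in calls:
            if call.cgl not in normal_alleles:
                somatic.add((lid, call.cgl))
    loh = [
        lid
        for lid in normal.calls
        if normal.is_heterozygous(lid)
        and lid in tumor.calls
        and len(set(tumor.alleles(lid))) == 1
    ]
    both_loss = [lid for lid in normal.calls if lid not in tumor.calls]
    return TumorNormalReport(
        het_normal=heterozygosity_fraction(normal),
        het_tumor=heterozygosity_fraction(tumor),
        somatic_alleles=somatic,
        loh_loci=sorted(loh),
        both_allele_loss=sorted(both_loss),
    )


def overlap_annotations(
    loci: list[tuple[int, str, int, int]],
    features: dict[str, list[tuple[str, int, int]]],
) -> pd.DataFrame:
    """Per-locus overlap flags against feature interval classes.

    All intervals are 0-based half-open on a shared coordinate system; any
    overlap of at least one base sets the flag.  Input order does not
    matter.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls, ivs in features.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in ivs:
            if end > start:
                per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees[cls] = per_chrom
    rows = []
    for locus_id, chrom, start, end in loci:
        row = {"locus_id": locus_id}
        for cls in features:
            tree = trees[cls].get(chrom)
            row[cls] = bool(tree.overlap(start, end)) if tree is not None else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus_id")
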