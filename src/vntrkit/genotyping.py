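"""Per-sample allele calling and VCF encoding for tandem-repeat genotypes.

A genotype at a repeat locus is a set of integer alleles, each expressed as
copies gained or lost (CGL) relative to the reference copy number and backed
by a read-support count (SP).  An allele is called only when at least two
reads show the same integer array copy number.  Per-sample loci showing more
alleles than the expected chromosome count ("multis") are filtered out, and
a locus is labelled a VNTR when any surviving non-reference allele is seen
in any sample.

Two VCF files are emitted per cohort: all genotyped loci, and the subset of
VNTR loci.  Genotypes are carried in two custom FORMAT fields: ``SP``
(integer read support per allele) and ``CGL`` (signed copies gained/lost per
allele, e.g. ``0,+2`` for a heterozygous reference / two-copy-gain call).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .reference import ReferenceTRSet
from .repeat import ReadTR, ScoringScheme, match_read_to_locus, wraparound_align

__all__ = [
    "AlleleCall",
    "SampleGenotype",
    "encode_cgl",
    "decode_cgl",
    "format_cgl",
    "call_genotypes",
    "observe_read_copies",
    "genotype_sample",
    "filter_multis",
    "classify_vntr_loci",
    "write_vcf",
    "read_vcf",
]


@dataclass(frozen=True)
class AlleleCall:
    locus_id: int
    cgl: int
    sp: int


@dataclass
class SampleGenotype:
    """All allele calls for one sample; loci with no supported allele are absent."""

    sample_id: str
    sex: str  # "F" or "M"
    calls: dict[int, list[AlleleCall]] = field(default_factory=dict)

    def alleles(self, locus_id: int) -> list[int]:
        return [c.cgl for c in self.calls.get(locus_id, [])]

    def is_heterozygous(self, locus_id: int) -> bool:
        return len(set(self.alleles(locus_id))) >= 2

    def nonref_alleles(self) -> set[tuple[int, int]]:
        """All (locus_id, cgl) pairs with cgl != 0."""
        return {
            (lid, c.cgl) for lid, calls in self.calls.items() for c in calls if c.cgl != 0
        }


def encode_cgl(observed_copies: int, ref_copies: float) -> int:
    """Copies gained/lost of an observed integer copy number vs the reference."""
    return observed_copies - round(ref_copies)


def decode_cgl(cgl: int, ref_copies: float) -> int:
    """Inverse of :func:`encode_cgl`: the observed integer copy number."""
    return cgl + round(ref_copies)


def format_cgl(cgl: int) -> str:
    return f"+{cgl}" if cgl > 0 else str(cgl)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def call_genotypes(
    observations: dict[int, list[float]],
    ref_set: ReferenceTRSet,
    sample_id: str = "sample",
    sex: str = "F",
    min_support: int = 2,
) -> SampleGenotype:
    """Turn per-locus read copy-number observations into allele calls.

    Each observation (a fractional copy number from one read) is rounded to
    the nearest integer; every integer value supported by at least
    ``min_support`` reads becomes an allele, encoded as CGL.  Loci where no
    value reaches support are left ungenotyped.
    """
    geno = SampleGenotype(sample_id=sample_id, sex=sex)
    for locus_id, copies_list in observations.items():
        ref_copies = ref_set[locus_id].ref_copies
        counts: dict[int, int] = {}
        for c in copies_list:
            k = _round_half_up(c)
            counts[k] = counts.get(k, 0) + 1
        calls = [
            AlleleCall(locus_id, encode_cgl(k, ref_copies), n)
            for k, n in sorted(counts.items())
            if n >= min_support
        ]
        if calls:
            geno.calls[locus_id] = calls
    return geno


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def observe_read_copies(
    reads: list[str],
    ref_set: ReferenceTRSet,
    min_flank: int = 10,
    max_flank: int = 50,
    min_copies: float = 1.9,
    scoring: ScoringScheme = ScoringScheme(),
) -> dict[int, list[float]]:
    """Scan reads for reference repeat arrays and measure their copy numbers.

    For each read (both orientations) and each singleton locus, the locus'
    array-adjacent flanks are located in the read; the sequence between them
    is aligned to the locus pattern with wraparound DP and the spanned copy
    number recorded.  Reads whose flanks match ambiguously (two loci, or an
    indistinguishable family) are discarded by :func:`match_read_to_locus`.
    """
    seeds = []
    for locus in ref_set:
        seeds.append(
            (locus, locus.left_flank[-min_flank:], locus.right_flank[:min_flank])
        )
    observations: dict[int, list[float]] = {}
    for read in reads:
        for oriented in (read, _revcomp(read)):
            hit = False
            for locus, lseed, rseed in seeds:
                lpos = oriented.find(lseed)
                if lpos < 0:
                    continue
                astart = lpos + len(lseed)
                rpos = oriented.find(rseed, astart)
                if rpos < 0:
                    continue
                array = oriented[astart:rpos]
                if len(array) < locus.pattern_length * min_copies:
                    continue
                read_tr = ReadTR(
                    pattern=locus.pattern,
                    array=array,
                    left_flank=oriented[max(0, astart - max_flank) : astart],
                    right_flank=oriented[rpos : rpos + max_flank],
                )
                matched = match_read_to_locus(
                    read_tr, ref_set, min_flank=min_flank, max_flank=max_flank
                )
                if matched is None:
                    continue
                aln = wraparound_align(array, ref_set[matched].pattern, scoring)
                if aln.copies < min_copies:
                    continue
                observations.setdefault(matched, []).append(aln.copies)
                hit = True
            if hit:
                break  # a read carries the locus in one orientation only
    return observations


def genotype_sample(
    reads: list[str],
    ref_set: ReferenceTRSet,
    sample_id: str = "sample",
    sex: str = "F",
    min_support: int = 2,
    **observe_kwargs,
) -> SampleGenotype:
    """End-to-end genotyping of one sample's reads against a reference set."""
    obs = observe_read_copies(reads, ref_set, **observe_kwargs)
    return call_genotypes(obs, ref_set, sample_id=sample_id, sex=sex, min_support=min_support)


def expected_allele_count(chrom: str, sex: str) -> int:
    """Expected chromosome copies for a (chromosome, sex) combination."""
    name = chrom.removeprefix("chr")
    if name == "X":
        return 2 if sex == "F" else 1
    if name == "Y":
        return 0 if sex == "F" else 1
    if name.isdigit():
        return 2
    raise ValueError(f"unrecognised chromosome label: {chrom!r}")


def filter_multis(
    genotype: SampleGenotype, chrom_of: dict[int, str]
) -> tuple[SampleGenotype, list[int]]:
    """Remove per-sample loci with more alleles than expected chromosomes.

    Returns the filtered genotype and the list of removed ("multi") locus
    ids.  Loci within expectation are untouched, so the filter is idempotent.
    """
    filtered = SampleGenotype(sample_id=genotype.sample_id, sex=genotype.sex)
    multis: list[int] = []
    for locus_id, calls in genotype.calls.items():
        expected = expected_allele_count(chrom_of[locus_id], genotype.sex)
        if len(calls) > expected:
            multis.append(locus_id)
        else:
            filtered.calls[locus_id] = list(calls)
    return filtered, multis


def classify_vntr_loci(cohort: list[SampleGenotype]) -> dict[int, bool]:
    """Per-locus VNTR flag: true iff any sample carries a non-reference allele.

    Input genotypes must already be multi-filtered; a locus removed
    everywhere by the multi filter never appears here.
    """
    flags: dict[int, bool] = {}
    for geno in cohort:
        for locus_id, calls in geno.calls.items():
            nonref = any(c.cgl != 0 for c in calls)
            flags[locus_id] = flags.get(locus_id, False) or nonref
    return flags


# ---------------------------------------------------------------------------
# VCF input/output


def write_vcf(
    cohort: list[SampleGenotype],
    ref_set: ReferenceTRSet,
    all_path: str | Path,
    vntr_path: str | Path,
) -> dict[int, bool]:
    """Write the two genotype VCFs: all genotyped loci, and VNTR loci only.

    Returns the VNTR flags used for the subset.  Sample sex is preserved in
    structured ``##SAMPLE`` header lines so a cohort roundtrips losslessly.
    """
    flags = classify_vntr_loci(cohort)
    genotyped = sorted(
        {lid for g in cohort for lid in g.calls},
        key=lambda lid: (ref_set[lid].chrom, ref_set[lid].start),
    )
    contigs = []
    for lid in genotyped:
        c = ref_set[lid].chrom
        if c not in contigs:
            contigs.append(c)

    def emit(path: str | Path, locus_ids: list[int]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=vntrkit\n')
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                '##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit pattern">\n'
            )
            fh.write(
                '##INFO=<ID=PATLEN,Number=1,Type=Integer,Description="Pattern length in bp">\n'
            )
            fh.write(
                '##INFO=<ID=REFCOPIES,Number=1,Type=Float,Description="Reference copy number">\n'
            )
            fh.write(
                '##INFO=<ID=VNTR,Number=0,Type=Flag,Description="Locus has a non-reference allele in some sample">\n'
            )
            fh.write(
                '##FORMAT=<ID=SP,Number=.,Type=Integer,Description="Reads supporting each allele">\n'
            )
            fh.write(
                '##FORMAT=<ID=CGL,Number=.,Type=String,Description="Copies gained or lost per allele">\n'
            )
            for g in cohort:
                fh.write(f"##SAMPLE=<ID={g.sample_id},Sex={g.sex}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(g.sample_id for g in cohort)
                + "\n"
            )
            for lid in locus_ids:
                loc = ref_set[lid]
                info = f"RU={loc.pattern};PATLEN={loc.pattern_length};REFCOPIES={loc.ref_copies}"
                if flags.get(lid, False):
                    info += ";VNTR"
                cols = [
                    loc.chrom,
                    str(loc.start + 1),
                    str(lid),
                    "N",
                    ".",
                    ".",
                    "PASS",
                    info,
                    "SP:CGL",
                ]
                for g in cohort:
                    calls = g.calls.get(lid)
                    if not calls:
                        cols.append(".:.")
                    else:
                        sp = ",".join(str(c.sp) for c in calls)
                        cgl = ",".join(format_cgl(c.cgl) for c in calls)
                        cols.append(f"{sp}:{cgl}")
                fh.write("\t".join(cols) + "\n")

    emit(all_path, genotyped)
    emit(vntr_path, [lid for lid in genotyped if flags.get(lid, False)])
    return flags


_CGL_RE = re.compile(r"^[+-]?\d+$")


def read_vcf(path: str | Path) -> list[SampleGenotype]:
    """Parse a genotype VCF back into per-sample calls.

    Malformed records raise ``ValueError`` naming the offending record.
    """
    with pysam.VariantFile(str(path)) as vcf:
        sex_of: dict[str, str] = {}
        for rec in vcf.header.records:
            if rec.key == "SAMPLE":
                sex_of[rec.get("ID")] = rec.get("Sex", "F")
        samples = [
            SampleGenotype(sample_id=s, sex=sex_of.get(s, "F")) for s in vcf.header.samples
        ]
        for lineno, rec in enumerate(vcf, start=1):
            locus_id = int(rec.id)
            for geno in samples:
                fmt = rec.samples[geno.sample_id]
                cgl_vals = fmt.get("CGL")
                sp_vals = fmt.get("SP")
                if cgl_vals is None or cgl_vals in ((None,), "."):
                    continue
                if isinstance(cgl_vals, str):
                    cgl_vals = (cgl_vals,)
                if isinstance(sp_vals, int):
                    sp_vals = (sp_vals,)
                cgl_vals = [v for v in cgl_vals if v not in (None, ".")]
                sp_vals = [v for v in (sp_vals or []) if v is not None]
                if not cgl_vals:
                    continue
                if len(cgl_vals) != len(sp_vals):
                    raise ValueError(
                        f"record {lineno} (locus {rec.id}): SP/CGL length mismatch"
                    )
                calls = []
                for cgl_s, sp in zip(cgl_vals, sp_vals):
                    if not _CGL_RE.match(cgl_s):
                        raise ValueError(
                            f"record {lineno} (locus {rec.id}): bad CGL value {cgl_s!r}"
                        )
                    calls.append(AlleleCall(locus_id, int(cgl_s), int(sp)))
                geno.calls[locus_id] = calls
    return samples
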