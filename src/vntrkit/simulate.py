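"""Synthetic cohorts for the minisatellite VNTR pipeline.

Everything the downstream stages consume can be generated here: a reference
genome carrying tandem-repeat loci (patterns 7–126 bp), diploid
multi-population cohorts with optional planted population-specific alleles,
mother-father-child trios, error-bearing short or long reads, and expression
matrices with planted genotype effects, sex/population covariates and hidden
factors.  Every generator is a pure function of its configuration and seed.

Copy-number truth is discretised to integer copies gained/lost (CGL) per
haplotype.  The default allele-frequency model gives the reference allele
weight 0.8 and distributes the rest over non-reference CGLs as a truncated
geometric in |CGL|, with copy losses favoured 1.8:1 over gains — mirroring
the loss/gain spectrum observed in large human cohorts.  Haplotypes are
drawn independently per locus (no linkage).  Coverage is depth per
haplotype: the read count equals coverage × (total length of the sample's
chromosome copies) / read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotyping import AlleleCall, SampleGenotype
from .reference import ReferenceTRLocus, ReferenceTRSet

__all__ = [
    "SimulationConfig",
    "MarkerAlleleSpec",
    "EqtlEffectSpec",
    "TrueGenotypeTable",
    "ExpressionSim",
    "generate_reference",
    "sample_cohort",
    "generate_trio",
    "synthesize_reads",
    "simulate_expression",
    "write_fastq",
    "read_fastq",
    "write_genome_fasta",
    "genotype_class_label",
]

_NA = -128  # sentinel for "no allele on this haplotype" (male X, Y rules)
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MarkerAlleleSpec:
    """A planted population-specific allele: haplotype frequency ``f_in``
    inside the target population and ``f_out`` everywhere else."""

    locus_id: int
    cgl: int
    population: str
    f_in: float
    f_out: float


@dataclass(frozen=True)
class EqtlEffectSpec:
    """A planted expression effect: per-genotype-class mean shifts (log2
    units) of one gene driven by one locus."""

    gene: str
    locus_id: int
    class_shifts: dict[str, float]


@dataclass
class SimulationConfig:
    n_populations: int = 5
    samples_per_population: int = 200
    n_loci: int = 100
    pattern_length_range: tuple[int, int] = (7, 126)
    ref_copies_range: tuple[float, float] = (2.0, 10.0)
    allele_cgl_range: tuple[int, int] = (-5, 3)
    marker_allele_spec: list[MarkerAlleleSpec] = field(default_factory=list)
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.001
    trio_mutation_rate: float = 0.0
    eqtl_effect_spec: list[EqtlEffectSpec] = field(default_factory=list)
    n_hidden_factors: int = 2
    seed: int = 0
    # reference-set composition and allele-frequency model
    indistinguishable_fraction: float = 0.16
    ref_allele_weight: float = 0.8
    loss_gain_bias: float = 1.8
    cgl_geometric_p: float = 0.5
    x_fraction: float = 0.05
    y_fraction: float = 0.02
    spacer_range: tuple[int, int] = (60, 200)

    def validate(self) -> None:
        lo, hi = self.pattern_length_range
        if not (7 <= lo <= hi <= 126):
            raise ValueError("pattern lengths must lie within 7–126 bp")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0,1)")
        for m in self.marker_allele_spec:
            if not (0 <= m.f_in <= 1 and 0 <= m.f_out <= 1):
                raise ValueError("marker frequencies must be in [0,1]")
        if not 0 <= self.indistinguishable_fraction <= 1:
            raise ValueError("indistinguishable fraction must be in [0,1]")


def _rng(config_seed: int, seed: int | None, salt: int) -> np.random.Generator:
    base = config_seed if seed is None else seed
    return np.random.default_rng((int(base), salt))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _is_primitive(pattern: str) -> bool:
    n = len(pattern)
    for d in range(1, n):
        if n % d == 0 and pattern == pattern[:d] * (n // d):
            return False
    return True


def _tile(pattern: str, length: int) -> str:
    return (pattern * (length // len(pattern) + 2))[:length]


def _quantize_copies(x: float, pattern_length: int) -> float:
    """Snap a copy number to a whole-bp array length so the stored reference
    copies are exact (array length / pattern length).  Arrays landing on the
    half-copy rounding boundary are nudged one base longer."""
    length = round(pattern_length * x)
    if 2 * (length % pattern_length) == pattern_length:
        length += 1
    return length / pattern_length


def generate_reference(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ReferenceTRSet, dict[str, str]]:
    """Generate a reference TR set embedded in a synthetic genome.

    Loci are placed without overlap, separated by random spacers, each with
    50 bp of recorded flanking context.  A configurable fraction of loci is
    laid down as *indistinguishable* pairs sharing their pattern and
    near-identical flanks (one mismatch per flank); the rest are singletons
    with unique random context.  Returns the locus set and the genome as a
    chrom → sequence dict.
    """
    config.validate()
    rng = _rng(config.seed, seed, salt=1)
    n = config.n_loci
    if n == 0:
        return ReferenceTRSet([]), {}

    n_ind = int(round(config.indistinguishable_fraction * n))
    n_pairs = n_ind // 2
    n_y = int(round(config.y_fraction * n))
    n_x = int(round(config.x_fraction * n))
    n_y = min(n_y, max(0, n - 2 * n_pairs))
    n_x = min(n_x, max(0, n - 2 * n_pairs - n_y))

    plo, phi = config.pattern_length_range
    clo, chi = config.ref_copies_range
    specs = []  # (pattern, ref_copies, partner_index or None)
    for i in range(n - 2 * n_pairs):
        while True:
            pat = _random_seq(rng, int(rng.integers(plo, phi + 1)))
            if _is_primitive(pat):
                break
        specs.append((pat, _quantize_copies(rng.uniform(clo, chi), len(pat)), None))
    for _ in range(n_pairs):
        while True:
            pat = _random_seq(rng, int(rng.integers(plo, phi + 1)))
            if _is_primitive(pat):
                break
        copies = _quantize_copies(rng.uniform(clo, chi), len(pat))
        specs.append((pat, copies, len(specs) + 1))
        specs.append((pat, copies, len(specs) - 1))

    chrom_of_index = (
        ["chrY"] * n_y + ["chrX"] * n_x + ["chr1"] * (n - n_x - n_y - 2 * n_pairs)
        + ["chr1"] * (2 * n_pairs)
    )

    loci: list[ReferenceTRLocus] = []
    genome: dict[str, str] = {}
    slo, shi = config.spacer_range
    flanks_by_index: dict[int, tuple[str, str]] = {}
    for chrom in ("chr1", "chrX", "chrY"):
        parts: list[str] = []
        offset = 0
        for i, (pat, copies, partner) in enumerate(specs):
            if chrom_of_index[i] != chrom:
                continue
            spacer = _random_seq(rng, int(rng.integers(slo, shi + 1)))
            if partner is not None and partner in flanks_by_index:
                lf, rf = flanks_by_index[partner]
                lf = _mutate_one(lf, rng)
                rf = _mutate_one(rf, rng)
            else:
                lf = _random_seq(rng, 50)
                rf = _random_seq(rng, 50)
            if partner is not None:
                flanks_by_index.setdefault(i, (lf, rf))
            array = _tile(pat, round(len(pat) * copies))
            start = offset + len(spacer) + len(lf)
            loci.append(
                ReferenceTRLocus(
                    locus_id=i + 1,
                    chrom=chrom,
                    start=start,
                    end=start + len(array),
                    pattern=pat,
                    ref_copies=copies,
                    left_flank=lf,
                    right_flank=rf,
                    indistinguishable=partner is not None,
                )
            )
            parts.append(spacer + lf + array + rf)
            offset = start + len(array) + len(rf)
        if parts:
            parts.append(_random_seq(rng, int(rng.integers(slo, shi + 1))))
            genome[chrom] = "".join(parts)
    loci.sort(key=lambda L: L.locus_id)
    return ReferenceTRSet(loci), genome


def _mutate_one(seq: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(0, len(seq)))
    alt = [b for b in "ACGT" if b != seq[i]][int(rng.integers(0, 3))]
    return seq[:i] + alt + seq[i + 1 :]


# ---------------------------------------------------------------------------
# cohort truth


@dataclass
class TrueGenotypeTable:
    """Ground-truth diploid CGL genotypes for a cohort.

    ``alleles`` has shape (n_loci, n_samples, 2); absent haplotypes (male X
    second slot, Y rules) carry the NA sentinel.  Autosomal entries always
    hold two alleles, male X/Y one, female Y none.
    """

    samples: pd.DataFrame  # columns: sample_id, sex, population
    locus_ids: list[int]
    chrom_of: dict[int, str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self._locus_index = {lid: i for i, lid in enumerate(self.locus_ids)}
        self._sample_index = {
            s: i for i, s in enumerate(self.samples["sample_id"])
        }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def sample_alleles(self, sample_id: str, locus_id: int) -> tuple[int, ...]:
        row = self.alleles[self._locus_index[locus_id], self._sample_index[sample_id]]
        return tuple(int(a) for a in row if a != _NA)

    def sex_of(self, sample_id: str) -> str:
        return self.samples.set_index("sample_id").loc[sample_id, "sex"]

    def to_cohort(self, sp: int = 30) -> list[SampleGenotype]:
        """Express the truth as called genotypes with nominal read support."""
        cohort = []
        for _, row in self.samples.iterrows():
            geno = SampleGenotype(sample_id=row["sample_id"], sex=row["sex"])
            si = self._sample_index[row["sample_id"]]
            for li, lid in enumerate(self.locus_ids):
                present = [int(a) for a in self.alleles[li, si] if a != _NA]
                if not present:
                    continue
                geno.calls[lid] = [
                    AlleleCall(lid, cgl, sp * present.count(cgl))
                    for cgl in sorted(set(present))
                ]
            cohort.append(geno)
        return cohort

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tsex\tpopulation\tlocus_id\talleles\n")
            for _, row in self.samples.iterrows():
                si = self._sample_index[row["sample_id"]]
                for li, lid in enumerate(self.locus_ids):
                    present = [int(a) for a in self.alleles[li, si] if a != _NA]
                    fh.write(
                        f"{row['sample_id']}\t{row['sex']}\t{row['population']}\t"
                        f"{lid}\t{','.join(map(str, present)) or '.'}\n"
                    )


def _allele_distribution(
    locus: ReferenceTRLocus, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the per-haplotype CGL distribution."""
    lo, hi = config.allele_cgl_range
    ref_int = round(locus.ref_copies)
    support = np.array([c for c in range(lo, hi + 1) if ref_int + c >= 1 or c == 0])
    if 0 not in support:
        support = np.sort(np.append(support, 0))
    w = np.zeros(len(support), dtype=float)
    p = config.cgl_geometric_p
    for i, c in enumerate(support):
        if c == 0:
            continue
        w[i] = p * (1 - p) ** (abs(c) - 1)
        if c < 0:
            w[i] *= config.loss_gain_bias
    if w.sum() > 0:
        w = w / w.sum() * (1 - config.ref_allele_weight)
    w[support == 0] = 1.0 - w.sum()
    return support, w


def sample_cohort(
    ref_set: ReferenceTRSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> TrueGenotypeTable:
    """Draw a diploid multi-population cohort of true genotypes.

    Haplotypes are sampled independently per locus from the shared allele
    distribution, overridden at planted marker alleles: frequency ``f_in``
    inside the target population, ``f_out`` elsewhere.  Sexes alternate
    within each population; male X/Y loci carry one allele, female Y none.
    """
    config.validate()
    rng = _rng(config.seed, seed, salt=2)
    pops = [f"POP{i + 1}" for i in range(config.n_populations)]
    n_s = config.samples_per_population
    records = []
    for pop in pops:
        for j in range(n_s):
            records.append(
                {
                    "sample_id": f"{pop}_S{j:04d}",
                    "sex": "F" if j % 2 == 0 else "M",
                    "population": pop,
                }
            )
    samples = pd.DataFrame(records)
    n_total = len(samples)
    is_male = (samples["sex"] == "M").to_numpy()

    markers_at: dict[int, list[MarkerAlleleSpec]] = {}
    for m in config.marker_allele_spec:
        if m.locus_id not in ref_set:
            raise KeyError(f"marker references unknown locus {m.locus_id}")
        markers_at.setdefault(m.locus_id, []).append(m)

    locus_ids = [loc.locus_id for loc in ref_set]
    A = np.full((len(locus_ids), n_total, 2), _NA, dtype=np.int16)
    for li, locus in enumerate(ref_set):
        support, base_probs = _allele_distribution(locus, config)
        chrom = locus.chrom
        for pi, pop in enumerate(pops):
            probs = base_probs.copy()
            for m in markers_at.get(locus.locus_id, []):
                f = m.f_in if pop == m.population else m.f_out
                idx = int(np.where(support == m.cgl)[0][0])
                rest = probs.sum() - probs[idx]
                if rest > 0:
                    probs *= (1 - f) / rest
                probs[idx] = f
                probs /= probs.sum()
            sl = slice(pi * n_s, (pi + 1) * n_s)
            draw = rng.choice(support, size=(n_s, 2), p=probs)
            if chrom == "chrY":
                draw[:, 1] = _NA
                draw[~is_male[sl], :] = _NA
            elif chrom == "chrX":
                draw[is_male[sl], 1] = _NA
            A[li, sl] = draw
    return TrueGenotypeTable(
        samples=samples,
        locus_ids=locus_ids,
        chrom_of={loc.locus_id: loc.chrom for loc in ref_set},
        alleles=A,
    )


def generate_trio(
    table: TrueGenotypeTable,
    mother_id: str,
    father_id: str,
    child_id: str = "CHILD",
    mutation_rate: float = 0.0,
    seed: int | None = None,
    child_sex: str = "M",
) -> TrueGenotypeTable:
    """Append a child drawn by Mendelian inheritance from two cohort members.

    At each autosomal locus the child receives one uniformly chosen allele
    from each parent; with probability ``mutation_rate`` (per locus) one
    inherited allele is perturbed by ±1 copy.  A son's X comes from the
    mother and Y from the father; a daughter receives the father's X.
    """
    rng = np.random.default_rng((seed or 0, 3))
    mi = table._sample_index[mother_id]
    fi = table._sample_index[father_id]
    if table.samples.iloc[mi]["sex"] != "F" or table.samples.iloc[fi]["sex"] != "M":
        raise ValueError("mother must be female and father male")
    n_loci = len(table.locus_ids)
    child = np.full((n_loci, 1, 2), _NA, dtype=np.int16)
    for li, lid in enumerate(table.locus_ids):
        chrom = table.chrom_of[lid]
        m_row = table.alleles[li, mi]
        f_row = table.alleles[li, fi]
        if chrom == "chrY":
            if child_sex == "M":
                child[li, 0, 0] = f_row[0]
            continue
        if chrom == "chrX":
            child[li, 0, 0] = m_row[int(rng.integers(2))]
            if child_sex == "F":
                child[li, 0, 1] = f_row[0]
            continue
        child[li, 0, 0] = m_row[int(rng.integers(2))]
        child[li, 0, 1] = f_row[int(rng.integers(2))]
        if mutation_rate > 0 and rng.random() < mutation_rate:
            k = int(rng.integers(2))
            delta = int(rng.choice([-1, 1]))
            child[li, 0, k] = int(child[li, 0, k]) + delta
    samples = pd.concat(
        [
            table.samples,
            pd.DataFrame(
                [
                    {
                        "sample_id": child_id,
                        "sex": child_sex,
                        "population": table.samples.iloc[mi]["population"],
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    return TrueGenotypeTable(
        samples=samples,
        locus_ids=list(table.locus_ids),
        chrom_of=dict(table.chrom_of),
        alleles=np.concatenate([table.alleles, child], axis=1),
    )


# ---------------------------------------------------------------------------
# reads


def _haplotype_sequences(
    table: TrueGenotypeTable,
    sample_id: str,
    ref_set: ReferenceTRSet,
    genome: dict[str, str],
) -> list[str]:
    """The sample's chromosome copies with each array resized per its allele."""
    sex = table.sex_of(sample_id)
    si = table._sample_index[sample_id]
    seqs: list[str] = []
    for chrom, ref_seq in genome.items():
        loci = sorted(
            (loc for loc in ref_set if loc.chrom == chrom), key=lambda L: L.start
        )
        if chrom == "chrY":
            hap_slots = [0] if sex == "M" else []
        elif chrom == "chrX":
            hap_slots = [0, 1] if sex == "F" else [0]
        else:
            hap_slots = [0, 1]
        for slot in hap_slots:
            parts = []
            pos = 0
            for loc in loci:
                cgl = int(table.alleles[table._locus_index[loc.locus_id], si, slot])
                if cgl == _NA:
                    continue
                parts.append(ref_seq[pos : loc.start])
                new_len = max(0, loc.array_length + loc.pattern_length * cgl)
                parts.append(_tile(loc.pattern, new_len))
                pos = loc.end
            parts.append(ref_seq[pos:])
            seqs.append("".join(parts))
    return seqs


def synthesize_reads(
    table: TrueGenotypeTable,
    sample_id: str,
    ref_set: ReferenceTRSet,
    genome: dict[str, str],
    read_length: int = 150,
    coverage: float = 30.0,
    error_rate: float = 0.001,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Sample substitution-error reads uniformly from a sample's haplotypes.

    Coverage is per haplotype: the read count is
    ``round(coverage × total haplotype length / read_length)``.  Each read is
    taken from a uniformly chosen valid start position on a uniformly chosen
    strand.  Returns (read id, sequence) pairs; coverage 0 gives no reads.
    """
    rng = np.random.default_rng((seed or 0, 4))
    haps = _haplotype_sequences(table, sample_id, ref_set, genome)
    starts = [max(0, len(h) - read_length + 1) for h in haps]
    total_positions = sum(starts)
    total_len = sum(len(h) for h in haps)
    n_reads = int(round(coverage * total_len / read_length))
    reads: list[tuple[str, str]] = []
    if total_positions == 0 or n_reads == 0:
        return reads
    cum = np.cumsum(starts)
    pos_draw = rng.integers(0, total_positions, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    comp = str.maketrans("ACGTN", "TGCAN")
    for i in range(n_reads):
        u = int(pos_draw[i])
        h = int(np.searchsorted(cum, u, side="right"))
        start = u - (int(cum[h - 1]) if h > 0 else 0)
        seq = haps[h][start : start + read_length]
        if error_rate > 0:
            errs = np.nonzero(rng.random(len(seq)) < error_rate)[0]
            if len(errs):
                chars = list(seq)
                for j in errs:
                    chars[j] = "ACGT"[(("ACGT".find(chars[j]) + 1 + int(rng.integers(3))) % 4)]
                seq = "".join(chars)
        if strands[i]:
            seq = seq.translate(comp)[::-1]
        reads.append((f"{sample_id}_r{i}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_genome_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# expression


def genotype_class_label(alleles: tuple[int, ...] | list[int]) -> str:
    """Canonical genotype-class label: the sorted CGL multiset, e.g. "0/+1"."""
    if not alleles:
        return "other"

    def fmt(c: int) -> str:
        return f"+{c}" if c > 0 else str(c)

    return "/".join(fmt(c) for c in sorted(alleles))


@dataclass
class ExpressionSim:
    """Simulated expression with its generating covariates and factor truth."""

    tpm: pd.DataFrame  # genes × samples
    covariates: pd.DataFrame  # index sample_id: sex, population
    factor_scores: pd.DataFrame  # factors × samples (ground truth)
    gene_intervals: pd.DataFrame  # gene, chrom, start, end


def simulate_expression(
    table: TrueGenotypeTable,
    ref_set: ReferenceTRSet,
    config: SimulationConfig,
    n_genes: int = 50,
    seed: int | None = None,
    noise_sd: float = 0.5,
    factor_sd: float = 0.7,
) -> ExpressionSim:
    """Simulate a TPM matrix with planted genotype effects.

    In log2 space each gene is baseline + sex effect + population effect +
    hidden-factor loadings × factor scores + the planted per-genotype-class
    shift + Gaussian noise; TPM is the exponentiated value.  Genes named in
    the effect spec are placed adjacent to their driving locus so interval
    pairing downstream finds them; filler genes live on a separate contig.
    """
    rng = _rng(config.seed, seed, salt=5)
    sample_ids = table.sample_ids
    n = len(sample_ids)
    effect_genes = [e.gene for e in config.eqtl_effect_spec]
    genes = list(dict.fromkeys(effect_genes))
    genes += [f"GENE{i:04d}" for i in range(max(0, n_genes - len(genes)))]
    genes = genes[: max(n_genes, len(effect_genes))]
    g = len(genes)

    sex_num = (table.samples["sex"] == "M").to_numpy().astype(float)
    pop_codes = pd.Categorical(table.samples["population"]).codes

    baseline = rng.normal(5.0, 1.0, size=g)
    sex_beta = np.where(rng.random(g) < 0.3, rng.normal(0, 0.3, size=g), 0.0)
    n_pops = pop_codes.max() + 1
    pop_beta = np.where(
        rng.random((g, n_pops)) < 0.3, rng.normal(0, 0.3, size=(g, n_pops)), 0.0
    )
    k = config.n_hidden_factors
    scores = rng.normal(0, 1, size=(k, n))
    loadings = rng.normal(0, factor_sd, size=(g, k))

    log2 = (
        baseline[:, None]
        + sex_beta[:, None] * sex_num[None, :]
        + pop_beta[:, pop_codes]
        + loadings @ scores
        + rng.normal(0, noise_sd, size=(g, n))
    )
    gene_index = {gene: i for i, gene in enumerate(genes)}
    for eff in config.eqtl_effect_spec:
        gi = gene_index[eff.gene]
        for si, sid in enumerate(sample_ids):
            label = genotype_class_label(table.sample_alleles(sid, eff.locus_id))
            log2[gi, si] += eff.class_shifts.get(label, 0.0)

    tpm = pd.DataFrame(np.power(2.0, log2), index=genes, columns=sample_ids)
    covariates = table.samples.set_index("sample_id")[["sex", "population"]]
    factor_scores = pd.DataFrame(
        scores, index=[f"factor{i + 1}" for i in range(k)], columns=sample_ids
    )

    intervals = []
    placed = {}
    for eff in config.eqtl_effect_spec:
        loc = ref_set[eff.locus_id]
        placed[eff.gene] = (loc.chrom, loc.end + 500, loc.end + 2500)
    filler_pos = 0
    for gene in genes:
        if gene in placed:
            chrom, start, end = placed[gene]
        else:
            chrom, start, end = "chrU", filler_pos, filler_pos + 2000
            filler_pos += 50_000
        intervals.append({"gene": gene, "chrom": chrom, "start": start, "end": end})
    return ExpressionSim(
        tpm=tpm,
        covariates=covariates,
        factor_scores=factor_scores,
        gene_intervals=pd.DataFrame(intervals),
    )
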