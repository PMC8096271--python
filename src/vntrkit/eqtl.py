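"""VNTR–gene-expression association scan.

Genes are paired with VNTR loci within 10 kb; each individual's genotype at
a locus becomes a class label (the sorted copies-gained/lost multiset, e.g.
``0/+1``; individuals without a call form the pooled ``other`` class).
Expression (log2 TPM) is residualized against sex, population structure and
iteratively-estimated hidden factors, and a one-way ANOVA across genotype
classes is applied per pair, with Benjamini-Hochberg FDR across all tested
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multitest import multipletests

from .genotyping import SampleGenotype
from .reference import ReferenceTRSet
from .simulate import genotype_class_label

__all__ = [
    "pair_genes_vntrs",
    "GenotypeClassing",
    "build_genotype_classes",
    "make_design",
    "estimate_hidden_factors",
    "residualize",
    "anova_scan",
    "eqtl_scan",
]


def pair_genes_vntrs(
    gene_intervals: pd.DataFrame,
    vntr_loci: list,
    window: int = 10_000,
) -> list[tuple[str, int]]:
    """Pairs of (gene, locus id) whose intervals lie within ``window`` bp.

    ``gene_intervals`` needs columns gene/chrom/start/end (0-based
    half-open).  Distance is measured between interval hulls: 0 when they
    overlap, else the gap between the nearer ends.
    """
    pairs = []
    for _, row in gene_intervals.iterrows():
        for loc in vntr_loci:
            if loc.chrom != row["chrom"]:
                continue
            gap = max(row["start"] - loc.end, loc.start - row["end"], 0)
            if gap <= window:
                pairs.append((row["gene"], loc.locus_id))
    return pairs


@dataclass
class GenotypeClassing:
    """Per-sample genotype class labels at one locus, post filtering."""

    locus_id: int
    labels: pd.Series  # sample_id -> class label
    class_counts: dict[str, int]


def build_genotype_classes(
    cohort: list[SampleGenotype],
    locus_id: int,
    expression_samples: list[str],
    min_class_size: int = 20,
) -> GenotypeClassing | None:
    """Genotype classes at a locus over the expression cohort, or ``None``.

    Samples without a call become the single pooled ``other`` class.  The
    locus is excluded (``None``) unless at least two classes exist (three if
    ``other`` is among them) and every class holds at least
    ``min_class_size`` individuals.
    """
    by_sample = {g.sample_id: g for g in cohort}
    labels = {}
    for sid in expression_samples:
        g = by_sample.get(sid)
        alleles = g.alleles(locus_id) if g is not None else []
        labels[sid] = genotype_class_label(tuple(alleles))
    ser = pd.Series(labels, name="genotype_class")
    counts = ser.value_counts().to_dict()
    min_classes = 3 if "other" in counts else 2
    if len(counts) < min_classes:
        return None
    if any(n < min_class_size for n in counts.values()):
        return None
    return GenotypeClassing(locus_id=locus_id, labels=ser, class_counts=counts)


def make_design(
    covariates: pd.DataFrame,
    hidden_factors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Numeric design matrix (with intercept) from sample covariates.

    ``sex`` is encoded 0/1; a categorical ``population`` column becomes
    dummy indicators (first level dropped); any other numeric columns (e.g.
    population PCs) pass through.  ``hidden_factors`` (factors × samples)
    are appended as columns.  Missing values raise, naming the samples.
    """
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if name == "sex":
            cols["sex"] = (col == "M").astype(float)
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.update({c: dummies[c] for c in dummies})
        else:
            cols[name] = col.astype(float)
    design = pd.DataFrame(cols, index=covariates.index)
    if hidden_factors is not None:
        design = design.join(hidden_factors.T)
    bad = design.index[design.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing covariate values for samples: {list(bad)}")
    design.insert(0, "intercept", 1.0)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of collinear columns by greedy elimination
        keep: list[int] = []
        collinear: list[str] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
            else:
                collinear.append(design.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y (genes × samples) on design X (samples × k)."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def residualize(
    log2_tpm: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene OLS residuals of log2 expression on the design matrix."""
    design = design.reindex(log2_tpm.columns)
    bad = design.index[design.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing covariate values for samples: {list(bad)}")
    _check_full_rank(design)
    resid = _ols_residuals(log2_tpm.to_numpy(dtype=float), design.to_numpy(dtype=float))
    return pd.DataFrame(resid, index=log2_tpm.index, columns=log2_tpm.columns)


def estimate_hidden_factors(
    log2_tpm: pd.DataFrame,
    design: pd.DataFrame,
    max_k: int = 15,
    corr_cutoff: float = 0.85,
) -> pd.DataFrame:
    """Iterative surrogate-factor estimation from expression residuals.

    Repeatedly residualizes expression on the known design plus accepted
    factors, extracts the leading principal component of the residual over
    samples, and accepts it unless its absolute correlation with any
    existing covariate or factor exceeds ``corr_cutoff``.  Stops at the
    first rejection or at ``max_k``.  Returns factors × samples scores.
    """
    design = design.reindex(log2_tpm.columns)
    _check_full_rank(design)
    compare = [
        design[c].to_numpy(dtype=float)
        for c in design.columns
        if design[c].nunique() > 1
    ]
    accepted: list[np.ndarray] = []
    Y = log2_tpm.to_numpy(dtype=float)
    X0 = design.to_numpy(dtype=float)
    for _ in range(max_k):
        X = X0 if not accepted else np.column_stack([X0] + accepted)
        R = _ols_residuals(Y, X)
        # leading PC over samples of the centred residual matrix
        Rc = R - R.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(Rc, full_matrices=False)
        candidate = vt[0]
        too_close = any(
            abs(np.corrcoef(candidate, v)[0, 1]) > corr_cutoff
            for v in compare + accepted
            if np.std(v) > 0
        )
        if too_close:
            break
        accepted.append(candidate)
    return pd.DataFrame(
        accepted,
        index=[f"SV{i + 1}" for i in range(len(accepted))],
        columns=log2_tpm.columns,
    )


def anova_scan(
    residuals: pd.DataFrame,
    classings: list[tuple[str, GenotypeClassing]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of residual expression across genotype classes.

    One row per (gene, locus) pair with F, p, BH q, the maximum pairwise
    difference of class residual means, and the significance flag
    ``q < fdr``.
    """
    rows = []
    for gene, classing in classings:
        if gene not in residuals.index:
            continue
        values = residuals.loc[gene]
        groups = [
            values[classing.labels.index[classing.labels == cls]].to_numpy()
            for cls in classing.class_counts
        ]
        f_stat, p = f_oneway(*groups)
        means = [g.mean() for g in groups]
        max_diff = max(means) - min(means)
        rows.append(
            {
                "gene": gene,
                "locus_id": classing.locus_id,
                "F": f_stat,
                "p_value": p,
                "max_mean_diff": max_diff,
                "classes": dict(classing.class_counts),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        result["significant"] = []
        return result
    result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["significant"] = result["q_value"] < fdr
    return result[
        ["gene", "locus_id", "F", "p_value", "q_value", "max_mean_diff", "significant", "classes"]
    ]


def eqtl_scan(
    cohort: list[SampleGenotype],
    ref_set: ReferenceTRSet,
    gene_intervals: pd.DataFrame,
    tpm: pd.DataFrame,
    covariates: pd.DataFrame,
    window: int = 10_000,
    max_hidden_factors: int = 15,
    corr_cutoff: float = 0.85,
    min_class_size: int = 20,
    fdr: float = 0.05,
    vntr_loci: list[int] | None = None,
) -> pd.DataFrame:
    """Full association scan: pairing, filtering, residualization, ANOVA.

    ``tpm`` is genes × samples on the TPM scale; log2(TPM + 1) is used
    internally.  Genes with median TPM of zero are excluded.  ``vntr_loci``
    defaults to every locus where some sample carries a non-reference
    allele.
    """
    from .genotyping import classify_vntr_loci

    samples = [s for s in tpm.columns if s in {g.sample_id for g in cohort}]
    tpm = tpm[samples]
    tpm = tpm[tpm.median(axis=1) > 0]
    log2m = np.log2(tpm + 1.0)

    if vntr_loci is None:
        flags = classify_vntr_loci(cohort)
        vntr_loci = [lid for lid, f in flags.items() if f]
    loci = [ref_set[lid] for lid in vntr_loci]
    pairs = pair_genes_vntrs(
        gene_intervals[gene_intervals["gene"].isin(log2m.index)], loci, window
    )

    design = make_design(covariates.loc[samples])
    hidden = estimate_hidden_factors(
        log2m, design, max_k=max_hidden_factors, corr_cutoff=corr_cutoff
    )
    full_design = make_design(covariates.loc[samples], hidden_factors=hidden)
    residuals = residualize(log2m, full_design)

    classings = []
    classing_cache: dict[int, GenotypeClassing | None] = {}
    for gene, lid in pairs:
        if lid not in classing_cache:
            classing_cache[lid] = build_genotype_classes(
                cohort, lid, samples, min_class_size
            )
        if classing_cache[lid] is not None:
            classings.append((gene, classing_cache[lid]))
    return anova_scan(residuals, classings, fdr=fdr)
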