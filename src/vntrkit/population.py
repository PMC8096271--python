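"""Population-specific allele discovery and ancestry prediction.

Samples are encoded as binary presence/absence vectors over common VNTR
alleles, embedded by PCA, and classified into super-populations with a
decision tree trained on the top principal components.  Population-specific
marker alleles are found by a one-sided Fisher exact test of
over-representation in one population versus all others, with
Benjamini-Hochberg FDR control and a log2 odds-ratio effect floor.  A
"virtual gel" table renders each observed allele as its fragment length in
bp, mimicking agarose-gel bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.decomposition import PCA
from sklearn.metrics import recall_score
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .genotyping import SampleGenotype, format_cgl
from .reference import ReferenceTRSet

__all__ = [
    "AlleleMatrix",
    "build_allele_matrix",
    "pca_embed",
    "ClassificationResult",
    "classify_populations",
    "population_markers",
    "virtual_gel",
]


@dataclass
class AlleleMatrix:
    """Samples × alleles binary carrier matrix with population labels.

    Columns are (locus_id, CGL) pairs; a cell is 1 when the sample carries
    that allele at least once.  Every retained column is present in at least
    the configured fraction of samples.
    """

    data: pd.DataFrame  # index sample_id, columns MultiIndex (locus_id, cgl)
    labels: pd.Series  # sample_id -> population


def build_allele_matrix(
    cohort: list[SampleGenotype],
    labels: dict[str, str] | pd.Series,
    loci: list[int] | None = None,
    min_presence: float = 0.05,
) -> AlleleMatrix:
    """Binary presence/absence matrix over the alleles of the given loci.

    ``loci`` is normally the common-VNTR subset; ``None`` uses every
    genotyped locus.  Columns present in fewer than ``min_presence`` of the
    samples are dropped as uninformative.
    """
    locus_filter = set(loci) if loci is not None else None
    columns: dict[tuple[int, int], set[str]] = {}
    for g in cohort:
        for lid, calls in g.calls.items():
            if locus_filter is not None and lid not in locus_filter:
                continue
            for call in calls:
                columns.setdefault((lid, call.cgl), set()).add(g.sample_id)
    sample_ids = [g.sample_id for g in cohort]
    n = len(sample_ids)
    keys = sorted(k for k, carriers in columns.items() if n and len(carriers) / n >= min_presence)
    mat = np.zeros((n, len(keys)), dtype=np.int8)
    for j, key in enumerate(keys):
        carriers = columns[key]
        for i, sid in enumerate(sample_ids):
            if sid in carriers:
                mat[i, j] = 1
    data = pd.DataFrame(
        mat,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.MultiIndex.from_tuples(keys, names=["locus_id", "cgl"]),
    )
    lab = pd.Series(dict(labels)).reindex(sample_ids)
    return AlleleMatrix(data=data, labels=lab)


def pca_embed(
    matrix: AlleleMatrix, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the allele matrix.

    Columns are mean-centred but not variance-scaled (the data are binary).
    Returns (scores, explained-variance ratios); scores are deterministic up
    to sign.
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 alleles")
    k = min(n_components or min(X.shape), min(X.shape))
    if np.allclose(X.var(axis=0), 0):  # constant matrix: degenerate embedding
        cols = [f"PC{i + 1}" for i in range(k)]
        return (
            pd.DataFrame(np.zeros((X.shape[0], k)), index=matrix.data.index, columns=cols),
            np.zeros(k),
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.data.index, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClassificationResult:
    model: DecisionTreeClassifier
    recall_per_population: dict[str, float]
    test_index: pd.Index

    @property
    def min_recall(self) -> float:
        return min(self.recall_per_population.values())


def classify_populations(
    scores: pd.DataFrame,
    labels: pd.Series,
    n_pcs: int = 10,
    test_size: float = 0.3,
    cv: int = 10,
    seed: int = 0,
) -> ClassificationResult:
    """Train and evaluate an ancestry decision tree on PCA scores.

    A stratified 70/30 split is drawn with the given seed; the tree's depth
    is selected by ``cv``-fold cross-validation on the training partition
    and per-population recall is reported on the held-out samples.
    """
    X = scores.iloc[:, : min(n_pcs, scores.shape[1])]
    y = labels.reindex(X.index)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    # depth candidates ordered deepest-first: on tied CV scores the
    # unrestricted tree is preferred, which refits more stably on the full
    # training partition than a truncated one
    grid = GridSearchCV(
        DecisionTreeClassifier(random_state=seed),
        {"max_depth": [None, 8, 5, 3]},
        cv=cv,
    )
    grid.fit(X_tr, y_tr)
    model = grid.best_estimator_
    pops = sorted(y.unique())
    recalls = recall_score(y_te, model.predict(X_te), labels=pops, average=None)
    return ClassificationResult(
        model=model,
        recall_per_population=dict(zip(pops, recalls)),
        test_index=X_te.index,
    )


def population_markers(
    matrix: AlleleMatrix,
    fdr: float = 0.05,
    min_log2_or: float = 1.0,
) -> pd.DataFrame:
    """One-sided Fisher scan for alleles over-represented in one population.

    For every (allele, population) pair a 2×2 table of carriers inside the
    population versus all others is tested for over-representation (the
    hypergeometric upper tail).  The log2 odds ratio uses a 0.5 continuity
    correction when any cell is zero; the p-value stays exact.  q-values are
    Benjamini-Hochberg across all tests; a marker requires q < ``fdr`` and
    log2 OR > ``min_log2_or``.
    """
    pops = [p for p in sorted(matrix.labels.dropna().unique())]
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    rows = []
    X = matrix.data
    for pop in pops:
        in_pop = (matrix.labels == pop).to_numpy()
        n_in, n_out = int(in_pop.sum()), int((~in_pop).sum())
        if n_in == 0:
            continue
        carriers_in = X.to_numpy()[in_pop].sum(axis=0)
        carriers_out = X.to_numpy()[~in_pop].sum(axis=0)
        for j, (lid, cgl) in enumerate(X.columns):
            a = int(carriers_in[j])
            b = n_in - a
            c = int(carriers_out[j])
            d = n_out - c
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            if min(a, b, c, d) == 0:
                aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            else:
                aa, bb, cc, dd = a, b, c, d
            log2_or = np.log2((aa * dd) / (bb * cc))
            rows.append(
                {
                    "locus_id": lid,
                    "cgl": cgl,
                    "population": pop,
                    "carriers_in": a,
                    "carriers_out": c,
                    "p_value": p,
                    "log2_odds_ratio": log2_or,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        result["marker"] = []
        return result
    result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["marker"] = (result["q_value"] < fdr) & (result["log2_odds_ratio"] > min_log2_or)
    return result


def virtual_gel(
    loci: list[int],
    cohort: list[SampleGenotype],
    ref_set: ReferenceTRSet,
    labels: dict[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Band table for a virtual-gel rendering of selected loci.

    One row per observed allele per sample; the band length is the allele's
    array length in bp (pattern length × allele copies).  Plot-layer jitter
    is left to the caller.
    """
    labels = dict(labels) if labels is not None else {}
    rows = []
    for g in cohort:
        for lid in loci:
            for cgl in g.alleles(lid):
                rows.append(
                    {
                        "sample_id": g.sample_id,
                        "population": labels.get(g.sample_id, ""),
                        "locus_id": lid,
                        "allele": format_cgl(cgl),
                        "band_bp": ref_set[lid].allele_array_length(cgl),
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "population", "locus_id", "allele", "band_bp"])
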