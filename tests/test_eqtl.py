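"""Gene-VNTR pairing, genotype classes, residualization and ANOVA scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vntrkit.eqtl import (
    anova_scan,
    build_genotype_classes,
    estimate_hidden_factors,
    eqtl_scan,
    make_design,
    pair_genes_vntrs,
    residualize,
)
from vntrkit.genotyping import AlleleCall, SampleGenotype
from vntrkit.reference import ReferenceTRLocus
from vntrkit.simulate import (
    EqtlEffectSpec,
    SimulationConfig,
    generate_reference,
    sample_cohort,
    simulate_expression,
)


def geno(calls_by_locus, sample_id="S"):
    g = SampleGenotype(sample_id=sample_id, sex="F")
    for lid, alleles in calls_by_locus.items():
        g.calls[lid] = [AlleleCall(lid, c, 5) for c in alleles]
    return g


def locus(lid, start, end, chrom="chr1"):
    return ReferenceTRLocus(lid, chrom, start, end, "ACGTACG", 3.0)


class TestPairing:
    def test_within_and_beyond_window(self):
        genes = pd.DataFrame(
            [
                {"gene": "G1", "chrom": "chr1", "start": 20_000, "end": 22_000},
                {"gene": "G2", "chrom": "chr1", "start": 40_000, "end": 42_000},
                {"gene": "G3", "chrom": "chr2", "start": 20_000, "end": 22_000},
            ]
        )
        loci = [locus(1, 14_000, 15_000), locus(2, 29_000, 29_999)]
        pairs = pair_genes_vntrs(genes, loci)
        # locus 1 is 5 kb upstream of G1 -> paired; locus 2 ends 10 001 bp
        # before G2 -> not paired; chrom mismatch for G3
        assert ("G1", 1) in pairs
        assert ("G2", 2) not in pairs
        assert not any(g == "G3" for g, _ in pairs)

    def test_exact_boundary_and_overlap(self):
        genes = pd.DataFrame(
            [{"gene": "G", "chrom": "chr1", "start": 20_000, "end": 22_000}]
        )
        assert pair_genes_vntrs(genes, [locus(1, 9_000, 10_000)]) == [("G", 1)]
        assert pair_genes_vntrs(genes, [locus(2, 20_500, 20_600)]) == [("G", 2)]


class TestGenotypeClasses:
    def _cohort(self, counts):
        cohort, sids = [], []
        i = 0
        for label, n in counts.items():
            for _ in range(n):
                sid = f"S{i}"
                if label == "other":
                    cohort.append(geno({}, sample_id=sid))
                else:
                    alleles = [int(x) for x in label.split("/")]
                    cohort.append(geno({1: alleles}, sample_id=sid))
                sids.append(sid)
                i += 1
        return cohort, sids

    def test_retained_with_three_classes(self):
        cohort, sids = self._cohort({"0/0": 200, "0/+1": 150, "other": 95})
        classing = build_genotype_classes(cohort, 1, sids)
        assert classing.class_counts == {"0/0": 200, "0/+1": 150, "other": 95}

    def test_small_class_excludes_locus(self):
        cohort, sids = self._cohort({"0/0": 430, "0/+1": 15})
        assert build_genotype_classes(cohort, 1, sids) is None

    def test_other_requires_three_classes(self):
        cohort, sids = self._cohort({"0/0": 425, "other": 20})
        assert build_genotype_classes(cohort, 1, sids) is None

    def test_two_called_classes_suffice(self):
        cohort, sids = self._cohort({"0/0": 30, "-1/0": 25})
        classing = build_genotype_classes(cohort, 1, sids)
        assert set(classing.class_counts) == {"0/0", "-1/0"}


class TestResidualize:
    def _data(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], size=n),
                "population": rng.choice(["P1", "P2", "P3"], size=n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        return cov

    def test_exact_linear_function_leaves_zero_residuals(self):
        cov = self._data()
        design = make_design(cov)
        Y = pd.DataFrame(
            (2.0 * design["sex"] + 3.0 * design.get("population_P2", 0) + 1.0).to_numpy()[None, :],
            index=["G"],
            columns=cov.index,
        )
        resid = residualize(Y, design)
        assert np.allclose(resid.to_numpy(), 0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        cov = self._data(seed=4)
        design = make_design(cov)
        Y = pd.DataFrame(
            rng.normal(size=(30, len(cov))), index=[f"G{i}" for i in range(30)], columns=cov.index
        )
        resid = residualize(Y, design)
        for col in design.columns[1:]:
            v = design[col].to_numpy(dtype=float)
            if np.std(v) == 0:
                continue
            corr = np.corrcoef(resid.to_numpy(), v)[: len(resid), -1]
            assert np.abs(corr).max() < 1e-8

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        cov = self._data(seed=5)
        design = make_design(cov)
        Y = pd.DataFrame(
            rng.normal(size=(5, len(cov))), index=list("ABCDE"), columns=cov.index
        )
        resid = residualize(Y, design)
        perm = rng.permutation(len(cov))
        resid_p = residualize(Y.iloc[:, perm], design.iloc[perm])
        assert np.allclose(resid.iloc[:, perm].to_numpy(), resid_p.to_numpy())

    def test_rank_deficient_design_names_columns(self):
        cov = self._data()
        design = make_design(cov)
        design["dup"] = design["sex"]
        with pytest.raises(ValueError, match="dup"):
            residualize(
                pd.DataFrame(np.zeros((1, len(cov))), index=["G"], columns=cov.index),
                design,
            )

    def test_missing_covariates_name_samples(self):
        cov = self._data()
        design = make_design(cov)
        design.iloc[3, 1] = np.nan
        with pytest.raises(ValueError, match="S3"):
            residualize(
                pd.DataFrame(np.zeros((1, len(cov))), index=["G"], columns=cov.index),
                design,
            )


class TestHiddenFactors:
    def _sim(self, seed=61, n_hidden=2):
        cfg = SimulationConfig(
            n_populations=2, samples_per_population=100, n_loci=10,
            pattern_length_range=(7, 12), indistinguishable_fraction=0.0,
            x_fraction=0.0, y_fraction=0.0, n_hidden_factors=n_hidden, seed=seed,
        )
        ref_set, _ = generate_reference(cfg)
        truth = sample_cohort(ref_set, cfg)
        sim = simulate_expression(truth, ref_set, cfg, n_genes=60)
        return sim

    def test_planted_batch_factor_recovered(self):
        sim = self._sim(n_hidden=1)
        log2m = np.log2(sim.tpm + 1.0)
        design = make_design(sim.covariates)
        factors = estimate_hidden_factors(log2m, design, max_k=5)
        assert len(factors) >= 1
        truth_scores = sim.factor_scores.iloc[0]
        best = max(
            abs(np.corrcoef(truth_scores, est)[0, 1]) for _, est in factors.iterrows()
        )
        assert best > 0.9

    def test_two_factor_subspace_recovered(self):
        # individual factors are only identified up to rotation; check that
        # the estimated factors span the planted subspace
        sim = self._sim(n_hidden=2)
        log2m = np.log2(sim.tpm + 1.0)
        factors = estimate_hidden_factors(log2m, make_design(sim.covariates), max_k=5)
        F = factors.to_numpy().T  # samples x k
        F = np.column_stack([np.ones(F.shape[0]), F])
        for _, truth_scores in sim.factor_scores.iterrows():
            y = truth_scores.to_numpy()
            beta, *_ = np.linalg.lstsq(F, y, rcond=None)
            r2 = 1 - np.sum((y - F @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
            assert r2 > 0.8

    def test_zero_cutoff_accepts_nothing(self):
        sim = self._sim()
        log2m = np.log2(sim.tpm + 1.0)
        factors = estimate_hidden_factors(
            log2m, make_design(sim.covariates), max_k=5, corr_cutoff=0.0
        )
        assert len(factors) == 0

    def test_pure_noise_factors_are_uninformative(self):
        """On pure noise every extracted factor explains only about
        1/min(n_genes, n_samples) of the residual variance."""
        rng = np.random.default_rng(7)
        n = 100
        cov = pd.DataFrame(
            {"sex": ["F", "M"] * (n // 2)}, index=[f"S{i}" for i in range(n)]
        )
        Y = pd.DataFrame(
            rng.normal(size=(50, n)), index=[f"G{i}" for i in range(50)], columns=cov.index
        )
        factors = estimate_hidden_factors(Y, make_design(cov), max_k=5)
        R = Y.to_numpy() - Y.to_numpy().mean(axis=1, keepdims=True)
        total_var = (R**2).sum()
        for _, est in factors.iterrows():
            v = est.to_numpy()
            proj = R @ v[:, None] / np.linalg.norm(v)
            share = (proj**2).sum() / total_var
            assert share < 3 / min(Y.shape)


class TestAnova:
    def test_equal_means_give_null_statistics(self):
        rng = np.random.default_rng(8)
        sids = [f"S{i}" for i in range(200)]
        resid = pd.DataFrame(rng.normal(size=(1, 200)), index=["G"], columns=sids)
        labels = pd.Series(["0/0"] * 100 + ["0/+1"] * 100, index=sids)
        from vntrkit.eqtl import GenotypeClassing

        classing = GenotypeClassing(1, labels, {"0/0": 100, "0/+1": 100})
        res = anova_scan(resid, [("G", classing)])
        assert res.iloc[0]["p_value"] > 0.05

    def test_f_equals_squared_t_for_two_classes(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.4, 1, 80)
        sids = [f"S{i}" for i in range(140)]
        resid = pd.DataFrame(np.concatenate([a, b])[None, :], index=["G"], columns=sids)
        labels = pd.Series(["A"] * 60 + ["B"] * 80, index=sids)
        from vntrkit.eqtl import GenotypeClassing

        classing = GenotypeClassing(1, labels, {"A": 60, "B": 80})
        res = anova_scan(resid, [("G", classing)])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.iloc[0]["F"] == pytest.approx(t**2, rel=1e-9)

    def test_bh_null_simulation_controls_discoveries(self):
        """With no true effects, BH at 5% yields (on average) almost no
        discoveries across 1000 independent null pairs."""
        rng = np.random.default_rng(10)
        from vntrkit.eqtl import GenotypeClassing

        sids = [f"S{i}" for i in range(80)]
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=sids)
        classing = GenotypeClassing(1, labels, {"A": 40, "B": 40})
        resid = pd.DataFrame(
            rng.normal(size=(1000, 80)), index=[f"G{i}" for i in range(1000)], columns=sids
        )
        res = anova_scan(resid, [(f"G{i}", classing) for i in range(1000)])
        assert res["significant"].sum() <= 0.05 * 1000


class TestFullScan:
    def test_planted_effects_recovered_with_fdr_control(self):
        """A scan over 1071 gene-VNTR pairs with 193 planted 1.0-log2 effects
        attains sensitivity >= 0.9 at observed FDR <= 0.1."""
        n_pairs, n_effects = 1071, 193
        cfg = SimulationConfig(
            n_populations=2, samples_per_population=223, n_loci=n_pairs,
            pattern_length_range=(7, 12), ref_copies_range=(2.0, 4.5),
            allele_cgl_range=(-1, 0), ref_allele_weight=0.6,
            indistinguishable_fraction=0.0, x_fraction=0.0, y_fraction=0.0,
            n_hidden_factors=2, seed=71,
        )
        ref_set, _ = generate_reference(cfg)
        truth = sample_cohort(ref_set, cfg)
        effects = [
            EqtlEffectSpec(
                f"EG{i}", i + 1, {"-1/0": 1.0, "-1/-1": 1.0}
            )
            for i in range(n_effects)
        ]
        cfg.eqtl_effect_spec = effects
        sim = simulate_expression(truth, ref_set, cfg, n_genes=n_pairs)
        cohort = truth.to_cohort()
        sids = list(sim.tpm.columns)

        log2m = np.log2(sim.tpm + 1.0)
        design = make_design(sim.covariates)
        hidden = estimate_hidden_factors(log2m, design, max_k=5)
        resid = residualize(log2m, make_design(sim.covariates, hidden))

        classings = []
        genes = list(sim.tpm.index)
        for i, gene in enumerate(genes[:n_pairs]):
            classing = build_genotype_classes(cohort, i + 1, sids)
            if classing is not None:
                classings.append((gene, classing))
        assert len(classings) > 1000  # the 20-member filter rarely triggers
        res = anova_scan(resid, classings)

        true_genes = {f"EG{i}" for i in range(n_effects)}
        hits = set(res[res["significant"]]["gene"])
        tp = len(hits & true_genes)
        fp = len(hits - true_genes)
        sensitivity = tp / len(true_genes & set(res["gene"]))
        assert sensitivity >= 0.9
        assert fp / max(1, len(hits)) <= 0.1
        # effect size is recovered in the reported max mean difference
        sig_true = res[res["significant"] & res["gene"].isin(true_genes)]
        assert abs(sig_true["max_mean_diff"].median() - 1.0) < 0.25

    def test_null_scan_through_pipeline_wrapper(self):
        cfg = SimulationConfig(
            n_populations=2, samples_per_population=60, n_loci=30,
            pattern_length_range=(7, 12), ref_copies_range=(2.0, 4.5),
            allele_cgl_range=(-1, 0), ref_allele_weight=0.6,
            indistinguishable_fraction=0.0, x_fraction=0.0, y_fraction=0.0,
            n_hidden_factors=1, seed=73,
        )
        ref_set, _ = generate_reference(cfg)
        truth = sample_cohort(ref_set, cfg)
        sim = simulate_expression(truth, ref_set, cfg, n_genes=40)
        # place every gene near a locus so some pairs form
        genes = sim.gene_intervals.copy()
        loci = list(ref_set)
        for i in range(len(genes)):
            loc = loci[i % len(loci)]
            genes.loc[i, ["chrom", "start", "end"]] = [loc.chrom, loc.end + 100, loc.end + 2100]
        res = eqtl_scan(
            truth.to_cohort(), ref_set, genes, sim.tpm, sim.covariates,
            max_hidden_factors=3,
        )
        assert len(res) > 0
        assert res["significant"].sum() <= max(2, 0.05 * len(res))
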