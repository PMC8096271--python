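"""Scan for VNTR-expression associations with planted effects.

Simulates expression for 150 genes where five genes' log2 levels shift by
+1.0 in carriers of a one-copy loss at a nearby locus, then runs the full
scan: pairing within 10 kb, genotype classes ("other" pools ungenotyped
samples; every class needs >= 20 members), residualization on sex +
population + hidden factors, one-way ANOVA per pair, BH FDR.

The gene panel is deliberately not tiny: surrogate-variable estimation works
on the residual's leading principal components, and with very few genes a
single strong genotype effect can dominate a component and be absorbed.
"""

from vntrkit.eqtl import eqtl_scan
from vntrkit.simulate import (
    EqtlEffectSpec, SimulationConfig, generate_reference, sample_cohort, simulate_expression,
)

cfg = SimulationConfig(
    n_populations=2, samples_per_population=120, n_loci=40,
    pattern_length_range=(7, 12), ref_copies_range=(2.0, 4.5),
    allele_cgl_range=(-1, 0), ref_allele_weight=0.6,
    indistinguishable_fraction=0.0, x_fraction=0.0, y_fraction=0.0,
    n_hidden_factors=2, seed=61,
)
ref_set, _ = generate_reference(cfg)
truth = sample_cohort(ref_set, cfg)

targets = [loc.locus_id for loc in ref_set.singletons[:5]]
cfg.eqtl_effect_spec = [
    EqtlEffectSpec(f"TARGET{i}", lid, {"-1/0": 1.0, "-1/-1": 1.0})
    for i, lid in enumerate(targets)
]
sim = simulate_expression(truth, ref_set, cfg, n_genes=150)

result = eqtl_scan(truth.to_cohort(), ref_set, sim.gene_intervals,
                   sim.tpm, sim.covariates, max_hidden_factors=5)
sig = result[result["significant"]]
print(f"tested {len(result)} gene-VNTR pairs; {len(sig)} significant at FDR<0.05")
for _, hit in sig.iterrows():
    print(f"  {hit['gene']} ~ locus {hit['locus_id']}: F={hit['F']:.1f}, "
          f"q={hit['q_value']:.2e}, max class-mean difference {hit['max_mean_diff']:.2f} log2")
recovered = {(f"TARGET{i}", lid) for i, lid in enumerate(targets)} & set(
    zip(sig["gene"], sig["locus_id"])
)
print(f"{len(recovered)}/5 planted gene-locus pairs recovered at their true locus;")
print("the planted shift was 1.0 log2 units for carriers of the -1 allele")
print(f"(class table of the first hit: {sig.iloc[0]['classes']})")
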