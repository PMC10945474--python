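"""Classify genes into the ten additive / ELD / TRE categories.

Each gene is judged by three pairwise NB differential-expression
verdicts (allotetraploid vs each parent, parent vs parent) at FC > 2 and
FDR < 0.05; the verdict triple maps onto categories a-j.  Complete
expression-level dominance (ELD) means total expression matches one
parent but not the other; transgressive expression (TRE) lies outside
both parents.
"""

from homeobias import (
    SimConfig, classify_all, estimate_dispersion, simulate_experiment,
    tally_categories, test_contrast, tmm_factors, filter_expressed,
)

ds = simulate_experiment(SimConfig(n_chromosomes=4, genes_per_chromosome=150, seed=2, eld_fraction=0.08))
cm = ds.unphased.subset_genes(filter_expressed(ds.unphased))
groups = cm.sample_meta["group"]
factors = tmm_factors(cm)
disp = estimate_dispersion(cm, groups, factors)

de = {
    pair: test_contrast(cm, groups, pair, factors, disp)
    for pair in [("Sd", "Cg2"), ("Sd", "Co2"), ("Cg2", "Co2")]
}
cats = classify_all(de[("Sd", "Cg2")], de[("Sd", "Co2")], de[("Cg2", "Co2")], group="Sd")

print(cats["category"].value_counts().sort_index().to_string())
print()
print(tally_categories({"Sd": cats}).to_string(index=False))
print("\ncategories c-f are complete ELD; g-j are TRE; a/b are additive-like.")
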