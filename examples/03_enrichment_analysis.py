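"""Fisher's-exact over-representation of keloid-specific DE mRNAs.

Builds a small synthetic gene-set collection (ten random background sets plus
one set concentrated in the planted DE genes), then tests the keloid-specific
mRNA list against it.  The planted set should dominate the ranking.
"""

from keloidcerna import (
    DEThresholds,
    SimulationConfig,
    emit_gene_sets,
    fisher_enrichment,
    keloid_specific_features,
    nb_wald_test,
    screen_de,
    simulate_counts,
)

config = SimulationConfig(seed=3)
counts, sheet, biotypes, lengths, truth = simulate_counts(config)

thr = DEThresholds()
keloid = screen_de(nb_wald_test(counts.select(group="keloid")), thr)
control = screen_de(nb_wald_test(counts.select(group="control")), thr)
specific = keloid_specific_features(keloid, control).keloid_specific

universe = biotypes.genes_of("mRNA", counts.feature_ids)
de_mrnas = specific & set(universe)
gene_sets = emit_gene_sets(truth, universe, seed=config.seed)

records = fisher_enrichment(de_mrnas, universe, gene_sets, alpha=0.05)

print(f"DE mRNAs tested: {len(de_mrnas)} of a {len(universe)}-gene universe\n")
print("term              Ct.   p-value     adjusted p  significant")
for r in records[:5]:
    print(f"{r.term_id:<18}{r.count:<6}{r.pvalue:<12.3g}{r.padj:<12.3g}{r.significant}")
print("\n'Ct.' counts the DE genes inside each term; only the set built from")
print("the planted DE genes reaches significance — random sets stay near p 1.")
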