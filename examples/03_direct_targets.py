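"""Direct-target calling by regulatory potential plus DE rank product.

Assigns peaks to genes within 3 kb of the TSS, scores each gene by the
distance-decay regulatory potential sum(exp(-(0.5 + 4d/3kb))), calls DEGs
with non-zero potential ranked by the normalized rank product, and runs
the one-sided KS test that classifies the factor as activator/repressor.
"""

from chipexpr import (
    SynthConfig,
    assign_peaks_to_genes,
    call_direct_targets,
    ks_function_test,
    regulatory_potential,
    simulate_all,
)

bundle = simulate_all(SynthConfig(seed=1))

assignments = assign_peaks_to_genes(bundle.peaks_a, bundle.tss, window_bp=3000)
rp = regulatory_potential(assignments, window_norm_bp=3000)
calls = call_direct_targets(rp, bundle.degs_a, fdr_cutoff=0.05)
ftest = ks_function_test(rp, bundle.degs_a)

print(f"direct targets called for factor A: {len(calls)}")
top = calls[0]
print(
    f"best-ranked target {top.gene_id}: rank product {top.rank_product:.4f}, "
    f"log2FC {top.log2fc:+.2f} ({top.direction})"
)
n_down = sum(c.log2fc < 0 for c in calls)
print(f"targets down in the mutant: {n_down}/{len(calls)}")
print(f"KS verdict: {ftest.verdict} (p_down={ftest.p_down:.2e}, p_up={ftest.p_up:.2f})")
# Nearly all direct targets are down in the mutant and only the down-set
# carries elevated potential, so the factor reads as an activator.
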