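"""Map additive growth loci: scan, prune linked peaks, select by FDR.

Simulates five causal loci among 60 markers, runs the per-environment
marginal scan, collapses peaks within 20 kb and r^2 > 0.9 to one
representative, and fits the survivors jointly with BH FDR control.
"""

import pandas as pd

from ggxe import (
    LocusSet,
    SimArchitecture,
    estimate_effects,
    marginal_scan,
    polygenic_select,
    prune_loci,
    simulate_genotypes,
    simulate_phenotypes,
    uniform_map,
)

gmap = uniform_map(n_chrom=6, markers_per_chrom=10, spacing_cM=15.0)
geno = simulate_genotypes(2000, gmap, seed=3)
causal = geno.markers[::12][:5]
arch = SimArchitecture(
    environments=["env01"],
    additive_effects={m: {"env01": 0.3} for m in causal},
    residual_sd=1.0,
    replicates=2,
)
pheno = simulate_phenotypes(geno, arch, seed=4)

scan = marginal_scan(geno, pheno, "env01")
peaks = scan[scan["p"] < 0.05 / len(geno.markers)]
print(f"marginal scan: {len(peaks)} markers below the genome-wide threshold")
pruned = prune_loci(peaks, geno, max_dist_bp=20_000, min_r2=0.9)
print(f"after pruning (20 kb AND r^2 > 0.9): {len(pruned.loci)} independent peaks")
selected = polygenic_select(geno, pheno, pruned, fdr=0.05)
flagged = selected.significant("env01")
print(f"joint polygenic fit, BH FDR < 0.05: {len(flagged)} loci flagged")
print(f"planted causal loci recovered: {sorted(set(flagged) & set(causal))}")

effects = estimate_effects(geno, pheno, selected, "env01")
print(effects[effects["significant"]][["locus", "effect", "se", "p_adj"]]
      .to_string(index=False))
# Effects are per allele copy on the 0/2 coding: a planted 0.3 should be
# estimated near 0.3 with SE ~ 1/sqrt(n).
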