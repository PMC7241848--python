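"""Partition growth variance into genotype (G) and G-by-environment parts.

Plants a panel in which one locus has a constant effect everywhere (pure G)
and another switches sign across environments (pure G-by-E), then checks the
two-way ANOVA recovers the planted 1:3 SS ratio.
"""

import numpy as np

from ggxe import SimArchitecture, partition_gxe, simulate_genotypes, simulate_phenotypes, uniform_map

gmap = uniform_map(n_chrom=2, markers_per_chrom=1, spacing_cM=0.0)
geno = simulate_genotypes(2000, gmap, seed=1)
const_locus, switch_locus = geno.markers
envs = [f"env{j:02d}" for j in range(20)]
b_c = 0.3
# choose the switched effect so that E[SS_G]/E[SS_GxE] = 1/3
b_s = np.sqrt(20 * b_c**2 / ((1 / 3) * 19))
arch = SimArchitecture(
    environments=envs,
    additive_effects={
        const_locus: {e: b_c for e in envs},
        switch_locus: {e: (b_s if j % 2 == 0 else -b_s) for j, e in enumerate(envs)},
    },
    residual_sd=0.05,
    replicates=1,
)
pheno = simulate_phenotypes(geno, arch, seed=2)

vc = partition_gxe(pheno)
print(f"SS_G      = {vc.SS_G:10.2f}  (fraction {vc.fraction_G:.3f})")
print(f"SS_E      = {vc.SS_E:10.2f}  (fraction {vc.fraction_E:.3f})")
print(f"SS_GxE    = {vc.SS_GxE:10.2f}  (fraction {vc.fraction_GxE:.3f})")
print(f"SS_resid  = {vc.SS_resid:10.2f}")
print(f"G : GxE ratio = {vc.fraction_G / vc.fraction_GxE:.3f} (planted 1/3)")
# A ratio near 1/3 means genotype main effects carry a third as much growth
# variance as genotype-by-environment interactions in this panel.
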