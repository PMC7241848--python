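"""Quantify hub capacitation: conditional heritability by hub genotype.

In the active environment the hub's 0-allele hides the six radial effects
(masked stratum: h^2 ~ 0) while the 2-allele releases them
(h^2 ~ Var_radial / (Var_radial + sigma^2) ~ 0.35 for six effects of 0.3).
"""

from ggxe import (
    conditional_h2,
    decreasing_allele_profile,
    genotype_class_env_lrt,
    make_capacitor_arch,
    simulate_genotypes,
    simulate_phenotypes,
    uniform_map,
)

gmap = uniform_map(n_chrom=6, markers_per_chrom=10, spacing_cM=15.0)
arch = make_capacitor_arch(gmap, n_envs=3, seed=10)
geno = simulate_genotypes(4000, gmap, seed=11)
pheno = simulate_phenotypes(geno, arch, seed=12)
cap = arch.capacitors[0]
radials = cap.radials("env01")

stat = conditional_h2(geno, pheno, cap.hub, radials, "env01")
print(f"hub {cap.hub} in env01:")
print(f"  h^2 | hub allele 0 = {stat.h2_allele0:.3f}  (n = {stat.n_allele0})")
print(f"  h^2 | hub allele 2 = {stat.h2_allele2:.3f}  (n = {stat.n_allele2})")
print(f"  delta h^2 = {stat.delta_h2:+.3f}")

lr, df, p = genotype_class_env_lrt(geno, pheno, [cap.hub] + radials[:5],
                                   arch.environments)
print(f"genotype-class x environment LRT: LR = {lr:.1f}, df = {df}, p = {p:.2e}")

profile = decreasing_allele_profile(geno, pheno, cap.hub, radials, "env01")
print(profile.to_string(index=False))
# In the released stratum mean growth falls with the number of
# growth-decreasing radial alleles; in the masked stratum it stays flat —
# the radial variation is cryptic there.
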