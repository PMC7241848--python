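"""Simulate a haploid biparental cross with a known capacitor architecture.

Builds a small genetic map, generates segregants by Haldane-model meiosis,
and simulates replicated growth in three environments in which a hub locus
masks six radial loci in the first environment and is silent in the last.
"""

from ggxe import make_capacitor_arch, simulate_genotypes, simulate_phenotypes, uniform_map

gmap = uniform_map(n_chrom=6, markers_per_chrom=10, spacing_cM=15.0)
arch = make_capacitor_arch(gmap, n_envs=3, seed=0)
geno = simulate_genotypes(n_segregants=1000, gmap=gmap, seed=1)
pheno = simulate_phenotypes(geno, arch, seed=2)

cap = arch.capacitors[0]
print(f"map: {len(gmap.markers)} markers on 6 chromosomes")
print(f"panel: {len(geno.segregants)} segregants x {len(geno.markers)} markers")
print(f"phenotypes: {len(pheno.records)} rows "
      f"({len(arch.environments)} environments x {arch.replicates} replicates)")
print(f"planted hub: {cap.hub}, masking allele {cap.masking_allele}")
for env in arch.environments:
    print(f"  {env}: {len(arch.true_pairs(env))} active hub-radial interactions")
# The hub's interactions are fully active in env01 and absent in env03:
# growth variance released by the hub differs between those environments.
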