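import numpy as np
import pandas as pd
import pytest

from ggxe import (
    Capacitor,
    GeneticMap,
    SimArchitecture,
    simulate_genotypes,
    simulate_phenotypes,
    uniform_map,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Six chromosomes, 8 markers each, 25 cM spacing (loosely linked)."""
    return uniform_map(n_chrom=6, markers_per_chrom=8, spacing_cM=25.0)


@pytest.fixture(scope="session")
def unlinked_map() -> GeneticMap:
    """One marker per chromosome: all loci segregate independently."""
    return uniform_map(n_chrom=24, markers_per_chrom=1, spacing_cM=0.0)


def unlinked_genotypes(n: int, n_loci: int, seed: int):
    """Genotypes at fully independent loci (one per chromosome)."""
    gmap = uniform_map(n_chrom=n_loci, markers_per_chrom=1, spacing_cM=0.0)
    return simulate_genotypes(n, gmap, seed=seed)


def capacitor_panel(
    n: int,
    seed: int,
    radial_effect: float = 0.3,
    n_radials: int = 6,
    residual_sd: float = 1.0,
    replicates: int = 1,
    n_null: int = 5,
    masking_allele: int = 0,
    active_env: str = "env01",
    silent_env: str = "env02",
):
    """Panel with one hub masking ``n_radials`` radial effects in one
    environment and silent in another, plus ``n_null`` inert loci.

    Returns (geno, pheno, arch); all loci are unlinked.
    """
    n_loci = 1 + n_radials + n_null
    geno = unlinked_genotypes(n, n_loci, seed)
    markers = geno.markers
    hub, radials = markers[0], markers[1 : 1 + n_radials]
    arch = SimArchitecture(
        environments=[active_env, silent_env],
        capacitors=[
            Capacitor(
                hub=hub,
                masking_allele=masking_allele,
                radial_effects={active_env: {r: radial_effect for r in radials}},
            )
        ],
        residual_sd=residual_sd,
        replicates=replicates,
    )
    pheno = simulate_phenotypes(geno, arch, seed=seed + 1)
    return geno, pheno, arch


@pytest.fixture(scope="session")
def cap_panel():
    """A moderately sized capacitor panel shared across read-only tests."""
    return capacitor_panel(n=2000, seed=11)
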