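"""Hub capacitation: conditional heritability and masked allelic effects.

A capacitor hub hides or releases the effects of its radial interactors
depending on which allele a segregant carries.  The stratified analysis
splits the panel by hub genotype and, within each stratum, estimates the
narrow-sense heritability captured by the radial loci (adjusted r^2 of their
joint additive model on segregant mean growth) together with the per-radial
allelic effects.  A strong capacitor shows a large heritability difference
between strata and near-zero radial effects in the masked stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import gaussian_lrt, ols_fit
from .additive import _env_means
from .simulate import GenotypeMatrix, PhenotypeTable

__all__ = [
    "CapacitationStat",
    "conditional_h2",
    "genotype_class_env_lrt",
    "decreasing_allele_profile",
]


@dataclass
class CapacitationStat:
    hub: str
    environment: str
    h2_allele0: float
    h2_allele2: float
    n_allele0: int
    n_allele2: int
    radial_effects: pd.DataFrame  # locus, allele stratum, effect, se

    @property
    def delta_h2(self) -> float:
        """h^2 on the hub's 2-allele minus h^2 on its 0-allele (signed)."""
        return self.h2_allele2 - self.h2_allele0

    @property
    def abs_delta_h2(self) -> float:
        return abs(self.delta_h2)


def conditional_h2(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    hub: str,
    radials: list[str],
    environment: str,
    min_group: int = 30,
) -> CapacitationStat:
    """Stratified narrow-sense heritability of the radial loci by hub genotype.

    Within each hub-genotype group, h^2 = adjusted r^2 (clamped at 0) of the
    joint additive model of the radial loci on segregant mean growth; the
    per-radial effect estimates come from the same stratified fits.
    """
    if hub in radials:
        raise ValueError("hub cannot be among its own radial loci")
    segs, y = _env_means(geno, pheno, environment)
    h = geno.values.loc[segs, hub].to_numpy(dtype=float)
    G = geno.values.loc[segs, list(radials)].to_numpy(dtype=float)
    out_h2, out_n, eff_rows = {}, {}, []
    for allele in (0, 2):
        sel = h == allele
        n = int(sel.sum())
        if n < min_group:
            raise ValueError(
                f"hub {hub!r} allele {allele} stratum has {n} segregants "
                f"(< {min_group})"
            )
        X = np.column_stack([np.ones(n), G[sel]])
        fit = ols_fit(X, y[sel])
        out_h2[allele] = max(fit.adj_r2, 0.0)
        out_n[allele] = n
        for j, locus in enumerate(radials):
            eff_rows.append(
                {
                    "locus": locus,
                    "hub_allele": allele,
                    "effect": fit.coef[j + 1],
                    "se": fit.se[j + 1],
                }
            )
    return CapacitationStat(
        hub=hub,
        environment=environment,
        h2_allele0=out_h2[0],
        h2_allele2=out_h2[2],
        n_allele0=out_n[0],
        n_allele2=out_n[2],
        radial_effects=pd.DataFrame(eff_rows),
    )


def genotype_class_env_lrt(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    loci: list[str],
    environments: list[str] | None = None,
) -> tuple[float, int, float]:
    """Multi-locus genotype-class x environment interaction LRT.

    The 2^L genotype classes defined by up to 6 loci replace the single-locus
    indicator: replicate-level growth is modelled with class and environment
    main effects (reduced) versus class, environment, and class x environment
    (full).  With all classes observed in all environments the df is
    (n_classes - 1) * (n_envs - 1); empty class-environment combinations are
    dropped and the df computed from the design ranks.
    """
    if len(loci) > 6:
        raise ValueError("at most 6 loci (64 genotype classes) supported")
    rec = pheno.records
    if environments is not None:
        rec = rec[rec["environment"].isin(environments)]
    rec = rec[rec["segregant"].isin(geno.segregants)]
    envs = sorted(rec["environment"].unique())
    if len(envs) < 2:
        raise ValueError("need >= 2 environments")
    G = geno.values.loc[rec["segregant"], list(loci)].to_numpy()
    labels = [tuple(row) for row in (G // 2)]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError(f"only {len(classes)} observed genotype class(es)")
    class_idx = {c: i for i, c in enumerate(classes)}
    ci = np.array([class_idx[l] for l in labels])
    ei = pd.Categorical(rec["environment"], categories=envs).codes
    y = rec["growth"].to_numpy(dtype=float)
    n = len(y)
    C = np.zeros((n, len(classes) - 1))
    for c in range(1, len(classes)):
        C[ci == c, c - 1] = 1.0
    E = np.zeros((n, len(envs) - 1))
    for j in range(1, len(envs)):
        E[ei == j, j - 1] = 1.0
    X_red = np.column_stack([np.ones(n), C, E])
    inter = np.einsum("ij,ik->ijk", C, E).reshape(n, -1)
    X_full = np.column_stack([X_red, inter])
    return gaussian_lrt(X_full, X_red, y)


def decreasing_allele_profile(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    hub: str,
    radials: list[str],
    environment: str,
    signs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Growth by number of growth-decreasing radial alleles and hub genotype.

    Radial allele signs come from the joint additive fit of hub + radials on
    segregant mean growth in the environment: for a positive effect the
    0-allele decreases growth, for a negative effect the 2-allele does.
    Each segregant's count of growth-decreasing radial alleles is tabulated
    against its hub genotype with group means and dispersions.

    When effects are truly null, estimating the signs from the same data
    induces a winner's-curse association between the count and growth; pass
    externally determined ``signs`` (locus -> +1/-1) to avoid it.
    """
    segs, y = _env_means(geno, pheno, environment)
    G = geno.values.loc[segs, list(radials)].to_numpy(dtype=float)
    h = geno.values.loc[segs, hub].to_numpy(dtype=float)
    if signs is None:
        X = np.column_stack([np.ones(len(y)), h, G])
        fit = ols_fit(X, y)
        sign_arr = np.sign(fit.coef[2:])
    else:
        sign_arr = np.asarray([signs[r] for r in radials], dtype=float)
    signs = sign_arr
    # effect > 0: carrying allele 0 decreases growth; effect < 0: allele 2 does
    decreasing = np.where(signs[None, :] >= 0, G == 0, G == 2)
    counts = decreasing.sum(axis=1)
    df = pd.DataFrame(
        {"segregant": segs, "hub_genotype": h.astype(int), "n_decreasing": counts,
         "growth": y}
    )
    out = (
        df.groupby(["n_decreasing", "hub_genotype"])["growth"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    out.attrs["effect_signs"] = dict(zip(radials, signs))
    return out
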