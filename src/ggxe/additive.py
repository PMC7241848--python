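"""Additive locus definition and joint effect estimation.

Stages:

1. ``marginal_scan`` — per-marker simple regression of replicate-mean growth
   on the 0/2-coded genotype within one environment (a stand-in for an
   upstream per-environment QTL scan when real peak tables are unavailable).
2. ``prune_loci`` — collapse peaks that are both physically close (< 20 kb)
   and in strong linkage (r^2 > 0.9) to their most significant member, giving
   a set of statistically independent loci.
3. ``polygenic_select`` — per environment, fit all pruned candidates jointly
   by least squares and flag loci surviving Benjamini-Hochberg FDR control.
4. ``estimate_effects`` — joint multi-locus estimates of the per-allele-copy
   additive effects in one environment (all loci fitted simultaneously).
5. ``group_lrt`` — likelihood-ratio test of whether the loci *not*
   individually significant in an environment still contribute as a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, gaussian_lrt, ols_fit
from .simulate import GenotypeMatrix, PhenotypeTable

__all__ = [
    "LocusSet",
    "marginal_scan",
    "prune_loci",
    "polygenic_select",
    "estimate_effects",
    "estimate_effects_all_envs",
    "group_lrt",
]


@dataclass
class LocusSet:
    """An ordered set of (pruned) loci with optional per-environment flags."""

    loci: list[str]
    flags: pd.DataFrame | None = None  # index locus, columns environment, bool
    metadata: dict = field(default_factory=dict)

    def significant(self, environment: str) -> list[str]:
        if self.flags is None or environment not in self.flags.columns:
            raise KeyError(f"no significance flags for environment {environment!r}")
        col = self.flags[environment]
        return [l for l in self.loci if bool(col.get(l, False))]

    def __len__(self) -> int:
        return len(self.loci)


def _env_means(geno: GenotypeMatrix, pheno: PhenotypeTable, environment: str):
    """Segregant-mean growth aligned with genotype rows."""
    means = pheno.segregant_means(environment)
    common = [s for s in geno.segregants if s in means.index]
    if not common:
        raise ValueError(
            f"no segregants shared between genotypes and environment {environment!r}"
        )
    return common, means.loc[common].to_numpy()


def marginal_scan(
    geno: GenotypeMatrix, pheno: PhenotypeTable, environment: str
) -> pd.DataFrame:
    """Single-marker regression scan of mean growth in one environment.

    Returns a QTL table with columns locus, environment, effect, se, t, p and
    a ``monomorphic`` flag (monomorphic markers get effect 0 and p = 1).
    """
    segs, y = _env_means(geno, pheno, environment)
    G = geno.values.loc[segs].to_numpy(dtype=float)
    n = len(y)
    gm = G.mean(axis=0)
    gv = G.var(axis=0)
    mono = gv == 0
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (G - gm).T @ yc / (n * gv)
    slope[mono] = 0.0
    # residual variance of the simple regression, per marker
    ssy = float(yc @ yc)
    ss_expl = slope**2 * n * gv
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.maximum(ssy - ss_expl, 0.0) / df
        se = np.sqrt(sigma2 / (n * gv))
        t = np.where(se > 0, slope / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[mono] = 1.0
    se[mono] = np.nan
    out = pd.DataFrame(
        {
            "locus": geno.markers,
            "environment": environment,
            "effect": slope,
            "se": se,
            "t": t,
            "p": p,
            "monomorphic": mono,
        }
    )
    out.attrs["provenance"] = "scan"
    return out


def prune_loci(
    peaks: pd.DataFrame,
    geno: GenotypeMatrix,
    max_dist_bp: int = 20_000,
    min_r2: float = 0.9,
) -> LocusSet:
    """Collapse clusters of nearby, highly correlated peaks.

    Two peaks are clustered when they are on the same chromosome, within
    ``max_dist_bp`` of each other, AND their coded genotypes are correlated
    with r^2 > ``min_r2`` (both conditions required).  Clusters are connected
    components of that relation; each is represented by its most significant
    peak (smallest p, ties broken by leftmost genomic coordinate).
    """
    if peaks.empty:
        raise ValueError("peak table is empty")
    if geno.gmap is None:
        raise ValueError("genotype matrix has no genetic map")
    best_p = peaks.groupby("locus")["p"].min()
    loci = list(best_p.index)
    info = geno.gmap.table.set_index("marker")
    pos = info.loc[loci]
    G = geno.values[loci].to_numpy(dtype=float)
    graph = nx.Graph()
    graph.add_nodes_from(loci)
    for i, a in enumerate(loci):
        for j in range(i + 1, len(loci)):
            b = loci[j]
            if pos.loc[a, "chrom"] != pos.loc[b, "chrom"]:
                continue
            if abs(pos.loc[a, "pos_bp"] - pos.loc[b, "pos_bp"]) >= max_dist_bp:
                continue
            ga, gb = G[:, i], G[:, j]
            if ga.var() == 0 or gb.var() == 0:
                continue
            r2 = np.corrcoef(ga, gb)[0, 1] ** 2
            if r2 > min_r2:
                graph.add_edge(a, b)
    keep = []
    for comp in nx.connected_components(graph):
        members = sorted(
            comp, key=lambda l: (best_p[l], pos.loc[l, "chrom"], pos.loc[l, "pos_bp"])
        )
        keep.append(members[0])
    order = {m: k for k, m in enumerate(geno.markers)}
    keep.sort(key=lambda l: order.get(l, len(order)))
    return LocusSet(
        loci=keep,
        metadata={"max_dist_bp": max_dist_bp, "min_r2": min_r2, "n_input": len(loci)},
    )


def _joint_design(geno: GenotypeMatrix, segs: list[str], loci: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(segs)), geno.values.loc[segs, loci].to_numpy(dtype=float)]
    )
    return X


def polygenic_select(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    candidates: LocusSet,
    fdr: float = 0.05,
    environments: list[str] | None = None,
    backward: bool = False,
) -> LocusSet:
    """Per-environment multi-locus association with BH FDR control.

    All candidate loci are fitted jointly by least squares on segregant mean
    growth; per-locus t-test p-values are BH-adjusted within the environment
    and loci with adjusted p below ``fdr`` are flagged.  With
    ``backward=True``, the least significant locus is dropped iteratively
    until every remaining locus survives BH at ``fdr`` (backward
    elimination); the flags then mark the surviving set.
    """
    envs = environments or pheno.environments
    loci = list(candidates.loci)
    flags = pd.DataFrame(False, index=loci, columns=envs)
    for env in envs:
        segs, y = _env_means(geno, pheno, env)
        if len(segs) <= len(loci) + 1:
            raise ValueError(
                f"{len(loci)} loci not jointly estimable with {len(segs)} segregants"
            )
        if backward:
            current = list(loci)
            while current:
                fit = _fit_named(geno, segs, y, current)
                adj = bh_adjust(fit.p[1:])
                if (adj <= fdr).all():
                    break
                current.pop(int(np.argmax(adj)))
            flags.loc[current, env] = True
        else:
            fit = _fit_named(geno, segs, y, loci)
            adj = bh_adjust(fit.p[1:])
            flags.loc[np.array(loci)[adj <= fdr], env] = True
    return LocusSet(
        loci=loci,
        flags=flags,
        metadata={**candidates.metadata, "fdr": fdr, "backward": backward},
    )


def _fit_named(geno, segs, y, loci):
    X = _joint_design(geno, segs, loci)
    try:
        return ols_fit(X, y)
    except np.linalg.LinAlgError as exc:
        collinear = _find_aliased(geno, segs, loci)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear loci: {collinear}"
        ) from exc


def _find_aliased(geno, segs, loci) -> list[str]:
    G = geno.values.loc[segs, loci].to_numpy(dtype=float)
    bad = []
    for j, l in enumerate(loci):
        if G[:, j].var() == 0:
            bad.append(l)
    corr = np.corrcoef(G, rowvar=False)
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if np.isclose(abs(corr[i, j]), 1.0):
                bad.extend([loci[i], loci[j]])
    return sorted(set(bad))


def estimate_effects(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    loci: LocusSet | list[str],
    environment: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Joint per-allele-copy additive effect estimates in one environment.

    All loci are fitted simultaneously on segregant mean growth; the
    ``significant`` flag applies BH at ``fdr`` within the environment.
    """
    names = loci.loci if isinstance(loci, LocusSet) else list(loci)
    segs, y = _env_means(geno, pheno, environment)
    fit = _fit_named(geno, segs, y, names)
    adj = bh_adjust(fit.p[1:])
    return pd.DataFrame(
        {
            "locus": names,
            "environment": environment,
            "effect": fit.coef[1:],
            "se": fit.se[1:],
            "t": fit.t[1:],
            "p": fit.p[1:],
            "p_adj": adj,
            "significant": adj <= fdr,
        }
    )


def estimate_effects_all_envs(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    loci: LocusSet | list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Long table of joint additive effects for every environment."""
    parts = [
        estimate_effects(geno, pheno, loci, env, fdr=fdr)
        for env in pheno.environments
    ]
    return pd.concat(parts, ignore_index=True)


def group_lrt(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    sig_loci: list[str],
    other_loci: list[str],
    environment: str,
) -> tuple[float, int, float]:
    """LRT of the joint contribution of ``other_loci`` beyond ``sig_loci``.

    Compares mean growth ~ significant loci (reduced) against the model with
    the remaining loci added (full); LR ~ chi-square with df = number of
    independent extra columns.
    """
    if not other_loci:
        return 0.0, 0, 1.0
    segs, y = _env_means(geno, pheno, environment)
    X1 = _joint_design(geno, segs, list(sig_loci))
    X2 = _joint_design(geno, segs, list(sig_loci) + list(other_loci))
    return gaussian_lrt(X2, X1, y)
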