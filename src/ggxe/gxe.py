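"""Per-locus QTL-by-environment interaction tests.

For each focal locus x, replicate-level growth y_ijk is modelled as

    reduced: y = u + E_j + sum_x a_x b_x + e
    full:    y = u + E_j + sum_x a_x b_x + (E_j * a_x) B_x + e

where E_j are environment main effects, a_x the 0/2-coded genotypes of all
mapped loci (polygenicity is accounted for by fitting them simultaneously),
and the focal locus's environment interaction adds (n_env - 1) columns.  The
likelihood-ratio statistic is referred to chi-square with df = n_env - 1.
Family-wise control across loci uses Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import gaussian_lrt
from .additive import LocusSet
from .simulate import GenotypeMatrix, PhenotypeTable

__all__ = ["GxEResult", "qtl_by_env_lrt", "gxe_scan", "correct_gxe"]


@dataclass
class GxEResult:
    locus: str
    lr: float
    df: int
    p: float
    p_adj: float | None = None
    significant: bool | None = None


def _replicate_design(geno: GenotypeMatrix, pheno: PhenotypeTable, loci: list[str]):
    """Replicate-level base design: intercept, env dummies, all loci coded."""
    rec = pheno.records
    segs = rec["segregant"].to_numpy()
    known = set(geno.segregants)
    mask = np.fromiter((s in known for s in segs), bool, len(segs))
    rec = rec[mask]
    envs = sorted(rec["environment"].unique())
    y = rec["growth"].to_numpy(dtype=float)
    env_codes = pd.Categorical(rec["environment"], categories=envs).codes
    n = len(rec)
    E = np.zeros((n, len(envs) - 1))
    for j in range(1, len(envs)):
        E[env_codes == j, j - 1] = 1.0
    G = geno.values.loc[rec["segregant"], loci].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), E, G])
    return X, y, env_codes, G, envs, rec


def _interaction_cols(env_codes: np.ndarray, n_envs: int, a: np.ndarray) -> np.ndarray:
    cols = np.zeros((len(a), n_envs - 1))
    for j in range(1, n_envs):
        sel = env_codes == j
        cols[sel, j - 1] = a[sel]
    return cols


def qtl_by_env_lrt(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    loci: LocusSet | list[str],
    focal: str,
) -> GxEResult:
    """Test one locus for genotype-by-environment interaction."""
    names = loci.loci if isinstance(loci, LocusSet) else list(loci)
    if focal not in names:
        raise ValueError(f"focal locus {focal!r} not among the fitted loci")
    X, y, env_codes, G, envs, rec = _replicate_design(geno, pheno, names)
    a = G[:, names.index(focal)]
    for j, env in enumerate(envs):
        if len(np.unique(a[env_codes == j])) < 2:
            raise ValueError(
                f"focal locus {focal!r} has a single genotype class in "
                f"environment {env!r}; interaction inestimable"
            )
    X_full = np.column_stack([X, _interaction_cols(env_codes, len(envs), a)])
    lr, df, p = gaussian_lrt(X_full, X, y)
    return GxEResult(locus=focal, lr=lr, df=df, p=p)


def gxe_scan(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    loci: LocusSet | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """QTL-by-environment LRT for every locus, Bonferroni-corrected.

    The shared base design is built once; each focal locus adds its own
    environment-interaction columns.  Loci whose interaction is inestimable
    (a single genotype class in some environment) get p = NaN and are
    excluded from the correction count.
    """
    from scipy import stats as _st

    from ._stats import rss_rank

    names = loci.loci if isinstance(loci, LocusSet) else list(loci)
    X, y, env_codes, G, envs, rec = _replicate_design(geno, pheno, names)
    # the reduced model is shared by every focal locus: fit it once
    rss_red, rank_red = rss_rank(X, y)
    n = y.size
    rows = []
    for i, locus in enumerate(names):
        a = G[:, i]
        ok = all(
            len(np.unique(a[env_codes == j])) > 1 for j in range(len(envs))
        )
        if not ok:
            rows.append({"locus": locus, "lr": np.nan, "df": len(envs) - 1, "p": np.nan})
            continue
        X_full = np.column_stack([X, _interaction_cols(env_codes, len(envs), a)])
        rss_full, rank_full = rss_rank(X_full, y)
        df = rank_full - rank_red
        if df <= 0 or rss_full <= 0:
            lr, p = 0.0, 1.0
        else:
            lr = max(0.0, n * np.log(rss_red / rss_full))
            p = float(_st.chi2.sf(lr, df))
        rows.append({"locus": locus, "lr": lr, "df": df, "p": p})
    return correct_gxe(pd.DataFrame(rows), alpha=alpha)


def correct_gxe(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni family-wise correction over the tested loci."""
    if results.empty:
        raise ValueError("no results to correct")
    out = results.copy()
    m = int(out["p"].notna().sum())
    out["p_adj"] = np.minimum(out["p"] * max(m, 1), 1.0)
    out["significant"] = out["p_adj"] <= alpha
    out.loc[out["p"].isna(), "significant"] = False
    return out
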