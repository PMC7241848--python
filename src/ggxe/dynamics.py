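"""Population-level links between network activity and genetic variance.

Connects three layers of the analysis: (i) how variable each locus's
marginal additive effect is across environments, (ii) how connected the
locus is in the epistatic network, and (iii) how much total genetic variance
the population expresses per environment.  Loci whose network connectivity
changes most across environments are expected to show the most variable
additive effects, and environments with more active epistatic edges to
express more total genetic variance — the signature of epistatic
suppression/release of cryptic variation.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjusted_r2_from_rss, ols_fit, rss_rank
from .additive import _env_means
from .network import EpistaticNetwork
from .simulate import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "broad_sense_h2",
    "narrow_sense_h2",
    "effect_variance_by_locus",
    "variance_vs_connectivity",
    "hub_vs_nonhub_test",
    "summarize_environments",
    "total_variance_vs_edges",
    "noncapacitated_rank",
]


def broad_sense_h2(pheno: PhenotypeTable, environment: str) -> tuple[float, float]:
    """Phenotypic variance and broad-sense heritability from repeatability.

    One-way ANOVA across segregants with replicate measurements:
    H2 = (MS_between - MS_within) / (MS_between + (kbar - 1) * MS_within)
    with kbar the mean replicate count; clamped to [0, 1].  Vp is the
    phenotypic variance implied by the same components,
    Vp = MS_within + (MS_between - MS_within) / kbar, so that
    Vp * H2 estimates the total (between-segregant) genetic variance.
    """
    rec = pheno.records[pheno.records["environment"] == environment]
    if rec.empty:
        raise KeyError(f"environment {environment!r} has no records")
    counts = rec.groupby("segregant")["growth"].size()
    if (counts >= 2).mean() < 0.5:
        raise ValueError(
            f"fewer than half the segregants have >= 2 replicates in "
            f"{environment!r}; repeatability inestimable"
        )
    groups = rec.groupby("segregant")["growth"]
    means = groups.mean()
    grand = rec["growth"].mean()
    n_i = counts.to_numpy(dtype=float)
    I = len(counts)
    ss_between = float(np.sum(n_i * (means.to_numpy() - grand) ** 2))
    ss_within = float((rec["growth"] - groups.transform("mean")).pow(2).sum())
    ms_between = ss_between / (I - 1)
    n_total = float(n_i.sum())
    ms_within = ss_within / (n_total - I) if n_total > I else 0.0
    kbar = n_total / I
    denom = ms_between + (kbar - 1.0) * ms_within
    h2 = (ms_between - ms_within) / denom if denom > 0 else 0.0
    h2 = float(np.clip(h2, 0.0, 1.0))
    sigma_g = max((ms_between - ms_within) / kbar, 0.0)
    vp = ms_within + sigma_g
    return float(vp), h2


def narrow_sense_h2(
    geno: GenotypeMatrix, pheno: PhenotypeTable, loci: list[str], environment: str
) -> float:
    """Adjusted r^2 of the joint additive model on segregant means (clamped)."""
    segs, y = _env_means(geno, pheno, environment)
    X = np.column_stack(
        [np.ones(len(segs)), geno.values.loc[segs, list(loci)].to_numpy(float)]
    )
    rss, rank = rss_rank(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    return max(adjusted_r2_from_rss(rss, tss, len(y), rank), 0.0)


def effect_variance_by_locus(
    additive: pd.DataFrame, net: EpistaticNetwork | None = None
) -> pd.DataFrame:
    """Across-environment variance of each locus's joint additive effect.

    Uses the estimate from every environment (significant or not).  When a
    network is supplied, each locus also gets its maximum per-environment
    interactor count and a hub flag (> 4 interactors somewhere).
    """
    wide = additive.pivot(index="locus", columns="environment", values="effect")
    if wide.shape[1] < 2:
        raise ValueError("effects needed in >= 2 environments")
    out = pd.DataFrame(
        {"locus": wide.index, "effect_variance": wide.var(axis=1, ddof=1).to_numpy()}
    )
    if net is not None:
        out["max_interactors"] = [
            max((net.interactor_count(l, e) for e in net.environments), default=0)
            for l in out["locus"]
        ]
        out["hub"] = out["max_interactors"] > 4
    return out.reset_index(drop=True)


def variance_vs_connectivity(dyn: pd.DataFrame) -> tuple[float, float]:
    """Regress additive-effect variance on maximum interactor count.

    Returns (slope, two-sided p) of the simple linear regression across loci.
    """
    if len(dyn) < 3:
        raise ValueError("need >= 3 loci")
    x = dyn["max_interactors"].to_numpy(dtype=float)
    if x.var() == 0:
        raise ValueError("interactor counts are constant; slope undefined")
    y = dyn["effect_variance"].to_numpy(dtype=float)
    fit = ols_fit(np.column_stack([np.ones(len(x)), x]), y)
    return float(fit.coef[1]), float(fit.p[1])


def hub_vs_nonhub_test(dyn: pd.DataFrame) -> tuple[float, float]:
    """Wilcoxon rank-sum test of effect variance, hub vs non-hub loci.

    Uses the tie-corrected normal approximation; returns (W, two-sided p).
    """
    hub = dyn.loc[dyn["hub"], "effect_variance"].to_numpy()
    non = dyn.loc[~dyn["hub"], "effect_variance"].to_numpy()
    if hub.size == 0 or non.size == 0:
        raise ValueError("both hub and non-hub groups must be non-empty")
    res = stats.mannwhitneyu(hub, non, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def summarize_environments(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    net: EpistaticNetwork,
    loci: list[str],
) -> pd.DataFrame:
    """Per-environment variance summary: Vp, H2, h2, V_total, n_ep.

    V_total = Vp * H2 (phenotypic variance times broad-sense heritability);
    n_ep counts the network's active epistatic edges in the environment.
    """
    rows = []
    for env in pheno.environments:
        vp, h2_broad = broad_sense_h2(pheno, env)
        # the additive model is fitted on replicate means, whose variance is
        # Vg + sigma^2/k; rescale its adjusted r^2 to the phenotypic-variance
        # scale so that h2 is comparable with (and bounded by) H2
        segs, y = _env_means(geno, pheno, env)
        var_means = float(np.var(y, ddof=1))
        r2_means = narrow_sense_h2(geno, pheno, loci, env)
        h2 = min(r2_means * var_means / vp, 1.0) if vp > 0 else 0.0
        rows.append(
            {
                "environment": env,
                "Vp": vp,
                "H2": h2_broad,
                "h2": h2,
                "V_total": vp * h2_broad,
                "n_ep": net.n_ep(env),
            }
        )
    return pd.DataFrame(rows)


def total_variance_vs_edges(
    summaries: pd.DataFrame, nominal_pairwise_p: bool = False
) -> tuple[float, float]:
    """Pairwise-difference regression of total genetic variance on edge count.

    For every unordered environment pair, the difference in V_total is
    regressed on the difference in the number of active epistatic edges
    (both oriented as lexicographically earlier minus later environment).

    The slope of this pairwise-difference regression is algebraically
    identical to that of the environment-level regression of V_total on
    n_ep, but the C(E,2) pairs carry only E - 1 independent contrasts, so a
    t-test on the pairs is strongly anti-conservative.  The returned p-value
    therefore comes from the environment-level regression (same slope,
    honest degrees of freedom); pass ``nominal_pairwise_p=True`` to get the
    nominal pairwise p instead (with its non-independence caveat logged).
    """
    s = summaries.set_index("environment").sort_index()
    if len(s) < 3:
        raise ValueError("need >= 3 environments")
    dv, dn = [], []
    for e1, e2 in combinations(s.index, 2):
        dv.append(s.loc[e1, "V_total"] - s.loc[e2, "V_total"])
        dn.append(s.loc[e1, "n_ep"] - s.loc[e2, "n_ep"])
    dn = np.asarray(dn, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if dn.var() == 0:
        return 0.0, 1.0
    pair_fit = ols_fit(np.column_stack([np.ones(len(dn)), dn]), dv)
    slope = float(pair_fit.coef[1])
    if nominal_pairwise_p:
        logger.info(
            "total_variance_vs_edges: nominal p over %d environment pairs "
            "treated as independent observations (they are not)", len(dn),
        )
        return slope, float(pair_fit.p[1])
    n_ep = s["n_ep"].to_numpy(dtype=float)
    v_tot = s["V_total"].to_numpy(dtype=float)
    env_fit = ols_fit(np.column_stack([np.ones(len(s)), n_ep]), v_tot)
    # identical slopes up to roundoff; the env-level fit supplies the p
    return slope, float(env_fit.p[1])


def noncapacitated_rank(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    hub_masking: dict[str, int],
) -> pd.DataFrame:
    """Mean growth rank per segregant versus its non-capacitating hub alleles.

    Growth is ranked within each environment (rank 1 = best growth, ties
    averaged), ranks are averaged across environments, and each segregant's
    count of non-masking (non-capacitating) alleles across the given hubs is
    attached.  The table carries Spearman rho/p of mean rank vs count in
    ``attrs``.
    """
    if not hub_masking:
        raise ValueError("no hubs given")
    grid = pheno.cell_means()
    ranks = grid.rank(axis=0, ascending=False, method="average")
    mean_rank = ranks.mean(axis=1)
    segs = [s for s in mean_rank.index if s in set(geno.segregants)]
    counts = np.zeros(len(segs), dtype=int)
    for hub, masking in hub_masking.items():
        alleles = geno.values.loc[segs, hub].to_numpy()
        counts += (alleles != masking).astype(int)
    out = pd.DataFrame(
        {
            "segregant": segs,
            "n_noncapacitating": counts,
            "mean_growth_rank": mean_rank.loc[segs].to_numpy(),
        }
    )
    if out["n_noncapacitating"].nunique() > 1:
        rho, p = stats.spearmanr(out["n_noncapacitating"], out["mean_growth_rank"])
    else:
        rho, p = np.nan, np.nan
    out.attrs["spearman_rho"] = float(rho) if rho == rho else np.nan
    out.attrs["spearman_p"] = float(p) if p == p else np.nan
    return out
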