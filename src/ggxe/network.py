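"""Across-environment epistatic interaction network.

Pairwise interactions discovered in single environments are re-tested in
every other environment at a lenient threshold that corrects only for the
total number of discovered pairs; loci connected by an interaction active in
any environment form a multigraph whose edges are keyed by environment.
Highly connected loci (hubs, > 4 interactors in at least one environment)
are extracted and profiled for how their interaction activity and their
interactors' additive effects change across environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import adjusted_r2_from_rss, gaussian_lrt, rss_rank
from .additive import _env_means
from .simulate import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "EpistaticNetwork",
    "HubReport",
    "pairwise_lrt",
    "retest_across_envs",
    "build_network",
    "find_hubs",
    "hub_activity_profile",
    "network_fit_rank",
    "summarize_network",
]


def pairwise_lrt(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    pair: tuple[str, str],
    environment: str,
) -> dict:
    """LRT for a pairwise (product-term) interaction in one environment.

    Full model: mean growth ~ 1 + a_A + a_B + a_A*a_B; reduced drops the
    product.  LR ~ chi-square(1).  If one of the four two-locus genotype
    classes is empty the record is flagged inestimable (p = NaN).
    """
    a_name, b_name = pair
    if a_name == b_name:
        raise ValueError("a pair must consist of two distinct loci")
    segs, y = _env_means(geno, pheno, environment)
    a = geno.values.loc[segs, a_name].to_numpy(dtype=float)
    b = geno.values.loc[segs, b_name].to_numpy(dtype=float)
    if a.var() == 0 or b.var() == 0:
        raise ValueError(f"monomorphic locus in pair {pair}")
    classes = {(ga, gb) for ga, gb in zip(a, b)}
    record = {
        "locus_a": min(a_name, b_name),
        "locus_b": max(a_name, b_name),
        "environment": environment,
    }
    if len(classes) < 4:
        logger.warning("pair %s in %s: empty genotype class", pair, environment)
        record.update({"lr": np.nan, "p": np.nan, "estimable": False})
        return record
    X_red = np.column_stack([np.ones(len(y)), a, b])
    X_full = np.column_stack([X_red, a * b])
    lr, df, p = gaussian_lrt(X_full, X_red, y)
    record.update({"lr": lr, "p": p, "estimable": True})
    return record


def retest_across_envs(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    seed_pairs: list[tuple[str, str, str]],
    environments: list[str] | None = None,
    alpha: float = 0.05,
    per_env_correction: bool = False,
) -> pd.DataFrame:
    """Re-test discovered pairs in every environment at a lenient threshold.

    ``seed_pairs`` are (locusA, locusB, discovery environment) triples.  Each
    distinct pair is tested in every environment; it is active where it was
    originally discovered, or where the re-test p-value falls below
    alpha / N_pairs (the lenient rule correcting only for the total number
    of discovered pairs).  ``per_env_correction=True`` switches to the
    stricter alpha / (N_pairs * (n_env - 1)) variant.
    """
    if not seed_pairs:
        raise ValueError("seed_pairs is empty")
    envs = environments or pheno.environments
    pairs: dict[tuple[str, str], set[str]] = {}
    for a, b, env in seed_pairs:
        pairs.setdefault(tuple(sorted((a, b))), set()).add(env)
    n_pairs = len(pairs)
    threshold = alpha / n_pairs
    if per_env_correction:
        threshold = alpha / (n_pairs * max(len(envs) - 1, 1))
    rows = []
    for (a, b), discovered in sorted(pairs.items()):
        for env in envs:
            rec = pairwise_lrt(geno, pheno, (a, b), env)
            rec["discovery"] = env in discovered
            rec["active"] = bool(
                rec["discovery"]
                or (rec["estimable"] and rec["p"] < threshold)
            )
            rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_pairs"] = n_pairs
    return out


@dataclass
class EpistaticNetwork:
    """Multigraph of loci; edges are active interactions keyed by environment."""

    graph: nx.MultiGraph
    environments: list[str]

    @property
    def loci(self) -> list[str]:
        return sorted(self.graph.nodes)

    def interactor_count(self, locus: str, environment: str) -> int:
        """Distinct partners with an active edge to ``locus`` in one environment."""
        if locus not in self.graph:
            return 0
        partners = {
            nbr
            for nbr, edges in self.graph.adj[locus].items()
            if environment in edges
        }
        return len(partners)

    def interactors(self, locus: str, environment: str) -> list[str]:
        if locus not in self.graph:
            return []
        return sorted(
            nbr for nbr, edges in self.graph.adj[locus].items() if environment in edges
        )

    def n_envs_epistatic(self, locus: str) -> int:
        """Environments in which a locus has at least one active interaction."""
        if locus not in self.graph:
            return 0
        envs = {env for _, edges in self.graph.adj[locus].items() for env in edges}
        return len(envs)

    def edge_env_count(self, a: str, b: str) -> int:
        data = self.graph.get_edge_data(a, b)
        return 0 if data is None else len(data)

    def n_ep(self, environment: str) -> int:
        """Active epistatic edge count in one environment."""
        return sum(
            1 for _, _, env in self.graph.edges(keys=True) if env == environment
        )

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_a": min(a, b),
                "locus_b": max(a, b),
                "environment": env,
                **{
                    k: v
                    for k, v in self.graph.get_edge_data(a, b, env).items()
                },
            }
            for a, b, env in self.graph.edges(keys=True)
        ]
        return pd.DataFrame(rows)


def build_network(
    records: pd.DataFrame, environments: list[str] | None = None
) -> EpistaticNetwork:
    """Assemble the across-environment network from active interaction records."""
    active = records[records["active"].astype(bool)]
    envs = environments or sorted(records["environment"].unique())
    g = nx.MultiGraph()
    for _, row in active.iterrows():
        g.add_edge(
            row["locus_a"],
            row["locus_b"],
            key=row["environment"],
            p=row.get("p", np.nan),
            lr=row.get("lr", np.nan),
        )
    return EpistaticNetwork(graph=g, environments=list(envs))


def find_hubs(net: EpistaticNetwork, min_interactors: int = 4) -> list[str]:
    """Loci with strictly more than ``min_interactors`` partners in one environment."""
    hubs = []
    for locus in net.loci:
        if any(
            net.interactor_count(locus, env) > min_interactors
            for env in net.environments
        ):
            hubs.append(locus)
    return hubs


@dataclass
class HubReport:
    hub: str
    reference_environment: str
    reference_interactors: list[str]
    active_fraction: pd.Series  # per environment
    additive_fraction: pd.Series  # per environment
    extra: dict = field(default_factory=dict)


def hub_activity_profile(
    net: EpistaticNetwork, additive: pd.DataFrame, hub: str
) -> HubReport:
    """Profile a hub's interaction activity and interactor additive effects.

    The reference interactor set is the hub's partners in its most highly
    activated environment (ties broken by the alphabetically first
    environment label).  For every environment the report gives the fraction
    of reference interactors still epistatically active with the hub, and
    the fraction with a significant additive effect there.
    """
    counts = {env: net.interactor_count(hub, env) for env in net.environments}
    ref_env = min(counts, key=lambda e: (-counts[e], e))
    ref = net.interactors(hub, ref_env)
    if not ref:
        raise ValueError(f"{hub!r} has no interactors in any environment")
    sig = additive[additive["significant"].astype(bool)]
    sig_by_env = {
        env: set(sub["locus"]) for env, sub in sig.groupby("environment")
    }
    act, add = {}, {}
    for env in net.environments:
        partners = set(net.interactors(hub, env))
        act[env] = len(partners & set(ref)) / len(ref)
        add[env] = len(sig_by_env.get(env, set()) & set(ref)) / len(ref)
    return HubReport(
        hub=hub,
        reference_environment=ref_env,
        reference_interactors=ref,
        active_fraction=pd.Series(act),
        additive_fraction=pd.Series(add),
    )


def _network_design(geno, segs, hub, radials):
    """Additive + hub x radial interaction design for one hub network."""
    h = geno.values.loc[segs, hub].to_numpy(dtype=float)
    cols = [np.ones(len(segs)), h]
    for r in radials:
        a = geno.values.loc[segs, r].to_numpy(dtype=float)
        cols.extend([a, a * h])
    return np.column_stack(cols)


def network_fit_rank(
    net: EpistaticNetwork,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    hubs: list[str] | None = None,
    additive: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adjusted r^2 and within-environment rank of each hub network's fit.

    For every hub network (hub + its reference interactors) and every
    environment, segregant mean growth is regressed on the network loci
    (additive terms plus hub x radial interactions); networks are ranked
    within each environment by adjusted r^2 (rank 1 = best fit).  Aliased
    design columns are tolerated (rank-aware RSS).
    """
    hubs = hubs if hubs is not None else find_hubs(net)
    if len(hubs) < 2:
        raise ValueError("need at least 2 hub networks to rank")
    add = additive if additive is not None else pd.DataFrame(
        columns=["locus", "environment", "significant"]
    )
    refs = {h: hub_activity_profile(net, add, h) for h in hubs}
    rows = []
    for env in net.environments:
        segs, y = _env_means(geno, pheno, env)
        tss = float(np.sum((y - y.mean()) ** 2))
        for h in hubs:
            radials = refs[h].reference_interactors
            X = _network_design(geno, segs, h, radials)
            rss, rank = rss_rank(X, y)
            if rank < X.shape[1]:
                logger.warning(
                    "hub %s in %s: %d aliased column(s) dropped",
                    h, env, X.shape[1] - rank,
                )
            rows.append(
                {
                    "hub": h,
                    "environment": env,
                    "n_interactors": net.interactor_count(h, env),
                    "adj_r2": adjusted_r2_from_rss(rss, tss, len(y), rank),
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("environment")["adj_r2"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    return out


def summarize_network(
    net: EpistaticNetwork,
    additive: pd.DataFrame | None = None,
    geno: GenotypeMatrix | None = None,
    pheno: PhenotypeTable | None = None,
    full_loci: list[str] | None = None,
) -> dict:
    """Locus/edge activity histograms and network variance-explained shares.

    Returns per-locus epistatic environment counts, per-locus additive
    environment counts (when an additive table is given), per-edge
    environment counts, and — when genotypes/phenotypes/full locus set are
    supplied — the fraction of additive genetic variance in each environment
    captured by the network loci, computed as the ratio of the network-loci
    additive model's adjusted r^2 to that of the full locus set (negative
    adjusted r^2 clamped to 0; ratio clamped to [0, 1]).
    """
    loci = net.loci
    epi_counts = pd.Series(
        {l: net.n_envs_epistatic(l) for l in loci}, name="n_envs_epistatic"
    )
    summary: dict = {
        "n_loci": len(loci),
        "n_pairs": len({tuple(sorted((a, b))) for a, b, _ in net.graph.edges(keys=True)}),
        "locus_epistatic_env_counts": epi_counts,
    }
    if additive is not None:
        sig = additive[additive["significant"].astype(bool)]
        add_counts = sig.groupby("locus")["environment"].nunique()
        summary["locus_additive_env_counts"] = add_counts.reindex(loci, fill_value=0)
    edge_counts = pd.Series(
        {
            (min(a, b), max(a, b)): net.edge_env_count(a, b)
            for a, b in {tuple(sorted(e[:2])) for e in net.graph.edges(keys=True)}
        },
        name="n_envs_active",
    )
    summary["edge_env_counts"] = edge_counts
    if geno is not None and pheno is not None and full_loci is not None:
        fracs = {}
        net_loci = [l for l in loci if l in set(geno.markers)]
        for env in net.environments:
            segs, y = _env_means(geno, pheno, env)
            tss = float(np.sum((y - y.mean()) ** 2))

            def _adj(ls):
                X = np.column_stack(
                    [np.ones(len(segs)), geno.values.loc[segs, ls].to_numpy(float)]
                )
                rss, rank = rss_rank(X, y)
                return max(adjusted_r2_from_rss(rss, tss, len(y), rank), 0.0)

            num = _adj(net_loci)
            den = _adj(list(full_loci))
            fracs[env] = min(num / den, 1.0) if den > 0 else 0.0
        summary["additive_variance_fraction"] = pd.Series(fracs)
    return summary
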