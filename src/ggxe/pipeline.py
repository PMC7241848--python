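"""End-to-end pipeline orchestration with config and reproducibility manifest.

Stages (each optional inputs permitting): simulate -> variance partition ->
additive scan/prune/select -> joint effects -> QTL-by-environment tests ->
epistatic network -> capacitation -> dynamics.  Every stage writes its
artefacts to the output directory; a manifest records the package version,
seed, config hash and completed stages so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .additive import (
    LocusSet,
    estimate_effects_all_envs,
    marginal_scan,
    polygenic_select,
    prune_loci,
)
from .capacitation import conditional_h2, decreasing_allele_profile
from .dynamics import (
    effect_variance_by_locus,
    hub_vs_nonhub_test,
    noncapacitated_rank,
    summarize_environments,
    total_variance_vs_edges,
    variance_vs_connectivity,
)
from .gxe import gxe_scan
from .network import (
    build_network,
    find_hubs,
    hub_activity_profile,
    pairwise_lrt,
    retest_across_envs,
)
from .simulate import (
    make_capacitor_arch,
    simulate_genotypes,
    simulate_phenotypes,
    uniform_map,
)
from .variance import partition_gxe

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]

DEFAULT_THRESHOLDS = {
    "prune_dist_bp": 20_000,
    "prune_r2": 0.9,
    "fdr": 0.05,
    "scan_alpha": 0.05,
    "gxe_alpha": 0.05,
    "lenient_alpha": 0.05,
    "per_env_correction": False,
    "hub_min_interactors": 4,
}


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds)
        self.thresholds = thr
        if not (0 < thr["fdr"] < 1) or not (0 < thr["lenient_alpha"] < 1):
            raise ValueError("FDR and alpha thresholds must lie in (0, 1)")
        if thr["prune_dist_bp"] <= 0 or not (0 < thr["prune_r2"] <= 1):
            raise ValueError("pruning thresholds out of range")
        if self.simulate is None:
            for key in ("genotypes", "map", "phenotypes"):
                path = self.inputs.get(key)
                if path is None:
                    raise ValueError(f"config missing inputs.{key} (and no simulate block)")
                if not Path(path).exists():
                    raise FileNotFoundError(f"inputs.{key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 1)),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs", {}) or {},
            thresholds=raw.get("thresholds", {}) or {},
        )

    def digest(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "simulate": self.simulate, "inputs": self.inputs,
             "thresholds": self.thresholds},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_simulate(cfg: PipelineConfig, outdir: Path):
    sim = cfg.simulate or {}
    map_cfg = sim.get("map", {})
    gmap = uniform_map(
        n_chrom=map_cfg.get("n_chrom", 6),
        markers_per_chrom=map_cfg.get("markers_per_chrom", 10),
        spacing_cM=map_cfg.get("spacing_cM", 15.0),
    )
    arch = make_capacitor_arch(
        gmap,
        n_envs=sim.get("n_envs", 6),
        hub_spec=sim.get("hub_spec"),
        seed=cfg.seed,
    )
    geno = simulate_genotypes(sim.get("n_segregants", 1000), gmap, seed=cfg.seed + 1)
    pheno = simulate_phenotypes(geno, arch, seed=cfg.seed + 2)
    gio.write_map(gmap, outdir / "map.tsv")
    gio.write_genotypes(geno, outdir / "genotypes.tsv")
    gio.write_phenotypes(pheno, outdir / "phenotypes.tsv")
    gio.write_architecture(arch, outdir / "truth.json")
    return gmap, geno, pheno, arch


def _discover_pairs(geno, pheno, loci, alpha):
    """Per-environment two-locus scan among candidate loci (upstream stand-in)."""
    pairs = list(combinations(loci, 2))
    envs = pheno.environments
    n_tests = max(len(pairs) * len(envs), 1)
    seed_pairs = []
    for env in envs:
        for pair in pairs:
            rec = pairwise_lrt(geno, pheno, pair, env)
            if rec["estimable"] and rec["p"] < alpha / n_tests:
                seed_pairs.append((rec["locus_a"], rec["locus_b"], env))
    return seed_pairs


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage; returns a dict of key results; artefacts in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    stages: list[str] = []
    results: dict = {}

    def done(name):
        stages.append(name)
        logger.info("stage complete: %s", name)

    try:
        # --- inputs ------------------------------------------------------
        if cfg.simulate is not None:
            gmap, geno, pheno, arch = _stage_simulate(cfg, outdir)
            done("simulate")
        else:
            gmap = gio.read_map(cfg.inputs["map"])
            geno = gio.read_genotypes(cfg.inputs["genotypes"], gmap)
            pheno = gio.read_phenotypes(cfg.inputs["phenotypes"])
            done("load")
        envs = pheno.environments

        # --- variance partition -----------------------------------------
        varcomp = partition_gxe(pheno)
        (outdir / "varcomp.json").write_text(json.dumps(varcomp.as_dict(), indent=2))
        results["varcomp"] = varcomp
        done("partition")

        # --- additive mapping -------------------------------------------
        n_markers = len(geno.markers)
        peak_frames = []
        for env in envs:
            scan = marginal_scan(geno, pheno, env)
            hits = scan[scan["p"] < thr["scan_alpha"] / n_markers]
            peak_frames.append(hits)
        peaks = pd.concat(peak_frames, ignore_index=True)
        if peaks.empty:
            raise RuntimeError("additive scan found no peaks in any environment")
        peaks.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        pruned = prune_loci(peaks, geno, thr["prune_dist_bp"], thr["prune_r2"])
        selected = polygenic_select(geno, pheno, pruned, fdr=thr["fdr"])
        keep = [l for l in selected.loci if selected.flags.loc[l].any()]
        loci = LocusSet(loci=keep, flags=selected.flags.loc[keep], metadata=selected.metadata)
        loci.flags.to_csv(outdir / "locus_flags.tsv", sep="\t")
        results["loci"] = loci
        done("scan-prune-select")

        # --- joint effects -----------------------------------------------
        additive = estimate_effects_all_envs(geno, pheno, loci, fdr=thr["fdr"])
        additive.to_csv(outdir / "additive_effects.tsv", sep="\t", index=False)
        results["additive"] = additive
        done("effects")

        # --- QTL x E ------------------------------------------------------
        gxe = gxe_scan(geno, pheno, loci, alpha=thr["gxe_alpha"])
        gxe.to_csv(outdir / "gxe.tsv", sep="\t", index=False)
        results["gxe"] = gxe
        done("gxe")

        # --- network ------------------------------------------------------
        if cfg.inputs.get("interactions"):
            imported = gio.read_interactions(cfg.inputs["interactions"])
            seed_pairs = [
                (r["locus_a"], r["locus_b"], r["environment"])
                for _, r in imported.iterrows()
                if bool(r["active"])
            ]
        else:
            seed_pairs = _discover_pairs(geno, pheno, loci.loci, thr["lenient_alpha"])
        if not seed_pairs:
            raise RuntimeError("no pairwise interactions discovered; network empty")
        records = retest_across_envs(
            geno, pheno, seed_pairs, envs,
            alpha=thr["lenient_alpha"],
            per_env_correction=thr["per_env_correction"],
        )
        gio.write_interactions(records, outdir / "interactions.tsv")
        net = build_network(records, envs)
        gio.write_network(net, outdir / "network_edges.tsv", outdir / "network.graphml")
        hubs = find_hubs(net, thr["hub_min_interactors"])
        results["network"] = net
        results["hubs"] = hubs
        done("network")

        # --- capacitation -------------------------------------------------
        cap_rows = []
        hub_masking = {}
        for hub in hubs:
            profile = hub_activity_profile(net, additive, hub)
            try:
                stat = conditional_h2(
                    geno, pheno, hub, profile.reference_interactors,
                    profile.reference_environment,
                )
            except ValueError as exc:
                logger.warning("capacitation skipped for %s: %s", hub, exc)
                continue
            masking = 0 if stat.h2_allele0 < stat.h2_allele2 else 2
            hub_masking[hub] = masking
            cap_rows.append(
                {
                    "hub": hub,
                    "environment": stat.environment,
                    "h2_allele0": stat.h2_allele0,
                    "h2_allele2": stat.h2_allele2,
                    "delta_h2": stat.delta_h2,
                    "masking_allele": masking,
                    "n_radials": len(profile.reference_interactors),
                }
            )
            decreasing_allele_profile(
                geno, pheno, hub, profile.reference_interactors,
                profile.reference_environment,
            ).to_csv(outdir / f"allele_profile_{hub}.tsv", sep="\t", index=False)
        capacitation = pd.DataFrame(cap_rows)
        capacitation.to_csv(outdir / "capacitation.tsv", sep="\t", index=False)
        results["capacitation"] = capacitation
        done("capacitation")

        # --- dynamics -----------------------------------------------------
        dyn = effect_variance_by_locus(additive, net)
        dyn.to_csv(outdir / "locus_dynamics.tsv", sep="\t", index=False)
        dynamics: dict = {}
        if dyn["max_interactors"].var() > 0 and len(dyn) >= 3:
            slope, p = variance_vs_connectivity(dyn)
            dynamics["variance_vs_connectivity"] = {"slope": slope, "p": p}
        if dyn["hub"].any() and (~dyn["hub"]).any():
            w, p = hub_vs_nonhub_test(dyn)
            dynamics["hub_vs_nonhub"] = {"W": w, "p": p}
        summaries = summarize_environments(geno, pheno, net, loci.loci)
        summaries.to_csv(outdir / "env_summaries.tsv", sep="\t", index=False)
        if len(summaries) >= 3 and summaries["n_ep"].var() > 0:
            slope, p = total_variance_vs_edges(summaries)
            dynamics["total_variance_vs_edges"] = {"slope": slope, "p": p}
        if hub_masking:
            ranks = noncapacitated_rank(geno, pheno, hub_masking)
            ranks.to_csv(outdir / "noncapacitated_rank.tsv", sep="\t", index=False)
            dynamics["noncapacitated_rank"] = {
                "spearman_rho": ranks.attrs["spearman_rho"],
                "spearman_p": ranks.attrs["spearman_p"],
            }
        (outdir / "dynamics.json").write_text(json.dumps(dynamics, indent=2))
        results["dynamics"] = dynamics
        results["env_summaries"] = summaries
        done("dynamics")
    except Exception as exc:
        stage = f"after stages {stages}" if stages else "before any stage"
        raise RuntimeError(f"pipeline failed {stage}: {exc}") from exc

    from . import __version__

    manifest = {
        "package": "ggxe",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.digest(),
        "stages": stages,
        "thresholds": thr,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
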