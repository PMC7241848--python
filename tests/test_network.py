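"""Across-environment epistatic network: re-testing, assembly, hubs."""

import numpy as np
import pandas as pd
import pytest

from ggxe import (
    EpistaticPair,
    SimArchitecture,
    build_network,
    estimate_effects_all_envs,
    find_hubs,
    hub_activity_profile,
    network_fit_rank,
    pairwise_lrt,
    retest_across_envs,
    simulate_phenotypes,
    summarize_network,
)

from conftest import capacitor_panel, unlinked_genotypes


def toy_records(rows):
    return pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "environment", "lr", "p", "active"]
    )


def star_records(hub, n_leaves, env):
    return toy_records(
        [
            (min(hub, f"leaf{i}"), max(hub, f"leaf{i}"), env, 10.0, 1e-4, True)
            for i in range(n_leaves)
        ]
    )


class TestPairwiseLRT:
    def test_noiseless_additive_phenotype_gives_zero_lr(self):
        from ggxe.simulate import PhenotypeTable

        geno = unlinked_genotypes(400, 2, seed=1)
        y = 0.5 * geno.coded(geno.markers).sum(axis=1)  # exactly additive
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "segregant": geno.segregants,
                    "environment": "e1",
                    "replicate": 1,
                    "growth": y,
                }
            )
        )
        rec = pairwise_lrt(geno, pheno, tuple(geno.markers), "e1")
        assert rec["lr"] == 0.0

    def test_null_calibration(self):
        rejections = 0
        n_sims = 300
        for s in range(n_sims):
            geno = unlinked_genotypes(300, 2, seed=100 + s)
            rng = np.random.default_rng(500 + s)
            arch = SimArchitecture(
                environments=["e1"],
                additive_effects={m: {"e1": 0.3} for m in geno.markers},
                residual_sd=1.0,
                replicates=1,
            )
            pheno = simulate_phenotypes(geno, arch, seed=1000 + s)
            rec = pairwise_lrt(geno, pheno, tuple(geno.markers), "e1")
            rejections += rec["p"] < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rejections / n_sims - 0.05) < half

    def test_power_for_planted_interaction(self):
        hits = 0
        for s in range(20):
            geno = unlinked_genotypes(4000, 2, seed=2000 + s)
            a, b = geno.markers
            arch = SimArchitecture(
                environments=["e1"],
                epistatic_pairs=[EpistaticPair(a, b, {"e1": 0.4})],
                residual_sd=1.0,
                replicates=1,
            )
            pheno = simulate_phenotypes(geno, arch, seed=3000 + s)
            rec = pairwise_lrt(geno, pheno, (a, b), "e1")
            hits += rec["p"] < 1e-4
        assert hits >= 19

    def test_empty_genotype_class_flagged_inestimable(self):
        from ggxe.simulate import GenotypeMatrix, PhenotypeTable

        vals = pd.DataFrame(
            # classes (0,0), (2,0), (2,2) present; (0,2) missing
            {"mA": [0, 2, 2] * 20, "mB": [0, 0, 2] * 20},
            index=pd.Index([f"s{i}" for i in range(60)], name="segregant"),
        )
        geno = GenotypeMatrix(vals)
        rng = np.random.default_rng(3)
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "segregant": geno.segregants,
                    "environment": "e1",
                    "replicate": 1,
                    "growth": rng.normal(size=60),
                }
            )
        )
        rec = pairwise_lrt(geno, pheno, ("mA", "mB"), "e1")
        assert not rec["estimable"] and np.isnan(rec["p"])


class TestRetestAcrossEnvs:
    def test_lenient_threshold_arithmetic(self, cap_panel):
        geno, pheno, arch = cap_panel
        pairs = [(f"pA{i}", f"pB{i}", "env01") for i in range(212)]
        # only the threshold matters here; use real loci for the first pair
        real = arch.all_true_pairs()
        records = retest_across_envs(geno, pheno, real)
        assert records.attrs["threshold"] == pytest.approx(
            0.05 / records.attrs["n_pairs"]
        )
        # the published rule: 212 pairs -> 0.05 / 212 ~ 2.36e-4
        assert 0.05 / 212 == pytest.approx(2.358e-4, rel=1e-3)

    def test_single_seed_pair_threshold_is_alpha(self, cap_panel):
        geno, pheno, arch = cap_panel
        one = arch.all_true_pairs()[:1]
        records = retest_across_envs(geno, pheno, one)
        assert records.attrs["threshold"] == pytest.approx(0.05)

    def test_activity_recovered_in_planted_environments(self):
        # interaction active in 2 of 3 environments
        hits = 0
        for s in range(10):
            geno = unlinked_genotypes(4000, 2, seed=4000 + s)
            a, b = geno.markers
            arch = SimArchitecture(
                environments=["e1", "e2", "e3"],
                epistatic_pairs=[EpistaticPair(a, b, {"e1": 0.5, "e2": 0.5})],
                residual_sd=1.0,
                replicates=1,
            )
            pheno = simulate_phenotypes(geno, arch, seed=5000 + s)
            rec = retest_across_envs(geno, pheno, [(a, b, "e1")])
            active = set(rec.loc[rec["active"], "environment"])
            hits += active == {"e1", "e2"}
        assert hits >= 9

    def test_per_env_correction_is_never_more_permissive(self, cap_panel):
        geno, pheno, arch = cap_panel
        seeds = arch.all_true_pairs()
        lenient = retest_across_envs(geno, pheno, seeds, per_env_correction=False)
        strict = retest_across_envs(geno, pheno, seeds, per_env_correction=True)
        assert int(strict["active"].sum()) <= int(lenient["active"].sum())


class TestBuildNetwork:
    def test_toy_two_edge_network(self):
        rec = toy_records(
            [("A", "B", "e1", 9.0, 1e-3, True), ("B", "C", "e2", 8.0, 1e-3, True)]
        )
        net = build_network(rec, ["e1", "e2"])
        assert net.loci == ["A", "B", "C"]
        assert net.graph.number_of_edges() == 2
        assert net.interactor_count("B", "e1") == 1
        assert net.interactor_count("B", "e2") == 1
        assert net.n_envs_epistatic("B") == 2

    def test_empty_active_records_give_empty_network(self):
        rec = toy_records([("A", "B", "e1", 1.0, 0.9, False)])
        net = build_network(rec, ["e1"])
        assert net.loci == [] and net.graph.number_of_edges() == 0

    def test_interactor_counts_invariant_to_order_and_swap(self):
        rows = [
            ("A", "B", "e1", 9.0, 1e-3, True),
            ("A", "C", "e1", 9.0, 1e-3, True),
            ("B", "C", "e2", 9.0, 1e-3, True),
        ]
        net1 = build_network(toy_records(rows), ["e1", "e2"])
        swapped = [(b, a, e, lr, p, act) for a, b, e, lr, p, act in rows[::-1]]
        net2 = build_network(toy_records(swapped), ["e1", "e2"])
        for locus in "ABC":
            for env in ("e1", "e2"):
                assert net1.interactor_count(locus, env) == net2.interactor_count(
                    locus, env
                )


class TestFindHubs:
    def test_five_leaves_is_a_hub(self):
        net = build_network(star_records("hub", 5, "e1"), ["e1"])
        assert find_hubs(net) == ["hub"]

    def test_four_leaves_is_not_a_hub(self):
        net = build_network(star_records("hub", 4, "e1"), ["e1"])
        assert find_hubs(net) == []

    def test_counting_is_per_environment(self):
        rec = pd.concat(
            [star_records("hub", 2, "e1"), star_records("hub", 3, "e2").assign(
                locus_b=lambda d: d["locus_b"].str.replace("leaf", "other")
            )],
            ignore_index=True,
        )
        net = build_network(rec, ["e1", "e2"])
        assert find_hubs(net) == []  # 2 + 3 partners but never > 4 in one env


class TestHubProfileAndRank:
    def test_profile_fractions_on_planted_capacitor(self):
        geno, pheno, arch = capacitor_panel(n=4000, seed=60, radial_effect=0.5)
        cap = arch.capacitors[0]
        rec = retest_across_envs(geno, pheno, arch.all_true_pairs())
        net = build_network(rec, ["env01", "env02"])
        assert cap.hub in find_hubs(net)
        additive = estimate_effects_all_envs(geno, pheno, sorted(arch.loci()))
        prof = hub_activity_profile(net, additive, cap.hub)
        assert prof.reference_environment == "env01"
        assert prof.active_fraction["env01"] == 1.0  # reference env by construction
        assert prof.active_fraction["env02"] <= 0.2  # silent env

    def test_additive_fraction_counts_env_specific_effects(self):
        rec = star_records("hub", 5, "e1")
        net = build_network(rec, ["e1", "e2"])
        additive = pd.DataFrame(
            {
                "locus": ["leaf0", "leaf0"],
                "environment": ["e1", "e2"],
                "effect": [0.3, 0.3],
                "significant": [False, True],
            }
        )
        prof = hub_activity_profile(net, additive, "hub")
        assert prof.additive_fraction["e2"] == pytest.approx(1 / 5)
        assert prof.additive_fraction["e1"] == 0.0

    def test_ranks_are_permutation_and_strong_network_ranks_first(self):
        # two hub networks, one planted strong in env01, plus a null one
        geno, pheno, arch = capacitor_panel(
            n=4000, seed=61, radial_effect=0.5, n_null=7
        )
        cap = arch.capacitors[0]
        nulls = [m for m in geno.markers if m != cap.hub][-6:]
        fake_rows = [
            (min(nulls[0], l), max(nulls[0], l), "env01", 1.0, 0.5, True)
            for l in nulls[1:]
        ]
        rec = retest_across_envs(geno, pheno, arch.all_true_pairs())
        records = pd.concat(
            [rec, toy_records(fake_rows)], ignore_index=True
        )
        net = build_network(records, ["env01", "env02"])
        additive = estimate_effects_all_envs(geno, pheno, sorted(set(arch.loci()) | set(nulls)))
        ranks = network_fit_rank(
            net, geno, pheno, hubs=[cap.hub, nulls[0]], additive=additive
        )
        for env, sub in ranks.groupby("environment"):
            assert sorted(sub["rank"]) == [1, 2]
        env01 = ranks[ranks["environment"] == "env01"].set_index("hub")
        assert env01.loc[cap.hub, "rank"] == 1
        # a network of inert loci explains ~nothing
        assert abs(env01.loc[nulls[0], "adj_r2"]) < 0.01


class TestSummaries:
    def test_toy_counts(self):
        rec = toy_records(
            [
                ("A", "B", "e1", 9.0, 1e-3, True),
                ("A", "B", "e2", 9.0, 1e-3, True),
                ("A", "B", "e3", 9.0, 1e-3, True),
                ("B", "C", "e2", 8.0, 1e-3, True),
            ]
        )
        net = build_network(rec, ["e1", "e2", "e3"])
        summary = summarize_network(net)
        assert summary["locus_epistatic_env_counts"]["B"] == 3
        assert summary["edge_env_counts"][("A", "B")] == 3
        assert summary["n_pairs"] == 2

    def test_variance_fraction_in_unit_interval(self):
        geno, pheno, arch = capacitor_panel(n=1500, seed=62, radial_effect=0.5)
        cap = arch.capacitors[0]
        rec = retest_across_envs(geno, pheno, arch.all_true_pairs())
        net = build_network(rec, ["env01", "env02"])
        additive = estimate_effects_all_envs(geno, pheno, sorted(arch.loci()))
        summary = summarize_network(
            net, additive, geno, pheno, full_loci=sorted(arch.loci())
        )
        frac = summary["additive_variance_fraction"]
        assert ((frac >= 0) & (frac <= 1)).all()
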