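"""Additive locus definition, joint effect estimation, group LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ggxe import (
    LocusSet,
    SimArchitecture,
    estimate_effects,
    group_lrt,
    marginal_scan,
    polygenic_select,
    prune_loci,
    simulate_genotypes,
    simulate_phenotypes,
    uniform_map,
)
from ggxe.simulate import GeneticMap, GenotypeMatrix, PhenotypeTable

from conftest import unlinked_genotypes


def means_table(geno, y, env="e1"):
    return PhenotypeTable(
        pd.DataFrame(
            {
                "segregant": geno.segregants,
                "environment": env,
                "replicate": 1,
                "growth": y,
            }
        )
    )


class TestMarginalScan:
    def test_planted_locus_attains_minimum_p(self):
        geno = unlinked_genotypes(2000, 20, seed=1)
        rng = np.random.default_rng(2)
        target = geno.markers[7]
        y = 0.5 * geno.coded([target])[:, 0] + rng.normal(0, 1, 2000)
        scan = marginal_scan(geno, means_table(geno, y), "e1")
        assert scan.loc[scan["p"].idxmin(), "locus"] == target

    def test_null_calibration(self):
        # fraction of p < 0.05 across markers/sims within the binomial CI
        n_sims, n_markers = 50, 20
        count = total = 0
        for s in range(n_sims):
            geno = unlinked_genotypes(300, n_markers, seed=100 + s)
            rng = np.random.default_rng(200 + s)
            y = rng.normal(size=300)
            scan = marginal_scan(geno, means_table(geno, y), "e1")
            count += int((scan["p"] < 0.05).sum())
            total += n_markers
        half = 1.96 * np.sqrt(0.05 * 0.95 / total)
        assert abs(count / total - 0.05) < half

    def test_constant_phenotype_gives_zero_effects(self):
        geno = unlinked_genotypes(100, 5, seed=3)
        scan = marginal_scan(geno, means_table(geno, np.zeros(100)), "e1")
        assert np.allclose(scan["effect"], 0.0)

    def test_monomorphic_marker_flagged_with_p_one(self):
        geno = unlinked_genotypes(100, 3, seed=4)
        vals = geno.values.copy()
        vals.iloc[:, 0] = 2
        geno2 = GenotypeMatrix(vals, gmap=geno.gmap)
        rng = np.random.default_rng(5)
        scan = marginal_scan(geno2, means_table(geno2, rng.normal(size=100)), "e1")
        row = scan.iloc[0]
        assert row["monomorphic"] and row["p"] == 1.0 and row["effect"] == 0.0


def linked_pair_panel(r2_high: bool, seed: int = 6):
    """Two markers 5 kb apart; tight or loose linkage via the cM gap."""
    cm_gap = 0.05 if r2_high else 80.0
    gmap = GeneticMap(
        pd.DataFrame(
            {
                "marker": ["mA", "mB", "mC"],
                "chrom": ["c1", "c1", "c2"],
                "pos_bp": [10_000, 15_000, 10_000],
                "pos_cM": [0.0, cm_gap, 0.0],
            }
        )
    )
    return simulate_genotypes(3000, gmap, seed=seed)


class TestPruneLoci:
    def test_single_peak_unchanged(self):
        geno = unlinked_genotypes(100, 3, seed=7)
        peaks = pd.DataFrame(
            [{"locus": geno.markers[0], "environment": "e1", "p": 1e-5, "effect": 0.2}]
        )
        assert prune_loci(peaks, geno).loci == [geno.markers[0]]

    def test_close_and_correlated_peaks_collapse_to_most_significant(self):
        geno = linked_pair_panel(r2_high=True)
        r2 = np.corrcoef(geno.coded(["mA"])[:, 0], geno.coded(["mB"])[:, 0])[0, 1] ** 2
        assert r2 > 0.9  # construction check
        peaks = pd.DataFrame(
            [
                {"locus": "mA", "environment": "e1", "p": 1e-4, "effect": 0.1},
                {"locus": "mB", "environment": "e1", "p": 1e-10, "effect": 0.2},
            ]
        )
        assert prune_loci(peaks, geno).loci == ["mB"]

    def test_close_but_uncorrelated_peaks_both_kept(self):
        geno = linked_pair_panel(r2_high=False)
        r2 = np.corrcoef(geno.coded(["mA"])[:, 0], geno.coded(["mB"])[:, 0])[0, 1] ** 2
        assert r2 < 0.9
        peaks = pd.DataFrame(
            [
                {"locus": "mA", "environment": "e1", "p": 1e-4, "effect": 0.1},
                {"locus": "mB", "environment": "e1", "p": 1e-10, "effect": 0.2},
            ]
        )
        assert set(prune_loci(peaks, geno).loci) == {"mA", "mB"}

    def test_pruned_set_satisfies_its_invariant(self):
        # random peak configurations: no two surviving loci may be both close
        # and tightly linked
        gmap = uniform_map(n_chrom=2, markers_per_chrom=12, spacing_cM=1.0,
                           bp_per_cM=3000.0)
        geno = simulate_genotypes(2000, gmap, seed=8)
        rng = np.random.default_rng(9)
        for trial in range(5):
            chosen = rng.choice(geno.markers, size=10, replace=False)
            peaks = pd.DataFrame(
                {
                    "locus": chosen,
                    "environment": "e1",
                    "p": rng.uniform(1e-12, 1e-3, size=10),
                    "effect": rng.normal(size=10),
                }
            )
            kept = prune_loci(peaks, geno, max_dist_bp=20_000, min_r2=0.9).loci
            info = gmap.table.set_index("marker")
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    if info.loc[a, "chrom"] != info.loc[b, "chrom"]:
                        continue
                    close = abs(info.loc[a, "pos_bp"] - info.loc[b, "pos_bp"]) < 20_000
                    r2 = (
                        np.corrcoef(geno.coded([a])[:, 0], geno.coded([b])[:, 0])[0, 1]
                        ** 2
                    )
                    assert not (close and r2 > 0.9)


class TestPolygenicSelect:
    def make_panel(self, seed, n=2000, b=0.4, n_true=5, n_null=5):
        geno = unlinked_genotypes(n, n_true + n_null, seed)
        true = geno.markers[:n_true]
        rng = np.random.default_rng(seed + 1)
        y = geno.coded(true).sum(axis=1) * b + rng.normal(0, 1, n)
        return geno, means_table(geno, y), true

    def test_planted_loci_flagged_nulls_mostly_not(self):
        flagged_null = 0
        for s in range(10):
            geno, pheno, true = self.make_panel(seed=40 + s)
            cands = LocusSet(loci=geno.markers)
            sel = polygenic_select(geno, pheno, cands, fdr=0.05)
            assert set(sel.significant("e1")) >= set(true)
            flagged_null += len(set(sel.significant("e1")) - set(true))
        # expected false flags bounded by FDR * (# flags) ~ 0.05 * 10 per sim
        assert flagged_null <= 10

    def test_pure_noise_rarely_flags(self):
        clean = 0
        for s in range(40):
            geno = unlinked_genotypes(400, 8, seed=300 + s)
            rng = np.random.default_rng(400 + s)
            pheno = means_table(geno, rng.normal(size=400))
            sel = polygenic_select(geno, pheno, LocusSet(loci=geno.markers), fdr=0.05)
            clean += not sel.significant("e1")
        assert clean >= 36  # >= 90 % of sims flag nothing

    def test_single_huge_effect_flagged(self):
        geno = unlinked_genotypes(200, 1, seed=10)
        y = geno.coded(geno.markers)[:, 0] * 2.0
        sel = polygenic_select(
            geno, means_table(geno, y + np.random.default_rng(11).normal(0, 0.1, 200)),
            LocusSet(loci=geno.markers),
        )
        assert sel.significant("e1") == geno.markers

    def test_fdr_monotonicity(self):
        geno, pheno, _ = self.make_panel(seed=12, b=0.15)
        cands = LocusSet(loci=geno.markers)
        strict = set(polygenic_select(geno, pheno, cands, fdr=0.01).significant("e1"))
        loose = set(polygenic_select(geno, pheno, cands, fdr=0.05).significant("e1"))
        assert strict <= loose

    def test_backward_elimination_variant(self):
        geno, pheno, true = self.make_panel(seed=13)
        sel = polygenic_select(
            geno, pheno, LocusSet(loci=geno.markers), fdr=0.05, backward=True
        )
        assert set(sel.significant("e1")) >= set(true)


class TestEstimateEffects:
    def test_noiseless_single_locus_exact(self):
        geno = unlinked_genotypes(500, 1, seed=14)
        y = 0.3 * geno.coded(geno.markers)[:, 0]
        table = estimate_effects(geno, means_table(geno, y), geno.markers, "e1")
        assert table["effect"].iloc[0] == pytest.approx(0.3, abs=1e-10)

    def test_sampling_distribution_matches_ols_theory(self):
        # 60 replicate fits: mean near truth, empirical SE near the analytic
        # OLS value sigma / sqrt(n Var(a))
        n, b, sigma, reps = 1000, 0.3, 1.0, 60
        estimates = []
        for s in range(reps):
            geno = unlinked_genotypes(n, 5, seed=500 + s)
            rng = np.random.default_rng(600 + s)
            y = b * geno.coded([geno.markers[0]])[:, 0] + rng.normal(0, sigma, n)
            t = estimate_effects(geno, means_table(geno, y), geno.markers, "e1")
            estimates.append(t["effect"].iloc[0])
        estimates = np.asarray(estimates)
        analytic_se = sigma / np.sqrt(n * 1.0)  # Var(coded genotype) = 1
        assert abs(estimates.mean() - b) < 4 * analytic_se / np.sqrt(reps)
        assert abs(estimates.std(ddof=1) - analytic_se) / analytic_se < 0.3

    def test_joint_fit_attributes_effect_to_causal_locus(self):
        # two linked loci (r^2 ~ 0.5), one causal: the joint fit centres the
        # null locus at 0 while the marginal fit inflates it
        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker": ["mA", "mB"],
                    "chrom": ["c1", "c1"],
                    "pos_bp": [1000, 200_000],
                    "pos_cM": [0.0, 22.0],
                }
            )
        )
        joint_null, marginal_null = [], []
        for s in range(30):
            geno = simulate_genotypes(2000, gmap, seed=700 + s)
            rng = np.random.default_rng(800 + s)
            y = 0.4 * geno.coded(["mA"])[:, 0] + rng.normal(0, 1, 2000)
            pheno = means_table(geno, y)
            joint = estimate_effects(geno, pheno, ["mA", "mB"], "e1")
            joint_null.append(joint.set_index("locus").loc["mB", "effect"])
            marg = marginal_scan(geno, pheno, "e1").set_index("locus")
            marginal_null.append(marg.loc["mB", "effect"])
        assert abs(np.mean(joint_null)) < 0.02
        assert np.mean(marginal_null) > 0.1

    def test_orthogonal_loci_match_marginal_estimates(self):
        # with exactly orthogonal (mean-centred, uncorrelated) designs the
        # joint and marginal estimates coincide; build one explicitly
        vals = pd.DataFrame(
            {
                "mA": [0, 0, 2, 2] * 25,
                "mB": [0, 2, 0, 2] * 25,
            },
            index=pd.Index([f"s{i}" for i in range(100)], name="segregant"),
        )
        geno = GenotypeMatrix(vals)
        rng = np.random.default_rng(15)
        y = 0.3 * vals["mA"].to_numpy() - 0.2 * vals["mB"].to_numpy() + rng.normal(
            0, 1, 100
        )
        pheno = means_table(geno, y)
        joint = estimate_effects(geno, pheno, ["mA", "mB"], "e1").set_index("locus")
        marg = marginal_scan(geno, pheno, "e1").set_index("locus")
        for m in ("mA", "mB"):
            assert joint.loc[m, "effect"] == pytest.approx(
                marg.loc[m, "effect"], abs=1e-8
            )

    def test_rank_deficient_design_names_collinear_loci(self):
        vals = pd.DataFrame(
            {"mA": [0, 2] * 50, "mB": [0, 2] * 50},
            index=pd.Index([f"s{i}" for i in range(100)], name="segregant"),
        )
        geno = GenotypeMatrix(vals)
        rng = np.random.default_rng(16)
        pheno = means_table(geno, rng.normal(size=100))
        with pytest.raises(np.linalg.LinAlgError, match="mA"):
            estimate_effects(geno, pheno, ["mA", "mB"], "e1")


class TestGroupLRT:
    def test_empty_other_loci(self):
        geno = unlinked_genotypes(100, 2, seed=17)
        pheno = means_table(geno, np.zeros(100))
        assert group_lrt(geno, pheno, geno.markers, [], "e1") == (0.0, 0, 1.0)

    def test_null_p_values_uniform(self):
        pvals = []
        for s in range(200):
            geno = unlinked_genotypes(300, 4, seed=900 + s)
            rng = np.random.default_rng(1100 + s)
            y = 0.3 * geno.coded([geno.markers[0]])[:, 0] + rng.normal(0, 1, 300)
            pheno = means_table(geno, y)
            _, _, p = group_lrt(
                geno, pheno, [geno.markers[0]], geno.markers[2:], "e1"
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_planted_group_effect(self):
        hits = 0
        for s in range(20):
            geno = unlinked_genotypes(4000, 4, seed=1300 + s)
            rng = np.random.default_rng(1400 + s)
            y = 0.3 * geno.coded([geno.markers[2]])[:, 0] + rng.normal(0, 1, 4000)
            pheno = means_table(geno, y)
            _, _, p = group_lrt(
                geno, pheno, geno.markers[:2], geno.markers[2:], "e1"
            )
            hits += p < 1e-6
        assert hits >= 19
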