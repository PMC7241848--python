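# Methods

## Model overview

All analyses are ordinary linear models with homoscedastic Gaussian
residuals, fitted by least squares. Likelihood-ratio statistics use the
profiled Gaussian log-likelihood, LR = n·log(RSS₀/RSS₁), referred to a χ²
with degrees of freedom equal to the rank difference of the nested designs;
rank is computed from the data so aliased columns never inflate the
reference distribution. Genotypes are coded 0/2 for the two parental
haploid alleles, so an "additive effect" is per allele copy and the
genotype-group mean difference is twice the coefficient. At allele
frequency ½ the coded genotype has variance 1, which makes the analytic
values used in the tests simple: a set of k unlinked loci with effects b
contributes genetic variance k·b².

## The simulator

`simulate_genotypes` performs Haldane-model meiosis: within a chromosome the
first marker's parental origin is Bernoulli(½) and each subsequent marker
switches origin with probability r = ½(1 − e^(−2d/100)) for an interval of d
cM; chromosomes segregate independently. There is no crossover
interference, no genotyping error and no segregation distortion — the
panel is an idealised version of a real cross, so recovery tests
demonstrate statistical correctness of the pipeline, not robustness to
those artefacts.

`simulate_phenotypes` builds each environment's genetic value as

    g = Σ additive effects × coded genotype
      + Σ active pairwise interactions × product of coded genotypes
      + Σ capacitor radial effects × coded genotype × 1[hub ≠ masking allele]

and adds i.i.d. Gaussian replicate noise. A capacitor term with radial
effect b is algebraically a hub × radial product interaction of strength
b/2 on this coding, so capacitor architectures are detectable by the
pairwise product-term LRT — that is the point of the masking model, not a
coincidence. Growth values are emitted as deviations from a control
condition: the panel mean of the deterministic genetic value is subtracted
within each environment (`center_environments=True`), which makes the
environment main effect null by construction; an explicit
`env_main_effects` override exists for robustness testing. Replicate noise
is Gaussian and homoscedastic because the downstream models assume exactly
that; the residual distribution of real growth data is an assumption, not
an established fact.

Default study conditions mirror the motivating cross: 4,390 segregants, 20
environments, two replicates per segregant × environment, residual sd 1.0
(growth-deviation units), moderate per-allele effects (0.2–0.5). Tests use
smaller panels (300–4,000 segregants) chosen so that the statistical
property under test — calibration, bias, power — is decisive at the stated
tolerance.

## Stage-by-stage choices

**Variance partition.** Model (ȳ_ij = u + id_i + E_j + id·E + e) is fitted
as a balanced two-way factorial on the grid of replicate means; unbalanced
replicate counts are absorbed by averaging first. Segregants not observed
in every environment are excluded with a warning: the interaction is
undefined for a single-environment segregant, and an incomplete grid breaks
the orthogonal decomposition. SS_total is computed directly from the data,
so the identity SS_G + SS_E + SS_GxE + SS_resid = SS_total is a genuine
check of the decomposition, not an accounting tautology. SS_E is computed
and reported even though control-normalised data should carry none.

**Pruning and selection.** Peaks are clustered when both within 20 kb and
in genotype r² > 0.9 (connected components of that conjunction); each
cluster is represented by its smallest p-value, ties broken by leftmost
genomic coordinate. "FDR < 0.05" is implemented as Benjamini–Hochberg on
the per-locus t-tests of the one-shot joint fit; backward elimination is
available as an option because the literature is ambiguous about which
variant a "multi-locus polygenic association analysis" denotes. Both
thresholds are exposed as configuration.

**QTL-by-environment tests.** Fitted at replicate level, as the model is
written, with environment main effects and all mapped loci simultaneously;
the focal locus contributes (n_env − 1) interaction columns. The
multiple-testing correction is Bonferroni across tested loci — conservative,
chosen because no specific procedure is canonical here and the downstream
summaries are insensitive to the choice.

**Network.** Pairs discovered in single environments are re-tested
everywhere at the lenient threshold α/n_pairs (correcting only for the
number of discovered pairs); the stricter α/(n_pairs·(n_env − 1)) variant
is a flag, since the verbal rule admits both readings. A pair is active
where it was discovered or where the re-test clears the threshold. Edges
inestimable in an environment (an empty two-locus genotype class) count as
inactive and are logged. Hubs are loci with strictly more than 4 distinct
partners in at least one environment; a hub's reference interactor set is
its partner set in the most-activated environment, ties broken by the
alphabetically first environment label. The "fraction of additive variance
explained by network loci" is the ratio of adjusted r² of the network-loci
additive model to that of the full locus-set additive model, both clamped
at 0 and the ratio at 1, because "additive genetic variance" needs an
estimator and this one is internal to the package's own fits.

**Capacitation.** Stratified h² is the adjusted r² (clamped at 0) of the
radial-loci additive model within each hub-genotype stratum; adjusted
rather than raw r² to avoid stratum-size bias. With one replicate and no
other loci active, the expected released-stratum value is
Var_radial/(Var_radial + σ²), the closed form used in the recovery tests.
The genotype-class × environment LRT treats the 2^L multi-locus genotype
classes (L ≤ 6) as a single factor; empty class-environment cells are
dropped and the df comes from design ranks, equalling
(n_classes − 1)(n_env − 1) when all cells are populated.
"Growth-decreasing" radial alleles are defined per environment from the
sign of the joint-fit effect. When effects are truly null, estimating those
signs from the same data induces a winner's-curse association between the
allele count and growth; the function accepts externally fixed signs for
null analyses, and profiles based on in-sample signs should be read as
descriptive.

**Dynamics.** Broad-sense H² is replicate repeatability from a one-way
ANOVA across segregants, H² = (MS_B − MS_W)/(MS_B + (k̄ − 1)·MS_W) with k̄
the mean replicate count, clamped to [0, 1]; the phenotypic variance is the
implied V_p = MS_W + (MS_B − MS_W)/k̄, so V_total = V_p·H² estimates the
between-segregant genetic variance. The narrow-sense h² reported per
environment rescales the additive model's mean-level adjusted r² by
Var(means)/V_p so that h² and H² share a denominator (otherwise h² can
exceed H² purely because replicate means are less noisy than single
measurements). Effect variance per locus is the sample variance (ddof 1)
of the joint-model estimates across all environments, significant or not.
n_ep counts active edges, not endpoint incidences. For the pairwise
environment-difference regression of ΔV_total on Δn_ep, differences are
oriented lexicographically earlier − later; the slope over all C(E,2)
pairs is algebraically identical to the slope of the environment-level
regression of V_total on n_ep, but the pairs carry only E − 1 independent
contrasts, so a t-test on the pairs is strongly anti-conservative. The
returned p-value therefore comes from the environment-level regression
(same slope, honest degrees of freedom); the nominal pairwise p remains
available via `nominal_pairwise_p=True` with its caveat logged. Growth
ranks use 1 = best growth with ties averaged.

## Numerical conventions

Rank-deficient joint designs raise an error naming the collinear loci
(pruning is supposed to prevent them); the network-fit ranking instead
tolerates aliasing via rank-aware RSS, logging how many columns were
dropped. Degenerate LRTs (both models fitting exactly) return LR 0,
p 1. Monomorphic markers in the marginal scan get effect 0, p 1 and a
flag. All simulation randomness flows through `numpy.random.default_rng`
seeds supplied by the caller; identical seeds give byte-identical outputs.

## What passing tests show — and what they do not

The test suite verifies type-I error calibration of every LRT under planted
nulls, unbiasedness and correct sampling variance of the joint effect
estimates, exactness of the variance decomposition, recovery of planted
capacitor hubs (detection, Δh², masked-stratum effects), and the sign and
calibration of the dynamics regressions. All of this is under the
simulator's assumptions: unlinked or Haldane-linked biallelic loci at
frequency ½, Gaussian homoscedastic noise, no genotyping error, no shared
environmental structure among replicates. Real cross data violate several
of these (allele-frequency distortion, heteroscedastic growth, plate
effects), so passing tests certify the statistical machinery, not the
biology of any particular dataset.

## Known limitations

Diploid genetics, dominance, crossover interference and kinship/mixed-model
corrections are out of scope (a full-sib haploid panel needs none of the
latter). The genome-wide two-locus scan over all marker pairs is not
implemented; pair discovery is either imported or simulated over candidate
locus sets. The pairwise environment-difference regression is reported as
printed but its nominal inference is replaced as described above.
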