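"""Synthetic biparental haploid cross simulator with ground truth.

Generates panels of haploid segregants from a two-parent cross (alleles coded
0/2 for the two parental homozygotes, mirroring the effect scale of the
downstream linear models) together with replicated growth phenotypes whose
genetic architecture — environment-dependent additive effects, pairwise
epistasis, and hub "capacitor" loci that mask or release the effects of
radial interactors — is fully known.  Recombination follows the Haldane
(no-interference) map function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "EpistaticPair",
    "Capacitor",
    "SimArchitecture",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_capacitor_arch",
    "uniform_map",
    "haldane_r",
]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in centiMorgan (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass
class GeneticMap:
    """Marker map: marker id, chromosome, physical (bp) and genetic (cM) position.

    Physical positions must be strictly increasing within a chromosome and
    genetic positions non-decreasing (markers may share a cM position, in
    which case they co-segregate deterministically).
    """

    table: pd.DataFrame  # columns: marker, chrom, pos_bp, pos_cM

    COLUMNS = ("marker", "chrom", "pos_bp", "pos_cM")

    def __post_init__(self):
        t = self.table
        missing = set(self.COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r} in map")
        if (t["pos_cM"] < 0).any():
            raise ValueError("genetic positions (cM) must be non-negative")
        for chrom, sub in t.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            cm = sub["pos_cM"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"physical positions not strictly increasing on chromosome {chrom}"
                )
            if np.any(np.diff(cm) < 0):
                raise ValueError(
                    f"genetic positions decreasing on chromosome {chrom}"
                )

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def position(self, marker: str) -> tuple:
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        r = row.iloc[0]
        return r["chrom"], int(r["pos_bp"]), float(r["pos_cM"])


def uniform_map(
    n_chrom: int = 4, markers_per_chrom: int = 10, spacing_cM: float = 10.0,
    bp_per_cM: float = 2000.0,
) -> GeneticMap:
    """Evenly spaced multi-chromosome map, convenient for simulations."""
    rows = []
    for c in range(1, n_chrom + 1):
        for m in range(markers_per_chrom):
            rows.append(
                {
                    "marker": f"chr{c:02d}_m{m:02d}",
                    "chrom": f"chr{c:02d}",
                    "pos_bp": int((m + 1) * spacing_cM * bp_per_cM),
                    "pos_cM": m * spacing_cM,
                }
            )
    return GeneticMap(pd.DataFrame(rows))


@dataclass
class GenotypeMatrix:
    """Haploid biallelic genotypes, segregants x markers, values in {0, 2}."""

    values: pd.DataFrame  # index: segregant ids, columns: marker ids
    gmap: GeneticMap | None = None

    def __post_init__(self):
        v = self.values.to_numpy()
        bad = ~np.isin(v, (0, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "genotype values must be 0 or 2; found "
                f"{v[i, j]!r} at segregant {self.values.index[i]!r}, "
                f"marker {self.values.columns[j]!r}"
            )
        if self.gmap is not None:
            unknown = set(self.values.columns) - set(self.gmap.markers)
            if unknown:
                raise ValueError(f"markers absent from map: {sorted(unknown)[:5]}")

    @property
    def segregants(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def markers(self) -> list[str]:
        return self.values.columns.tolist()

    def coded(self, markers) -> np.ndarray:
        """float array of coded genotypes for the given marker(s)."""
        return self.values[list(markers)].to_numpy(dtype=float)


@dataclass
class PhenotypeTable:
    """Long-format replicated growth values, one row per measurement.

    Growth values are deviations from growth in a control medium
    (dimensionless), so the environment main effect is ~0 by construction.
    """

    records: pd.DataFrame  # columns: segregant, environment, replicate, growth

    COLUMNS = ("segregant", "environment", "replicate", "growth")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())

    def segregant_means(self, environment: str) -> pd.Series:
        """Replicate-mean growth per segregant in one environment."""
        sub = self.records[self.records["environment"] == environment]
        if sub.empty:
            raise KeyError(f"environment {environment!r} has no records")
        return sub.groupby("segregant", sort=True)["growth"].mean()

    def cell_means(self) -> pd.DataFrame:
        """Segregant x environment grid of replicate means."""
        return self.records.pivot_table(
            index="segregant", columns="environment", values="growth", aggfunc="mean"
        )


@dataclass
class EpistaticPair:
    """Pairwise interaction with an environment -> coefficient activity map.

    The phenotype contribution in an active environment is
    ``effect * a_A * a_B`` on the 0/2 coding.
    """

    locus_a: str
    locus_b: str
    effects: dict[str, float]  # environment -> interaction coefficient

    def __post_init__(self):
        if self.locus_a == self.locus_b:
            raise ValueError(f"self-interaction at locus {self.locus_a!r}")


@dataclass
class Capacitor:
    """Hub locus that masks radial-locus effects on one of its alleles.

    In each listed environment, a radial locus contributes
    ``effect * a_radial`` only for segregants whose hub allele differs from
    ``masking_allele``; on the masking allele the radial effect is hidden
    (cryptic).  On the 0/2 coding this is algebraically a product
    interaction of strength effect/2 between hub and radial.
    """

    hub: str
    masking_allele: int  # 0 or 2
    radial_effects: dict[str, dict[str, float]]  # env -> {radial locus: effect}

    def __post_init__(self):
        if self.masking_allele not in (0, 2):
            raise ValueError("masking_allele must be 0 or 2")
        for env, rad in self.radial_effects.items():
            if self.hub in rad:
                raise ValueError(
                    f"capacitor hub {self.hub!r} listed among its own radial loci"
                )

    def radials(self, environment: str | None = None) -> list[str]:
        if environment is not None:
            return sorted(self.radial_effects.get(environment, {}))
        out: set[str] = set()
        for rad in self.radial_effects.values():
            out.update(rad)
        return sorted(out)


@dataclass
class SimArchitecture:
    """Ground-truth generative architecture for a synthetic panel."""

    environments: list[str]
    additive_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    capacitors: list[Capacitor] = field(default_factory=list)
    residual_sd: float | dict[str, float] = 1.0
    replicates: int = 2
    env_main_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        sds = (
            self.residual_sd.values()
            if isinstance(self.residual_sd, dict)
            else [self.residual_sd]
        )
        if any(s <= 0 for s in sds):
            raise ValueError("residual_sd must be > 0")

    def sd(self, environment: str) -> float:
        if isinstance(self.residual_sd, dict):
            return self.residual_sd[environment]
        return self.residual_sd

    def loci(self) -> list[str]:
        out: set[str] = set(self.additive_effects)
        for pair in self.epistatic_pairs:
            out.update((pair.locus_a, pair.locus_b))
        for cap in self.capacitors:
            out.add(cap.hub)
            out.update(cap.radials())
        return sorted(out)

    def true_pairs(self, environment: str) -> list[tuple[str, str]]:
        """Unordered locus pairs with an active interaction in one environment.

        Capacitor hub-radial masking counts as an interaction because it is
        one (the masked/released radial effect is a hub x radial product term).
        """
        pairs: set[tuple[str, str]] = set()
        for pr in self.epistatic_pairs:
            if pr.effects.get(environment, 0.0) != 0.0:
                pairs.add(tuple(sorted((pr.locus_a, pr.locus_b))))
        for cap in self.capacitors:
            for radial, eff in cap.radial_effects.get(environment, {}).items():
                if eff != 0.0:
                    pairs.add(tuple(sorted((cap.hub, radial))))
        return sorted(pairs)

    def all_true_pairs(self) -> list[tuple[str, str, str]]:
        """(locusA, locusB, environment) triples for every active interaction."""
        out = []
        for env in self.environments:
            for a, b in self.true_pairs(env):
                out.append((a, b, env))
        return out

    # --- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimArchitecture":
        d = json.loads(text)
        d["epistatic_pairs"] = [EpistaticPair(**p) for p in d["epistatic_pairs"]]
        d["capacitors"] = [Capacitor(**c) for c in d["capacitors"]]
        return cls(**d)

    def validate_against(self, geno: GenotypeMatrix) -> None:
        markers = set(geno.markers)
        missing = [l for l in self.loci() if l not in markers]
        if missing:
            raise ValueError(
                f"architecture loci absent from genotype matrix: {missing[:5]}"
            )


def simulate_genotypes(
    n_segregants: int, gmap: GeneticMap, seed: int
) -> GenotypeMatrix:
    """Simulate haploid segregant genotypes by Haldane-model meiosis.

    Within a chromosome the first marker's allele is Bernoulli(1/2); each
    subsequent marker switches parental origin with the Haldane
    recombination fraction of its interval.  Chromosomes are independent.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if len(gmap.table) == 0:
        raise ValueError("genetic map is empty")
    rng = np.random.default_rng(seed)
    blocks = []
    cols: list[str] = []
    for chrom, sub in gmap.table.groupby("chrom", sort=False):
        m = len(sub)
        cols.extend(sub["marker"].tolist())
        first = rng.integers(0, 2, size=n_segregants)
        if m == 1:
            states = first[:, None]
        else:
            r = haldane_r(np.diff(sub["pos_cM"].to_numpy()))
            switches = rng.random((n_segregants, m - 1)) < r
            states = np.concatenate(
                [first[:, None], np.cumsum(switches, axis=1)], axis=1
            )
            states[:, 1:] += first[:, None]
            states %= 2
        blocks.append(states)
    geno = 2 * np.concatenate(blocks, axis=1).astype(np.int8)
    idx = pd.Index([f"seg{i:05d}" for i in range(n_segregants)], name="segregant")
    return GenotypeMatrix(pd.DataFrame(geno, index=idx, columns=cols), gmap=gmap)


def genetic_values(
    geno: GenotypeMatrix, arch: SimArchitecture, environment: str
) -> np.ndarray:
    """Deterministic genetic value of every segregant in one environment."""
    arch.validate_against(geno)
    n = len(geno.segregants)
    g = np.zeros(n)
    for locus, env_eff in arch.additive_effects.items():
        b = env_eff.get(environment, 0.0)
        if b != 0.0:
            g += b * geno.coded([locus])[:, 0]
    for pair in arch.epistatic_pairs:
        w = pair.effects.get(environment, 0.0)
        if w != 0.0:
            a = geno.coded([pair.locus_a])[:, 0]
            b = geno.coded([pair.locus_b])[:, 0]
            g += w * a * b
    for cap in arch.capacitors:
        rad = cap.radial_effects.get(environment, {})
        if rad:
            hub = geno.coded([cap.hub])[:, 0]
            release = hub != cap.masking_allele
            for radial, eff in rad.items():
                if eff != 0.0:
                    g += eff * geno.coded([radial])[:, 0] * release
    return g


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: SimArchitecture,
    seed: int,
    center_environments: bool = True,
) -> PhenotypeTable:
    """Simulate replicated growth deviations under a known architecture.

    ``center_environments`` subtracts the panel mean of the deterministic
    genetic value within each environment, emulating growth data normalised
    against a control medium (no environment main effect); an explicit
    ``env_main_effects`` override in the architecture is added afterwards.
    """
    arch.validate_against(geno)
    rng = np.random.default_rng(seed)
    n = len(geno.segregants)
    frames = []
    for env in arch.environments:
        g = genetic_values(geno, arch, env)
        if center_environments:
            g = g - g.mean()
        g = g + arch.env_main_effects.get(env, 0.0)
        sd = arch.sd(env)
        for k in range(arch.replicates):
            y = g + rng.normal(0.0, sd, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "segregant": geno.segregants,
                        "environment": env,
                        "replicate": k + 1,
                        "growth": y,
                    }
                )
            )
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def make_capacitor_arch(
    gmap: GeneticMap,
    n_envs: int = 3,
    hub_spec: dict | None = None,
    seed: int = 0,
) -> SimArchitecture:
    """Build a hub-capacitor architecture active in some environments only.

    The hub's radial interactions are fully active in the first environment,
    fully silent in the last, and active in every second intermediate
    environment — echoing the gradual deactivation of a capacitor network
    along an environmental gradient.  Background additive loci with
    environment-constant effects are added on the remaining markers.

    ``hub_spec`` keys (all optional): ``n_radials`` (default 6),
    ``radial_effect`` (0.3), ``masking_allele`` (0), ``hub_additive`` (0.2),
    ``n_background`` (4), ``background_effect`` (0.2), ``residual_sd`` (1.0),
    ``replicates`` (2).
    """
    if n_envs < 2:
        raise ValueError("need at least 2 environments")
    spec = {
        "n_radials": 6,
        "radial_effect": 0.3,
        "masking_allele": 0,
        "hub_additive": 0.2,
        "n_background": 4,
        "background_effect": 0.2,
        "residual_sd": 1.0,
        "replicates": 2,
    }
    spec.update(hub_spec or {})
    markers = gmap.markers
    needed = 1 + spec["n_radials"] + spec["n_background"]
    if needed > len(markers):
        raise ValueError(
            f"hub_spec needs {needed} loci but the map has only {len(markers)} markers"
        )
    rng = np.random.default_rng(seed)
    chosen = [str(m) for m in rng.choice(markers, size=needed, replace=False)]
    hub, radials = chosen[0], chosen[1 : 1 + spec["n_radials"]]
    background = chosen[1 + spec["n_radials"] :]
    envs = [f"env{j + 1:02d}" for j in range(n_envs)]
    # active in env 1, silent in the last, alternating in between
    active_envs = [e for j, e in enumerate(envs[:-1]) if j % 2 == 0]
    radial_effects = {
        env: {r: spec["radial_effect"] for r in radials} for env in active_envs
    }
    additive = {hub: {env: spec["hub_additive"] for env in envs}}
    for b in background:
        additive[b] = {env: spec["background_effect"] for env in envs}
    return SimArchitecture(
        environments=envs,
        additive_effects=additive,
        epistatic_pairs=[],
        capacitors=[
            Capacitor(
                hub=hub,
                masking_allele=spec["masking_allele"],
                radial_effects=radial_effects,
            )
        ],
        residual_sd=spec["residual_sd"],
        replicates=spec["replicates"],
    )
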