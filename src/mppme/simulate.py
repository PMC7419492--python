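"""Synthetic NAM-style multi-environment QTL experiments with known truth.

The generator emulates the design of a maize nested association mapping
(NAM) experiment: one central parent crossed to several peripheral parents,
doubled-haploid (DH) progeny per cross, genotyped on a multi-chromosome
linkage map and phenotyped in several environments under an augmented p-rep
layout (a fraction of entries replicated, repeated checks, incomplete
blocks nested in replicates).

Meiosis uses Haldane's no-interference model: crossovers fall as a Poisson
process with one expected crossover per 100 cM, so the recombination
fraction between positions d cM apart is (1 - exp(-2d/100))/2, consistent
with the IBD machinery.  Each DH line is a single doubled gamete, so
dosages are 0 or 2 and the parental origin mosaic is known exactly —
planted QTL effects act on the true origins, giving every downstream
module an exact oracle.

Phenotypes follow the one-stage generative model: environment, replicate
and block effects, environment-specific cross effects, planted QTL
effects (per parental allele and environment, optionally linear in an
environmental covariate), a genotype main effect shared across
environments (compound symmetry) and an environment/cross-specific plot
error.

Default dimensions mirror the EU-NAM Flint experiment that motivates the
package: 11 crosses of ~74 DH lines on a 10 x ~158 cM map with ~3.8
markers/cM, two environments, one third of entries replicated, checks in
every block, and variance components giving a line-mean heritability near
0.5 and a between-environment genotypic correlation near 0.35.  Tests and
examples pass smaller configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envcov import EnvCovariate
from .markers import CrossTable, GeneticMap, MarkerMatrix
from .stage_one import PlotTable

__all__ = [
    "QtlTruth",
    "SimConfig",
    "SimGenotypes",
    "SimExperiment",
    "simulate_map",
    "simulate_nam_genotypes",
    "simulate_phenotypes",
    "simulate_experiment",
]


@dataclass
class QtlTruth:
    """A planted QTL.

    ``effects`` maps parent id -> list of per-environment allele
    substitution effects (trait units per allele copy, deviation from the
    central parent).  Alternatively give ``beta``/``gamma`` per parent and
    the effect in environment e becomes ``beta + Z_e * gamma`` using the
    config's environmental covariate.
    """

    chromosome: int
    position_cM: float
    effects: dict[str, list[float]] | None = None
    beta: dict[str, float] | None = None
    gamma: dict[str, float] | None = None

    def effect(self, parent: str, env_index: int, z: float) -> float:
        if self.effects is not None:
            if parent not in self.effects:
                return 0.0
            return float(self.effects[parent][env_index])
        b = (self.beta or {}).get(parent, 0.0)
        g = (self.gamma or {}).get(parent, 0.0)
        return float(b + z * g)


@dataclass
class SimConfig:
    """Parameters of a synthetic NAM multi-environment experiment."""

    n_parents: int = 12  # central parent + 11 peripheral parents
    cross_sizes: list[int] | int = 74  # DH lines per cross
    n_chromosomes: int = 10
    chrom_length_cM: float = 158.0
    marker_density: float = 3.8  # markers per cM
    jitter_positions: bool = False
    parent_allele_freq: float = 0.3  # P(peripheral parent carries the alt allele)
    n_environments: int = 2
    env_effects: list[float] | None = None  # fixed environment shifts
    env_covariate: list[float] | None = None  # e.g. precipitation per environment
    covariate_name: str = "precipitation"
    mu: float = 160.0  # e.g. dry matter yield, dt/ha
    qtls: list[QtlTruth] = field(default_factory=list)
    sigma2_g: float = 35.0  # genotype main effect across environments
    sigma2_e: float = 65.0  # plot error (mean of the (cross, env) strata)
    ecse_spread: float = 0.3  # relative spread of error variances across strata
    sigma2_rep: float = 2.0
    sigma2_block: float = 4.0
    cross_env_sd: float = 3.0  # sd of the fixed cross-by-environment effects
    p_rep: float = 1.0 / 3.0  # replicated fraction of the entries
    block_size: int = 8
    n_checks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cross_sizes, int):
            self.cross_sizes = [self.cross_sizes] * (self.n_parents - 1)
        if len(self.cross_sizes) != self.n_parents - 1:
            raise ValueError("need one cross size per peripheral parent")
        if any(s < 2 for s in self.cross_sizes):
            raise ValueError("cross sizes must be >= 2")
        for v in (self.sigma2_g, self.sigma2_e, self.sigma2_rep, self.sigma2_block):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if self.env_effects is None:
            self.env_effects = [5.0 * i for i in range(self.n_environments)]
        if self.env_covariate is None:
            self.env_covariate = [35.0 + 10.0 * i for i in range(self.n_environments)]

    @property
    def parents(self) -> list[str]:
        return ["P0"] + [f"P{i}" for i in range(1, self.n_parents)]

    @property
    def environments(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_environments)]


def simulate_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced (optionally jittered) marker positions per
    chromosome."""
    rng = np.random.default_rng(config.seed)
    rows = []
    spacing = 1.0 / config.marker_density
    for chrom in range(1, config.n_chromosomes + 1):
        pos = np.arange(0.0, config.chrom_length_cM + 1e-9, spacing)
        if config.jitter_positions and len(pos) > 2:
            jit = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=len(pos) - 2)
            pos = np.concatenate([[pos[0]], np.sort(pos[1:-1] + jit), [pos[-1]]])
        for j, p in enumerate(pos):
            rows.append((f"c{chrom}m{j + 1}", chrom, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]))


@dataclass
class SimGenotypes:
    """Simulated genotypes plus the true parental-origin mosaic.

    ``origins[cross]`` is an individuals x markers frame of indicators
    (1 = allele inherited from the central parent)."""

    geno: MarkerMatrix
    crosses: CrossTable
    origins: dict[str, pd.DataFrame]


def _simulate_gamete_origin(rng: np.random.Generator, pos: np.ndarray) -> np.ndarray:
    """Parental origin (0/1) at each position of one chromosome for one
    gamete: Poisson crossovers at rate 1/100 cM, no interference."""
    L = pos[-1] - pos[0] if len(pos) > 1 else 0.0
    n_co = rng.poisson(L / 100.0)
    state = int(rng.integers(2))
    if n_co == 0:
        return np.full(len(pos), state)
    xo = np.sort(rng.uniform(pos[0], pos[0] + L, size=n_co))
    crossings = np.searchsorted(xo, pos, side="right")
    return (state + crossings) % 2


def simulate_nam_genotypes(config: SimConfig, gmap: GeneticMap) -> SimGenotypes:
    """Parents and DH progeny on the given map.

    The central parent carries the reference allele everywhere; each
    peripheral parent carries the alternative allele at a random
    ``parent_allele_freq`` fraction of markers.  Each DH line is one
    recombinant gamete, doubled.
    """
    rng = np.random.default_rng(config.seed + 1)
    parents = config.parents
    markers = gmap.markers
    par_scores = pd.DataFrame(0.0, index=parents, columns=markers)
    for p in parents[1:]:
        par_scores.loc[p] = 2.0 * (rng.random(len(markers)) < config.parent_allele_freq)
    chrom_pos = {
        chrom: gmap.table.loc[gmap.table["chromosome"] == chrom, "position_cM"]
        .to_numpy(dtype=float)
        for chrom in gmap.chromosomes()
    }
    chrom_markers = {
        chrom: gmap.table.loc[gmap.table["chromosome"] == chrom, "marker"].tolist()
        for chrom in gmap.chromosomes()
    }
    ind_cross: dict[str, str] = {}
    cross_parents: dict[str, tuple[str, str]] = {}
    score_rows, origin_frames = [], {}
    ids: list[str] = []
    for ci, peri in enumerate(parents[1:], start=1):
        cross = f"X{ci}"
        cross_parents[cross] = ("P0", peri)
        n = config.cross_sizes[ci - 1]
        org = np.empty((n, len(markers)), dtype=int)
        for i in range(n):
            ind = f"{cross}_I{i + 1}"
            ids.append(ind)
            ind_cross[ind] = cross
            row = np.empty(len(markers), dtype=int)
            off = 0
            for chrom in gmap.chromosomes():
                pos = chrom_pos[chrom]
                row[off : off + len(pos)] = _simulate_gamete_origin(rng, pos)
                off += len(pos)
            org[i] = row
        origin_frames[cross] = pd.DataFrame(
            1 - org, index=ids[-n:], columns=markers
        )  # 1 = central parent origin
        central = par_scores.loc["P0"].to_numpy()
        periph = par_scores.loc[peri].to_numpy()
        scores = np.where(org == 0, central[None, :], periph[None, :])
        score_rows.append(pd.DataFrame(scores, index=ids[-n:], columns=markers))
    geno = MarkerMatrix(pd.concat(score_rows, axis=0), par_scores)
    crosses = CrossTable(pd.Series(ind_cross, name="cross"), cross_parents, "P0")
    return SimGenotypes(geno, crosses, origin_frames)


def _nearest_marker(gmap: GeneticMap, chrom: int, pos: float) -> str:
    tab = gmap.table[gmap.table["chromosome"] == chrom]
    if tab.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    j = (tab["position_cM"] - pos).abs().idxmin()
    return str(tab.loc[j, "marker"])


def simulate_phenotypes(
    config: SimConfig, gmap: GeneticMap, sim: SimGenotypes
) -> PlotTable:
    """Plot-level phenotypes under an augmented p-rep layout.

    Replicate 1 holds every entry; replicate 2 holds a random ``p_rep``
    fraction.  Entries are assigned to incomplete blocks of
    ``block_size - 1`` plots plus one check plot (checks cycle through the
    check genotypes, so every block carries a check).
    """
    rng = np.random.default_rng(config.seed + 2)
    envs = config.environments
    entries = sim.geno.individuals
    cross_of = sim.crosses.individual_cross
    # per-allele QTL contribution per entry per environment, from true origins
    zc = {e: config.env_covariate[i] - config.env_covariate[0]
          for i, e in enumerate(envs)}
    qtl_part = pd.DataFrame(0.0, index=entries, columns=envs)
    for q in config.qtls:
        marker = _nearest_marker(gmap, q.chromosome, q.position_cM)
        for cross in sim.crosses.crosses:
            peri = sim.crosses.peripheral_parent(cross)
            org = sim.origins[cross][marker]  # 1 = central origin
            x_peri = 2.0 * (1 - org)  # copies of the peripheral allele
            for i, e in enumerate(envs):
                eff = q.effect(peri, i, zc[e])
                qtl_part.loc[org.index, e] += x_peri.to_numpy() * eff
    g_main = pd.Series(
        rng.normal(0.0, np.sqrt(config.sigma2_g), size=len(entries)), index=entries
    )
    crosses = sim.crosses.crosses
    c_eff = {
        (c, e): rng.normal(0.0, config.cross_env_sd) for c in crosses for e in envs
    }
    spread = config.ecse_spread
    s2_cell = {
        (c, e): config.sigma2_e * float(rng.uniform(1 - spread, 1 + spread))
        for c in crosses for e in envs
    }
    checks = [f"CHK{k + 1}" for k in range(config.n_checks)]
    check_eff = {g: rng.normal(0.0, 5.0) for g in checks}
    g_check = {g: 0.0 for g in checks}
    rows = []
    ent_per_block = max(config.block_size - 1, 1)
    for ei, env in enumerate(envs):
        env_shift = config.env_effects[ei]
        n_rep2 = int(round(config.p_rep * len(entries)))
        rep2 = list(rng.choice(entries, size=n_rep2, replace=False))
        for rep_id, members in (("R1", list(entries)), ("R2", rep2)):
            if not members:
                continue
            rep_eff = rng.normal(0.0, np.sqrt(config.sigma2_rep))
            order = list(rng.permutation(members))
            n_blocks = int(np.ceil(len(order) / ent_per_block))
            for b in range(n_blocks):
                block_id = f"B{b + 1}"
                blk_eff = rng.normal(0.0, np.sqrt(config.sigma2_block))
                plot_members = order[b * ent_per_block : (b + 1) * ent_per_block]
                chk = checks[b % len(checks)] if checks else None
                for g in plot_members:
                    c = str(cross_of.loc[g])
                    y = (
                        config.mu
                        + env_shift
                        + rep_eff
                        + blk_eff
                        + c_eff[(c, env)]
                        + qtl_part.loc[g, env]
                        + g_main.loc[g]
                        + rng.normal(0.0, np.sqrt(s2_cell[(c, env)]))
                    )
                    rows.append((g, c, env, rep_id, block_id, False, y))
                if chk is not None:
                    y = (
                        config.mu
                        + env_shift
                        + rep_eff
                        + blk_eff
                        + check_eff[chk]
                        + g_check[chk]
                        + rng.normal(0.0, np.sqrt(config.sigma2_e))
                    )
                    rows.append((chk, "CHECK", env, rep_id, block_id, True, y))
    df = pd.DataFrame(
        rows,
        columns=["genotype", "cross", "env", "rep", "block", "check", "trait"],
    )
    return PlotTable(df)


@dataclass
class SimExperiment:
    """A complete simulated experiment."""

    config: SimConfig
    gmap: GeneticMap
    geno: MarkerMatrix
    crosses: CrossTable
    origins: dict[str, pd.DataFrame]
    plots: PlotTable
    covariate: EnvCovariate


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Map, genotypes and phenotypes in one call, deterministic under
    ``config.seed``."""
    gmap = simulate_map(config)
    sim = simulate_nam_genotypes(config, gmap)
    plots = simulate_phenotypes(config, gmap, sim)
    cov = EnvCovariate(
        {e: float(config.env_covariate[i]) for i, e in enumerate(config.environments)},
        name=config.covariate_name,
        reference_environment=config.environments[0],
    )
    return SimExperiment(config, gmap, sim.geno, sim.crosses, sim.origins, plots, cov)
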