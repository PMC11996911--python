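"""Synthetic communities with known assembly processes.

The generator produces a phylogeny, per-taxon environmental optima
evolved by Brownian motion (so niche positions carry phylogenetic
signal), and OTU tables assembled under one of five regimes:

* ``homogeneous_selection`` — Gaussian niche filtering toward one shared
  environment; communities converge on the same clades.
* ``heterogeneous_selection`` — the same niche model across a set of
  well-separated environment levels; samples at different levels draw
  from phylogenetically distant clades.
* ``dispersal_limitation`` — samples on a 1-D line draw from Gaussian
  spatial neighbourhoods of a pool whose species positions are
  independent of the phylogeny; turnover decays with distance.
* ``homogenizing_dispersal`` — several regions, each a well-mixed
  sub-pool; samples within a region are far more similar than a
  richness/occupancy-preserving null expects.
* ``drift`` — neutral Wright-Fisher resampling from the shared pool with
  no selection; divergence stays at the scale of sampling stochasticity.

Every draw flows from the config seed; identical configs give
bit-identical tables.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as eio
from .io import CommunityTable

SCENARIOS = ("heterogeneous_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "drift")


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated scenario.

    ``selection_strength`` is the inverse Gaussian niche width (1/sigma)
    on the standardized optimum scale; ``migration_rate`` m in (0, 1)
    sets the spatial neighbourhood radius 0.5 * m / (1 - m) for the
    dispersal-limitation scenario.
    """
    scenario: str = "drift"
    n_samples: int = 20          # per group
    n_groups: int = 1
    n_otus: int = 150            # regional species pool (nonzero abundance)
    pool_size: int = 300         # tree tips
    depth: int = 2000            # reads per sample
    selection_strength: float = 4.0
    migration_rate: float = 0.10
    env_range: float = 4.0
    n_env_levels: int = 4        # heterogeneous selection habitat types
    group_pool_size: int = 60    # homogenizing dispersal region sub-pool
    wf_generations: int = 5      # drift
    wf_ne: int = 20000           # drift effective size
    founder_occupancy: float = 0.6  # drift: per-sample pool inclusion prob
    env_noise: float = 0.1       # homogeneous selection micro-heterogeneity
    phylo_signal: float = 1.0    # Brownian rate for trait optima
    conservatism: float = 0.3    # depth transform; <1 = deep divergence
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "homogenizing_dispersal" and self.n_groups < 2:
            self.n_groups = 4
        if self.n_otus > self.pool_size:
            raise ValueError("n_otus cannot exceed pool_size")
        if not 0 < self.migration_rate < 1:
            raise ValueError("migration_rate must lie in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def simulate_tree(n_tips: int, model: str = "birth_death",
                  seed: int = 0) -> TreeNode:
    """Random phylogeny with tips OTU_0001..OTU_n.

    ``birth_death`` (lambda=1, mu=0.5) gives a non-ultrametric tree;
    ``coalescent`` (Kingman, pop size 1) an ultrametric one.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    labels = [f"OTU_{i + 1:04d}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(labels)
    if model == "birth_death":
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.5, num_extant_tips=n_tips,
            taxon_namespace=tns, rng=rng)
    elif model == "coalescent":
        tree = dendropy.simulate.treesim.pure_kingman_tree(
            taxon_namespace=tns, pop_size=1.0, rng=rng)
    else:
        raise ValueError(f"unknown tree model {model!r}")
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        if leaf.taxon is None:
            leaf.taxon = tns.get_taxon(lab)
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    sk = TreeNode.read([newick])
    for node in sk.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 1e-8
    return sk


def assign_trait_optima(tree: TreeNode, phylo_signal: float = 1.0,
                        seed: int = 0,
                        conservatism: float = 1.0) -> pd.Series:
    """Environmental optimum per tip evolved along the tree.

    ``conservatism = 1`` is plain Brownian motion: child value = parent
    value + Normal(0, sqrt(rate * branch length)); rate 0 leaves every
    tip at the root value. ``conservatism < 1`` applies a Pagel-delta
    style depth transform that concentrates trait divergence on deep
    branches (niche conservatism / early burst), so clades -- not just
    sister tips -- share niche positions.
    """
    if conservatism <= 0:
        raise ValueError("conservatism must be positive")
    rng = np.random.default_rng(seed)
    depth = {id(tree): 0.0}
    max_depth = 0.0
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if node.is_tip():
            max_depth = max(max_depth, depth[id(node)])
    t_total = max_depth or 1.0

    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        var = 0.0
        if phylo_signal > 0 and node.length:
            t0 = depth[id(node.parent)] / t_total
            t1 = min(depth[id(node)] / t_total, 1.0)
            if t1 > t0:
                var = phylo_signal * t_total * (t1 ** conservatism
                                                - t0 ** conservatism)
        step = rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({t.name: values[id(t)] for t in tree.tips()})


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    table: CommunityTable
    metadata: pd.DataFrame
    soil: pd.DataFrame
    tree: TreeNode
    optima: pd.Series
    manifest: dict = field(default_factory=dict)


def _lognormal_pool(rng, n):
    ab = rng.lognormal(0.0, 1.0, size=n)
    return ab / ab.sum()


def simulate_communities(config: ScenarioConfig, tree: TreeNode,
                         optima: pd.Series):
    """Assemble the OTU table, sample metadata and soil covariates.

    Returns ``(CommunityTable, metadata, soil)``; all-zero OTU columns
    are dropped (a real table only records observed OTUs).
    """
    rng = np.random.default_rng(config.seed)
    tips = list(optima.index)
    if config.n_otus > len(tips):
        raise ValueError("n_otus exceeds tree tip count")
    selection = config.scenario in ("homogeneous_selection",
                                    "heterogeneous_selection")
    # neutral scenarios draw from an n_otus-species regional pool;
    # selection scenarios filter the full flora (the environment, not a
    # prior dispersal lottery over species identity, decides who can
    # occur), which keeps close relatives of every community member
    # available
    n_pool = len(tips) if selection else config.n_otus
    pool_idx = np.sort(rng.choice(len(tips), size=n_pool, replace=False))
    pool_tips = [tips[i] for i in pool_idx]
    pool_ab = _lognormal_pool(rng, n_pool)

    opt = optima.loc[pool_tips].to_numpy(dtype=float)
    if opt.std() > 0:
        opt = (opt - opt.mean()) / opt.std()

    n_total = config.n_samples * config.n_groups
    groups = np.repeat([f"G{k + 1}" for k in range(config.n_groups)],
                       config.n_samples)
    env = np.zeros(n_total)
    position = np.linspace(0.0, 1.0, n_total)
    sigma = 1.0 / config.selection_strength

    weights = np.tile(pool_ab, (n_total, 1))
    # selection scenarios combine the Gaussian environmental filter with
    # a per-sample establishment lottery (not every suitable species
    # reaches every plot). The lottery decouples membership turnover
    # from the trait, so taxa absent from one plot still have close
    # relatives in the other -- the signature of selection the
    # phylogenetic null model detects.
    def _lottery():
        mask = rng.random((n_total, n_pool)) < config.founder_occupancy
        empty = ~mask.any(axis=1)
        if empty.any():
            mask[empty, rng.integers(0, n_pool, size=empty.sum())] = True
        return mask

    # site environments are anchored to quantiles of the realized pool
    # optima, so every site's niche is populated whatever the trait
    # draw; the upper tail is used for homogeneous selection because
    # extreme trait values are the clade-concentrated ones
    if config.scenario == "homogeneous_selection":
        env0 = float(np.quantile(opt, 0.90))
        env = rng.normal(env0, config.env_noise, size=n_total)
        # fitness, not regional abundance, sets the weights under strong
        # selection
        weights = np.exp(-(opt[None, :] - env[:, None]) ** 2
                         / (2 * sigma ** 2)) * _lottery()
    elif config.scenario == "heterogeneous_selection":
        levels = np.quantile(opt, np.linspace(0.05, 0.95,
                                              config.n_env_levels))
        env = levels[np.arange(n_total) % config.n_env_levels]
        weights = np.exp(-(opt[None, :] - env[:, None]) ** 2
                         / (2 * sigma ** 2)) * _lottery()
    elif config.scenario == "dispersal_limitation":
        radius = 0.5 * config.migration_rate / (1 - config.migration_rate)
        loc = rng.uniform(0.0, 1.0, size=n_pool)
        weights = pool_ab * np.exp(-(loc[None, :] - position[:, None]) ** 2
                                   / (2 * radius ** 2))
    elif config.scenario == "homogenizing_dispersal":
        weights = np.zeros((n_total, n_pool))
        for k in range(config.n_groups):
            sub = rng.choice(n_pool, size=config.group_pool_size,
                             replace=False, p=pool_ab)
            w = np.zeros(n_pool)
            w[sub] = pool_ab[sub]
            rows = slice(k * config.n_samples, (k + 1) * config.n_samples)
            weights[rows] = w
    elif config.scenario == "drift":
        # sample-specific founding pools: each local community is seeded
        # by an independent random subset of the metacommunity (lottery
        # establishment), then drifts neutrally
        mask = rng.random((n_total, n_pool)) < config.founder_occupancy
        # guard against an empty founding pool
        empty = ~mask.any(axis=1)
        if empty.any():
            mask[empty, rng.integers(0, n_pool, size=empty.sum())] = True
        weights = pool_ab * mask

    counts = np.zeros((n_total, n_pool), dtype=np.int64)
    for i in range(n_total):
        w = weights[i]
        if w.sum() == 0:
            raise ValueError("empty community weights; impossible config")
        p = w / w.sum()
        if config.scenario == "drift":
            for _ in range(config.wf_generations):
                x = rng.multinomial(config.wf_ne, p)
                p = x / config.wf_ne
            if p.sum() == 0:
                raise ValueError("community went extinct under drift")
        counts[i] = rng.multinomial(config.depth, p)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    table = CommunityTable(pd.DataFrame(
        counts, index=sample_ids, columns=pool_tips)).drop_empty_otus()

    compartment = np.where(np.arange(n_total) % 2 == 0,
                           "rhizosphere", "endosphere")
    metadata = pd.DataFrame({
        "compartment": compartment,
        "region": groups,
        "habitat": [eio.HABITATS[i % 3] for i in range(n_total)],
        "position": position,
    }, index=pd.Index(sample_ids, name="sample_id"))

    soil = _soil_covariates(rng, env, sample_ids)
    return table, metadata, soil


def _soil_covariates(rng, env, sample_ids):
    """Environment written as a pH-like gradient plus noise covariates
    with field-plausible scales."""
    n = len(env)
    soil = pd.DataFrame({
        "pH": np.clip(6.5 + 0.8 * env, 3.6, 9.4),
        "TN": rng.lognormal(0.0, 0.3, n),                 # mg/g
        "TP": 0.8 * rng.lognormal(0.0, 0.3, n),           # mg/g
        "AN": 60 * rng.lognormal(0.0, 0.4, n),            # ug/g
        "AP": 12 * rng.lognormal(0.0, 0.4, n),            # ug/g
        "AK": 150 * rng.lognormal(0.0, 0.4, n),           # ug/g
        "OC": 15 * rng.lognormal(0.0, 0.3, n),            # mg/g
        "EC": 250 * rng.lognormal(0.0, 0.5, n),           # uS/cm
        "SM": rng.uniform(10, 35, n),                     # % vwc
        "MAT": rng.normal(12, 2, n),                      # degC
        "MAP": rng.normal(600, 80, n),                    # mm
        "altitude": rng.uniform(5, 800, n),               # m
    }, index=pd.Index(sample_ids, name="sample_id"))
    return soil


def simulate_scenario(scenario: str, seed: int = 0,
                      **overrides) -> ScenarioBundle:
    """One-call scenario generator: tree, optima, communities, manifest."""
    config = ScenarioConfig(scenario=scenario, seed=seed, **overrides)
    # birth-death trees spread divergence over both deep and terminal
    # branches, so Brownian optima carry clade-level signal while
    # within-clade distances stay resolvable -- both matter for the
    # phylogenetic null model's power
    tree = simulate_tree(config.pool_size, model="birth_death",
                         seed=config.seed)
    optima = assign_trait_optima(tree, config.phylo_signal,
                                 seed=config.seed + 1,
                                 conservatism=config.conservatism)
    table, metadata, soil = simulate_communities(config, tree, optima)
    manifest = {"config": asdict(config),
                "n_samples_total": table.shape[0],
                "n_otus_observed": table.shape[1]}
    return ScenarioBundle(config=config, table=table, metadata=metadata,
                          soil=soil, tree=tree, optima=optima,
                          manifest=manifest)


def make_fixture_bundle(scenarios, out_dir, base_seed: int = 0,
                        **overrides) -> list[Path]:
    """Write one self-describing fixture directory per scenario."""
    out_dir = Path(out_dir)
    written = []
    for k, scenario in enumerate(scenarios):
        bundle = simulate_scenario(scenario, seed=base_seed + k, **overrides)
        d = out_dir / scenario
        d.mkdir(parents=True, exist_ok=True)
        eio.write_community_table(bundle.table, d / "otu_table.tsv")
        eio.write_newick(bundle.tree, d / "tree.nwk")
        bundle.metadata.to_csv(d / "metadata.csv")
        bundle.soil.to_csv(d / "soil.csv")
        with open(d / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        written.append(d)
    return written
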