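"""Synthetic metacommunity generator for the hatch/transition study design.

The generator emulates a rearing experiment in which fish from a single
sibship hatch in one of three water environments (A, B, C), are transferred at
the first sampled timepoint into net cages inside three tanks (one tank per
environment, one cage per hatching environment), and are sampled together
with tank water across seven timepoints spanning three developmental stages.

Generative model
----------------
* A two-level pure-birth phylogeny of ``n_otus`` tips, unit depth: tight
  terminal clusters on a deep backbone, the bimodal distance structure of
  real 16S trees.
* A Brownian-motion trait on that tree: the substrate of phylogenetic signal.
* Three environmental species pools over a shared OTU universe. Membership is
  partitioned into environment-unique, pairwise-shared and triple-shared sets
  (high host-affinity taxa preferentially shared); relative abundances are
  log-normal and shared across environments, so fully overlapping pools are
  also compositionally identical (a "well-mixed" pool).
* Water communities per (environment, timepoint): the pool with log-normal
  temporal jitter.
* Gut communities: a per-cage latent community evolves across timepoints —
  immigrants arrive from the source water (hatching environment before the
  transfer, rearing environment after) at rate ``dispersal_rate``, the
  community drifts idiosyncratically, and the stage's Gaussian trait filter
  (optimum per developmental stage, weight = that stage's selection strength
  ``s``) is applied at every step, so host selection compounds with
  development. Replicate fish are independent multinomial draws (drift).

Low ``dispersal_rate`` makes cages diverge (dispersal limitation); high
``dispersal_rate`` keeps every cage glued to its tank water (homogenizing
dispersal); ``s > 0`` concentrates reads on phylogenetically clustered taxa
(homogeneous selection within a stage, increasingly so at later stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import child_rng
from .data import OtuTable, stage_from_dph, validate_metadata

__all__ = [
    "ENVIRONMENTS",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_water_pools",
    "simulate_gut_sample",
    "simulate_study",
]

ENVIRONMENTS = ("A", "B", "C")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the emulated design.

    The Venn structure of the three pools is set by ``pool_unique_frac`` (total
    fraction of the OTU universe unique to a single environment, split equally)
    and ``pool_pair_frac`` (fraction in each of the three exactly-two-environment
    regions); the remainder is shared by all three environments.
    """

    n_otus: int = 1000
    pool_unique_frac: float = 0.637
    pool_pair_frac: float = 0.08
    dph_schedule: Sequence[int] = (12, 20, 27, 42, 56, 70, 98)
    n_tanks: int = 3
    cages_per_tank: int = 3
    replicates: int = 3
    water_replicates: int = 3
    depth: int = 14_666
    selection_strength_by_stage: Sequence[float] = (0.3, 0.6, 0.8)
    selection_sd: float = 0.35
    stage_optima_quantiles: Sequence[float] = (0.2, 0.5, 0.8)
    trait_rate: float = 1.0
    trait_depth_power: float = 1.0
    tree_cluster_fraction: float = 0.25
    dispersal_rate: float = 0.25
    cage_drift_sd: float = 0.4
    water_jitter_sd: float = 0.3
    abundance_sigma: float = 1.0
    host_affinity_bias: float = 3.0
    cage_pool_frac: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 3:
            raise ValueError("n_otus must be >= 3")
        for name in ("pool_unique_frac", "pool_pair_frac", "dispersal_rate", "cage_pool_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pool_unique_frac + 3 * self.pool_pair_frac > 1.0 + 1e-12:
            raise ValueError("pool fractions inconsistent: unique + 3*pair exceeds 1")
        if self.cage_pool_frac <= 0:
            raise ValueError("cage_pool_frac must be positive")
        sched = list(self.dph_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("dph_schedule must be strictly increasing")
        stages = {stage_from_dph(d) for d in sched}
        if len(self.selection_strength_by_stage) != 3:
            raise ValueError("selection_strength_by_stage needs one value per stage (3)")
        if any(not 0.0 <= s <= 1.0 for s in self.selection_strength_by_stage):
            raise ValueError("selection strengths must lie in [0, 1]")
        if self.selection_sd <= 0:
            raise ValueError("selection_sd must be positive")
        if self.trait_rate <= 0:
            raise ValueError("trait_rate must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        del stages  # validated as a side effect of stage_from_dph

    @property
    def n_timepoints(self) -> int:
        return len(self.dph_schedule)

    @property
    def water_dph(self) -> List[int]:
        """Water is sampled at every timepoint except the second one."""
        sched = list(self.dph_schedule)
        return [d for i, d in enumerate(sched) if i != 1] if len(sched) > 1 else sched


@dataclass
class SimulatedStudy:
    table: OtuTable
    tree: TreeNode
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)


# -- phylogeny and traits --------------------------------------------------

def _yule(n: int, rng: np.random.Generator) -> tuple[TreeNode, list, float]:
    """Grow a constant-rate pure-birth tree to ``n`` tips.

    Returns the root, the tip nodes and the tree depth measured from the
    first split (the root's own stem carries no length), so dividing branch
    lengths by the returned depth yields an exactly ultrametric unit-depth
    tree.
    """
    root = TreeNode(length=0.0)
    birth = {id(root): 0.0}
    active = [root]
    t = 0.0
    t_first = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        if len(active) == 1:
            t_first = t
        i = rng.integers(len(active))
        parent = active.pop(int(i))
        parent.length = t - birth.pop(id(parent)) if parent is not root else 0.0
        kids = [TreeNode(), TreeNode()]
        parent.extend(kids)
        for k in kids:
            birth[id(k)] = t
            active.append(k)
    total = t + rng.exponential(1.0 / max(len(active), 1))
    for tip in active:
        tip.length = total - birth[id(tip)]
    return root, active, total - t_first


def simulate_phylogeny(
    n_otus: int,
    seed: int = 0,
    cluster_fraction: float | None = 0.25,
    cluster_depth: float = 0.02,
    backbone_power: float = 3.0,
) -> TreeNode:
    """Two-level pure-birth ultrametric tree with ``n_otus`` tips, unit depth.

    A pure-birth backbone of roughly ``cluster_fraction * n_otus`` lineages
    spans depths 0..(1 - cluster_depth); each backbone lineage then radiates
    into a small pure-birth cluster of tips within the final
    ``cluster_depth``. Backbone node depths are additionally compressed
    toward the root (``u -> u**backbone_power``, an early-burst profile), so
    inter-cluster paths are uniformly long while within-cluster distances are
    of order ``2 * cluster_depth`` — the strongly bimodal distance structure
    of real 16S phylogenies (within-genus versus between-phylum distances).
    ``cluster_fraction=None`` gives a plain constant-rate Yule tree.
    """
    if n_otus < 3:
        raise ValueError("n_otus must be >= 3")
    rng = child_rng(seed, "phylogeny")
    width = max(1, len(str(n_otus)))

    if cluster_fraction is None:
        root, tips, total = _yule(n_otus, rng)
        for j, tip in enumerate(tips):
            tip.name = f"OTU_{j + 1:0{width}d}"
        for node in root.traverse(include_self=False):
            node.length /= total
        return root

    if not 0.0 < cluster_fraction < 1.0:
        raise ValueError("cluster_fraction must lie in (0, 1)")
    if not 0.0 < cluster_depth < 1.0:
        raise ValueError("cluster_depth must lie in (0, 1)")
    n_clusters = int(max(2, min(round(cluster_fraction * n_otus), n_otus // 2)))
    # every cluster gets at least 2 tips; remaining tips spread uniformly
    sizes = np.full(n_clusters, 2, dtype=int)
    extra = n_otus - 2 * n_clusters
    if extra > 0:
        sizes += rng.multinomial(extra, np.full(n_clusters, 1.0 / n_clusters))
    root, backbone_tips, total = _yule(n_clusters, rng)
    # compress backbone split times toward the root (early burst), then scale
    depth = {id(root): 0.0}
    for node in root.preorder(include_self=False):
        d_parent = depth[id(node.parent)]
        d_child = d_parent + node.length / total
        depth[id(node)] = d_child
        node.length = (1.0 - cluster_depth) * (
            d_child**backbone_power - d_parent**backbone_power
        )
    counter = 1
    for k, btip in enumerate(backbone_tips):
        sub_root, sub_tips, sub_total = _yule(int(sizes[k]), rng)
        for node in sub_root.traverse(include_self=False):
            node.length *= cluster_depth / sub_total
        for tip in sub_tips:
            tip.name = f"OTU_{counter:0{width}d}"
            counter += 1
        btip.extend(list(sub_root.children))
    return root


def simulate_traits(
    tree: TreeNode, rate: float = 1.0, seed: int = 0, depth_power: float = 1.0
) -> Dict[str, float]:
    """Brownian-motion trait simulated along the tree; returns tip values.

    ``depth_power < 1`` concentrates trait variance on branches near the root
    (an early-burst / niche-conservatism profile: divergence accumulates at
    deep splits and close relatives stay trait-similar), by substituting each
    branch's variance contribution ``depth_child^k - depth_parent^k`` for its
    raw length. ``depth_power=1`` is plain Brownian motion.
    """
    if rate <= 0:
        raise ValueError("Brownian rate must be positive")
    if depth_power <= 0:
        raise ValueError("depth_power must be positive")
    rng = child_rng(seed, "traits")
    values = {id(tree): 0.0}
    depths = {id(tree): 0.0}
    traits: Dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        d_parent = depths[id(node.parent)]
        d_child = d_parent + node.length
        depths[id(node)] = d_child
        var = rate * max(d_child**depth_power - d_parent**depth_power, 0.0)
        v = values[id(node.parent)] + rng.normal(0.0, np.sqrt(var))
        values[id(node)] = v
        if node.is_tip():
            traits[node.name] = float(v)
    return traits


# -- species pools ---------------------------------------------------------

def _membership(
    config: SimulationConfig,
    rng: np.random.Generator,
    host_affinity: np.ndarray | None = None,
) -> Dict[str, np.ndarray]:
    """Boolean membership vector per environment over the OTU universe.

    With ``host_affinity`` given (values in [0, 1]), taxa with high affinity
    are preferentially placed in the shared-by-all region: host-adapted taxa
    tend to be ubiquitous across environments (dispersed via hosts), while
    free-living taxa are environment-specific. The Venn region sizes are
    unchanged; only which taxa land where is biased.
    """
    n = config.n_otus
    if host_affinity is None:
        order = rng.permutation(n)
    else:
        # Gumbel-perturbed ranking: high-affinity taxa sink to the end of
        # `order`, where the shared-by-all block is carved out
        keys = config.host_affinity_bias * np.asarray(host_affinity) + rng.gumbel(size=n)
        order = np.argsort(keys)
    n_unique = int(round(config.pool_unique_frac * n / 3.0))
    n_pair = int(round(config.pool_pair_frac * n))
    member = {e: np.zeros(n, dtype=bool) for e in ENVIRONMENTS}
    pos = 0
    for e in ENVIRONMENTS:  # environment-unique blocks
        member[e][order[pos : pos + n_unique]] = True
        pos += n_unique
    pairs = [("A", "B"), ("A", "C"), ("B", "C")]
    for e1, e2 in pairs:
        idx = order[pos : pos + n_pair]
        member[e1][idx] = True
        member[e2][idx] = True
        pos += n_pair
    for e in ENVIRONMENTS:  # remainder shared by all three
        member[e][order[pos:]] = True
    return member


def simulate_water_pools(
    config: SimulationConfig,
    tree: TreeNode,
    seed: int = 0,
    host_affinity: np.ndarray | None = None,
) -> Dict[str, np.ndarray]:
    """Per-environment relative-abundance vectors over the OTU universe.

    Abundance ranks are shared across environments (one global log-normal
    abundance per OTU); environments differ through membership, so fully
    overlapping pools are compositionally identical.
    """
    n_tips = tree.count(tips=True)
    if n_tips != config.n_otus:
        raise ValueError(f"tree has {n_tips} tips, config expects {config.n_otus}")
    rng = child_rng(seed, "pools")
    member = _membership(config, rng, host_affinity)
    base = rng.lognormal(0.0, config.abundance_sigma, size=config.n_otus)
    pools = {}
    for e in ENVIRONMENTS:
        if not member[e].any():
            raise ValueError(f"environment {e} has an empty pool")
        v = np.where(member[e], base, 0.0)
        pools[e] = v / v.sum()
    return pools


# -- community assembly ----------------------------------------------------

def _filter_weights(traits: np.ndarray, optimum: float, s: float, sigma: float) -> np.ndarray:
    gauss = np.exp(-((traits - optimum) ** 2) / (2.0 * sigma**2))
    return (1.0 - s) + s * gauss


def simulate_gut_sample(
    pool: np.ndarray,
    traits: np.ndarray,
    stage_optimum: float,
    s: float,
    sigma: float,
    depth: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One gut community: trait-filtered multinomial draw from ``pool``.

    The sampling distribution is ``p ∝ pool * ((1-s) + s * exp(-(trait-opt)^2 /
    (2 sigma^2)))``; drift enters through the multinomial draw of ``depth``
    reads.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.sum() <= 0:
        raise ValueError("empty pool")
    if not 0.0 <= s <= 1.0:
        raise ValueError("selection strength s must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = pool * _filter_weights(np.asarray(traits, dtype=float), stage_optimum, s, sigma)
    p = p / p.sum()
    if rng is None:
        rng = child_rng(seed, "gut_sample")
    return rng.multinomial(int(depth), p)


def _jittered(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return base
    v = base * rng.lognormal(0.0, sd, size=base.size)
    return v / v.sum()


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full study: OTU table, tree, metadata and truth block."""
    seed = config.seed
    tree = simulate_phylogeny(config.n_otus, seed, config.tree_cluster_fraction)
    traits_map = simulate_traits(tree, config.trait_rate, seed, config.trait_depth_power)
    otu_ids = [t.name for t in tree.tips()]
    traits = np.array([traits_map[o] for o in otu_ids])
    z = (traits - traits.mean()) / traits.std()
    # optima at trait quantiles: every stage's niche is guaranteed to sit in
    # an occupied region of the (possibly multimodal) trait distribution
    q = np.quantile(z, list(config.stage_optima_quantiles))
    optima = {"S1": float(q[0]), "S2": float(q[1]), "S3": float(q[2])}
    s_by_stage = dict(zip(("S1", "S2", "S3"), config.selection_strength_by_stage))
    affinity = np.max(
        [np.exp(-((z - o) ** 2) / (2.0 * config.selection_sd**2)) for o in optima.values()],
        axis=0,
    )
    pools = simulate_water_pools(config, tree, seed, host_affinity=affinity)

    envs = list(ENVIRONMENTS[: config.n_tanks])
    water_env = {
        (e, d): _jittered(pools[e], config.water_jitter_sd, child_rng(seed, "water", e, d))
        for e in envs
        for d in config.dph_schedule
    }

    # fixed per-cage OTU availability (per-cage pool restriction scenario)
    cage_mask: Dict[str, np.ndarray] = {}

    columns, sample_ids, rows = [], [], []
    cage_no = 0
    for ti, tank in enumerate(envs):
        hatch_envs = envs[: config.cages_per_tank]
        for hi, hatch in enumerate(hatch_envs):
            cage_no += 1
            cage = str(cage_no)
            if config.cage_pool_frac < 1.0:
                crng = child_rng(seed, "cage_mask", cage)
                k = max(1, int(round(config.cage_pool_frac * config.n_otus)))
                mask = np.zeros(config.n_otus, dtype=bool)
                mask[crng.choice(config.n_otus, size=k, replace=False)] = True
                cage_mask[cage] = mask
            latent: np.ndarray | None = None
            for d in config.dph_schedule:
                stage = stage_from_dph(d)
                src = hatch if d == config.dph_schedule[0] else tank
                base = water_env[(src, d)]
                if cage in cage_mask:
                    restricted = np.where(cage_mask[cage], base, 0.0)
                    if restricted.sum() == 0:
                        raise ValueError(f"cage {cage} pool restriction removed all OTUs")
                    base = restricted / restricted.sum()
                # succession: the cage community carries over between sampling
                # times, receives immigrants from the source water at rate
                # dispersal_rate, drifts idiosyncratically, and is filtered by
                # the stage's host trait filter at every step, so selection
                # compounds across development while immigration keeps
                # re-seeding neutral mass
                if latent is None:
                    latent = base
                mixed = config.dispersal_rate * base + (1.0 - config.dispersal_rate) * latent
                mixed = _jittered(mixed, config.cage_drift_sd, child_rng(seed, "cage", cage, d))
                filt = mixed * _filter_weights(z, optima[stage], s_by_stage[stage], config.selection_sd)
                latent = filt / filt.sum()
                q = latent
                for rep in range(1, config.replicates + 1):
                    sid = f"gut_T{tank}_c{cage}_d{d}_r{rep}"
                    rng = child_rng(seed, "gut", sid)
                    counts = simulate_gut_sample(
                        q, z, optima[stage], s_by_stage[stage], config.selection_sd,
                        config.depth, rng=rng,
                    )
                    columns.append(counts)
                    sample_ids.append(sid)
                    rows.append(
                        dict(
                            sample_id=sid, habitat="gut", tank=tank, cage=cage,
                            hatch_env=hatch, rear_env=tank, dph=d, stage=stage,
                            transition=hatch != tank,
                            food="live" if d < 20 else "dry",
                        )
                    )
    for tank in envs:
        for d in config.water_dph:
            stage = stage_from_dph(d)
            w = water_env[(tank, d)]
            for rep in range(1, config.water_replicates + 1):
                sid = f"water_T{tank}_d{d}_r{rep}"
                rng = child_rng(seed, "water_sample", sid)
                columns.append(rng.multinomial(config.depth, w))
                sample_ids.append(sid)
                rows.append(
                    dict(
                        sample_id=sid, habitat="water", tank=tank, cage=pd.NA,
                        hatch_env=tank, rear_env=tank, dph=d, stage=stage,
                        transition=False, food="live" if d < 20 else "dry",
                    )
                )

    table = OtuTable(np.column_stack(columns), otu_ids, sample_ids)
    metadata = validate_metadata(pd.DataFrame(rows))
    truth = {
        "selection_strength_by_stage": s_by_stage,
        "stage_optima": optima,
        "selection_sd": config.selection_sd,
        "dispersal_rate": config.dispersal_rate,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(config).items()},
    }
    return SimulatedStudy(table=table, tree=tree, metadata=metadata, truth=truth)
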