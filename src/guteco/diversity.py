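"""Alpha diversity, beta diversity, shared-OTU fractions and Rao partitioning.

The Rao quadratic entropy Q of a community with relative abundances ``p`` and
a species dissimilarity matrix ``d`` is ``Q = sum_ij p_i p_j d_ij`` — the
expected dissimilarity between two randomly drawn reads. With the
species-neutral dissimilarity ``d_ij = 1(i != j)`` it reduces to the
Gini-Simpson index ``1 - sum p_i^2``.

The metacommunity partition decomposes the ecosystem diversity of a set of
water and gut samples into three additive components:

    gamma_ecosystem = alpha_local + beta_intra_habitats + beta_inter_habitats

where ``alpha_local`` is the mean per-sample diversity, ``beta_intra`` the mean
turnover among samples within a habitat, and ``beta_inter`` the turnover
between the pooled water and gut habitats. With the equivalent-numbers
correction (default) each level's mean raw Q is transformed to ``1/(1-Q)``
before differencing, which guarantees non-negative beta components because Q
is concave under pooling for the dissimilarities used here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .data import OtuTable

__all__ = [
    "alpha_diversity",
    "faith_pd",
    "beta_distance",
    "shared_otu_fractions",
    "rao_quadratic_entropy",
    "partition_diversity",
    "DiversityPartition",
]


# -- alpha -----------------------------------------------------------------

def _tip_paths(tree: TreeNode) -> Dict[str, Tuple[Tuple[int, ...], np.ndarray]]:
    """Per tip: ids and lengths of the edges on its path to the root."""
    paths = {}
    for tip in tree.tips():
        ids, lengths = [], []
        node = tip
        while node.parent is not None:
            ids.append(id(node))
            lengths.append(node.length)
            node = node.parent
        paths[tip.name] = (tuple(ids), np.asarray(lengths, dtype=float))
    return paths


def faith_pd(table: OtuTable, tree: TreeNode) -> pd.Series:
    """Faith phylogenetic diversity per sample (root-inclusive convention).

    PD is the total branch length of the union of root-to-tip paths of the
    OTUs present in the sample, including the path down to the tree root; the
    PD of the full tip set therefore equals the total branch length.
    """
    paths = _tip_paths(tree)
    missing = [o for o in table.otu_ids if o not in paths and table.counts[table._otu_index[o]].any()]
    if missing:
        raise ValueError(f"OTUs present in table but missing from tree: {missing[:10]}")
    lengths_by_id: Dict[int, float] = {}
    for ids, lens in paths.values():
        for i, l in zip(ids, lens):
            lengths_by_id[i] = l
    out = {}
    for sid in table.sample_ids:
        col = table.sample(sid)
        present = [o for o, c in zip(table.otu_ids, col) if c > 0]
        edge_ids = set()
        for o in present:
            edge_ids.update(paths[o][0])
        out[sid] = float(sum(lengths_by_id[i] for i in edge_ids))
    return pd.Series(out, name="pd")


def alpha_diversity(table: OtuTable, tree: Optional[TreeNode] = None) -> pd.DataFrame:
    """Richness, Shannon entropy (nats) and Faith PD per sample.

    ``tree`` may be omitted, in which case the ``pd`` column is skipped.
    """
    rel = table.relative_abundance()
    richness = (table.counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=0)
    df = pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    if tree is not None:
        df["pd"] = faith_pd(table, tree)
    return df


# -- beta ------------------------------------------------------------------

def beta_distance(table: OtuTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (abundance) or Jaccard (presence/absence) distances."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples for beta diversity")
    X = table.relative_abundance().T  # samples x OTUs; errors on all-zero samples
    if metric == "bray_curtis":
        condensed = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist(X > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown beta-diversity metric: {metric!r}")
    return DistanceMatrix(squareform(condensed), table.sample_ids)


# -- shared-OTU fractions --------------------------------------------------

def shared_otu_fractions(tables: Mapping[str, object]) -> Dict[Tuple[str, ...], float]:
    """Venn-style fractions of detected OTUs per exact environment subset.

    ``tables`` maps environment name to an :class:`OtuTable` (an OTU is
    "detected" if any sample has a positive count) or directly to an iterable
    of OTU ids. Returns, for every non-empty subset of environments, the
    fraction of all detected OTUs present in exactly that subset; the
    fractions sum to 1.
    """
    if len(tables) < 2:
        raise ValueError("need at least two environments")
    detected: Dict[str, frozenset] = {}
    for env, t in tables.items():
        if isinstance(t, OtuTable):
            detected[env] = frozenset(
                o for o, s in zip(t.otu_ids, t.otu_sums()) if s > 0
            )
        else:
            detected[env] = frozenset(t)
    envs = sorted(detected)
    universe = frozenset().union(*detected.values())
    if not universe:
        raise ValueError("no OTU detected in any environment")
    fractions: Dict[Tuple[str, ...], float] = {}
    for r in range(1, len(envs) + 1):
        for subset in itertools.combinations(envs, r):
            inside = set.intersection(*(set(detected[e]) for e in subset))
            for e in envs:
                if e not in subset:
                    inside -= detected[e]
            fractions[subset] = len(inside) / len(universe)
    return fractions


# -- Rao quadratic entropy and its partition -------------------------------

def rao_quadratic_entropy(p: np.ndarray, d: Optional[np.ndarray] = None) -> float:
    """Q = sum_ij p_i p_j d_ij; ``d=None`` means the species-neutral 0/1 matrix."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("abundances must sum to 1")
    if d is None:
        return float(1.0 - p @ p)
    d = np.asarray(d, dtype=float)
    if d.shape != (p.size, p.size):
        raise ValueError("dissimilarity matrix does not match the abundance vector")
    return float(p @ d @ p)


@dataclass
class DiversityPartition:
    """Additive Rao decomposition of ecosystem diversity within a scope."""

    scope: str
    gamma_ecosystem: float
    alpha_local: float
    beta_intra_habitats: float
    beta_inter_habitats: float
    equivalent_numbers: bool

    @property
    def fractions(self) -> Dict[str, float]:
        g = self.gamma_ecosystem
        if g <= 0:
            raise ValueError("gamma diversity is zero; fractions undefined")
        return {
            "alpha_local": self.alpha_local / g,
            "beta_intra_habitats": self.beta_intra_habitats / g,
            "beta_inter_habitats": self.beta_inter_habitats / g,
        }


def _rao_batch(P: np.ndarray, d: Optional[np.ndarray]) -> np.ndarray:
    if d is None:
        return 1.0 - np.einsum("ij,ij->i", P, P)
    return np.einsum("ij,jk,ik->i", P, d, P)


def partition_diversity(
    table: OtuTable,
    metadata: pd.DataFrame,
    d: Optional[np.ndarray] = None,
    scope: str = "all",
    equivalent_numbers: bool = True,
) -> DiversityPartition:
    """Decompose ecosystem Rao diversity into alpha / intra- / inter-habitat parts.

    ``scope`` is a tank id or ``"all"``; samples are grouped by habitat (water
    vs gut). Habitats contribute with equal weight regardless of their sample
    counts, pooled communities are unweighted means of their members'
    relative-abundance vectors, and the additivity
    ``gamma = alpha + beta_intra + beta_inter`` holds by construction.
    """
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if scope != "all":
        keep = [s for s in table.sample_ids if str(md.loc[s, "tank"]) == str(scope)]
        if not keep:
            raise ValueError(f"no samples in scope {scope!r}")
        table = table.select_samples(keep)
    habitats = sorted({md.loc[s, "habitat"] for s in table.sample_ids})
    for h in ("water", "gut"):
        if h not in habitats:
            raise ValueError(f"habitat {h!r} absent from scope {scope!r}")
    rel = table.relative_abundance().T  # samples x OTUs
    sample_hab = np.array([md.loc[s, "habitat"] for s in table.sample_ids])

    alpha_by_hab, gamma_by_hab, pooled_by_hab = [], [], []
    for h in habitats:
        Ph = rel[sample_hab == h]
        alpha_by_hab.append(_rao_batch(Ph, d).mean())
        pooled = Ph.mean(axis=0)
        pooled_by_hab.append(pooled)
        gamma_by_hab.append(rao_quadratic_entropy(pooled, d))
    eco_pool = np.mean(pooled_by_hab, axis=0)
    q_alpha = float(np.mean(alpha_by_hab))
    q_intra = float(np.mean(gamma_by_hab))
    q_gamma = rao_quadratic_entropy(eco_pool, d)

    if equivalent_numbers:
        for name, q in (("alpha", q_alpha), ("intra-habitat", q_intra), ("gamma", q_gamma)):
            if q >= 1.0 - 1e-12:
                raise ValueError(f"{name} Rao Q is 1; equivalent-numbers transform undefined")
        a, h_, g = 1.0 / (1.0 - q_alpha), 1.0 / (1.0 - q_intra), 1.0 / (1.0 - q_gamma)
    else:
        a, h_, g = q_alpha, q_intra, q_gamma
    return DiversityPartition(
        scope=str(scope),
        gamma_ecosystem=g,
        alpha_local=a,
        beta_intra_habitats=h_ - a,
        beta_inter_habitats=g - h_,
        equivalent_numbers=equivalent_numbers,
    )
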