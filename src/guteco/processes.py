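"""Null-model inference of community assembly processes.

For every pair of communities the pipeline computes

* the abundance-weighted beta mean nearest taxon distance (βMNTD) on a
  reference phylogeny, and its z-score βNTI against a tip-label-shuffle null;
* the Bray-Curtis-based Raup-Crick index RC_bray in [-1, 1], from a
  richness-preserving, occupancy-weighted probabilistic null assembly;
* a five-way process classification: |βNTI| > 2 signals selection
  (heterogeneous if positive, homogeneous if negative); otherwise
  |RC_bray| > 0.95 signals dispersal (limitation if positive, homogenizing if
  negative); anything else is undominated (weak selection, weak dispersal,
  diversification, drift).

Null random streams are derived from ``(seed, operation, canonical pair id)``
so every pairwise result is independent of iteration order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ._rng import child_rng
from .data import OtuTable, cophenetic_distances

__all__ = [
    "PROCESSES",
    "NullModelConfig",
    "SelectionStrengthResult",
    "bmntd",
    "bnti",
    "rc_bray",
    "classify_process",
    "pairwise_turnover",
    "process_profile",
    "selection_strength",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class NullModelConfig:
    """Replicate count, seed and classification thresholds for the null models."""

    n_null: int = 999
    seed: int = 0
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be positive")


# -- beta MNTD -------------------------------------------------------------

def bmntd(x: np.ndarray, y: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two communities.

    ``x`` and ``y`` are relative-abundance vectors aligned to the rows of the
    cophenetic matrix ``d``; a taxon shared by both communities contributes a
    nearest-taxon distance of zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("empty community")
    sub = d[np.ix_(ix, iy)]
    term_x = x[ix] / x[ix].sum() @ sub.min(axis=1)
    term_y = y[iy] / y[iy].sum() @ sub.min(axis=0)
    return float(0.5 * (term_x + term_y))


def _min_to_supports(D: np.ndarray, supports: Sequence[np.ndarray]) -> np.ndarray:
    """Row s: min distance from every taxon to sample s's support set."""
    return np.stack([D[:, idx].min(axis=1) for idx in supports])


def _bmntd_cross(X: np.ndarray, MN: np.ndarray) -> np.ndarray:
    """Full m x m βMNTD matrix from normalized abundances X and min-matrix MN."""
    cross = X @ MN.T
    return 0.5 * (cross + cross.T)


def _as_distance_array(tree_or_dm, otu_ids: Sequence[str]) -> np.ndarray:
    if isinstance(tree_or_dm, TreeNode):
        dm = cophenetic_distances(tree_or_dm)
    elif isinstance(tree_or_dm, DistanceMatrix):
        dm = tree_or_dm
    else:
        return np.asarray(tree_or_dm, dtype=float)
    missing = [o for o in otu_ids if o not in set(dm.ids)]
    if missing:
        raise ValueError(f"OTUs missing from the phylogeny/distance matrix: {missing[:10]}")
    return dm.filter(otu_ids).data


def bnti(
    x: np.ndarray,
    y: np.ndarray,
    tree_or_dm,
    config: Optional[NullModelConfig] = None,
    otu_ids: Optional[Sequence[str]] = None,
) -> Tuple[float, float]:
    """Observed βMNTD and its z-score against a taxa-shuffle null.

    The null shuffles tip labels across the whole phylogeny (equivalently,
    permutes rows and columns of the cophenetic matrix jointly) while keeping
    abundances fixed. Requires ``n_null >= 2`` so the null SD is defined.
    """
    config = config or NullModelConfig()
    if config.n_null < 2:
        raise ValueError("bnti needs n_null >= 2 for a defined null SD")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if otu_ids is None and isinstance(tree_or_dm, (TreeNode, DistanceMatrix)):
        ids = (
            sorted(t.name for t in tree_or_dm.tips())
            if isinstance(tree_or_dm, TreeNode)
            else sorted(tree_or_dm.ids)
        )
    else:
        ids = list(otu_ids) if otu_ids is not None else [str(i) for i in range(x.size)]
    # canonical (sorted-id) order makes the shuffle stream relabeling-invariant
    order = np.argsort(np.asarray(ids, dtype=object))
    D = _as_distance_array(tree_or_dm, [ids[i] for i in order])
    x, y = x[order], y[order]
    obs = bmntd(x, y, D)
    rng = child_rng(config.seed, "bnti")
    n = D.shape[0]
    null = np.empty(config.n_null)
    supports = [np.flatnonzero(x > 0), np.flatnonzero(y > 0)]
    X = np.stack([x / x.sum(), y / y.sum()])
    for k in range(config.n_null):
        perm = rng.permutation(n)
        Dk = D[np.ix_(perm, perm)]
        null[k] = _bmntd_cross(X, _min_to_supports(Dk, supports))[0, 1]
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate taxa-shuffle null: null βMNTD has zero variance")
    return obs, float((obs - null.mean()) / sd)


# -- Raup-Crick (Bray-Curtis) ---------------------------------------------

def _null_assemble(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occupancy: np.ndarray,
    meta_p: np.ndarray,
    n_null: int,
) -> np.ndarray:
    """n_null null communities: fixed richness, occupancy-weighted membership,
    abundance-weighted allocation of the remaining reads."""
    n = occupancy.size
    available = occupancy > 0
    if richness > available.sum():
        raise ValueError("observed richness exceeds the available species pool")
    logw = np.where(available, np.log(occupancy, where=available, out=np.full(n, -np.inf)), -np.inf)
    keys = logw + rng.gumbel(size=(n_null, n))
    support = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    counts = np.zeros((n_null, n), dtype=np.int64)
    np.put_along_axis(counts, support, 1, axis=1)
    remaining = total - richness
    if remaining > 0:
        probs = np.zeros((n_null, n))
        np.put_along_axis(probs, support, np.take(meta_p, support), axis=1)
        rowsums = probs.sum(axis=1, keepdims=True)
        # a drawn set with zero metacommunity mass cannot happen (occupancy > 0
        # implies positive total count), but guard against fp underflow
        probs = probs / rowsums
        counts += rng.multinomial(remaining, probs)
    return counts


def _table_null_weights(table: OtuTable) -> Tuple[np.ndarray, np.ndarray]:
    occupancy = (table.counts > 0).sum(axis=1).astype(float)
    total = table.counts.sum()
    meta_p = table.counts.sum(axis=1) / total
    return occupancy, meta_p


def rc_bray(
    x: np.ndarray,
    y: np.ndarray,
    table: OtuTable,
    config: Optional[NullModelConfig] = None,
    pair_id: Optional[Tuple[str, str]] = None,
) -> float:
    """Raup-Crick index on Bray-Curtis, in [-1, 1].

    Each of ``n_null`` replicates assembles both communities from the
    metacommunity ``table``: observed richness is preserved, species are drawn
    without replacement with probability proportional to their occupancy
    frequency, one read seeds each drawn species and the remaining reads are
    allocated with probability proportional to metacommunity relative
    abundance. RC is twice the (tie-half-weighted) fraction of null
    Bray-Curtis values below the observed one, minus 1.
    """
    config = config or NullModelConfig()
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    occupancy, meta_p = _table_null_weights(table)
    key = tuple(sorted(pair_id)) if pair_id is not None else ("x", "y")
    rng = child_rng(config.seed, "rc_bray", *key)
    return _rc_from_weights(x, y, occupancy, meta_p, config.n_null, rng)


def _rc_from_weights(x, y, occupancy, meta_p, n_null, rng) -> float:
    null_x = _null_assemble(rng, int((x > 0).sum()), int(x.sum()), occupancy, meta_p, n_null)
    null_y = _null_assemble(rng, int((y > 0).sum()), int(y.sum()), occupancy, meta_p, n_null)
    obs_num = np.abs(x - y).sum()
    null_num = np.abs(null_x - null_y).sum(axis=1)
    n_lt = int((null_num < obs_num).sum())
    n_eq = int((null_num == obs_num).sum())
    return float(2.0 * ((n_lt + 0.5 * n_eq) / n_null) - 1.0)


# -- classification --------------------------------------------------------

def classify_process(
    bnti_value: float, rc_value: float, config: Optional[NullModelConfig] = None
) -> str:
    """Map a (βNTI, RC_bray) pair to one of the five assembly processes.

    Selection thresholds take precedence: the dispersal rules only apply when
    |βNTI| is below the selection threshold.
    """
    config = config or NullModelConfig()
    if np.isnan(bnti_value) or np.isnan(rc_value):
        raise ValueError("NaN input to process classification")
    if not -1.0 - 1e-9 <= rc_value <= 1.0 + 1e-9:
        raise ValueError("RC_bray must lie in [-1, 1]")
    t, rt = config.bnti_threshold, config.rc_threshold
    if bnti_value > t:
        return "heterogeneous_selection"
    if bnti_value < -t:
        return "homogeneous_selection"
    if rc_value > rt:
        return "dispersal_limitation"
    if rc_value < -rt:
        return "homogenizing_dispersal"
    return "undominated"


# -- batch pipeline --------------------------------------------------------

def pairwise_turnover(
    table: OtuTable,
    tree_or_dm,
    metadata: pd.DataFrame,
    config: Optional[NullModelConfig] = None,
    group_by: str = "stage",
    habitat: str = "gut",
    within: Optional[str] = None,
) -> pd.DataFrame:
    """βMNTD, βNTI, Bray-Curtis, RC_bray and process for every within-group pair.

    Pairs are formed within levels of ``group_by`` (default: developmental
    stage) among samples of the given habitat, pooled across tanks and cages;
    pass ``within="cage"`` (or another metadata column) to additionally
    restrict pairs to samples sharing that column's value. The taxa-shuffle
    null permutation sequence is shared across all pairs, as in the standard
    weighted taxa-shuffle; RC nulls get one stream per canonical pair id.
    """
    config = config or NullModelConfig()
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    keep = [s for s in table.sample_ids if md.loc[s, "habitat"] == habitat]
    if len(keep) < 2:
        raise ValueError(f"fewer than two {habitat!r} samples")
    sub = table.select_samples(keep)
    # canonical orders: sorted OTU ids and sorted sample ids; the taxa-shuffle
    # universe is every OTU of the input table (the whole-study tree), not
    # just those detected in this habitat
    sub = sub.select_otus(sorted(sub.otu_ids)).select_samples(sorted(sub.sample_ids))

    D = _as_distance_array(tree_or_dm, sub.otu_ids)
    counts = sub.counts
    rel = sub.relative_abundance()
    m = sub.n_samples
    groups = np.array([md.loc[s, group_by] for s in sub.sample_ids], dtype=object)
    pair_idx: List[Tuple[int, int]] = []
    for i, j in itertools.combinations(range(m), 2):
        if groups[i] != groups[j]:
            continue
        if within is not None and md.loc[sub.sample_ids[i], within] != md.loc[sub.sample_ids[j], within]:
            continue
        pair_idx.append((i, j))
    if not pair_idx:
        raise ValueError("no within-group sample pairs")
    ii = np.array([p[0] for p in pair_idx])
    jj = np.array([p[1] for p in pair_idx])

    # observed βMNTD and the shared-permutation null, all pairs at once
    supports = [np.flatnonzero(counts[:, s] > 0) for s in range(m)]
    X = rel.T  # m x n, rows sum to 1
    obs_mat = _bmntd_cross(X, _min_to_supports(D, supports))
    obs = obs_mat[ii, jj]
    rng = child_rng(config.seed, "bnti")
    n = D.shape[0]
    null_sum = np.zeros(obs.size)
    null_sq = np.zeros(obs.size)
    D32 = D.astype(np.float32)
    X32 = X.astype(np.float32)
    for _ in range(config.n_null):
        perm = rng.permutation(n)
        Dk = D32[perm][:, perm]
        nk = _bmntd_cross(X32, _min_to_supports(Dk, supports))[ii, jj].astype(float)
        null_sum += nk
        null_sq += nk**2
    mean = null_sum / config.n_null
    var = (null_sq - config.n_null * mean**2) / (config.n_null - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    # pairs sharing their entire support have a constant null (bMNTD = 0 under
    # every shuffle); their phylogenetic turnover is exactly null-typical
    degenerate = sd <= 1e-12
    if (degenerate & (np.abs(obs - mean) > 1e-9)).any():
        raise ValueError("degenerate taxa-shuffle null: zero variance for some pair")
    z = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))

    # Bray-Curtis and Raup-Crick per pair
    occupancy, meta_p = _table_null_weights(sub)
    bc = np.array(
        [np.abs(rel[:, i] - rel[:, j]).sum() / (rel[:, i] + rel[:, j]).sum() for i, j in pair_idx]
    )
    rc = np.empty(obs.size)
    for k, (i, j) in enumerate(pair_idx):
        sid_i, sid_j = sub.sample_ids[i], sub.sample_ids[j]
        prng = child_rng(config.seed, "rc_bray", *sorted((sid_i, sid_j)))
        rc[k] = _rc_from_weights(
            counts[:, i], counts[:, j], occupancy, meta_p, config.n_null, prng
        )

    records = []
    for k, (i, j) in enumerate(pair_idx):
        records.append(
            dict(
                sample_a=sub.sample_ids[i],
                sample_b=sub.sample_ids[j],
                group=groups[i],
                bmntd_obs=obs[k],
                bnti=z[k],
                bc_obs=bc[k],
                rc_bray=rc[k],
                process=classify_process(z[k], rc[k], config),
            )
        )
    return pd.DataFrame.from_records(records)


def process_profile(turnover: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Fraction of pairs assigned to each process, per group; rows sum to 1."""
    if turnover.empty:
        raise ValueError("empty turnover table")
    out = {}
    for g, chunk in turnover.groupby(group_col, sort=True):
        frac = chunk["process"].value_counts(normalize=True)
        out[g] = [float(frac.get(p, 0.0)) for p in PROCESSES]
    return pd.DataFrame.from_dict(out, orient="index", columns=list(PROCESSES)).rename_axis(
        group_col
    )


# -- selection strength ----------------------------------------------------

@dataclass
class SelectionStrengthResult:
    group: str
    observed_similarity: float
    null_mean_similarity: float
    deterministic_ratio: float
    p_value: float
    n_null: int


def selection_strength(
    table: OtuTable,
    metadata: pd.DataFrame,
    group: str,
    config: Optional[NullModelConfig] = None,
    group_by: str = "stage",
    habitat: str = "gut",
    ratio_scale: str = "similarity",
) -> SelectionStrengthResult:
    """Excess of observed within-group similarity over an alpha/gamma-constrained null.

    Observed mean within-group Bray-Curtis similarity ``S_obs = 1 - mean(BC)``
    is compared with null communities assembled exactly as in the Raup-Crick
    null (richness-preserving, occupancy-weighted, abundance-allocated), which
    holds per-sample alpha diversity fixed and draws from the gamma pool of
    the whole table. The deterministic ratio is ``(S_obs - mean(S_null)) /
    S_obs`` clipped to [0, 1]; the p-value is the (+1-corrected) fraction of
    null replicate means at or above ``S_obs``.

    The exact ratio normalisation is one defensible reading of an ambiguous
    procedure; ``ratio_scale="dissimilarity"`` swaps in the alternative
    ``(D_null_mean - D_obs) / D_null_mean`` on the dissimilarity scale.
    """
    if ratio_scale not in ("similarity", "dissimilarity"):
        raise ValueError("ratio_scale must be 'similarity' or 'dissimilarity'")
    config = config or NullModelConfig()
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    members = [
        s
        for s in table.sample_ids
        if md.loc[s, "habitat"] == habitat and md.loc[s, group_by] == group
    ]
    if len(members) < 2:
        raise ValueError(f"group {group!r} has fewer than two samples")
    counts = np.stack([table.sample(s) for s in sorted(members)])  # g x n
    occupancy, meta_p = _table_null_weights(table)

    g = counts.shape[0]
    pair_i, pair_j = np.triu_indices(g, k=1)
    sums = counts.sum(axis=1)
    obs_bc = np.abs(counts[pair_i] - counts[pair_j]).sum(axis=1) / (
        sums[pair_i] + sums[pair_j]
    )
    s_obs = 1.0 - float(obs_bc.mean())
    if np.allclose(obs_bc, 0.0):
        warnings.warn("all group samples identical; deterministic ratio set to 1", stacklevel=2)
        degenerate = True
    else:
        degenerate = False

    nulls = []
    for idx, s in enumerate(sorted(members)):
        rng = child_rng(config.seed, "selection_strength", s)
        nulls.append(
            _null_assemble(
                rng, int((counts[idx] > 0).sum()), int(sums[idx]), occupancy, meta_p, config.n_null
            )
        )
    null_bc_mean = np.zeros(config.n_null)
    for a, b in zip(pair_i, pair_j):
        num = np.abs(nulls[a] - nulls[b]).sum(axis=1)
        null_bc_mean += num / (sums[a] + sums[b])
    null_bc_mean /= pair_i.size
    s_null = 1.0 - null_bc_mean
    p = (1.0 + int((s_null >= s_obs).sum())) / (1.0 + config.n_null)
    if degenerate:
        ratio = 1.0
    elif ratio_scale == "dissimilarity":
        d_null = null_bc_mean.mean()
        ratio = float(np.clip((d_null - float(obs_bc.mean())) / d_null, 0.0, 1.0))
    else:
        ratio = float(np.clip((s_obs - s_null.mean()) / s_obs, 0.0, 1.0))
    return SelectionStrengthResult(
        group=str(group),
        observed_similarity=s_obs,
        null_mean_similarity=float(s_null.mean()),
        deterministic_ratio=ratio,
        p_value=float(p),
        n_null=config.n_null,
    )
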