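"""Distance-based and variance-partitioning statistics.

PERMANOVA and (partial) Mantel tests use unrestricted label/id permutations
with the +1 correction, so permutation p-values are never exactly zero; both
offer an exhaustive mode that enumerates every distinct permutation for small
problems. Hierarchical partitioning follows the Chevan-Sutherland
decomposition: a factor's independent contribution is the average, over all
subsets of the remaining factors (stratified by subset size), of the R^2 gain
from adding that factor; the independent contributions sum exactly to the
full-model R^2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from ._rng import child_rng

__all__ = [
    "PermanovaResult",
    "MantelResult",
    "AnovaLsdResult",
    "permanova",
    "mantel",
    "partial_mantel",
    "anova_lsd",
    "variance_partition",
]


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    p_value: float
    n_perm: int
    n_samples: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        return math.inf
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
    factor: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with whole-sample label permutations.

    ``labels`` aligns with ``dm.ids`` (or is a mapping/Series indexed by id).
    ``exact=True`` enumerates all distinct label assignments instead of
    sampling ``n_perm`` random permutations.
    """
    if hasattr(labels, "loc"):
        labels = [labels.loc[i] for i in dm.ids]
    elif isinstance(labels, dict):
        labels = [labels[i] for i in dm.ids]
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(dm.ids):
        raise ValueError("labels do not align with the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = dm.data.astype(float) ** 2
    if d2.sum() == 0:
        raise ValueError("degenerate input: all pairwise distances are zero")
    f_obs = _pseudo_f(d2, codes, uniq.size)

    if exact:
        seen = set()
        n_ge = 0
        for perm in itertools.permutations(range(codes.size)):
            key = tuple(codes[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            if _pseudo_f(d2, np.asarray(key), uniq.size) >= f_obs - 1e-12:
                n_ge += 1
        total = len(seen)
        return PermanovaResult(factor, f_obs, n_ge / total, total - 1, codes.size, uniq.size)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = child_rng(seed, "permanova", factor)
    n_ge = 0
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(codes.size)]
        if _pseudo_f(d2, perm_codes, uniq.size) >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return PermanovaResult(factor, f_obs, p, n_perm, codes.size, uniq.size)


# -- Mantel ----------------------------------------------------------------

@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_perm: int
    controlled: Optional[str] = None


def _aligned(a: DistanceMatrix, *others: DistanceMatrix) -> List[np.ndarray]:
    mats = [a.data.astype(float)]
    ids = list(a.ids)
    for b in others:
        if set(b.ids) != set(ids):
            raise ValueError("distance matrices have different id sets")
        mats.append(b.filter(ids).data.astype(float))
    return mats


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValueError("zero variance in a distance matrix")
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs; the
    one-sided p-value permutes the ids of ``b`` (+1 corrected). ``exact=True``
    enumerates all n! permutations.
    """
    A, B = _aligned(a, b)
    u = _condensed(A)
    r_obs = _pearson(u, _condensed(B))
    n = A.shape[0]
    if exact:
        n_ge, total = 0, 0
        for perm in itertools.permutations(range(n)):
            perm = list(perm)
            if _pearson(u, _condensed(B[np.ix_(perm, perm)])) >= r_obs - 1e-12:
                n_ge += 1
            total += 1
        return MantelResult(r_obs, n_ge / total, total - 1)
    rng = child_rng(seed, "mantel")
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pearson(u, _condensed(B[np.ix_(perm, perm)])) >= r_obs - 1e-12:
            n_ge += 1
    return MantelResult(r_obs, (1 + n_ge) / (1 + n_perm), n_perm)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    num = r_ab - r_ac * r_bc
    den = (1 - r_ac**2) * (1 - r_bc**2)
    if den <= 1e-12:
        # B == C (or a perfectly correlated control): numerator vanishes with
        # the denominator and the partial correlation is 0 by construction
        if abs(num) <= 1e-9:
            return 0.0
        raise ValueError("partial correlation undefined: |r_AC| or |r_BC| equals 1")
    return num / math.sqrt(den)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    controlled: str = "C",
) -> MantelResult:
    """Partial Mantel r(AB.C): correlation of A and B controlling for C.

    The permutation test permutes A's ids, recomputing r_AB and r_AC while
    r_BC stays fixed.
    """
    A, B, C = _aligned(a, b, c)
    ua, ub, uc = _condensed(A), _condensed(B), _condensed(C)
    r_bc = _pearson(ub, uc)
    r_obs = _partial_r(_pearson(ua, ub), _pearson(ua, uc), r_bc)
    rng = child_rng(seed, "partial_mantel")
    n = A.shape[0]
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        up = _condensed(A[np.ix_(perm, perm)])
        if _partial_r(_pearson(up, ub), _pearson(up, uc), r_bc) >= r_obs - 1e-12:
            n_ge += 1
    return MantelResult(r_obs, (1 + n_ge) / (1 + n_perm), n_perm, controlled=controlled)


# -- ANOVA with LSD --------------------------------------------------------

@dataclass
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    group_means: pd.Series
    letters: Dict[str, str]
    alpha: float


def anova_lsd(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's least-significant-difference letters.

    Pairwise LSD t-tests use the pooled ANOVA mean square error and are, by
    design, unadjusted for multiplicity. Groups that share a letter are not
    significantly different at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    by_group = {g: values[groups == g] for g in names}
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    f_stat, p = sps.f_oneway(*(by_group[g] for g in names))
    n_total = values.size
    k = len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / (n_total - k)
    means = pd.Series({g: by_group[g].mean() for g in names})

    import networkx as nx

    nonsig = nx.Graph()
    nonsig.add_nodes_from(names)
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = by_group[g1].size, by_group[g2].size
        if mse == 0:
            different = means[g1] != means[g2]
        else:
            t = abs(means[g1] - means[g2]) / math.sqrt(mse * (1 / n1 + 1 / n2))
            different = 2 * sps.t.sf(t, n_total - k) < alpha
        if not different:
            nonsig.add_edge(g1, g2)
    cliques = sorted(
        (sorted(c, key=lambda g: -means[g]) for c in nx.find_cliques(nonsig)),
        key=lambda c: -means[c[0]],
    )
    letters = {g: "" for g in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    letters = {g: "".join(sorted(l)) for g, l in letters.items()}
    return AnovaLsdResult(float(f_stat), float(p), means, letters, alpha)


# -- GLM variance explained and hierarchical partitioning ------------------

def _design(md: pd.DataFrame, factors: Sequence[str]) -> np.ndarray:
    if not factors:
        return np.ones((len(md), 1))
    dummies = pd.get_dummies(md[list(factors)].astype(str), drop_first=True)
    X = np.column_stack([np.ones(len(md)), dummies.to_numpy(dtype=float)])
    return X


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return float(1.0 - (resid**2).sum() / ss_tot)


def variance_partition(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    responses: Sequence[str] = ("pd", "richness", "shannon"),
    factors: Sequence[str] = ("stage", "rear_env", "transition", "food"),
) -> Dict[str, pd.DataFrame]:
    """Marginal R^2 and Chevan-Sutherland independent/joint contributions.

    ``alpha`` is the per-sample alpha-diversity table (indexed by sample id);
    ``metadata`` supplies the categorical factors. Returns one DataFrame per
    response with columns ``marginal_r2``, ``independent``, ``joint`` and
    ``independent_pct`` (percentages normalised to sum to 100).
    """
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    md = md.loc[alpha.index]
    for f in factors:
        if md[f].astype(str).nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    full_X = _design(md, factors)
    if np.linalg.matrix_rank(full_X) < full_X.shape[1]:
        raise ValueError(f"aliased/collinear factor levels among {list(factors)}")

    out: Dict[str, pd.DataFrame] = {}
    k = len(factors)
    for resp in responses:
        y = alpha[resp].to_numpy(dtype=float)
        r2_cache = {
            subset: _r2(y, _design(md, subset))
            for r in range(k + 1)
            for subset in itertools.combinations(factors, r)
        }
        rows = {}
        for f in factors:
            others = [x for x in factors if x != f]
            by_size = []
            for j in range(k):
                gains = [
                    r2_cache[tuple(sorted(set(s) | {f}, key=factors.index))] - r2_cache[s]
                    for s in itertools.combinations(others, j)
                ]
                by_size.append(np.mean(gains))
            independent = float(np.mean(by_size))
            marginal = r2_cache[(f,)]
            rows[f] = dict(
                marginal_r2=marginal, independent=independent, joint=marginal - independent
            )
        df = pd.DataFrame.from_dict(rows, orient="index")
        total = df["independent"].sum()
        df["independent_pct"] = 100.0 * df["independent"] / total if total != 0 else np.nan
        df.attrs["full_model_r2"] = r2_cache[tuple(factors)]
        out[resp] = df
    return out
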