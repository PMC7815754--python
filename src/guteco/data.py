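"""Core data model and I/O: OTU tables, phylogenies, sample metadata, distances.

Conventions
-----------
* OTU tables are OTUs-by-samples (rows are OTUs, columns are samples), matching
  common amplicon tooling output; counts are non-negative integers (reads).
* Phylogenies are rooted scikit-bio ``TreeNode`` objects whose tips are OTU ids;
  every edge must carry a branch length (strict newick) because phylogenetic
  turnover and Faith PD are undefined without lengths.
* Distance matrices are ``skbio.DistanceMatrix`` (symmetric, hollow, finite).
* Sample metadata is a pandas DataFrame with one row per sample and the columns
  listed in :data:`METADATA_COLUMNS`.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ._rng import child_rng

__all__ = [
    "OtuTable",
    "DEFAULT_RAREFACTION_DEPTH",
    "METADATA_COLUMNS",
    "STAGES",
    "STAGE_RANGES",
    "stage_from_dph",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "cophenetic_distances",
    "rarefy",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: Sequencing depth every sample is resampled to before community analysis.
DEFAULT_RAREFACTION_DEPTH = 14_666

METADATA_COLUMNS = [
    "sample_id",
    "habitat",
    "tank",
    "cage",
    "hatch_env",
    "rear_env",
    "dph",
    "stage",
    "transition",
    "food",
]

#: Developmental stages and their day-post-hatching ranges (inclusive).
STAGES = ("S1", "S2", "S3")
STAGE_RANGES = {"S1": (12, 20), "S2": (27, 42), "S3": (56, 98)}


class OtuTable:
    """An OTU-by-sample table of non-negative integer read counts.

    Parameters
    ----------
    counts : array-like of shape (n_otus, n_samples)
        Read counts; coerced to int64. Negative values are rejected.
    otu_ids, sample_ids : sequences of unique strings
        Row and column labels.
    """

    def __init__(
        self,
        counts,
        otu_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (OTUs x samples)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers (reads)")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        otu_ids = [str(o) for o in otu_ids]
        sample_ids = [str(s) for s in sample_ids]
        if len(otu_ids) != counts.shape[0] or len(sample_ids) != counts.shape[1]:
            raise ValueError("id lengths do not match the counts matrix shape")
        if len(set(otu_ids)) != len(otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("need at least one OTU and one sample")
        self.counts = counts
        self.otu_ids = list(otu_ids)
        self.sample_ids = list(sample_ids)
        self._otu_index = {o: i for i, o in enumerate(self.otu_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    # -- basic views -------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised matrix; errors on all-zero samples."""
        sums = self.sample_sums()
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise ValueError(f"all-zero samples: {bad}")
        return self.counts / sums.astype(float)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self._sample_index[sample_id]]

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return OtuTable(self.counts[:, idx], self.otu_ids, [self.sample_ids[j] for j in idx])

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        idx = [self._otu_index[o] for o in otu_ids]
        return OtuTable(self.counts[idx, :], [self.otu_ids[i] for i in idx], self.sample_ids)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.otu_sums() > 0
        if not keep.any():
            raise ValueError("table has no OTU with positive count")
        return OtuTable(
            self.counts[keep], [o for o, k in zip(self.otu_ids, keep) if k], self.sample_ids
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


# -- OTU table I/O ---------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from TSV (default) or BIOM 2.x HDF5.

    The TSV layout is: header row of sample ids, first column ``otu_id``.
    """
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom":
        return _read_otu_biom(path)
    raise ValueError(f"unknown OTU table format: {format!r}")


def _read_otu_tsv(path) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed file: surface a parse error
        raise ValueError(f"could not parse OTU table {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ValueError(f"OTU table {path}: header row has no sample columns")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"OTU table {path}: non-numeric columns {bad}")
    return OtuTable(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


def _read_otu_biom(path) -> OtuTable:
    # Minimal BIOM 2.x (HDF5, CSR on observations) reader.
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(otu_ids), len(sample_ids)),
        )
    return OtuTable(np.asarray(mat.todense()), otu_ids, sample_ids)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


# -- phylogeny I/O ---------------------------------------------------------

def read_tree(path, strict: bool = True) -> TreeNode:
    """Read a rooted newick tree whose tips are OTU ids.

    In strict mode (default) every non-root edge must carry a branch length and
    every tip must be labelled; with ``strict=False`` missing lengths become 0.
    """
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree, strict=strict)


def validate_tree(tree: TreeNode, strict: bool = True) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if strict:
                raise ValueError("newick edge without a branch length (strict mode)")
            node.length = 0.0
        elif node.length < 0:
            raise ValueError("negative branch length")
    tips = list(tree.tips())
    if any(t.name is None for t in tips):
        raise ValueError("unlabeled tip in newick tree")
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tip labels")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path)."""
    return tree.tip_tip_distances()


# -- rarefaction -----------------------------------------------------------

def rarefy(table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Each sample gets an independent random stream derived from
    ``(seed, "rarefy", sample_id)``, so the result does not depend on sample
    order.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    keep, columns = [], []
    for j, sid in enumerate(table.sample_ids):
        total = sums[j]
        if total < depth:
            warnings.warn(
                f"dropping sample {sid!r}: total reads {total} < depth {depth}",
                stacklevel=2,
            )
            continue
        col = table.counts[:, j]
        if total == depth:
            columns.append(col.copy())
        else:
            rng = child_rng(seed, "rarefy", sid)
            columns.append(rng.multivariate_hypergeometric(col, depth))
        keep.append(sid)
    if not keep:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(np.column_stack(columns), table.otu_ids, keep)


# -- metadata --------------------------------------------------------------

def stage_from_dph(dph: int, strict: bool = True) -> str:
    """Map days post-hatching to developmental stage S1/S2/S3.

    12-20 dph -> S1, 27-42 -> S2, 56-98 -> S3. Outside these ranges: error in
    strict mode, otherwise the nearest range with a warning.
    """
    dph = int(dph)
    if dph < 0:
        raise ValueError("dph must be non-negative")
    for stage, (lo, hi) in STAGE_RANGES.items():
        if lo <= dph <= hi:
            return stage
    if strict:
        raise ValueError(f"dph {dph} outside the sampled stage ranges {STAGE_RANGES}")
    dist = {
        s: min(abs(dph - lo), abs(dph - hi)) for s, (lo, hi) in STAGE_RANGES.items()
    }
    nearest = min(dist, key=dist.get)
    warnings.warn(f"dph {dph} outside stage ranges; using nearest stage {nearest}", stacklevel=2)
    return nearest


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check metadata invariants; returns the (typed) frame.

    Invariants: stage is the deterministic function of dph; transition holds
    iff hatch_env != rear_env (gut samples); water samples carry no cage.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    md = metadata.copy()
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad_hab = set(md["habitat"]) - {"water", "gut"}
    if bad_hab:
        raise ValueError(f"unknown habitat values: {bad_hab}")
    md["dph"] = md["dph"].astype(int)
    md["transition"] = md["transition"].astype(bool)
    for _, row in md.iterrows():
        expect = stage_from_dph(row["dph"])
        if row["stage"] != expect:
            raise ValueError(
                f"sample {row['sample_id']}: stage {row['stage']} != {expect} from dph {row['dph']}"
            )
        if row["habitat"] == "gut":
            if row["transition"] != (row["hatch_env"] != row["rear_env"]):
                raise ValueError(
                    f"sample {row['sample_id']}: transition flag inconsistent with environments"
                )
        else:
            if not (pd.isna(row["cage"]) or row["cage"] in ("", "NA")):
                raise ValueError(f"water sample {row['sample_id']} must not carry a cage")
    return md


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"cage": "string"})
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


# -- distance matrices -----------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")
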