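"""End-to-end orchestration: simulate/load -> rarefy -> diversity -> processes -> stats.

Every intermediate is written as plain TSV plus one JSON summary; identical
config and seed produce byte-identical outputs. One global seed fans out to
per-stage child streams (via stage-name hashing in :mod:`guteco._rng`), so
adding a pipeline stage never perturbs the streams of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import diversity as div
from . import processes as proc
from . import stats as st
from .data import (
    DEFAULT_RAREFACTION_DEPTH,
    OtuTable,
    rarefy,
    read_metadata,
    read_otu_table,
    read_tree,
    stage_from_dph,
    write_distance_matrix,
    write_metadata,
    write_otu_table,
)
from .simulate import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_from_dph", "factor_distance"]

log = logging.getLogger("guteco")

STAGE_RANK = {"S1": 1, "S2": 2, "S3": 3}


@dataclass
class PipelineConfig:
    """Inputs (paths or an embedded simulation), depths, null config, output."""

    table_path: Optional[str] = None
    tree_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    null: proc.NullModelConfig = field(default_factory=proc.NullModelConfig)
    out_dir: str = "guteco_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = all(p is not None for p in (self.table_path, self.tree_path, self.metadata_path))
        if self.simulation is None and not has_paths:
            raise ValueError("provide either input paths or a simulation block")
        if self.simulation is not None and has_paths:
            raise ValueError("provide input paths or a simulation block, not both")


@dataclass
class RunReport:
    process_profile: pd.DataFrame
    partitions: List[div.DiversityPartition]
    permanova: pd.DataFrame
    mantel: pd.DataFrame
    selection: pd.DataFrame
    alpha: pd.DataFrame
    out_dir: Path
    config: dict


def factor_distance(metadata: pd.DataFrame, sample_ids, factor: str) -> DistanceMatrix:
    """Model distance matrix for a metadata factor.

    ``stage`` is ordinal (|rank difference| over S1<S2<S3); every other factor
    is a 0/1 mismatch.
    """
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    vals = [md.loc[s, factor] for s in sample_ids]
    if factor == "stage":
        v = np.array([STAGE_RANK[x] for x in vals], dtype=float)
        mat = np.abs(v[:, None] - v[None, :])
    else:
        v = np.asarray(vals, dtype=object)
        mat = (v[:, None] != v[None, :]).astype(float)
    return DistanceMatrix(mat, list(sample_ids))


def _stage(name: str):
    log.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order, writing all intermediates to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _run(config, out)


def _run(config: PipelineConfig, out: Path) -> RunReport:
    _stage("inputs")
    if config.simulation is not None:
        study = simulate_study(config.simulation)
        table, tree, metadata = study.table, study.tree, study.metadata
        write_otu_table(table, out / "otu_table.tsv")
        tree.write(str(out / "tree.nwk"), format="newick")
        write_metadata(metadata, out / "metadata.tsv")
        (out / "truth.json").write_text(json.dumps(study.truth, indent=2, default=str))
    else:
        table = read_otu_table(config.table_path)
        tree = read_tree(config.tree_path)
        metadata = read_metadata(config.metadata_path)

    _stage("rarefy")
    table = rarefy(table, config.rarefaction_depth, config.seed)
    metadata = metadata[metadata["sample_id"].isin(table.sample_ids)].reset_index(drop=True)
    write_otu_table(table, out / "otu_table_rarefied.tsv")

    _stage("alpha_diversity")
    alpha = div.alpha_diversity(table, tree)
    alpha.to_csv(out / "alpha.tsv", sep="\t")

    _stage("beta_diversity")
    md = metadata.set_index("sample_id")
    gut_ids = sorted(s for s in table.sample_ids if md.loc[s, "habitat"] == "gut")
    gut = table.select_samples(gut_ids)
    beta = {m: div.beta_distance(gut, m) for m in ("bray_curtis", "jaccard")}
    for m, dm in beta.items():
        write_distance_matrix(dm, out / f"beta_{m}.tsv")

    _stage("diversity_partition")
    tanks = sorted(metadata["tank"].unique())
    partitions = [div.partition_diversity(table, metadata, scope=t) for t in tanks]
    partitions.append(div.partition_diversity(table, metadata, scope="all"))
    part_rows = []
    for p in partitions:
        row = dict(scope=p.scope, gamma_ecosystem=p.gamma_ecosystem, alpha_local=p.alpha_local,
                   beta_intra_habitats=p.beta_intra_habitats,
                   beta_inter_habitats=p.beta_inter_habitats)
        row.update({f"frac_{k}": v for k, v in p.fractions.items()})
        part_rows.append(row)
    pd.DataFrame(part_rows).to_csv(out / "partition.tsv", sep="\t", index=False)

    _stage("assembly_processes")
    turnover = proc.pairwise_turnover(table, tree, metadata, config.null)
    turnover.to_csv(out / "pairwise_turnover.tsv", sep="\t", index=False)
    profile = proc.process_profile(turnover)
    profile.to_csv(out / "process_profile.tsv", sep="\t")

    _stage("selection_strength")
    sel_rows = []
    for stage in sorted({md.loc[s, "stage"] for s in gut_ids}):
        r = proc.selection_strength(gut, metadata, stage, config.null)
        sel_rows.append(dataclasses.asdict(r))
    selection = pd.DataFrame(sel_rows)
    selection.to_csv(out / "selection_strength.tsv", sep="\t", index=False)

    _stage("community_stats")
    perm_rows, mantel_rows = [], []
    stages = sorted({md.loc[s, "stage"] for s in gut_ids})
    for metric, dm in beta.items():
        for s1, s2 in [(a, b) for i, a in enumerate(stages) for b in stages[i + 1 :]]:
            ids = [s for s in gut_ids if md.loc[s, "stage"] in (s1, s2)]
            sub = dm.filter(ids)
            res = st.permanova(sub, md.loc[ids, "stage"], n_perm=config.null.n_null,
                               seed=config.seed, factor=f"{s1}_vs_{s2}")
            perm_rows.append(dict(metric=metric, contrast=res.factor, pseudo_F=res.pseudo_F,
                                  p_value=res.p_value, n_perm=res.n_perm))
        stage_dm = factor_distance(metadata, dm.ids, "stage")
        res = st.mantel(dm, stage_dm, n_perm=config.null.n_null, seed=config.seed)
        mantel_rows.append(dict(metric=metric, test="r(MS)", r=res.statistic, p=res.p_value))
        for fac, tag in (("rear_env", "E"), ("transition", "T"), ("food", "F")):
            ctrl = factor_distance(metadata, dm.ids, fac)
            res = st.partial_mantel(dm, stage_dm, ctrl, n_perm=config.null.n_null,
                                    seed=config.seed, controlled=fac)
            mantel_rows.append(dict(metric=metric, test=f"r(MS.{tag})", r=res.statistic,
                                    p=res.p_value))
    permanova_df = pd.DataFrame(perm_rows)
    mantel_df = pd.DataFrame(mantel_rows)
    permanova_df.to_csv(out / "permanova.tsv", sep="\t", index=False)
    mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)

    _stage("report")
    cfg = {
        "seed": config.seed,
        "rarefaction_depth": config.rarefaction_depth,
        "n_null": config.null.n_null,
        "bnti_threshold": config.null.bnti_threshold,
        "rc_threshold": config.null.rc_threshold,
        "simulated": config.simulation is not None,
    }
    summary = {
        "config": cfg,
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
        "process_profile": profile.to_dict(),
        "partitions": part_rows,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return RunReport(
        process_profile=profile,
        partitions=partitions,
        permanova=permanova_df,
        mantel=mantel_df,
        selection=selection,
        alpha=alpha,
        out_dir=out,
        config=cfg,
    )
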