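"""Distance-based and variance-partitioning statistics on a simulated study.

PERMANOVA contrasts of developmental stages, Mantel and partial Mantel tests
of stage against community distance, and hierarchical partitioning of
alpha-diversity variance across stage / environment / transition / food.
"""

from guteco import SimulationConfig, alpha_diversity, mantel, partial_mantel, permanova, simulate_study
from guteco.diversity import beta_distance
from guteco.pipeline import factor_distance
from guteco.stats import variance_partition

cfg = SimulationConfig(n_otus=400, dph_schedule=(12, 20, 27, 42, 56, 98),
                       replicates=1, depth=800, seed=3)
study = simulate_study(cfg)
md = study.metadata.set_index("sample_id")
gut_ids = sorted(s for s in study.table.sample_ids if md.loc[s, "habitat"] == "gut")
gut = study.table.select_samples(gut_ids)

dm = beta_distance(gut, "bray_curtis")
stages = [md.loc[s, "stage"] for s in gut_ids]
res = permanova(dm, stages, n_perm=999, seed=0)
print(f"PERMANOVA (stage, Bray-Curtis): pseudo-F={res.pseudo_F:.1f} p={res.p_value:.3f}")

stage_dm = factor_distance(study.metadata, dm.ids, "stage")
rm = mantel(dm, stage_dm, n_perm=999, seed=0)
print(f"Mantel r(community, stage) = {rm.statistic:.2f}, p = {rm.p_value:.3f}")
for factor, tag in [("rear_env", "E"), ("transition", "T"), ("food", "F")]:
    ctrl = factor_distance(study.metadata, dm.ids, factor)
    rp = partial_mantel(dm, stage_dm, ctrl, n_perm=499, seed=0, controlled=factor)
    print(f"partial Mantel r(MS.{tag}) = {rp.statistic:.2f}, p = {rp.p_value:.3f}")

alpha = alpha_diversity(gut).loc[gut_ids]
vp = variance_partition(alpha, study.metadata, responses=("richness", "shannon"))
print("\nhierarchical partitioning of richness variance (% of explained):")
print(vp["richness"].round(3))
print(
    "\nStage carries the largest independent contribution: development drives"
    "\nalpha diversity. Transferred cages also carry a residual signal - their"
    "\ncommunities blend hatching- and rearing-pool taxa and are a bit richer."
)
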