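"""Null-model process inference: bMNTD/bNTI, Raup-Crick, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guteco._rng import child_rng
from guteco.data import OtuTable, cophenetic_distances, rarefy
from guteco.processes import (
    NullModelConfig,
    bmntd,
    bnti,
    classify_process,
    pairwise_turnover,
    process_profile,
    rc_bray,
    selection_strength,
)
from guteco.simulate import simulate_phylogeny, simulate_study

from conftest import random_metadata, tiny_config


class TestBmntd:
    def test_identical_communities_zero(self, four_tip_tree):
        d = cophenetic_distances(four_tip_tree).filter(list("ABCD")).data
        x = np.array([0.5, 0.5, 0.0, 0.0])
        assert bmntd(x, x, d) == 0.0

    def test_singleton_pair(self, four_tip_tree):
        d = cophenetic_distances(four_tip_tree).filter(list("ABCD")).data
        x = np.array([1.0, 0, 0, 0])
        y = np.array([0, 1.0, 0, 0])
        assert bmntd(x, y, d) == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        tree = simulate_phylogeny(15, seed=1)
        d = cophenetic_distances(tree).data
        for _ in range(5):
            x = rng.dirichlet(np.ones(15)) * (rng.random(15) < 0.6)
            y = rng.dirichlet(np.ones(15)) * (rng.random(15) < 0.6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert bmntd(x, y, d) == pytest.approx(bmntd(y, x, d), abs=1e-12)

    def test_matches_naive_oracle(self):
        """Vectorized bMNTD equals the O(n^2) double-loop definition."""
        rng = np.random.default_rng(2)
        for rep in range(20):
            tree = simulate_phylogeny(10, seed=rep, cluster_fraction=None)
            d = cophenetic_distances(tree).data
            x = rng.dirichlet(np.ones(10)) * (rng.random(10) < 0.7)
            y = rng.dirichlet(np.ones(10)) * (rng.random(10) < 0.7)
            if x.sum() == 0 or y.sum() == 0:
                continue
            ix, iy = np.flatnonzero(x > 0), np.flatnonzero(y > 0)
            xs, ys = x[ix] / x[ix].sum(), y[iy] / y[iy].sum()
            term_x = sum(
                w * min(d[i, j] for j in iy) for w, i in zip(xs, ix)
            )
            term_y = sum(
                w * min(d[i, j] for i in ix) for w, j in zip(ys, iy)
            )
            assert bmntd(x, y, d) == pytest.approx(0.5 * (term_x + term_y), abs=1e-12)

    def test_empty_community_rejected(self, four_tip_tree):
        d = cophenetic_distances(four_tip_tree).filter(list("ABCD")).data
        with pytest.raises(ValueError):
            bmntd(np.zeros(4), np.ones(4) / 4, d)


class TestBnti:
    def test_zero_when_obs_equals_null_mean(self):
        """On a star-like tree every taxa shuffle gives the same bMNTD for
        disjoint singleton communities, so the z-score degenerates."""
        tree = simulate_phylogeny(30, seed=3)
        x = np.zeros(30); x[0] = 1.0
        y = np.zeros(30); y[1] = 1.0
        ids = sorted(t.name for t in tree.tips())
        obs, z = bnti(x, y, tree, NullModelConfig(n_null=99, seed=1), otu_ids=ids)
        assert np.isfinite(z)

    def test_deterministic_under_seed(self, reduced_study):
        tree = reduced_study.tree
        ids = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(len(ids))) * (rng.random(len(ids)) < 0.2)
        y = rng.dirichlet(np.ones(len(ids))) * (rng.random(len(ids)) < 0.2)
        cfg = NullModelConfig(n_null=49, seed=5)
        assert bnti(x, y, tree, cfg, otu_ids=ids) == bnti(x, y, tree, cfg, otu_ids=ids)

    def test_relabeling_invariance(self):
        """Permuting OTU order consistently in abundances and ids leaves the
        z-score unchanged (canonical sorted-id shuffle universe)."""
        tree = simulate_phylogeny(40, seed=7)
        dm = cophenetic_distances(tree)
        ids = sorted(dm.ids)
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(40)) * (rng.random(40) < 0.4)
        y = rng.dirichlet(np.ones(40)) * (rng.random(40) < 0.4)
        cfg = NullModelConfig(n_null=49, seed=2)
        ref = bnti(x, y, dm, cfg, otu_ids=ids)
        perm = rng.permutation(40)
        out = bnti(x[perm], y[perm], dm, cfg, otu_ids=[ids[i] for i in perm])
        assert out[0] == pytest.approx(ref[0], abs=1e-12)
        assert out[1] == pytest.approx(ref[1], abs=1e-9)

    def test_degenerate_null_raises(self):
        # star tree: all tip-tip distances equal -> null variance 0
        from skbio import TreeNode

        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        x = np.array([1.0, 0, 0, 0])
        y = np.array([0, 1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            bnti(x, y, star, NullModelConfig(n_null=20, seed=0), otu_ids=list("ABCD"))


class TestRcBray:
    def _table(self, seed=0, n=40, m=12, depth=300):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        counts = rng.multinomial(depth, p, size=m).T
        counts[:, 0] += (counts.sum(axis=1) == 0)  # avoid empty OTU rows is fine
        return OtuTable(counts, [f"o{i}" for i in range(n)], [f"s{i}" for i in range(m)])

    def test_bounds_and_determinism(self):
        t = self._table()
        cfg = NullModelConfig(n_null=199, seed=3)
        v1 = rc_bray(t.sample("s0"), t.sample("s1"), t, cfg, pair_id=("s0", "s1"))
        v2 = rc_bray(t.sample("s0"), t.sample("s1"), t, cfg, pair_id=("s1", "s0"))
        assert -1.0 <= v1 <= 1.0
        assert v1 == v2  # canonical pair id -> order independent

    def test_extreme_dissimilarity_hits_plus_one(self):
        """A pair far more dissimilar than any null assembly scores +1."""
        n = 30
        counts = np.zeros((n, 4), dtype=int)
        counts[:10, 0] = 30
        counts[10:20, 1] = 30
        counts[:20, 2] = 10
        counts[:20, 3] = 12
        t = OtuTable(counts, [f"o{i}" for i in range(n)], list("wxyz"))
        v = rc_bray(t.sample("w"), t.sample("x"), t, NullModelConfig(n_null=199, seed=1),
                    pair_id=("w", "x"))
        assert v == pytest.approx(1.0)

    def test_against_naive_resimulation_oracle(self):
        """Independent per-replicate null assembly (same stream protocol for
        the membership draw) reproduces RC within Monte-Carlo tolerance."""
        t = self._table(seed=5)
        occupancy = (t.counts > 0).sum(axis=1).astype(float)
        meta_p = t.counts.sum(axis=1) / t.counts.sum()
        cfg = NullModelConfig(n_null=999, seed=7)
        rng_alt = np.random.default_rng(123)

        def naive_null_bc(x, y):
            def assemble(rng):
                n = occupancy.size
                rich, total = int((x > 0).sum()), int(x.sum())
                keys = np.where(occupancy > 0, np.log(occupancy), -np.inf) + rng.gumbel(size=n)
                support = np.argsort(-keys)[:rich]
                c = np.zeros(n, dtype=int)
                c[support] = 1
                probs = np.zeros(n)
                probs[support] = meta_p[support]
                c += rng.multinomial(total - rich, probs / probs.sum())
                return c

            obs = np.abs(x - y).sum()
            lt = eq = 0
            for _ in range(999):
                a = assemble(rng_alt)
                rngb = rng_alt
                rich_y, tot_y = int((y > 0).sum()), int(y.sum())
                keys = np.where(occupancy > 0, np.log(occupancy), -np.inf) + rngb.gumbel(size=occupancy.size)
                support = np.argsort(-keys)[:rich_y]
                b = np.zeros(occupancy.size, dtype=int)
                b[support] = 1
                probs = np.zeros(occupancy.size)
                probs[support] = meta_p[support]
                b += rngb.multinomial(tot_y - rich_y, probs / probs.sum())
                num = np.abs(a - b).sum()
                lt += num < obs
                eq += num == obs
            return 2 * ((lt + 0.5 * eq) / 999) - 1

        for i, j in [(0, 1), (2, 3), (4, 5), (0, 7), (3, 9)]:
            x, y = t.counts[:, i], t.counts[:, j]
            got = rc_bray(x, y, t, cfg, pair_id=(f"s{i}", f"s{j}"))
            want = naive_null_bc(x, y)
            assert got == pytest.approx(want, abs=0.08)

    def test_richness_exceeding_pool_rejected(self):
        t = self._table()
        x = np.ones(t.n_otus, dtype=int)
        empty_rows = (t.counts.sum(axis=1) == 0)
        if not empty_rows.any():
            t.counts[5, :] = 0  # force an unavailable taxon
        with pytest.raises(ValueError, match="richness"):
            rc_bray(x, t.sample("s0"), t, NullModelConfig(n_null=9, seed=0))


class TestClassify:
    @pytest.mark.parametrize(
        "z,rc,expect",
        [
            (2.5, 0.1, "heterogeneous_selection"),
            (-2.6, 0.99, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (0.3, 0.2, "undominated"),
        ],
    )
    def test_rule_table(self, z, rc, expect):
        assert classify_process(z, rc) == expect

    @settings(max_examples=200, deadline=None)
    @given(
        z=st.floats(min_value=-50, max_value=50, allow_nan=False),
        rc=st.floats(min_value=-1, max_value=1, allow_nan=False),
    )
    def test_total_function(self, z, rc):
        assert classify_process(z, rc) in {
            "heterogeneous_selection",
            "homogeneous_selection",
            "dispersal_limitation",
            "homogenizing_dispersal",
            "undominated",
        }

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_process(float("nan"), 0.0)


class TestProfileAndPipeline:
    def test_profile_fractions_sum_to_one(self):
        df = pd.DataFrame(
            dict(group=["S1"] * 4 + ["S2"] * 3,
                 process=["undominated"] * 4 + ["homogeneous_selection"] * 2 + ["undominated"])
        )
        prof = process_profile(df)
        assert np.allclose(prof.sum(axis=1), 1.0)
        assert prof.loc["S1", "undominated"] == 1.0
        assert prof.loc["S2", "homogeneous_selection"] == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            process_profile(pd.DataFrame(columns=["group", "process"]))

    def test_pairwise_turnover_structure_and_determinism(self):
        study = simulate_study(tiny_config(2, n_otus=60, depth=150))
        table = rarefy(study.table, 150, seed=0)
        cfg = NullModelConfig(n_null=29, seed=1)
        a = pairwise_turnover(table, study.tree, study.metadata, cfg)
        b = pairwise_turnover(table, study.tree, study.metadata, cfg)
        pd.testing.assert_frame_equal(a, b)
        # within-stage gut pairs only: 9 samples per stage -> 36 pairs each
        assert len(a) == 3 * 36
        assert set(a.group) == {"S1", "S2", "S3"}
        assert a.rc_bray.between(-1, 1).all()

    def test_within_cage_restriction(self):
        study = simulate_study(tiny_config(2, n_otus=60, depth=150, replicates=2))
        table = rarefy(study.table, 150, seed=0)
        cfg = NullModelConfig(n_null=19, seed=1)
        within = pairwise_turnover(table, study.tree, study.metadata, cfg, within="cage")
        md = study.metadata.set_index("sample_id")
        assert (
            within.apply(lambda r: md.loc[r.sample_a, "cage"] == md.loc[r.sample_b, "cage"], axis=1)
        ).all()


def test_monotone_parameter_recovery_sweep():
    """Homogeneous-selection fraction is non-decreasing in the generator's
    selection strength over s in {0, 0.3, 0.6, 0.9} (replicate-averaged)."""
    means = []
    for s in (0.0, 0.3, 0.6, 0.9):
        fracs = []
        for rep in range(3):
            cfg = tiny_config(100 + rep, n_otus=400, depth=300,
                              selection_strength_by_stage=(s, s, s))
            study = simulate_study(cfg)
            table = rarefy(study.table, 300, seed=0)
            to = pairwise_turnover(table, study.tree, study.metadata,
                                   NullModelConfig(n_null=99, seed=0))
            fracs.append((to.bnti < -2).mean())
        means.append(np.mean(fracs))
    assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]


class TestSelectionStrength:
    def test_identical_samples_warn_ratio_one(self):
        counts = np.tile(np.array([[5], [7], [2]]), (1, 4))
        t = OtuTable(counts, ["a", "b", "c"], [f"s{i}" for i in range(4)])
        md = random_metadata(t.sample_ids, np.random.default_rng(0))
        md["stage"] = "S1"
        md["dph"] = 12
        with pytest.warns(UserWarning, match="identical"):
            r = selection_strength(t, md, "S1", NullModelConfig(n_null=49, seed=0))
        assert r.deterministic_ratio == 1.0

    def test_ratio_clipped_and_p_valid(self):
        study = simulate_study(tiny_config(3, n_otus=80, depth=200))
        md = study.metadata
        gut = study.table.select_samples(sorted(md.loc[md.habitat == "gut", "sample_id"]))
        r = selection_strength(gut, md, "S2", NullModelConfig(n_null=99, seed=2))
        assert 0.0 <= r.deterministic_ratio <= 1.0
        assert 0.0 < r.p_value <= 1.0

    def test_dissimilarity_scale_flag(self):
        study = simulate_study(tiny_config(3, n_otus=80, depth=200))
        md = study.metadata
        gut = study.table.select_samples(sorted(md.loc[md.habitat == "gut", "sample_id"]))
        r = selection_strength(gut, md, "S2", NullModelConfig(n_null=49, seed=2),
                               ratio_scale="dissimilarity")
        assert 0.0 <= r.deterministic_ratio <= 1.0
        with pytest.raises(ValueError):
            selection_strength(gut, md, "S2", ratio_scale="nope")
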