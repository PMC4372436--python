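"""Faith's PD, MPD/MNTD, and the sample.pool SES."""

import numpy as np
import pandas as pd
import pytest
from helpers import mntd_oracle, mpd_oracle, pd_oracle, random_tree

from phylodiv import (
    ScenarioSpec,
    alpha_table,
    assemble_communities,
    faith_pd,
    mntd,
    mpd,
    parse_newick,
    ses,
    simulate_bd_tree,
)
from phylodiv.alpha import records_to_frame
from phylodiv.community import CommunityMatrix


class TestFaithPD:
    def test_full_set_equals_total_branch_length(self):
        t = random_tree(0)
        assert faith_pd(t, t.leaf_labels) == pytest.approx(t.total_branch_length())

    def test_single_taxon_is_root_path(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert faith_pd(t, {"A"}) == pytest.approx(2.0)

    def test_star_tree_pair(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert faith_pd(t, {"A", "B"}) == pytest.approx(2.0)

    def test_unrooted_variant_excludes_root_path(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert faith_pd(t, {"A", "B"}, rooted=False) == pytest.approx(2.0)
        assert faith_pd(t, {"A", "B"}, rooted=True) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_in_taxa(self, seed):
        t = random_tree(seed)
        rng = np.random.default_rng(seed)
        labels = t.leaf_labels
        k = int(rng.integers(1, t.n_leaves))
        subset = set(rng.choice(labels, size=k, replace=False))
        extra = rng.choice([l for l in labels if l not in subset])
        assert faith_pd(t, subset | {extra}) >= faith_pd(t, subset) - 1e-12

    def test_matches_skbio(self):
        import skbio.diversity

        t = random_tree(77, ultrametric=True)
        sk_tree = skbio.TreeNode.read([t.to_newick()])
        taxa = t.leaf_labels[: t.n_leaves // 2 + 1]
        counts = [1 if l in taxa else 0 for l in t.leaf_labels]
        expect = skbio.diversity.alpha.faith_pd(
            counts, taxa=t.leaf_labels, tree=sk_tree
        )
        assert faith_pd(t, taxa) == pytest.approx(expect)


class TestMPDMNTD:
    def test_pair_is_their_distance(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        d = t.patristic_distances()
        assert mpd(d, {"A", "C"}) == pytest.approx(4.0)
        assert mntd(d, {"A", "C"}) == pytest.approx(4.0)

    def test_star_tree_all_pairs_equal(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        d = t.patristic_distances()
        assert mpd(d, t.leaf_labels) == pytest.approx(2.0)

    def test_cherry_plus_outgroup_mntd_below_mpd(self):
        t = parse_newick("((A:1,B:1):3,C:4);")
        d = t.patristic_distances()
        # MPD = (2 + 8 + 8)/3 = 6; MNTD = (2 + 2 + 8)/3 = 4
        assert mpd(d, {"A", "B", "C"}) == pytest.approx(6.0)
        assert mntd(d, {"A", "B", "C"}) == pytest.approx(4.0)

    def test_singleton_returns_missing(self):
        t = parse_newick("(A:1,B:1);")
        d = t.patristic_distances()
        assert mpd(d, {"A"}) is None
        assert mntd(d, {"A"}) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        t = random_tree(seed + 200, n_min=5)
        d = t.patristic_distances()
        rng = np.random.default_rng(seed)
        taxa = set(rng.choice(t.leaf_labels, size=4, replace=False))
        assert mpd(d, taxa) == pytest.approx(mpd_oracle(t, taxa))
        assert mntd(d, taxa) == pytest.approx(mntd_oracle(t, taxa))


@pytest.fixture(scope="module")
def tree():
    return simulate_bd_tree(40, seed=11)


class TestSES:
    def test_degenerate_when_site_is_pool(self, tree):
        d = tree.patristic_distances()
        pool = tree.leaf_labels
        res = ses("MPD", d, pool, pool, n_rand=99, seed=0)
        assert res.degenerate and res.z is None
        assert res.null_sd == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_under_seed(self, tree):
        d = tree.patristic_distances()
        pool = tree.leaf_labels
        a = ses("MPD", d, pool[:10], pool, n_rand=199, seed=5)
        b = ses("MPD", d, pool[:10], pool, n_rand=199, seed=5)
        assert a == b
        c = ses("MPD", d, pool[:10], pool, n_rand=199, seed=6)
        assert a.null_mean != c.null_mean

    def test_z_matches_definition(self, tree):
        d = tree.patristic_distances()
        pool = tree.leaf_labels
        r = ses("MNTD", d, pool[:8], pool, n_rand=199, seed=1)
        assert r.z == pytest.approx((r.observed - r.null_mean) / r.null_sd)
        assert 1 / (r.n_rand + 1) <= r.p_rank <= 1

    def test_scenario_signs(self, tree):
        # strong assembly kernels must push z(MPD) in the expected direction
        d = tree.patristic_distances()
        pool = tree.leaf_labels
        for scenario, sign in (("clustered", -1), ("overdispersed", 1)):
            cm = assemble_communities(
                tree, 12, ScenarioSpec(scenario, 10, strength=10.0, seed=3)
            )
            zs = [
                ses("MPD", d, cm.site_taxa(s), pool, n_rand=199, seed=i).z
                for i, s in enumerate(cm.sites)
            ]
            assert np.sign(np.mean(zs)) == sign

    def test_rejects_tiny_site_or_foreign_taxa(self, tree):
        d = tree.patristic_distances()
        pool = tree.leaf_labels
        with pytest.raises(ValueError, match="richness"):
            ses("MPD", d, pool[:1], pool, n_rand=99)
        with pytest.raises(ValueError, match="outside"):
            ses("MPD", d, {"t1", "nope"}, pool[:5], n_rand=99)


class TestAlphaTable:
    def test_single_site_covering_pool(self):
        tree = simulate_bd_tree(12, seed=2)
        table = pd.DataFrame(
            [[1] * 12], index=["only"], columns=tree.leaf_labels
        )
        records = alpha_table(tree, CommunityMatrix(table), n_rand=99, seed=0)
        by_site = {r.site: r for r in records}
        assert by_site["only"].pd == pytest.approx(tree.total_branch_length())
        assert by_site["Total"].pd == pytest.approx(tree.total_branch_length())
        assert by_site["Total"].nri is None

    def test_columns_internally_consistent(self):
        tree = simulate_bd_tree(30, seed=4)
        cm = assemble_communities(tree, 5, ScenarioSpec("random", (5, 15), seed=4))
        from phylodiv import TaxonomyMap, family_rollup, richness

        tax = TaxonomyMap({t: f"F{int(t[1:]) % 6}" for t in tree.leaf_labels})
        records = alpha_table(tree, cm, tax, n_rand=99, seed=9)
        frame = records_to_frame(records).drop(index="Total")
        assert frame["sr"].to_dict() == richness(cm).to_dict()
        fam, _ = family_rollup(cm, tax)
        assert frame["fam"].to_dict() == fam.to_dict()
        assert (frame["fam"] <= frame["sr"]).all()
        # PD never exceeds the whole tree
        assert (frame["pd"] <= tree.total_branch_length() + 1e-9).all()


@pytest.mark.parametrize("seed", range(10))
def test_pd_oracle_cross_check(seed):
    t = random_tree(seed + 300)
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, t.n_leaves + 1))
    taxa = set(rng.choice(t.leaf_labels, size=k, replace=False))
    assert faith_pd(t, taxa) == pytest.approx(pd_oracle(t, taxa))
    if len(taxa) >= 2:
        assert faith_pd(t, taxa, rooted=False) == pytest.approx(
            pd_oracle(t, taxa, rooted=False)
        )
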