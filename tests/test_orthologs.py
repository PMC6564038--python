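"""Ortholog categories, expansion flags, species-specific sets, tandem runs."""

import numpy as np
import pytest

from tetlrr import orthologs
from tetlrr.io import OrthologClusters


def make_clusters(spec, extra_universe=None):
    """spec: {cluster_id: {species: n_genes}} with auto-generated gene ids."""
    clusters, universe = {}, {}
    for cid, by_sp in spec.items():
        clusters[cid] = {}
        for sp, n in by_sp.items():
            genes = [f"{sp}_{cid}_{i}" for i in range(n)]
            clusters[cid][sp] = genes
            universe.setdefault(sp, set()).update(genes)
    for sp, extra in (extra_universe or {}).items():
        universe.setdefault(sp, set()).update(extra)
    return OrthologClusters(clusters, universe)


class TestCategorize:
    def test_category_counts_species(self):
        oc = make_clusters(
            {
                "c3": {"A": 1, "B": 1, "C": 1},
                "c1": {"A": 5},
                "cX": {s: 1 for s in "ABCDEFGHIJ"},
            }
        )
        df = orthologs.categorize(oc)
        assert df.loc["c3", "category"] == 3
        assert df.loc["c1", "category"] == 1
        assert df.loc["cX", "category"] == 10
        assert df.loc["cX", "category_roman"] == "X"

    def test_stress_fixture_spans_all_categories(self, stress_bundle):
        oc = stress_bundle.load_clusters()
        df = orthologs.categorize(oc)
        assert set(df["category"]) >= set(range(1, 11))


class TestExpansionTest:
    def test_dominant_species_flagged(self):
        oc = make_clusters({"exp": {"A": 61, "B": 1, "C": 1}})
        calls = orthologs.expansion_test(oc)
        flagged = {c.species for c in calls if c.flagged}
        assert flagged == {"A"}

    def test_uniform_counts_not_flagged(self):
        oc = make_clusters({"c": {"A": 2, "B": 2, "C": 2}})
        assert not any(c.flagged for c in orthologs.expansion_test(oc))

    def test_29_gene_expansion_flagged(self):
        oc = make_clusters({"exp": {s: 1 for s in "BCDEFGHIJ"} | {"A": 29}})
        calls = orthologs.expansion_test(oc)
        assert {c.species for c in calls if c.flagged} == {"A"}

    def test_small_clusters_skipped(self):
        oc = make_clusters({"c": {"A": 3, "B": 1}})
        assert orthologs.expansion_test(oc) == []

    def test_type_one_error_controlled_under_uniform_null(self):
        """On multinomial-uniform clusters the per-cluster family-wise flag
        rate stays at or below alpha."""
        rng = np.random.default_rng(0)
        S, N, n_clusters, alpha = 10, 20, 10_000, 0.01
        counts = rng.multinomial(N, [1 / S] * S, size=n_clusters)
        from scipy.stats import binom

        p_raw = binom.sf(counts - 1, N, 1 / S)
        flagged_any = (np.minimum(1.0, p_raw * S) < alpha).any(axis=1)
        assert flagged_any.mean() <= alpha


class TestSpeciesSpecific:
    def test_union_of_routes(self):
        oc = make_clusters(
            {
                "cat1": {"A": 3},
                "exp": {"A": 61, "B": 1, "C": 1},
                "cons": {"A": 1, "B": 1, "C": 1},
            },
            extra_universe={"A": {"lonely1", "lonely2"}},
        )
        calls = orthologs.expansion_test(oc)
        specific = orthologs.species_specific_genes(oc, calls, "A")
        assert len(specific) == 2 + 3 + 61

    def test_conserved_only_species_empty(self):
        oc = make_clusters({"cons": {"A": 1, "B": 1, "C": 1}})
        assert orthologs.species_specific_genes(oc, [], "B") == set()

    def test_specific_and_conserved_partition_universe(self, default_bundle):
        oc = default_bundle.load_clusters()
        calls = orthologs.expansion_test(oc)
        for sp in oc.species:
            specific = orthologs.species_specific_genes(oc, calls, sp)
            assert specific <= oc.universe[sp]


class TestTandem:
    def test_strict_and_relaxed_linkage(self):
        order = {"s1": ["a1", "a2", "b", "a3"]}
        cmap = {"a1": "c1", "a2": "c1", "a3": "c1", "b": "c2"}
        strict = orthologs.tandem_clusters(order, cmap, max_gap=0)
        assert [t.members for t in strict] == [("a1", "a2")]
        relaxed = orthologs.tandem_clusters(order, cmap, max_gap=3)
        assert [t.members for t in relaxed] == [("a1", "a2", "a3")]

    def test_long_strict_run(self):
        members = [f"g{i}" for i in range(17)]
        order = {"s1": members}
        cmap = {g: "c1" for g in members}
        (group,) = orthologs.tandem_clusters(order, cmap, max_gap=0)
        assert len(group.members) == 17

    def test_singletons_link_to_singletons(self):
        order = {"s1": ["x", "y", "z"]}
        cmap = {"x": None, "y": None, "z": "c1"}
        (group,) = orthologs.tandem_clusters(order, cmap, max_gap=0)
        assert group.members == ("x", "y") and group.label == "__singleton__"

    def test_missing_gene_raises(self):
        with pytest.raises(ValueError, match="missing"):
            orthologs.tandem_clusters({"s1": ["a"]}, {}, 0)

    def test_strict_groups_are_contiguous_intervals(self, toy_bundle):
        oc = toy_bundle.load_clusters()
        cmap = oc.gene_to_cluster()
        order = {}
        for sp in toy_bundle.species_names:
            for g in sorted(toy_bundle.load_genes(sp), key=lambda g: (g.scaffold, g.span[0])):
                order.setdefault(g.scaffold, []).append(g.gene_id)
        full = {g: cmap.get(g) for gs in order.values() for g in gs}
        for t in orthologs.tandem_clusters(order, full, max_gap=0):
            idx = [order[t.scaffold].index(m) for m in t.members]
            assert idx == list(range(idx[0], idx[0] + len(idx)))


class TestPercentTandem:
    def test_percentages(self):
        oc = make_clusters({"c1": {"A": 10}, "cX": {s: 1 for s in "ABCDEFGHIJ"}})
        cats = orthologs.categorize(oc)
        members = oc.clusters["c1"]["A"]
        groups = [orthologs.TandemGroup("s1", "c1", tuple(members[:4]))]
        pct = orthologs.percent_tandem_by_category(cats, oc, groups)
        assert pct[1] == pytest.approx(40.0)
        assert pct[10] == pytest.approx(0.0)

    def test_no_tandem_groups(self):
        oc = make_clusters({"c1": {"A": 10}, "c2": {"A": 1, "B": 1}})
        cats = orthologs.categorize(oc)
        pct = orthologs.percent_tandem_by_category(cats, oc, [])
        assert pct == {1: 0.0, 2: 0.0}
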