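"""IES-omitted coordinates, binning, region labels and association tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetlrr import landscape as lsc
from tetlrr.io import GeneModel


def simple_scape(length=30_000_000, ies=None, centromere=None):
    ies = ies if ies is not None else []
    centromere = centromere or (length // 2 - 1000, length // 2 + 1000)
    return lsc.ChromosomeLandscape({"c1": length}, {"c1": centromere}, {"c1": ies})


class TestMdsCoordinate:
    def test_subtracts_upstream_ies(self):
        s = simple_scape(100, ies=[(10, 20)], centromere=(40, 60))
        assert s.mds_coordinate("c1", 25) == (15, False)
        assert s.mds_coordinate("c1", 5) == (5, False)

    def test_inside_ies_collapses_left(self):
        s = simple_scape(100, ies=[(10, 20)], centromere=(40, 60))
        assert s.mds_coordinate("c1", 15) == (10, True)

    def test_out_of_bounds_raises(self):
        s = simple_scape(100, ies=[], centromere=(40, 60))
        with pytest.raises(ValueError):
            s.mds_coordinate("c1", 101)

    def test_mds_length_conservation(self):
        ies = [(100, 300), (1000, 1500), (4000, 4100)]
        s = simple_scape(10_000, ies=ies, centromere=(5000, 5200))
        assert s.mds_length("c1") == 10_000 - sum(e - b for b, e in ies)

    @given(st.integers(0, 9_999))
    @settings(deadline=None, derandomize=True)
    def test_mds_is_nondecreasing(self, pos):
        ies = [(100, 300), (1000, 1500), (4000, 4100)]
        s = simple_scape(10_000, ies=ies, centromere=(5000, 5200))
        a, _ = s.mds_coordinate("c1", pos)
        b, _ = s.mds_coordinate("c1", pos + 1)
        assert b >= a

    def test_overlapping_ies_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simple_scape(1000, ies=[(10, 50), (40, 80)], centromere=(100, 200))


class TestRegions:
    scape = simple_scape(20_000_000, centromere=(9_990_000, 10_010_000))

    def test_pericentromeric(self):
        assert lsc.region_of(self.scape, "c1", 9_500_000) == "pericentromeric"

    def test_subtelomeric(self):
        assert lsc.region_of(self.scape, "c1", 400_000) == "subtelomeric"
        assert lsc.region_of(self.scape, "c1", 19_500_000) == "subtelomeric"

    def test_arm(self):
        assert lsc.region_of(self.scape, "c1", 5_000_000) == "arm"

    def test_labels_partition_chromosome(self):
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, 20_000_000, size=500):
            assert lsc.region_of(self.scape, "c1", int(pos)) in lsc.REGIONS

    def test_region_bed_tiles_mds(self):
        bed = lsc.region_bed(self.scape)["c1"]
        assert bed[0][0] == 0
        assert bed[-1][1] >= self.scape.mds_length("c1")
        for (s1, e1, _), (s2, e2, _) in zip(bed, bed[1:]):
            assert e1 == s2


class TestBinValues:
    scape = simple_scape(2_000_000, centromere=(900_000, 1_100_000))

    def test_counts(self):
        items = [("c1", 100_000, None), ("c1", 200_000, None), ("c1", 1_500_000, None)]
        track = lsc.bin_values(items, self.scape)
        assert list(track.values["c1"]) == [2.0, 1.0]

    def test_median(self):
        items = [("c1", 1, 0.1), ("c1", 2, 0.3), ("c1", 3, 0.9)]
        track = lsc.bin_values(items, self.scape, mode="median")
        assert track.values["c1"][0] == pytest.approx(0.3)

    def test_fraction(self):
        subset = [("c1", i, None) for i in range(5)]
        everyone = [("c1", i) for i in range(20)]
        track = lsc.bin_values(subset, self.scape, mode="fraction_of_bin_genes", all_items=everyone)
        assert track.values["c1"][0] == pytest.approx(0.25)

    def test_bin_counts_sum_to_mapped_genes(self):
        rng = np.random.default_rng(1)
        items = [("c1", int(p), None) for p in rng.integers(0, 2_000_000, size=300)]
        track = lsc.bin_values(items, self.scape)
        assert track.values["c1"].sum() == 300

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            lsc.bin_values([], self.scape, bin_width=0)


class TestEnrichment:
    def test_biased_placement_detected(self):
        rng = np.random.default_rng(2)
        scape = simple_scape(6_000_000, centromere=(2_990_000, 3_010_000))
        # background uniform; subset 5x denser in the pericentromeric region
        all_pos = rng.integers(0, 6_000_000, size=2000)
        w = np.where(np.abs(all_pos - 3_000_000) <= 1_000_000, 5.0, 1.0)
        subset_idx = rng.choice(len(all_pos), size=300, replace=False, p=w / w.sum())
        regions_all = [lsc.region_of(scape, "c1", int(p)) for p in all_pos]
        regions_sub = [regions_all[i] for i in subset_idx]
        _, p = lsc.region_enrichment(regions_sub, regions_all)
        assert p is not None and p < 0.01

    def test_degenerate_table_skipped(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = lsc.region_enrichment(["arm"] * 5, ["arm"] * 10)
        assert p is None

    def test_null_values_rarely_significant(self):
        rng = np.random.default_rng(3)
        n_sig = 0
        for _ in range(100):
            vals = {"arm": rng.normal(size=40), "pericentromeric": rng.normal(size=40)}
            p = lsc.value_comparison(vals)[("arm", "pericentromeric")]
            n_sig += p <= 0.05
        assert n_sig <= 10  # identical distributions: p > 0.05 in >= 90 of 100


class TestIesGeneAssociation:
    def _gene(self, gid, exons):
        return GeneModel(gid, "sp", "c1", "+", tuple(exons))

    def test_intronic_ies_flags_containing_gene(self):
        scape = simple_scape(10_000, ies=[(150, 250)], centromere=(5000, 5100))
        g = self._gene("g1", [(100, 130), (300, 360)])  # IES inside the intron
        ies_table, flags = lsc.ies_gene_association(scape, [g])
        assert ies_table.loc[0, "containing_gene"] == "g1"
        assert flags.set_index("gene_id").loc["g1", "flanked_by_ies"]

    def test_intergenic_ies_associates_both_neighbours(self):
        scape = simple_scape(10_000, ies=[(500, 600)], centromere=(5000, 5100))
        a = self._gene("a", [(100, 400)])
        b = self._gene("b", [(700, 1000)])
        ies_table, flags = lsc.ies_gene_association(scape, [a, b])
        row = ies_table.iloc[0]
        assert (row["nearest_left"], row["nearest_right"]) == ("a", "b")
        assert flags["flanked_by_ies"].all()

    def test_gene_without_adjacent_ies_not_flagged(self):
        scape = simple_scape(10_000, ies=[(500, 600)], centromere=(5000, 5100))
        a = self._gene("a", [(100, 400)])
        b = self._gene("b", [(700, 1000)])
        c = self._gene("c", [(8000, 8300)])  # no IES in the b..c gap or inside c
        _, flags = lsc.ies_gene_association(scape, [a, b, c])
        by_id = flags.set_index("gene_id")["flanked_by_ies"]
        assert by_id["a"] and by_id["b"] and not by_id["c"]
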