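"""Exon matrices, position profiles, logo tests and near-identity clustering."""

import numpy as np
import pandas as pd
import pytest

from tetlrr import profiles as prof
from tetlrr.io import GeneModel, Genome


def matrix_from_rows(rows, **meta):
    n = len(rows)
    md = pd.DataFrame(
        {
            "gene_id": meta.get("gene_id", [f"g{i}" for i in range(n)]),
            "species": meta.get("species", ["sp"] * n),
            "group": meta.get("group", ["III"] * n),
            "family": meta.get("family", ["CRS1"] * n),
            "exon_index": meta.get("exon_index", list(range(1, n + 1))),
        }
    )
    return prof.ExonMatrix(list(rows), md)


def _random_rows(rng, n, L=90):
    return ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]


class TestBuildMatrix:
    def _gene(self, gid, exon_lengths, seq_parts):
        exons, pos = [], 0
        for L in exon_lengths:
            exons.append((pos, pos + L))
            pos += L + 10
        return GeneModel(gid, "sp", "s1", "+", tuple(exons))

    def test_row_counts_are_additive(self):
        rng = np.random.default_rng(0)
        chrom = "".join(rng.choice(list("ACGT"), size=5000))
        genome = Genome("sp", {"s1": chrom})
        genes, pos = [], 0
        for gid, n90 in (("a", 2), ("b", 3), ("c", 5)):
            lengths = [90] * n90 + [12]  # 90-exons plus a non-target exon
            exons = []
            for L in lengths:
                exons.append((pos, pos + L))
                pos += L + 10
            genes.append(GeneModel(gid, "sp", "s1", "+", tuple(exons)))
        m = prof.build_exon_matrix(genes, {"sp": genome})
        assert len(m) == 10

    def test_filter_with_no_rows_raises(self):
        genome = Genome("sp", {"s1": "A" * 400})
        g = GeneModel("a", "sp", "s1", "+", ((0, 90), (100, 190), (200, 290)))
        with pytest.raises(ValueError, match="group"):
            prof.build_exon_matrix([g], {"sp": genome}, group_of={"a": "III"}, groups=("II",))

    def test_only_exact_length_rows_kept(self):
        genome = Genome("sp", {"s1": "ACGT" * 300})
        g = GeneModel("a", "sp", "s1", "+", ((0, 89), (100, 190), (200, 291)))
        m = prof.build_exon_matrix([g], {"sp": genome})
        assert len(m) == 1 and m.meta.loc[0, "exon_index"] == 2


class TestProfileConsensus:
    def test_consensus_of_identical_rows(self):
        rng = np.random.default_rng(1)
        row = _random_rows(rng, 1)[0]
        p = prof.position_profile(matrix_from_rows([row, row]), "nt")
        assert prof.consensus(p) == row
        assert np.allclose(p.freqs.sum(axis=0), 1.0)

    def test_tie_breaks_by_symbol_order(self):
        p = prof.position_profile(matrix_from_rows(["A" * 90, "C" * 90]), "nt")
        assert prof.consensus(p) == "A" * 90

    def test_uniform_frequencies_concentrate(self):
        rng = np.random.default_rng(2)
        m = matrix_from_rows(_random_rows(rng, 10_000))
        p = prof.position_profile(m, "nt")
        assert (np.abs(p.freqs.to_numpy() - 0.25) < 0.02).all()

    def test_profiles_normalize_aa(self):
        rng = np.random.default_rng(3)
        m = matrix_from_rows(_random_rows(rng, 50))
        p = prof.position_profile(m, "aa")
        assert p.freqs.shape[1] == 29
        assert np.allclose(p.freqs.sum(axis=0), 1.0)

    def test_consensus_idempotent_under_duplication(self):
        rng = np.random.default_rng(4)
        rows = _random_rows(rng, 20)
        m = matrix_from_rows(rows)
        c = prof.consensus(prof.position_profile(m, "nt"))
        m2 = matrix_from_rows(rows + [c, c, c])
        assert prof.consensus(prof.position_profile(m2, "nt")) == c


class TestCodonIndex:
    def test_leucine_centre_positions(self):
        assert prof.codon_index_of_nt(48) == 16
        assert prof.codon_index_of_nt(2) == 1
        assert [prof.codon_index_of_nt(c) for c in (36, 48, 66, 75, 81, 87)] == [12, 16, 22, 25, 27, 29]

    @pytest.mark.parametrize("pos", [1, 89, 90, 0, 91])
    def test_junction_positions_raise(self, pos):
        with pytest.raises(ValueError):
            prof.codon_index_of_nt(pos)


class TestConservedPositions:
    def test_all_leucine_matrix(self):
        m = matrix_from_rows(["A" + "TTA" * 29 + "TT"] * 10)
        p = prof.position_profile(m, "aa")
        assert prof.conserved_positions(p, "L", 0.5) == list(range(1, 30))

    def test_unreachable_threshold(self):
        m = matrix_from_rows(["A" + "TTA" * 29 + "TT"] * 10)
        p = prof.position_profile(m, "aa")
        assert prof.conserved_positions(p, "L", 1.01) == []


class TestTwoSampleLogo:
    def test_strong_enrichment_called(self):
        a_rows = ["A" * 90] * 100
        b_rows = ["A" * 90] * 50 + ["C" * 90] * 50
        calls = prof.two_sample_logo(matrix_from_rows(a_rows), matrix_from_rows(b_rows), "nt")
        enriched = calls[(calls["direction"] == "enriched") & (calls["symbol"] == "A")]
        assert len(enriched) == 90  # every column
        assert (enriched["p"] < 1e-5).all()

    def test_identical_samples_make_no_calls(self):
        rng = np.random.default_rng(5)
        rows = _random_rows(rng, 60)
        m = matrix_from_rows(rows)
        calls = prof.two_sample_logo(m, m, "nt")
        assert len(calls) == 0

    def test_swapping_samples_swaps_directions(self):
        a = matrix_from_rows(["A" * 90] * 100)
        b = matrix_from_rows(["C" * 90] * 100)
        ab = prof.two_sample_logo(a, b, "nt")
        ba = prof.two_sample_logo(b, a, "nt")
        key = lambda df: sorted(zip(df["position"], df["symbol"], df["direction"]))
        flipped = [
            (p, s, "enriched" if d == "depleted" else "depleted") for p, s, d in key(ba)
        ]
        assert key(ab) == sorted(flipped)

    def test_small_samples_warn(self):
        m = matrix_from_rows(["A" * 90] * 5)
        with pytest.warns(UserWarning, match="underpowered"):
            prof.two_sample_logo(m, m, "nt")


def brute_force_clusters(rows, max_mismatch):
    """All-pairs union-find oracle for near-identity clustering."""
    n = len(rows)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sum(a != b for a, b in zip(rows[i], rows[j])) <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: (-len(c), c[0]))


def _mutate_row(rng, row, k):
    row = list(row)
    for pos in rng.choice(len(row), size=k, replace=False):
        row[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[row[pos]]
    return "".join(row)


class TestNearIdenticalClustering:
    def test_pair_and_outlier(self):
        rng = np.random.default_rng(6)
        s = _random_rows(rng, 1)[0]
        s3 = _mutate_row(rng, s, 3)
        clusters = prof.cluster_near_identical(matrix_from_rows([s, s, s3]))
        assert clusters == [[0, 1], [2]]

    def test_single_linkage_chain(self):
        rng = np.random.default_rng(7)
        a = _random_rows(rng, 1)[0]
        b = _mutate_row(rng, a, 2)
        # mutate two *different* positions of b so d(a, c) = 4
        c = list(b)
        free = [i for i in range(90) if a[i] == b[i]]
        for pos in free[:2]:
            c[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[pos]]
        c = "".join(c)
        clusters = prof.cluster_near_identical(matrix_from_rows([a, b, c]))
        assert clusters == [[0, 1, 2]]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        base = _random_rows(rng, 12)
        rows = []
        for b in base:
            rows.append(b)
            for _ in range(rng.integers(0, 4)):
                rows.append(_mutate_row(rng, b, int(rng.integers(1, 4))))
        rows = rows[:50]
        assert prof.cluster_near_identical(matrix_from_rows(rows)) == brute_force_clusters(rows, 2)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        base = _random_rows(rng, 8)
        rows = base + [_mutate_row(rng, b, 2) for b in base]
        perm = list(rng.permutation(len(rows)))
        shuffled = [rows[i] for i in perm]
        orig = prof.cluster_near_identical(matrix_from_rows(rows))
        shuf = prof.cluster_near_identical(matrix_from_rows(shuffled))
        # compare as partitions of the row *contents*
        as_sets = lambda clusters, rr: sorted(sorted(rr[i] for i in c) for c in clusters)
        assert as_sets(orig, rows) == as_sets(shuf, shuffled)


class TestConsensusDistances:
    def test_identical_groups_distance_zero(self):
        rng = np.random.default_rng(10)
        rows = _random_rows(rng, 5)
        d = prof.family_consensus_distance_matrix({"a": matrix_from_rows(rows), "b": matrix_from_rows(rows)})
        assert d.loc["a", "b"] == 0.0

    def test_fractional_hamming(self):
        row = "A" * 90
        other = "C" * 9 + "A" * 81
        d = prof.family_consensus_distance_matrix(
            {"a": matrix_from_rows([row] * 3), "b": matrix_from_rows([other] * 3)}
        )
        assert d.loc["a", "b"] == pytest.approx(0.1)

    def test_symmetry_and_small_groups_excluded(self, tmp_path):
        rng = np.random.default_rng(11)
        mats = {
            "a": matrix_from_rows(_random_rows(rng, 4)),
            "b": matrix_from_rows(_random_rows(rng, 4)),
            "c": matrix_from_rows(_random_rows(rng, 4)),
            "tiny": matrix_from_rows(_random_rows(rng, 2)),
        }
        with pytest.warns(UserWarning, match="tiny"):
            d = prof.family_consensus_distance_matrix(mats)
        assert list(d.index) == ["a", "b", "c"]
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0)
        prof.write_phylip(d, tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0] == "3" and len(lines) == 4
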