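"""Intron phases, exact-length arrays, length landscapes and frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetlrr import architecture as arch
from tetlrr.io import GeneModel


def gene_from_lengths(exon_lengths, intron_lengths=None, strand="+"):
    """Build a plus-strand gene model with the given exon/intron lengths."""
    introns = intron_lengths or [50] * (len(exon_lengths) - 1)
    exons, pos = [], 0
    for i, L in enumerate(exon_lengths):
        exons.append((pos, pos + L))
        if i < len(introns):
            pos += L + introns[i]
        else:
            pos += L
    return GeneModel("g", "sp", "s1", strand, tuple(exons))


lengths_strategy = st.lists(st.integers(1, 200), min_size=1, max_size=15).filter(
    lambda ls: sum(ls) % 3 == 0
)


class TestIntronPhases:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([11, 90, 90, 7], [2, 2, 2]),
            ([9, 9], [0]),
            ([300], []),
        ],
    )
    def test_examples(self, lengths, expected):
        assert arch.intron_phases(gene_from_lengths(lengths)) == expected

    @given(lengths_strategy)
    @settings(deadline=None, derandomize=True)
    def test_phase_recurrence(self, lengths):
        """phase_i = (phase_{i-1} + exon_i-length) mod 3, and the final
        cumulative phase closes at 0 for a codon-multiple CDS."""
        g = gene_from_lengths(lengths)
        phases = arch.intron_phases(g)
        prev = 0
        for ph, L in zip(phases, lengths):
            assert ph == (prev + L) % 3
            prev = ph
        assert (prev + lengths[-1]) % 3 == 0


class TestExactLengthArrays:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([45, 90, 90, 90, 90, 60], [(2, 4)]),
            ([90, 90, 45, 90, 90, 90], [(4, 3)]),
            ([90, 90, 90], [(1, 3)]),
        ],
    )
    def test_examples(self, lengths, expected):
        assert arch.find_exact_length_arrays(gene_from_lengths(lengths)) == expected

    @given(st.lists(st.sampled_from([45, 90, 120]), min_size=1, max_size=20).filter(lambda ls: sum(ls) % 3 == 0))
    @settings(deadline=None, derandomize=True)
    def test_runs_are_maximal(self, lengths):
        g = gene_from_lengths(lengths)
        for start, n in arch.find_exact_length_arrays(g):
            i0, i1 = start - 1, start - 1 + n  # 0-based half-open
            assert all(L == 90 for L in lengths[i0:i1])
            if i0 > 0:
                assert lengths[i0 - 1] != 90
            if i1 < len(lengths):
                assert lengths[i1] != 90


class TestPhaseBias:
    def test_single_lrr_gene_stratum(self):
        g = gene_from_lengths([11, 90, 90, 7])
        report = arch.phase_bias_report([g], {"g"})
        row = report.loc["lrr_preceding_target"]
        assert (row["phase0"], row["phase1"], row["phase2"]) == (0, 0, 2)
        assert row["phase2_pct"] == 100.0

    def test_empty_stratum_undefined(self):
        g = gene_from_lengths([11, 90, 90, 7])
        report = arch.phase_bias_report([g], set())  # no LRR genes
        assert report.loc["lrr_preceding_target", "n"] == 0
        assert np.isnan(report.loc["lrr_preceding_target", "phase2_pct"])


class TestLengthHistogram:
    def test_single_mode(self):
        h = arch.length_histogram([56] * 100)
        assert h.primary == 56 and h.secondary == []

    def test_primary_and_secondary(self):
        h = arch.length_histogram([257] * 80 + [122] * 20)
        assert h.primary == 257
        assert h.secondary == [122]

    def test_shoulder_not_a_peak(self):
        h = arch.length_histogram([90] * 50 + [91] * 2 + [89] * 1)
        assert h.primary == 90 and h.secondary == []

    def test_permutation_invariant(self):
        values = [257] * 80 + [122] * 20 + [56] * 40
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(values))
        a, b = arch.length_histogram(values), arch.length_histogram(shuffled)
        assert (a.primary, a.secondary) == (b.primary, b.secondary)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            arch.length_histogram([])


class TestRepeatUnits:
    def test_constant_introns(self):
        g = gene_from_lengths([90, 90, 90], [257, 257])
        assert arch.repeat_unit_lengths(g) == [347, 347]

    def test_additivity(self):
        g = gene_from_lengths([90, 90, 90], [122, 257])
        assert arch.repeat_unit_lengths(g) == [212, 347]

    def test_no_arrays(self):
        g = gene_from_lengths([60, 75], [100])
        assert arch.repeat_unit_lengths(g) == []

    def test_minus_strand_matches_plus(self):
        plus = gene_from_lengths([45, 90, 90, 90], [100, 257, 257])
        # same structure laid out on the minus strand
        exons = tuple((1000 - e, 1000 - s) for s, e in plus.exons)
        minus = GeneModel("g", "sp", "s1", "-", exons)
        assert arch.repeat_unit_lengths(minus) == arch.repeat_unit_lengths(plus)


class TestTranslation:
    def test_ciliate_code_reads_taa_as_glutamine(self):
        assert arch.translate_cds("TTATAA", "ciliate") == "LQ"

    def test_standard_code_terminal_stop_dropped(self):
        assert arch.translate_cds("TTATAA", "standard") == "L"

    def test_internal_stop_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="internal stop"):
            assert arch.translate_cds("TTATGATTT", "ciliate") == "L"

    def test_homopolymer(self):
        assert arch.translate_cds("CTT" * 30) == "L" * 30


class TestExonFrame:
    @pytest.mark.parametrize(
        "length,before,after,expected",
        [
            (90, 2, 2, (29, 31)),
            (90, 0, 0, (30, 30)),
            (91, 2, 0, (30, 31)),
        ],
    )
    def test_examples(self, length, before, after, expected):
        assert arch.exon_translation_frame(length, before, after) == expected

    def test_terminal_exon_raises(self):
        with pytest.raises(ValueError, match="terminal"):
            arch.exon_translation_frame(90, None, 2)

    def test_inconsistent_phases_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            arch.exon_translation_frame(90, 2, 1)

    @given(
        st.lists(st.integers(3, 200), min_size=3, max_size=15).filter(lambda ls: sum(ls) % 3 == 0)
    )
    @settings(deadline=None, derandomize=True)
    def test_codon_count_conservation(self, lengths):
        """Summing full codons over all exons plus one junction codon per
        phase!=0 intron recovers the total codon count of the CDS (exons of
        >= 3 nt, so no codon spans more than two exons)."""
        g = gene_from_lengths(lengths)
        phases = arch.intron_phases(g)
        bounded = [None] + phases + [None]
        full_total = 0
        for i, L in enumerate(lengths):
            before = bounded[i] if bounded[i] is not None else 0
            after = (before + L) % 3
            leading = (3 - before) % 3
            full_total += (L - leading) // 3
        junctions = sum(1 for p in phases if p != 0)
        assert full_total + junctions == sum(lengths) // 3


class TestComposition:
    def test_gc_content(self):
        assert arch.gc_content("ATGC") == 0.5
        assert arch.gc_content("AATT") == 0.0
        assert arch.gc_content("ATGN") == pytest.approx(1 / 3)

    def test_all_n_raises(self):
        with pytest.raises(ValueError):
            arch.gc_content("NNN")

    def test_leucine_usage(self):
        usage = arch.leucine_codon_usage(["TTATTATTA"])
        assert usage["TTA"] == 1.0
        assert sum(usage.values()) == 1.0

    def test_no_leucine(self):
        assert arch.leucine_codon_usage(["AAA"]) == dict.fromkeys(arch.LEUCINE_CODONS, 0.0)
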