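"""Generator contracts: structure, ground truth, determinism."""

import dataclasses
import filecmp

import numpy as np
import pytest

from tetlrr import architecture as arch, profiles as prof, synth
from tetlrr.synth import IntronMixture, make_group3_gene, thermophila_profile


class TestMakeGroup3Gene:
    def test_constant_intron_gives_347_units(self):
        profile = dataclasses.replace(thermophila_profile(), group3_intron=IntronMixture(257))
        rng = np.random.default_rng(0)
        model, _seq = make_group3_gene(profile, rng)
        units = arch.repeat_unit_lengths(model)
        assert units and set(units) == {347}
        assert len(units) == model.exon_lengths.count(90) - 1

    def test_phase2_probability_one(self):
        profile = dataclasses.replace(thermophila_profile(), phase2_prob=1.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            model, _ = make_group3_gene(profile, rng)
            phases = arch.intron_phases(model)
            lengths = model.exon_lengths
            preceding = [phases[i] for i in range(len(phases)) if lengths[i + 1] == 90]
            assert preceding and set(preceding) == {2}

    def test_full_retention_recovers_template_positions(self):
        profile = dataclasses.replace(
            thermophila_profile(), leucine_retention_g3=1.0, sub_rate_g3=0.0
        )
        rng = np.random.default_rng(2)
        genomes, genes = {}, []
        for i in range(20):
            model, seq = make_group3_gene(profile, rng)
            model = dataclasses.replace(model, gene_id=f"g{i}", scaffold=f"s{i}")
            genomes[f"s{i}"] = seq
            genes.append(model)
        from tetlrr.io import Genome

        genome = Genome(profile.name, genomes)
        m = prof.build_exon_matrix(genes, {profile.name: genome})
        aa = prof.position_profile(m, "aa")
        expected = sorted(prof.codon_index_of_nt(c) for c in profile.leucine_centers)
        assert prof.conserved_positions(aa, "L", 0.5) == expected

    def test_cds_translates_without_internal_stops(self):
        import warnings

        profile = thermophila_profile()
        rng = np.random.default_rng(3)
        for i in range(10):
            model, seq = make_group3_gene(profile, rng)
            from tetlrr.io import Genome

            genome = Genome(profile.name, {"synthetic": seq})
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # any internal-stop warning fails
                protein = arch.translate_cds(model.cds_sequence(genome), "ciliate")
            assert len(protein) == model.cds_length // 3 - 1  # terminal stop dropped

    def test_phase2_fraction_tracks_probability(self):
        """Across seeds, the per-gene phase-2 fraction stays within 3
        binomial standard errors of the configured probability."""
        p = 0.9
        profile = dataclasses.replace(thermophila_profile(), phase2_prob=p)
        n_genes, hits = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            for _ in range(30):
                model, _ = make_group3_gene(profile, rng)
                phases = arch.intron_phases(model)
                lengths = model.exon_lengths
                preceding = [phases[i] for i in range(len(phases)) if lengths[i + 1] == 90]
                n_genes += 1
                hits += preceding[0] == 2
        se = (p * (1 - p) / n_genes) ** 0.5
        assert abs(hits / n_genes - p) <= 3 * se


class TestBundleStructure:
    def test_gt_ag_intron_boundaries(self, toy_bundle):
        for sp in toy_bundle.species_names:
            genome = toy_bundle.load_genome(sp)
            for gene in toy_bundle.load_genes(sp, genome):
                chrom = genome.sequences[gene.scaffold]
                exons = gene.exons
                for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                    if gene.strand == "+":
                        intron = chrom[e1:s2]
                    else:
                        from tetlrr.io import revcomp

                        intron = revcomp(chrom[e2:s1])
                    assert intron.startswith("GT") and intron.endswith("AG")

    def test_group_mask_contract(self, toy_bundle):
        """Generated group III genes are masked above threshold; group II
        genes never reach it."""
        from tetlrr import grouping

        truth = toy_bundle.truth_genes()
        cls = dict(zip(truth["gene_id"], truth["gene_class"]))
        for sp in toy_bundle.species_names:
            genes = toy_bundle.load_genes(sp)
            lrr = [g for g in genes if cls[g.gene_id] in ("I", "II", "III")]
            for a in grouping.classify_groups(lrr, toy_bundle.load_mask(sp), families=toy_bundle.crs_families(sp)):
                assert a.group == cls[a.gene_id]

    def test_truth_covers_all_annotated_genes(self, toy_bundle):
        truth = toy_bundle.truth_genes()
        annotated = {g.gene_id for sp in toy_bundle.species_names for g in toy_bundle.load_genes(sp)}
        assert set(truth["gene_id"]) == annotated

    def test_placement_bias_matches_weights(self, default_bundle):
        """Pericentromeric+subtelomeric share of group III genes follows the
        5:5:1 placement weights within multinomial error."""
        truth = default_bundle.truth_genes()
        ref = default_bundle.reference_species
        g3 = truth[(truth["species"] == ref) & (truth["gene_class"] == "III")]
        regions = g3["region"].value_counts(normalize=True)
        # equal-sized regions weighted 5:5:1 -> expected peri share 5/11
        n = len(g3)
        se = (5 / 11 * 6 / 11 / n) ** 0.5
        assert abs(regions.get("pericentromeric", 0.0) - 5 / 11) < 4 * se


class TestDeterminismAndErrors:
    def test_same_seed_byte_identical(self, tmp_path):
        a = synth.make_fixture("toy", tmp_path / "a", seed=5)
        b = synth.make_fixture("toy", tmp_path / "b", seed=5)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []

    def test_unknown_fixture_lists_options(self, tmp_path):
        with pytest.raises(ValueError, match="toy"):
            synth.make_fixture("nope", tmp_path / "x")

    def test_infeasible_layout_raises(self, tmp_path):
        spec = synth.toy_spec()
        spec.layout.mds_length = 20_000  # far smaller than the gene content
        with pytest.raises(ValueError, match="infeasible"):
            synth.generate(spec, 0, tmp_path / "bad")

    def test_fixture_cache_reused(self, tmp_path):
        a = synth.make_fixture("toy", tmp_path / "c", seed=5)
        marker = (tmp_path / "c" / "manifest.yaml").stat().st_mtime_ns
        b = synth.make_fixture("toy", tmp_path / "c", seed=5)
        assert (tmp_path / "c" / "manifest.yaml").stat().st_mtime_ns == marker
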