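"""Session-scoped synthetic bundles shared across the test suite."""

from __future__ import annotations

import pytest

from tetlrr import grouping, synth


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    return synth.make_fixture("toy", tmp_path_factory.mktemp("toy") / "bundle", seed=42)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    return synth.make_fixture("default", tmp_path_factory.mktemp("default") / "bundle", seed=42)


@pytest.fixture(scope="session")
def stress_bundle(tmp_path_factory):
    return synth.make_fixture("stress", tmp_path_factory.mktemp("stress") / "bundle", seed=42)


@pytest.fixture(scope="session")
def default_data(default_bundle):
    """Parsed genomes, gene models, LRR ids and age-group assignments for
    the default fixture (loaded once per session)."""
    b = default_bundle
    genomes = {sp: b.load_genome(sp) for sp in b.species_names}
    genes = {sp: b.load_genes(sp, genomes[sp]) for sp in b.species_names}
    domains = b.load_domains()
    lrr_ids = grouping.identify_lrr_genes(domains, synth.LRR_DOMAIN_LABELS)
    assignments = {}
    for sp in b.species_names:
        lrr = [g for g in genes[sp] if g.gene_id in lrr_ids]
        assignments[sp] = grouping.classify_groups(
            lrr, b.load_mask(sp), families=b.crs_families(sp)
        )
    return {
        "bundle": b,
        "genomes": genomes,
        "genes": genes,
        "lrr_ids": lrr_ids,
        "assignments": assignments,
    }
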