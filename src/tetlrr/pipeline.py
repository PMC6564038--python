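"""Stage orchestration: plain-file handoff between analysis stages.

Every stage is a pure function of (bundle, config, seed) that writes
TSV/JSON/BED artifacts into its own subdirectory of the output directory,
so intermediate results stay inspectable and diffable.  ``run_all``
executes the stages in dependency order; a stage whose prerequisite
artifacts are missing raises :class:`PrerequisiteError` naming the stage
to run first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tetlrr import architecture as arch
from tetlrr import grouping, landscape as lsc, orthologs, profiles as prof, te
from tetlrr import io as tio
from tetlrr.synth import LRR_DOMAIN_LABELS, Bundle, make_fixture

logger = logging.getLogger("tetlrr")

STAGES = ("simulate", "architecture", "classify", "orthologs", "profiles", "landscape", "te", "report")


class PrerequisiteError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class RunConfig:
    """All tunables of the pipeline; round-trips losslessly through YAML."""

    bundle_dir: str = "bundle"
    out_dir: str = "out"
    fixture: str = "toy"
    seed: int = 42
    target_len: int = 90
    min_run: int = 3
    min_masked_bp: int = 50
    max_mismatch: int = 2
    logo_alpha: float = 1e-5
    expansion_alpha: float = 0.01
    tail_max_mismatches: int = 5
    flank_window: int = 1000
    bin_width: int = 1_000_000
    peri_halfwidth: int = 1_000_000
    subtel_len: int = 1_000_000
    lrr_labels: tuple[str, ...] = LRR_DOMAIN_LABELS
    max_cluster_rows: int = 6000

    def __post_init__(self) -> None:
        for name in ("target_len", "min_run", "min_masked_bp", "flank_window", "bin_width",
                     "peri_halfwidth", "subtel_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "lrr_labels" in data:
            data["lrr_labels"] = tuple(data["lrr_labels"])
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = {
            k: v for k, v in dataclasses.asdict(self).items() if k not in ("bundle_dir", "out_dir")
        }
        return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]

    @property
    def region_params(self) -> lsc.RegionParams:
        return lsc.RegionParams(self.peri_halfwidth, self.subtel_len)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PrerequisiteError(f"missing {path.name}: run the '{stage}' stage first")
    return path


def _outdir(config: RunConfig, stage: str) -> Path:
    d = Path(config.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _bundle(config: RunConfig) -> Bundle:
    path = Path(config.bundle_dir)
    _require(path / "manifest.yaml", "simulate")
    return Bundle.open(path)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=float)


def stage_simulate(config: RunConfig) -> Bundle:
    """Generate the named synthetic fixture into the bundle directory."""
    return make_fixture(config.fixture, config.bundle_dir, seed=config.seed)


def _load_species(bundle: Bundle, name: str):
    genome = bundle.load_genome(name)
    genes = bundle.load_genes(name, genome)
    return genome, genes


def stage_architecture(config: RunConfig) -> None:
    """Per-gene architecture tables, phase-bias strata, length histograms."""
    bundle = _bundle(config)
    out = _outdir(config, "architecture")
    domains = bundle.load_domains()
    lrr_ids = grouping.identify_lrr_genes(domains, config.lrr_labels)
    all_genes = []
    lrr_exon_lengths: list[int] = []
    for sp in bundle.species_names:
        _genome, genes = _load_species(bundle, sp)
        all_genes.extend(genes)
        arch.architecture_table(genes, config.target_len, config.min_run).to_csv(
            out / f"arch_{sp}.tsv", sep="\t", index=False
        )
        for g in genes:
            if g.gene_id in lrr_ids:
                lrr_exon_lengths.extend(g.exon_lengths)
    report = arch.phase_bias_report(all_genes, lrr_ids, config.target_len)
    report.to_csv(out / "phase_bias.tsv", sep="\t")
    hist = arch.length_histogram(lrr_exon_lengths)
    pd.DataFrame(sorted(hist.counts.items()), columns=["length", "count"]).to_csv(
        out / "lrr_exon_length_hist.tsv", sep="\t", index=False
    )
    _write_json(
        {"primary_peak": hist.primary, "secondary_peaks": hist.secondary, "n": hist.total},
        out / "lrr_exon_length_peaks.json",
    )


def stage_classify(config: RunConfig) -> None:
    """Age-group classification of LRR genes and per-group summaries."""
    bundle = _bundle(config)
    _require(Path(config.out_dir) / "orthologs" / "species_specific.json", "orthologs")
    out = _outdir(config, "classify")
    domains = bundle.load_domains()
    lrr_ids = grouping.identify_lrr_genes(domains, config.lrr_labels)
    with open(Path(config.out_dir) / "orthologs" / "species_specific.json") as fh:
        specific = {g for genes in json.load(fh).values() for g in genes}
    all_assignments = []
    for sp in bundle.species_names:
        _genome, genes = _load_species(bundle, sp)
        lrr_genes = [g for g in genes if g.gene_id in lrr_ids]
        hits = bundle.load_mask(sp)
        assignments = grouping.classify_groups(
            lrr_genes,
            hits,
            families=bundle.crs_families(sp),
            target_len=config.target_len,
            min_masked_bp=config.min_masked_bp,
        )
        all_assignments.extend(assignments)
        df = grouping.assignments_table(assignments)
        df.insert(1, "species", sp)
        df.to_csv(out / f"groups_{sp}.tsv", sep="\t", index=False)
    summary, pvals = grouping.group_summary(all_assignments, specific)
    summary.to_csv(out / "group_summary.tsv", sep="\t")
    _write_json({f"{a}_vs_{b}": p for (a, b), p in pvals.items()}, out / "group_tests.json")


def stage_orthologs(config: RunConfig) -> None:
    """Categories, expansion flags, species-specific sets, tandem statistics."""
    bundle = _bundle(config)
    out = _outdir(config, "orthologs")
    clusters = bundle.load_clusters()
    categories = orthologs.categorize(clusters)
    categories.to_csv(out / "categories.tsv", sep="\t")
    calls = orthologs.expansion_test(clusters, alpha=config.expansion_alpha)
    orthologs.expansion_calls_table(calls).to_csv(out / "expansion_calls.tsv", sep="\t", index=False)
    specific = {
        sp: sorted(orthologs.species_specific_genes(clusters, calls, sp, categories))
        for sp in clusters.species
    }
    _write_json(specific, out / "species_specific.json")

    gene_cluster_map = clusters.gene_to_cluster()
    gene_order: dict[str, list[str]] = {}
    full_map: dict[str, str | None] = {}
    for sp in bundle.species_names:
        genes = bundle.load_genes(sp)
        for g in sorted(genes, key=lambda g: (g.scaffold, g.span[0])):
            gene_order.setdefault(g.scaffold, []).append(g.gene_id)
            full_map[g.gene_id] = gene_cluster_map.get(g.gene_id)
    for label, gap in (("strict", 0), ("relaxed", 3)):
        groups = orthologs.tandem_clusters(gene_order, full_map, max_gap=gap)
        rows = [
            {"scaffold": t.scaffold, "label": t.label, "size": len(t.members), "members": ";".join(t.members)}
            for t in groups
        ]
        pd.DataFrame(rows, columns=["scaffold", "label", "size", "members"]).to_csv(
            out / f"tandem_{label}.tsv", sep="\t", index=False
        )
        if label == "strict":
            pct = orthologs.percent_tandem_by_category(categories, clusters, groups)
            _write_json({str(k): v for k, v in pct.items()}, out / "percent_tandem_by_category.json")


def stage_profiles(config: RunConfig) -> None:
    """Exon matrices, profiles, consensus distances, logo comparison,
    near-identity exon clustering."""
    bundle = _bundle(config)
    classify_dir = Path(config.out_dir) / "classify"
    out = _outdir(config, "profiles")
    group_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for sp in bundle.species_names:
        df = pd.read_csv(_require(classify_dir / f"groups_{sp}.tsv", "classify"), sep="\t", keep_default_na=False)
        group_of.update(dict(zip(df["gene_id"], df["group"])))
        family_of.update(dict(zip(df["gene_id"], df["best_family"])))
    genomes = {sp: bundle.load_genome(sp) for sp in bundle.species_names}
    genes = [g for sp in bundle.species_names for g in bundle.load_genes(sp, genomes[sp])]

    matrices: dict[str, prof.ExonMatrix] = {}
    conserved: dict[str, list[int]] = {}
    for sp in bundle.species_names:
        try:
            m = prof.build_exon_matrix(
                genes, genomes, config.target_len, group_of, family_of,
                groups=("II", "III"), species=(sp,),
            )
        except ValueError:
            continue
        matrices[sp] = m
        aa = prof.position_profile(m, "aa")
        conserved[sp] = prof.conserved_positions(aa, "L", 0.5)
        nt = prof.position_profile(m, "nt")
        nt.freqs.to_csv(out / f"profile_nt_{sp}.tsv", sep="\t")
        with open(out / f"consensus_{sp}.txt", "w") as fh:
            fh.write(prof.consensus(nt) + "\n")
        clusters = prof.cluster_near_identical(
            m.subset(np.arange(len(m)) < config.max_cluster_rows), config.max_mismatch
        )
        prof.cluster_table(m, clusters[:50]).to_csv(out / f"exon_clusters_{sp}.tsv", sep="\t", index=False)
    _write_json(conserved, out / "conserved_positions.json")

    if len(matrices) >= 2:
        names = sorted(matrices)
        calls = prof.two_sample_logo(matrices[names[0]], matrices[names[1]], "aa", config.logo_alpha)
        calls.to_csv(out / "two_sample_logo.tsv", sep="\t", index=False)
    by_family: dict[tuple[str, str], prof.ExonMatrix] = {}
    for sp, m in matrices.items():
        for fam in sorted(set(m.meta["family"]) - {""}):
            sub = m.subset((m.meta["family"] == fam).to_numpy())
            if len(sub):
                by_family[(sp, fam)] = sub
    if len(by_family) >= 2:
        dist = prof.family_consensus_distance_matrix(by_family)
        prof.write_phylip(dist, out / "family_consensus_dist.phy")


def stage_landscape(config: RunConfig) -> None:
    """Reference-species chromosome landscape: bins, regions, enrichment,
    value comparisons, IES-gene association."""
    bundle = _bundle(config)
    ref = bundle.reference_species
    if ref is None:
        logger.warning("no reference species in bundle; landscape stage skipped")
        return
    classify_dir = Path(config.out_dir) / "classify"
    groups_df = pd.read_csv(_require(classify_dir / f"groups_{ref}.tsv", "classify"), sep="\t", keep_default_na=False)
    _require(Path(config.out_dir) / "orthologs" / "species_specific.json", "orthologs")
    with open(Path(config.out_dir) / "orthologs" / "species_specific.json") as fh:
        specific = set(json.load(fh).get(ref, ()))
    out = _outdir(config, "landscape")
    scape = bundle.load_landscape()
    genes = bundle.load_genes(ref)
    group_of = dict(zip(groups_df["gene_id"], groups_df["group"]))
    params = config.region_params
    regions = lsc.regions_of_genes(genes, scape, params)
    regions.to_csv(out / "gene_regions.tsv", sep="\t", index=False)
    placed = regions[~regions["inside_ies"]]
    region_by_gene = dict(zip(placed["gene_id"], placed["region"]))

    tracks = {}
    for grp in ("I", "II", "III"):
        subset = [g for g in genes if group_of.get(g.gene_id) == grp]
        tracks[f"group_{grp}"] = lsc.bin_values(
            ((g.scaffold, g.start, None) for g in subset), scape, config.bin_width, "count"
        )
    tracks["all_genes"] = lsc.bin_values(
        ((g.scaffold, g.start, None) for g in genes), scape, config.bin_width, "count"
    )
    for kind in ("ka_ks", "fpkm"):
        table = bundle.load_values(kind)
        tracks[kind] = lsc.bin_values(
            ((g.scaffold, g.start, table.values[g.gene_id]) for g in genes if g.gene_id in table.values),
            scape, config.bin_width, "median",
        )
    for name, track in tracks.items():
        track.to_frame().to_csv(out / f"track_{name}.tsv", sep="\t", index=False)

    enrichment = {}
    all_regions = [region_by_gene[g] for g in region_by_gene]
    for name, gene_set in (
        ("group_III", {g.gene_id for g in genes if group_of.get(g.gene_id) == "III"}),
        ("species_specific", specific),
    ):
        sub = [region_by_gene[g] for g in gene_set if g in region_by_gene]
        if sub:
            table, p = lsc.region_enrichment(sub, all_regions)
            enrichment[name] = {"p": p, "table": table.to_dict()}
    kaks = bundle.load_values("ka_ks")
    by_region: dict[str, list[float]] = {r: [] for r in lsc.REGIONS}
    for g, r in region_by_gene.items():
        if g in kaks.values:
            by_region[r].append(kaks.values[g])
    enrichment["kaks_mannwhitney"] = {
        f"{a}_vs_{b}": p for (a, b), p in lsc.value_comparison(by_region).items()
    }
    _write_json(enrichment, out / "enrichment.json")
    tio.write_bed_intervals(lsc.region_bed(scape, params), out / "regions.bed")
    ies_table, gene_flags = lsc.ies_gene_association(scape, genes)
    ies_table.to_csv(out / "ies_association.tsv", sep="\t", index=False)
    gene_flags.to_csv(out / "ies_gene_flags.tsv", sep="\t", index=False)


def stage_te(config: RunConfig) -> None:
    """Tail scanning, flanking-family ranking, colocalization report."""
    bundle = _bundle(config)
    ref = bundle.reference_species
    if ref is None:
        logger.warning("no reference species in bundle; te stage skipped")
        return
    out = _outdir(config, "te")
    genome = bundle.load_genome(ref)
    query = te.TailQuery(bundle.tail_sequence(), config.tail_max_mismatches)
    hits = te.scan_tail(genome, query)
    with open(out / "tail_hits.bed", "w") as fh:
        for h in hits:
            fh.write(f"{h.scaffold}\t{h.start}\t{h.end}\ttail\t{h.mismatches}\t{h.strand}\n")
    reps = bundle.load_reps()
    # flanking ranking is over germline repeat families, not the MAC CRS
    # gene-masking families used for age-group classification
    mac_families = set(bundle.crs_families(ref))
    mask = [h for h in bundle.load_mask(ref) if h.family not in mac_families]
    lrr_family = "tLRR-MIC-CRS"
    per_copy, summary, fraction = te.flanking_elements(reps, mask, config.flank_window, lrr_family)
    per_copy.to_csv(out / "rep_flanking.tsv", sep="\t", index=False)
    summary.to_csv(out / "flanking_summary.tsv", sep="\t", index=False)
    sens = te.colocalization_sensitivity(reps, mask, lrr_family)
    sens.to_csv(out / "colocalization_sensitivity.tsv", sep="\t", index=False)
    _write_json(
        {
            "n_tail_hits": len(hits),
            "n_rep_copies": len(reps),
            "n_functional": sum(1 for r in reps if r.functional),
            "colocalization_fraction": fraction,
            "window": config.flank_window,
            "lrr_family": lrr_family,
        },
        out / "colocalization.json",
    )
    scape = bundle.load_landscape()
    te.tail_distribution_track(hits, scape, config.bin_width).to_frame().to_csv(
        out / "tail_track.tsv", sep="\t", index=False
    )


def stage_report(config: RunConfig) -> None:
    """Merge the stage outputs into one summary JSON."""
    out_root = Path(config.out_dir)
    report: dict = {"config_digest": config.digest(), "seed": config.seed}
    peaks = out_root / "architecture" / "lrr_exon_length_peaks.json"
    _require(peaks, "architecture")
    with open(peaks) as fh:
        report["lrr_exon_length_peaks"] = json.load(fh)
    phase = pd.read_csv(out_root / "architecture" / "phase_bias.tsv", sep="\t", index_col=0)
    report["phase2_pct_lrr_preceding_target"] = float(phase.loc["lrr_preceding_target", "phase2_pct"])
    summary = _require(out_root / "classify" / "group_summary.tsv", "classify")
    report["group_counts"] = (
        pd.read_csv(summary, sep="\t", index_col=0)["n_genes"].to_dict()
    )
    conserved = out_root / "profiles" / "conserved_positions.json"
    _require(conserved, "profiles")
    with open(conserved) as fh:
        report["conserved_leucine_positions"] = json.load(fh)
    pct = out_root / "orthologs" / "percent_tandem_by_category.json"
    _require(pct, "orthologs")
    with open(pct) as fh:
        report["percent_tandem_by_category"] = json.load(fh)
    enrichment = out_root / "landscape" / "enrichment.json"
    if enrichment.exists():
        with open(enrichment) as fh:
            report["landscape_enrichment"] = json.load(fh)
    coloc = out_root / "te" / "colocalization.json"
    if coloc.exists():
        with open(coloc) as fh:
            report["te_colocalization"] = json.load(fh)
    _write_json(report, out_root / "report.json")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "architecture": stage_architecture,
    "classify": stage_classify,
    "orthologs": stage_orthologs,
    "profiles": stage_profiles,
    "landscape": stage_landscape,
    "te": stage_te,
    "report": stage_report,
}

#: dependency order used by ``run_all`` (classify needs orthologs' flags)
ALL_ORDER = ("simulate", "architecture", "orthologs", "classify", "profiles", "landscape", "te", "report")


def run_stage(name: str, config: RunConfig) -> None:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    logger.info("stage %s (config %s, seed %d)", name, config.digest(), config.seed)
    _STAGE_FUNCS[name](config)


def run_all(config: RunConfig) -> None:
    for name in ALL_ORDER:
        run_stage(name, config)
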