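"""Synthetic annotated-genome generator.

Emits multi-species genome bundles (FASTA + GFF3 + repeat-mask BED + domain
table + OrthoMCL groups + chromosome metadata + REP annotations + value
tables) whose statistical structure matches what the analyses assume:

* LRR genes of three age groups — group I without 90-bp exons, groups
  II/III with arrays of exactly-90-bp exons whose preceding introns are
  phase 2 with high probability;
* species-specific intron-length mixtures for group III (e.g. a 257-bp
  primary mode with a 122-bp secondary mode in the reference profile,
  232 bp in its closest relative), ~56-bp background introns;
* a leucine template at exon nucleotide centres {36,48,66,75,81,87} with
  per-group retention probabilities and a group III < group II background
  substitution gradient;
* repeat-family (CRS) mask hits over group III arrays;
* a reference (germline-like) species with 5 chromosomes, IESs,
  centromeres, and pericentromeric/subtelomeric placement bias for group
  III genes and REP retrotransposon copies carrying a conserved 54-bp
  tail, adjacent to LRR repeat units with a stated probability;
* ortholog clusters spanning 1..S species, inparalog expansions and strict
  and relaxed tandem runs, assigned by label (not by sequence similarity).

Ground-truth tables record every gene's class, family, cluster, tandem
block and placement region, and every REP copy's adjacency and ORF status.
Regenerating with the same spec and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from tetlrr import io as tio
from tetlrr.io import GeneModel, Genome, MaskHit, OrthologClusters, PerGeneValueTable
from tetlrr.landscape import ChromosomeLandscape, RegionParams
from tetlrr.profiles import codon_index_of_nt
from tetlrr.te import RepCopy

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = {c: i for i, c in enumerate("ACGT")}

#: Synthetic stand-in for the conserved 54-bp 3' tail of the REP element
#: (a fixed arbitrary AT-rich sequence, not a natural one).
DEFAULT_REP_TAIL = "TGTAACTTAACCATTAGGATTAAGATGGTTTAAGCCTTAACGGATTAACTTTGA"

LRR_DOMAIN_LABELS = ("Leucine-rich repeat", "PF13855")

SPECIES_NAMES = (
    "T_thermophila",
    "T_malaccensis",
    "T_elliotti",
    "T_pyriformis",
    "T_vorax",
    "T_borealis",
    "T_canadensis",
    "T_empidokyrea",
    "T_shanghaiensis",
    "T_paravorax",
)


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------


@dataclass
class IntronMixture:
    """Discretized-normal intron length mixture with an optional secondary
    mode (lengths are clamped at ``min_length``)."""

    primary_mode: int
    primary_sd: float = 0.0
    secondary_mode: int | None = None
    secondary_sd: float = 0.0
    secondary_weight: float = 0.0

    min_length: int = 12

    def draw(self, rng: np.random.Generator) -> int:
        if self.secondary_mode is not None and self.secondary_weight > 0 and rng.random() < self.secondary_weight:
            mode, sd = self.secondary_mode, self.secondary_sd
        else:
            mode, sd = self.primary_mode, self.primary_sd
        length = int(round(rng.normal(mode, sd))) if sd > 0 else int(mode)
        return max(self.min_length, length)


@dataclass
class SpeciesProfile:
    """Per-species gene counts and sequence parameters."""

    name: str
    n_background: int = 300
    n_group1: int = 120
    n_group2: int = 220
    n_group3: int = 330
    background_intron: IntronMixture = field(default_factory=lambda: IntronMixture(56, 8))
    group3_intron: IntronMixture = field(
        default_factory=lambda: IntronMixture(257, 10, secondary_mode=122, secondary_sd=5, secondary_weight=0.15)
    )
    exon_count_mean: float = 10.0  # Poisson mean, truncated >= 3
    phase2_prob: float = 0.99
    leucine_centers: tuple[int, ...] = (36, 48, 66, 75, 81, 87)
    leucine_retention_g3: float = 0.95
    leucine_retention_g2: float = 0.85
    sub_rate_g3: float = 0.02
    sub_rate_g2: float = 0.08
    n_crs_families: int = 4
    family_divergence: float = 0.05
    gc_intergenic: float = 0.25
    gc_cds: float = 0.27
    gc_cds_group3: float = 0.35
    is_reference: bool = False

    def __post_init__(self) -> None:
        for p in (self.phase2_prob, self.leucine_retention_g3, self.leucine_retention_g2,
                  self.sub_rate_g3, self.sub_rate_g2, self.family_divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probability {p} outside [0, 1]")
        for n in (self.n_background, self.n_group1, self.n_group2, self.n_group3):
            if n < 0:
                raise ValueError(f"{self.name}: negative gene count")


@dataclass
class ChromosomeLayout:
    """Reference-species chromosome geometry and placement model."""

    n_chromosomes: int = 5
    mds_length: int = 6_000_000
    ies_fraction_peri: float = 0.25
    ies_fraction_arm: float = 0.10
    ies_mean_length: int = 1500
    ies_sd: int = 400
    intron_ies_prob: float = 0.12
    placement_weights: tuple[float, float, float] = (5.0, 5.0, 1.0)  # peri : subtel : arm
    region: RegionParams = field(default_factory=RegionParams)
    min_gap: int = 200
    centromere_halfwidth: int = 25_000


@dataclass
class RepModel:
    """REP retrotransposon model: two ORFs plus the conserved 54-bp tail."""

    n_copies: int = 400
    adjacency_prob: float = 0.8
    functional_fraction: float = 0.25
    orf1_length: int = 900
    orf2_length: int = 1800
    body_mut_rate: float = 0.01
    tail_mut_rate: float = 0.02
    tail: str = DEFAULT_REP_TAIL


@dataclass
class OrthologLayout:
    """Label-level ortholog structure (clusters are assigned, not inferred)."""

    conserved_frac_bg: float = 0.60
    partial_clusters_per_category: int = 2
    conserved_frac_g1: float = 0.85
    conserved_frac_g2: float = 0.60
    conserved_frac_g3: float = 0.15
    g2_cluster_size: int = 3
    g3_cluster_size: int = 5
    singleton_frac_g3: float = 0.10
    expansion_sizes: tuple[int, ...] = (61, 29)
    n_strict_blocks_g3: int = 2
    include_17_block: bool = True


@dataclass
class SyntheticGenomeSpec:
    species: list[SpeciesProfile]
    layout: ChromosomeLayout = field(default_factory=ChromosomeLayout)
    rep: RepModel = field(default_factory=RepModel)
    orthologs: OrthologLayout = field(default_factory=OrthologLayout)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species profile required")
        names = [p.name for p in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")


def thermophila_profile(**overrides) -> SpeciesProfile:
    """Reference-species profile: 257-bp primary / 122-bp secondary group III
    intron modes, germline landscape enabled."""
    kw = dict(name="T_thermophila", is_reference=True)
    kw.update(overrides)
    return SpeciesProfile(**kw)


def malaccensis_profile(**overrides) -> SpeciesProfile:
    kw = dict(name="T_malaccensis", group3_intron=IntronMixture(232, 10))
    kw.update(overrides)
    return SpeciesProfile(**kw)


def elliotti_profile(**overrides) -> SpeciesProfile:
    kw = dict(name="T_elliotti", group3_intron=IntronMixture(245, 10))
    kw.update(overrides)
    return SpeciesProfile(**kw)


def default_spec() -> SyntheticGenomeSpec:
    """Three species, ~2,000 LRR genes in total."""
    return SyntheticGenomeSpec(
        species=[thermophila_profile(), malaccensis_profile(), elliotti_profile()]
    )


def toy_spec() -> SyntheticGenomeSpec:
    counts = dict(n_background=10, n_group1=4, n_group2=6, n_group3=10, n_crs_families=2)
    return SyntheticGenomeSpec(
        species=[
            thermophila_profile(**counts),
            malaccensis_profile(**counts),
        ],
        layout=ChromosomeLayout(n_chromosomes=2, mds_length=400_000),
        rep=RepModel(n_copies=12),
        orthologs=OrthologLayout(expansion_sizes=(), include_17_block=False, n_strict_blocks_g3=1),
    )


def stress_spec() -> SyntheticGenomeSpec:
    counts = dict(n_background=40, n_group1=8, n_group2=10, n_group3=14, n_crs_families=2)
    modes = (257, 232, 245, 260, 240, 250, 235, 248, 255, 265)
    species = []
    for i, name in enumerate(SPECIES_NAMES):
        kw = dict(counts)
        if i == 0:
            species.append(thermophila_profile(**kw))
        else:
            kw["group3_intron"] = IntronMixture(modes[i], 10)
            species.append(SpeciesProfile(name=name, **kw))
    return SyntheticGenomeSpec(
        species=species,
        layout=ChromosomeLayout(n_chromosomes=3, mds_length=1_500_000),
        rep=RepModel(n_copies=40),
        orthologs=OrthologLayout(expansion_sizes=(), include_17_block=False, n_strict_blocks_g3=1),
    )


FIXTURES = {"toy": toy_spec, "default": default_spec, "stress": stress_spec}


# ---------------------------------------------------------------------------
# sequence primitives (2-bit base codes: A=0, C=1, G=2, T=3)
# ---------------------------------------------------------------------------

_TGA = np.array([3, 2, 0], dtype=np.uint8)


class _SeqPool:
    """Buffered deterministic random-base source at a fixed GC content."""

    def __init__(self, rng: np.random.Generator, gc: float, buffer: int = 1 << 20) -> None:
        self.rng = rng
        at = (1.0 - gc) / 2.0
        self.probs = np.array([at, gc / 2.0, gc / 2.0, at])
        self.buffer_size = buffer
        self._buf = np.empty(0, dtype=np.uint8)
        self._pos = 0

    def take(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.uint8)
        filled = 0
        while filled < n:
            if self._pos >= len(self._buf):
                self._buf = self.rng.choice(4, size=self.buffer_size, p=self.probs).astype(np.uint8)
                self._pos = 0
            chunk = min(n - filled, len(self._buf) - self._pos)
            out[filled : filled + chunk] = self._buf[self._pos : self._pos + chunk]
            self._pos += chunk
            filled += chunk
        return out


def _decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.uint8)


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def _fix_frame_stops(arr: np.ndarray, offset: int = 0) -> None:
    """Rewrite every in-frame TGA codon (the only ciliate stop) to TAA
    starting at ``offset`` within ``arr``; operates in place."""
    usable = (len(arr) - offset) // 3 * 3
    if usable <= 0:
        return
    view = arr[offset : offset + usable].reshape(-1, 3)
    is_tga = (view == _TGA).all(axis=1)
    view[is_tga, 1] = 0  # TGA -> TAA (glutamine under the ciliate code)


_LEUCINE_CODES = {(3, 3, 0), (3, 3, 2), (1, 3, 3), (1, 3, 1), (1, 3, 0), (1, 3, 2)}


def _random_codon(pool: _SeqPool, forbid_leucine: bool = False) -> np.ndarray:
    while True:
        codon = pool.take(3)
        t = tuple(int(x) for x in codon)
        if t == (3, 2, 0):
            continue
        if forbid_leucine and t in _LEUCINE_CODES:
            continue
        return codon


def _make_exon_template(rng: np.random.Generator, pool: _SeqPool, centers: Sequence[int]) -> np.ndarray:
    """90-nt exon template: junction nucleotides A...TT (so every junction
    codon in an array reads TTA, leucine), leucine codons (TTA) at the
    template centres, and random non-leucine non-stop codons elsewhere."""
    t = np.empty(90, dtype=np.uint8)
    t[0] = 0  # A
    t[88] = 3  # T
    t[89] = 3  # T
    leu_codons = {codon_index_of_nt(c) for c in centers}
    for k in range(1, 30):  # codon k spans 1-based nts 3k-1..3k+1
        s = 3 * k - 2  # 0-based start
        if k in leu_codons:
            t[s : s + 3] = (3, 3, 0)  # TTA
        else:
            t[s : s + 3] = _random_codon(pool, forbid_leucine=True)
    return t


def _template_masks(centers: Sequence[int]) -> tuple[np.ndarray, list[int]]:
    """(mutable-position mask, 0-based starts of the leucine codons)."""
    mask = np.ones(90, dtype=bool)
    mask[[0, 88, 89]] = False
    starts = []
    for c in centers:
        k = codon_index_of_nt(c)
        s = 3 * k - 2
        starts.append(s)
        mask[s : s + 3] = False
    return mask, starts


def _mutate(rng: np.random.Generator, arr: np.ndarray, mask: np.ndarray, rate: float) -> None:
    hit = np.nonzero(mask & (rng.random(len(arr)) < rate))[0]
    if len(hit):
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=len(hit))) % 4


def _draw_90bp_exon(
    rng: np.random.Generator,
    base: np.ndarray,
    mut_mask: np.ndarray,
    leu_starts: Sequence[int],
    retention: float,
    sub_rate: float,
    pool: _SeqPool,
) -> np.ndarray:
    exon = base.copy()
    for s in leu_starts:
        if rng.random() >= retention:
            exon[s : s + 3] = _random_codon(pool)
    _mutate(rng, exon, mut_mask, sub_rate)
    _fix_frame_stops(exon, offset=1)  # the 29-codon frame starts at nt 2
    return exon


# ---------------------------------------------------------------------------
# gene payloads
# ---------------------------------------------------------------------------


@dataclass
class _GenePayload:
    gene_id: str
    species: str
    gene_class: str  # "bg", "I", "II", "III"
    exon_seqs: list[np.ndarray]
    intron_lens: list[int]
    strand: str
    family: str = ""
    cluster: str | None = None
    tandem_block: str = ""
    domains: tuple[str, ...] = ()
    region_truth: str = ""
    intron_ies: bool = False

    @property
    def is_lrr(self) -> bool:
        return self.gene_class in ("I", "II", "III")

    @property
    def item_length(self) -> int:
        return sum(len(e) for e in self.exon_seqs) + sum(self.intron_lens)


def _finalize_cds(exon_seqs: list[np.ndarray]) -> None:
    """Remove internal TGA stops from the concatenated CDS in place."""
    cds = np.concatenate(exon_seqs)
    usable = len(cds) // 3 * 3
    view = cds[:usable].reshape(-1, 3)
    is_tga = (view == _TGA).all(axis=1)
    is_tga[-1] = False  # keep the terminal stop
    for codon_idx in np.nonzero(is_tga)[0]:
        flat = codon_idx * 3 + 1  # patch the G
        off = 0
        for exon in exon_seqs:
            if flat < off + len(exon):
                exon[flat - off] = 0  # TGA -> TAA
                break
            off += len(exon)


def _plain_gene_exons(
    rng: np.random.Generator,
    pool: _SeqPool,
    n_exons: int,
    length_range: tuple[int, int],
    forbidden_len: int = 90,
) -> list[np.ndarray]:
    """Exon set for a background or group I gene: random lengths avoiding
    the forbidden (90-bp) value, total adjusted to a codon multiple, random
    codon content ending in a TGA stop."""
    lengths = []
    for _ in range(n_exons):
        while True:
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            if L != forbidden_len:
                break
        lengths.append(L)
    excess = sum(lengths) % 3
    if excess:
        lengths[-1] += 3 - excess
        if lengths[-1] == forbidden_len:
            lengths[-1] += 3
    total = sum(lengths)
    cds = pool.take(total)
    _fix_frame_stops(cds)
    cds[-3:] = _TGA  # terminal stop
    out, off = [], 0
    for L in lengths:
        out.append(cds[off : off + L].copy())
        off += L
    return out


def _lrr_gene_exons(
    rng: np.random.Generator,
    profile: SpeciesProfile,
    base: np.ndarray,
    group: str,
    pools: dict[str, _SeqPool],
) -> tuple[list[np.ndarray], int]:
    """(exon sequences, phase of the introns preceding the array exons) for
    a group II/III gene: lead exon + n x 90-bp array + tail exon with the
    terminal stop.  The lead-exon length sets the shared phase of every
    intron that precedes a 90-bp exon (90 = 0 mod 3), so the stated phase-2
    probability acts per gene."""
    n = 0
    while n < 3:
        n = int(rng.poisson(profile.exon_count_mean))
    phase = 2 if rng.random() < profile.phase2_prob else int(rng.integers(0, 2))
    pool = pools["g3" if group == "III" else "cds"]
    mut_mask, leu_starts = _template_masks(profile.leucine_centers)
    retention = profile.leucine_retention_g3 if group == "III" else profile.leucine_retention_g2
    sub_rate = profile.sub_rate_g3 if group == "III" else profile.sub_rate_g2

    lead_len = 9 + phase
    lead = np.concatenate([_random_codon(pool) for _ in range(3)])
    if phase:
        lead = np.concatenate([lead, np.full(phase, 3, dtype=np.uint8)])  # trailing T(T)
    lead = lead[:lead_len]

    exons = [lead]
    for _ in range(n):
        exons.append(_draw_90bp_exon(rng, base, mut_mask, leu_starts, retention, sub_rate, pool))

    j = (3 - phase) % 3
    tail_parts = [np.zeros(j, dtype=np.uint8)]  # junction A's
    tail_parts.append(_random_codon(pool))
    tail_parts.append(_TGA.copy())
    exons.append(np.concatenate(tail_parts))
    _finalize_cds(exons)
    return exons, phase


def _draw_introns(rng: np.random.Generator, mixture: IntronMixture, n: int) -> list[int]:
    return [mixture.draw(rng) for _ in range(n)]


def make_group3_gene(
    profile: SpeciesProfile,
    rng: np.random.Generator,
    family_consensus: np.ndarray | None = None,
) -> tuple[GeneModel, str]:
    """Draw a single group III LRR gene under a species profile.

    Returns the gene model (on a placeholder scaffold, forward strand,
    starting at 0) together with its genomic sequence.  Intron boundaries
    are GT..AG; every intron length is drawn from the group III mixture.
    """
    pools = {
        "cds": _SeqPool(rng, profile.gc_cds, buffer=1 << 14),
        "g3": _SeqPool(rng, profile.gc_cds_group3, buffer=1 << 14),
        "intron": _SeqPool(rng, profile.gc_intergenic, buffer=1 << 14),
    }
    if family_consensus is None:
        template = _make_exon_template(rng, pools["g3"], profile.leucine_centers)
        mut_mask, _ = _template_masks(profile.leucine_centers)
        family_consensus = template.copy()
        _mutate(rng, family_consensus, mut_mask, profile.family_divergence)
        _fix_frame_stops(family_consensus, offset=1)
    exons, _phase = _lrr_gene_exons(rng, profile, family_consensus, "III", pools)
    introns = _draw_introns(rng, profile.group3_intron, len(exons) - 1)
    payload = _GenePayload("synthetic_g3", profile.name, "III", exons, introns, "+")
    seq_codes, exon_ivs, _ = _assemble_gene_codes(payload, pools["intron"], rng)
    model = GeneModel(
        gene_id=payload.gene_id,
        species=profile.name,
        scaffold="synthetic",
        strand="+",
        exons=tuple(exon_ivs),
        domains=frozenset(LRR_DOMAIN_LABELS),
    )
    return model, _decode(seq_codes)


def _intron_codes(pool: _SeqPool, length: int, rng: np.random.Generator) -> np.ndarray:
    arr = pool.take(length)
    arr[0:2] = (2, 3)  # GT
    arr[-2:] = (0, 2)  # AG
    return arr


def _assemble_gene_codes(
    payload: _GenePayload,
    intron_pool: _SeqPool,
    rng: np.random.Generator,
    intron_ies: tuple[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]], tuple[int, int] | None]:
    """Build the genomic (forward-strand) sequence of a gene.

    Returns (codes, exon intervals in transcription order relative to the
    gene start, IES interval or None).  ``intron_ies`` inserts the given
    IES codes into the middle of intron ``index`` (0-based, sense order).
    """
    parts: list[np.ndarray] = []
    sense_exons: list[tuple[int, int]] = []
    ies_sense: tuple[int, int] | None = None
    off = 0
    for i, exon in enumerate(payload.exon_seqs):
        parts.append(exon)
        sense_exons.append((off, off + len(exon)))
        off += len(exon)
        if i < len(payload.intron_lens):
            intron = _intron_codes(intron_pool, payload.intron_lens[i], rng)
            if intron_ies is not None and intron_ies[0] == i:
                mid = len(intron) // 2
                ies = intron_ies[1]
                parts.extend([intron[:mid], ies, intron[mid:]])
                ies_sense = (off + mid, off + mid + len(ies))
                off += len(intron) + len(ies)
            else:
                parts.append(intron)
                off += len(intron)
    codes = np.concatenate(parts)
    total = len(codes)
    if payload.strand == "+":
        exon_ivs = sense_exons
        ies_iv = ies_sense
    else:
        codes = _revcomp_codes(codes).copy()
        exon_ivs = [(total - e, total - s) for s, e in sense_exons]
        ies_iv = (total - ies_sense[1], total - ies_sense[0]) if ies_sense else None
    return codes, exon_ivs, ies_iv


# ---------------------------------------------------------------------------
# ortholog / tandem label assignment
# ---------------------------------------------------------------------------


def _assign_clusters(
    spec: SyntheticGenomeSpec,
    ids: dict[str, dict[str, list[str]]],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, list[str]]], dict[str, str | None], dict[str, list[str]]]:
    """Assign gene ids to ortholog clusters by label.

    Returns (clusters, gene -> cluster-or-None, expansion host gene lists
    keyed by cluster id).
    """
    ol = spec.orthologs
    names = [p.name for p in spec.species]
    S = len(names)
    pools = {sp: {cls: list(ids[sp][cls]) for cls in ids[sp]} for sp in names}
    for sp in names:
        for cls in pools[sp]:
            perm = rng.permutation(len(pools[sp][cls]))
            pools[sp][cls] = [pools[sp][cls][i] for i in perm]
    clusters: dict[str, dict[str, list[str]]] = {}
    expansion_members: dict[str, list[str]] = {}

    def new_cluster(cid: str, members: dict[str, list[str]]) -> None:
        clusters[cid] = {sp: genes for sp, genes in members.items() if genes}

    # background: partial-category clusters (categories 2..S-1), conserved, cat-I
    if S > 2:
        for k in range(2, S):
            for j in range(ol.partial_clusters_per_category):
                subset = names[:k]
                if all(len(pools[sp]["bg"]) > 2 for sp in subset):
                    new_cluster(f"part{k}_{j}", {sp: [pools[sp]["bg"].pop()] for sp in subset})
    m = min(len(pools[sp]["bg"]) for sp in names)
    for i in range(int(ol.conserved_frac_bg * m)):
        new_cluster(f"bgc{i}", {sp: [pools[sp]["bg"].pop()] for sp in names})
    for sp in names:
        pool = pools[sp]["bg"]
        n_pairs = max(1, len(pool) // 20)
        for i in range(n_pairs):
            if len(pool) >= 2:
                new_cluster(f"bg1_{sp}_{i}", {sp: [pool.pop(), pool.pop()]})
    # remaining background genes stay singletons

    # group I: mostly conserved
    m = min(len(pools[sp]["g1"]) for sp in names)
    for i in range(int(ol.conserved_frac_g1 * m)):
        new_cluster(f"g1c{i}", {sp: [pools[sp]["g1"].pop()] for sp in names})
    for sp in names:
        pool = pools[sp]["g1"]
        while len(pool) >= 4:  # half of the rest in species-specific pairs
            new_cluster(f"g1s_{sp}_{len(pool)}", {sp: [pool.pop(), pool.pop()]})
            pool.pop()  # leave one singleton per pair drawn

    # group III expansions (multi-species clusters with one dominant species)
    for e_idx, size in enumerate(ol.expansion_sizes):
        host = names[e_idx % S]
        donors = [n for n in names if n != host][:2]
        if len(pools[host]["g3"]) < size + 20 or any(len(pools[d]["g3"]) < 5 for d in donors):
            continue
        members = {host: [pools[host]["g3"].pop() for _ in range(size)]}
        for d in donors:
            members[d] = [pools[d]["g3"].pop()]
        cid = f"exp{e_idx}"
        new_cluster(cid, members)
        expansion_members[cid] = list(members[host])

    # group II: conserved + species-specific clusters
    m = min(len(pools[sp]["g2"]) for sp in names)
    for i in range(int(ol.conserved_frac_g2 * m)):
        new_cluster(f"g2c{i}", {sp: [pools[sp]["g2"].pop()] for sp in names})
    for sp in names:
        pool = pools[sp]["g2"]
        i = 0
        while len(pool) >= ol.g2_cluster_size:
            new_cluster(f"g2s_{sp}_{i}", {sp: [pool.pop() for _ in range(ol.g2_cluster_size)]})
            i += 1

    # group III: a small conserved core, singletons, species-specific clusters
    m = min(len(pools[sp]["g3"]) for sp in names)
    for i in range(int(ol.conserved_frac_g3 * m)):
        new_cluster(f"g3c{i}", {sp: [pools[sp]["g3"].pop()] for sp in names})
    for sp in names:
        pool = pools[sp]["g3"]
        n_single = int(ol.singleton_frac_g3 * len(pool))
        for _ in range(n_single):
            pool.pop()  # stays singleton
        i = 0
        while len(pool) >= ol.g3_cluster_size:
            new_cluster(f"g3s_{sp}_{i}", {sp: [pool.pop() for _ in range(ol.g3_cluster_size)]})
            i += 1

    gene_cluster: dict[str, str | None] = {}
    for sp in names:
        for cls in ids[sp]:
            for g in ids[sp][cls]:
                gene_cluster[g] = None
    for cid, by_sp in clusters.items():
        for sp, genes in by_sp.items():
            for g in genes:
                gene_cluster[g] = cid
    return clusters, gene_cluster, expansion_members


# ---------------------------------------------------------------------------
# chromosome assembly
# ---------------------------------------------------------------------------


def _region_intervals(L: int, params: RegionParams) -> list[tuple[int, int, str]]:
    """Disjoint (start, end, label) intervals tiling MDS coordinates
    [0, L); pericentromeric takes precedence over subtelomeric."""
    mid = L // 2
    peri = (max(0, mid - params.peri_halfwidth), min(L, mid + params.peri_halfwidth))
    points = sorted({0, L, min(params.subtel_len, L), max(0, L - params.subtel_len), peri[0], peri[1]})
    out = []
    for a, b in zip(points, points[1:]):
        if a >= b:
            continue
        x = (a + b) // 2
        if peri[0] <= x < peri[1]:
            label = "pericentromeric"
        elif x < params.subtel_len or x >= L - params.subtel_len:
            label = "subtelomeric"
        else:
            label = "arm"
        out.append((a, b, label))
    return out


def _sample_anchor(
    rng: np.random.Generator,
    intervals: list[tuple[int, int, str]],
    weights: dict[str, float] | None,
) -> tuple[int, str]:
    w = np.array(
        [(weights[lab] if weights else 1.0) * (e - s) for s, e, lab in intervals], dtype=float
    )
    i = int(rng.choice(len(intervals), p=w / w.sum()))
    s, e, lab = intervals[i]
    return int(rng.integers(s, e)), lab


@dataclass
class _RepPayload:
    rep_id: str
    codes: np.ndarray
    strand: str
    adjacent: bool
    orf1: bool
    orf2: bool


def _make_rep_copies(
    rng: np.random.Generator, rep: RepModel, pool: _SeqPool, species: str
) -> list[_RepPayload]:
    tail = _encode(rep.tail)
    orf1 = pool.take(rep.orf1_length)
    orf2 = pool.take(rep.orf2_length)
    for orf in (orf1, orf2):
        orf[:3] = (0, 3, 2)  # ATG
        _fix_frame_stops(orf)
        orf[-3:] = _TGA
    spacer1, spacer2 = pool.take(50), pool.take(30)
    master = np.concatenate([orf1, spacer1, orf2, spacer2, tail])
    tail_off = len(master) - len(tail)
    copies = []
    for i in range(rep.n_copies):
        codes = master.copy()
        _mutate(rng, codes[:tail_off], np.ones(tail_off, dtype=bool), rep.body_mut_rate)
        _mutate(rng, codes[tail_off:], np.ones(len(tail), dtype=bool), rep.tail_mut_rate)
        functional = rng.random() < rep.functional_fraction
        orf1_ok = orf2_ok = True
        if not functional:
            which = int(rng.integers(0, 3))
            if which in (0, 2):
                codes[30:33] = _TGA  # premature stop in ORF1
                orf1_ok = False
            if which in (1, 2):
                codes[rep.orf1_length + 80 : rep.orf1_length + 83] = _TGA
                orf2_ok = False
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            codes = _revcomp_codes(codes).copy()
        copies.append(_RepPayload(f"{species}_REP{i:04d}", codes, strand, False, orf1_ok, orf2_ok))
    return copies


@dataclass
class _Item:
    anchor: int
    kind: str  # "gene", "block", "rep"
    genes: list[_GenePayload] = field(default_factory=list)
    reps: list[_RepPayload | None] = field(default_factory=list)  # parallel to genes for attached
    rep: _RepPayload | None = None
    region: str = ""


class _ChromAssembler:
    """Left-to-right assembly of one chromosome from anchored items."""

    def __init__(
        self,
        chrom: str,
        layout: ChromosomeLayout,
        rng: np.random.Generator,
        pools: dict[str, _SeqPool],
        reference: bool,
        mds_target: int,
        profile: SpeciesProfile,
    ) -> None:
        self.chrom = chrom
        self.layout = layout
        self.rng = rng
        self.pools = pools
        self.reference = reference
        self.mds_target = mds_target
        self.profile = profile
        self.parts: list[np.ndarray] = []
        self.cursor = 0  # MIC / genomic
        self.cursor_mds = 0
        self.ies: list[tuple[int, int]] = []
        self.genes: list[GeneModel] = []
        self.gene_truth: list[dict] = []
        self.mask_hits: list[MaskHit] = []
        self.reps: list[RepCopy] = []
        self.rep_truth: list[dict] = []
        self._regions = _region_intervals(mds_target, layout.region) if reference else None

    def _region_at(self, mds: int) -> str:
        for s, e, lab in self._regions:
            if s <= mds < e:
                return lab
        return "arm"

    def _ies_prob(self, region: str) -> float:
        frac = self.layout.ies_fraction_peri if region != "arm" else self.layout.ies_fraction_arm
        chunk, mean = 2000.0, float(self.layout.ies_mean_length)
        return min(0.95, frac * chunk / (mean * (1.0 - frac)))

    def emit_spacer(self, target_mds: int) -> None:
        while self.cursor_mds < target_mds:
            chunk = min(2000, target_mds - self.cursor_mds)
            self.parts.append(self.pools["intergenic"].take(chunk))
            self.cursor += chunk
            self.cursor_mds += chunk
            if self.reference and chunk == 2000:
                region = self._region_at(self.cursor_mds)
                if self.rng.random() < self._ies_prob(region):
                    ies_len = max(200, int(self.rng.normal(self.layout.ies_mean_length, self.layout.ies_sd)))
                    self.parts.append(self.pools["intergenic"].take(ies_len))
                    self.ies.append((self.cursor, self.cursor + ies_len))
                    self.cursor += ies_len

    def emit_gene(self, payload: _GenePayload) -> GeneModel:
        intron_ies = None
        if (
            self.reference
            and payload.intron_lens
            and self.rng.random() < self.layout.intron_ies_prob
        ):
            candidates = [i for i, L in enumerate(payload.intron_lens) if L >= 60]
            if candidates:
                idx = candidates[int(self.rng.integers(0, len(candidates)))]
                ies_len = max(200, int(self.rng.normal(800, 200)))
                intron_ies = (idx, self.pools["intergenic"].take(ies_len))
                payload.intron_ies = True
        codes, exon_ivs, ies_iv = _assemble_gene_codes(
            payload, self.pools["intergenic"], self.rng, intron_ies
        )
        start = self.cursor
        self.parts.append(codes)
        self.cursor += len(codes)
        mds_len = len(codes)
        if ies_iv is not None:
            self.ies.append((start + ies_iv[0], start + ies_iv[1]))
            mds_len -= ies_iv[1] - ies_iv[0]
        self.cursor_mds += mds_len
        exons = tuple((start + s, start + e) for s, e in exon_ivs)
        model = GeneModel(
            gene_id=payload.gene_id,
            species=payload.species,
            scaffold=self.chrom,
            strand=payload.strand,
            exons=exons,
            domains=frozenset(payload.domains),
        )
        self.genes.append(model)
        self._emit_mask_hits(payload, model)
        span = model.span
        self.gene_truth.append(
            {
                "gene_id": payload.gene_id,
                "species": payload.species,
                "scaffold": self.chrom,
                "start": span[0],
                "end": span[1],
                "strand": payload.strand,
                "gene_class": payload.gene_class,
                "family": payload.family,
                "cluster": payload.cluster or "",
                "tandem_block": payload.tandem_block,
                "region": payload.region_truth,
                "intron_ies": int(payload.intron_ies),
            }
        )
        return model

    def _emit_mask_hits(self, payload: _GenePayload, model: GeneModel) -> None:
        if payload.gene_class == "III":
            ivs90 = [iv for iv, L in zip(model.exons, model.exon_lengths) if L == 90]
            for s, e in ivs90:
                score = max(100.0, float(self.rng.normal(750, 80)))
                self.mask_hits.append(
                    MaskHit(self.chrom, max(0, s - 20), e + 20, payload.family, round(score, 1))
                )
            if self.reference and ivs90:
                lo = min(s for s, _ in ivs90)
                hi = max(e for _, e in ivs90)
                self.mask_hits.append(MaskHit(self.chrom, lo, hi, "tLRR-MIC-CRS", 900.0))
        elif payload.gene_class == "II" and self.rng.random() < 0.02:
            s = model.span[0]
            self.mask_hits.append(MaskHit(self.chrom, s, s + 30, "CRS1", 180.0))

    def emit_rep(self, rep: _RepPayload) -> None:
        start = self.cursor
        self.parts.append(rep.codes)
        self.cursor += len(rep.codes)
        self.cursor_mds += len(rep.codes)
        self.reps.append(
            RepCopy(rep.rep_id, self.chrom, start, start + len(rep.codes), rep.strand, rep.orf1, rep.orf2)
        )
        self.rep_truth.append(
            {
                "rep_id": rep.rep_id,
                "scaffold": self.chrom,
                "start": start,
                "end": start + len(rep.codes),
                "strand": rep.strand,
                "adjacent": int(rep.adjacent),
                "functional": int(rep.orf1 and rep.orf2),
                "orf1_intact": int(rep.orf1),
                "orf2_intact": int(rep.orf2),
            }
        )

    def run(self, items: list[_Item]) -> None:
        items.sort(key=lambda it: it.anchor)
        total_item_bp = sum(
            sum(g.item_length for g in it.genes)
            + sum(len(r.codes) for r in it.reps if r is not None)
            + (len(it.rep.codes) if it.rep is not None else 0)
            for it in items
        )
        budget = total_item_bp + (len(items) + 1) * self.layout.min_gap
        if budget > self.mds_target:
            raise ValueError(
                f"{self.chrom}: infeasible layout ({budget} bp of items in "
                f"{self.mds_target} bp of MDS)"
            )
        for it in items:
            self.emit_spacer(max(it.anchor, self.cursor_mds + self.layout.min_gap))
            if it.kind == "rep":
                self.emit_spacer(self.cursor_mds + 1500)
                self.emit_rep(it.rep)
                self.emit_spacer(self.cursor_mds + 1500)
            else:
                for payload, attached in zip(it.genes, it.reps):
                    payload.region_truth = it.region
                    self.emit_gene(payload)
                    if attached is not None:
                        gap = int(self.rng.integers(50, 300))
                        self.emit_spacer(self.cursor_mds + gap)
                        self.emit_rep(attached)
                    if it.kind == "block":
                        self.emit_spacer(self.cursor_mds + int(self.rng.integers(200, 600)))
        self.emit_spacer(self.mds_target)

    @property
    def sequence_codes(self) -> np.ndarray:
        return np.concatenate(self.parts) if self.parts else np.empty(0, dtype=np.uint8)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """Paths and loaders for a generated bundle directory."""

    root: Path
    manifest: dict

    @classmethod
    def open(cls, root: str | Path) -> "Bundle":
        root = Path(root)
        with open(root / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        return cls(root, manifest)

    @property
    def species_names(self) -> list[str]:
        return [s["name"] for s in self.manifest["species"]]

    @property
    def reference_species(self) -> str | None:
        return self.manifest.get("reference_species")

    def _species_entry(self, name: str) -> dict:
        for s in self.manifest["species"]:
            if s["name"] == name:
                return s
        raise KeyError(name)

    def load_genome(self, name: str) -> Genome:
        return tio.read_fasta(self.root / self._species_entry(name)["fasta"], species=name)

    def load_genes(self, name: str, genome: Genome | None = None) -> list[GeneModel]:
        return tio.read_gff3(self.root / self._species_entry(name)["gff3"], genome, species=name)

    def load_mask(self, name: str) -> list[MaskHit]:
        return tio.read_mask_table(self.root / self._species_entry(name)["mask_bed"])

    def crs_families(self, name: str) -> list[str]:
        return list(self._species_entry(name)["crs_families"])

    def load_domains(self) -> dict[str, set[str]]:
        return tio.read_domain_table(self.root / self.manifest["domains"])

    def load_clusters(self) -> OrthologClusters:
        universe = {}
        truth = self.truth_genes()
        for sp, sub in truth.groupby("species"):
            universe[sp] = set(sub["gene_id"])
        return tio.read_orthomcl_groups(self.root / self.manifest["groups"], universe)

    def load_landscape(self) -> ChromosomeLandscape:
        return ChromosomeLandscape.from_files(
            self.root / self.manifest["ref_sizes"],
            self.root / self.manifest["ref_centromeres"],
            self.root / self.manifest["ref_ies"],
        )

    def load_reps(self) -> list[RepCopy]:
        from tetlrr.te import read_rep_bed

        return read_rep_bed(self.root / self.manifest["rep_bed"])

    def tail_sequence(self) -> str:
        return self.manifest["rep_tail"]

    def load_values(self, kind: str) -> PerGeneValueTable:
        key = {"fpkm": "fpkm", "ka_ks": "kaks"}[kind]
        return tio.read_value_table(self.root / self.manifest[key], kind)

    def truth_genes(self):
        import pandas as pd

        return pd.read_csv(self.root / self.manifest["truth_genes"], sep="\t", keep_default_na=False)

    def truth_reps(self):
        import pandas as pd

        return pd.read_csv(self.root / self.manifest["truth_reps"], sep="\t")


def _build_payloads(
    profile: SpeciesProfile, rng: np.random.Generator
) -> tuple[dict[str, list[_GenePayload]], dict[str, _SeqPool]]:
    pools = {
        "cds": _SeqPool(rng, profile.gc_cds),
        "g3": _SeqPool(rng, profile.gc_cds_group3),
        "intergenic": _SeqPool(rng, profile.gc_intergenic),
    }
    template = _make_exon_template(rng, pools["g3"], profile.leucine_centers)
    mut_mask, _ = _template_masks(profile.leucine_centers)
    families = [f"CRS{i + 1}" for i in range(profile.n_crs_families)]
    consensi = {}
    for fam in families:
        cons = template.copy()
        _mutate(rng, cons, mut_mask, profile.family_divergence)
        _fix_frame_stops(cons, offset=1)
        consensi[fam] = cons
    out: dict[str, list[_GenePayload]] = {"bg": [], "g1": [], "g2": [], "g3": []}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{profile.name}_g{counter:05d}"

    bg_domains = ("Protein kinase domain", "EF-hand domain", "Ankyrin repeat", "WD40 repeat")
    for _ in range(profile.n_background):
        n_ex = int(rng.integers(1, 6))
        exons = _plain_gene_exons(rng, pools["cds"], n_ex, (100, 400))
        introns = _draw_introns(rng, profile.background_intron, n_ex - 1)
        dom = (bg_domains[int(rng.integers(0, len(bg_domains)))],) if rng.random() < 0.8 else ()
        strand = "+" if rng.random() < 0.5 else "-"
        out["bg"].append(_GenePayload(next_id(), profile.name, "bg", exons, introns, strand, domains=dom))
    for _ in range(profile.n_group1):
        n_ex = int(rng.integers(2, 9))
        exons = _plain_gene_exons(rng, pools["cds"], n_ex, (60, 200))
        introns = _draw_introns(rng, profile.background_intron, n_ex - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        out["g1"].append(
            _GenePayload(next_id(), profile.name, "I", exons, introns, strand, domains=LRR_DOMAIN_LABELS)
        )
    for _ in range(profile.n_group2):
        exons, _ = _lrr_gene_exons(rng, profile, template, "II", pools)
        introns = _draw_introns(rng, profile.background_intron, len(exons) - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        out["g2"].append(
            _GenePayload(next_id(), profile.name, "II", exons, introns, strand, domains=LRR_DOMAIN_LABELS)
        )
    fam_order = [families[i % len(families)] for i in range(profile.n_group3)]
    for i in range(profile.n_group3):
        fam = fam_order[i]
        exons, _ = _lrr_gene_exons(rng, profile, consensi[fam], "III", pools)
        introns = _draw_introns(rng, profile.group3_intron, len(exons) - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        domains = LRR_DOMAIN_LABELS if rng.random() < 0.9 else LRR_DOMAIN_LABELS + ("Protein kinase domain",)
        out["g3"].append(
            _GenePayload(
                next_id(), profile.name, "III", exons, introns, strand, family=fam, domains=domains
            )
        )
    return out, pools


def _build_tandem_blocks(
    spec: SyntheticGenomeSpec,
    payload_by_id: dict[str, _GenePayload],
    clusters: dict[str, dict[str, list[str]]],
    expansion_members: dict[str, list[str]],
    ids: dict[str, dict[str, list[str]]],
    gene_cluster: dict[str, str | None],
    rng: np.random.Generator,
) -> dict[str, list[_Item]]:
    """Build per-species tandem block items; marks payload.tandem_block."""
    ol = spec.orthologs
    blocks: dict[str, list[_Item]] = {p.name: [] for p in spec.species}

    def make_block(sp: str, block_id: str, gene_ids: list[str], region: str = "") -> None:
        genes = [payload_by_id[g] for g in gene_ids]
        for g in genes:
            g.tandem_block = block_id
        item = _Item(anchor=0, kind="block", genes=genes, reps=[None] * len(genes))
        blocks[sp].append(item)

    # the 17-strict / relaxed pattern inside the first expansion cluster
    if ol.include_17_block and "exp0" in expansion_members:
        host = next(sp for sp, g in clusters["exp0"].items() if len(g) > 2)
        members = expansion_members["exp0"]
        if len(members) >= 29:
            make_block(host, "strict17", members[:17])
            # relaxed run: triples of cluster genes separated by 1-2 singleton fillers
            fillers = [g for g in ids[host]["bg"] if gene_cluster[g] is None][:6]
            pattern: list[str] = []
            fill_i = 0
            chunk = members[17:29]
            for j in range(0, len(chunk), 3):
                pattern.extend(chunk[j : j + 3])
                if j + 3 < len(chunk) and fill_i < len(fillers):
                    pattern.append(fillers[fill_i])
                    fill_i += 1
            make_block(host, "relaxed_exp0", pattern)
    for profile in spec.species:
        sp = profile.name
        g3_cids = sorted(
            cid for cid in clusters if cid.startswith(f"g3s_{sp}_")
        )[: ol.n_strict_blocks_g3]
        for cid in g3_cids:
            make_block(sp, f"strict_{cid}", list(clusters[cid][sp]))
        g2_cids = sorted(cid for cid in clusters if cid.startswith(f"g2s_{sp}_"))[:1]
        for cid in g2_cids:
            make_block(sp, f"strict_{cid}", list(clusters[cid][sp]))
    return blocks


def generate(spec: SyntheticGenomeSpec, seed: int, outdir: str | Path) -> Bundle:
    """Generate a full bundle under ``outdir`` (created if needed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    species_seeds = master.spawn(len(spec.species) + 2)
    rng_global = np.random.default_rng(species_seeds[-1])

    ids: dict[str, dict[str, list[str]]] = {}
    payload_by_id: dict[str, _GenePayload] = {}
    species_pools: dict[str, dict[str, _SeqPool]] = {}
    species_rngs: dict[str, np.random.Generator] = {}
    for profile, seedseq in zip(spec.species, species_seeds):
        rng = np.random.default_rng(seedseq)
        payloads, pools = _build_payloads(profile, rng)
        species_pools[profile.name] = pools
        species_rngs[profile.name] = rng
        ids[profile.name] = {cls: [p.gene_id for p in payloads[cls]] for cls in payloads}
        for cls in payloads:
            for p in payloads[cls]:
                payload_by_id[p.gene_id] = p

    clusters, gene_cluster, expansion_members = _assign_clusters(spec, ids, rng_global)
    for gid, cid in gene_cluster.items():
        payload_by_id[gid].cluster = cid
    blocks = _build_tandem_blocks(
        spec, payload_by_id, clusters, expansion_members, ids, gene_cluster, rng_global
    )

    manifest: dict = {
        "species": [],
        "domains": "domains.tsv",
        "groups": "groups.txt",
        "fpkm": "fpkm.tsv",
        "kaks": "kaks.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_reps": "truth_reps.tsv",
        "rep_tail": spec.rep.tail,
        "seed": int(seed),
    }
    all_gene_truth: list[dict] = []
    all_rep_truth: list[dict] = []
    domain_rows: dict[str, set[str]] = {}
    reference = None

    for profile in spec.species:
        sp = profile.name
        rng = species_rngs[sp]
        pools = species_pools[sp]
        is_ref = profile.is_reference
        layout = spec.layout
        C = layout.n_chromosomes
        tag = "chr" if is_ref else "scf"
        chrom_names = [f"{sp}_{tag}{c + 1}" for c in range(C)]

        # collect items: blocks first, then unblocked genes, then REPs (reference)
        blocked_ids = {g.gene_id for it in blocks[sp] for g in it.genes}
        items_per_chrom: list[list[_Item]] = [[] for _ in range(C)]
        all_items: list[tuple[_Item, str]] = []  # (item, placement class)
        for it in blocks[sp]:
            cls = "weighted" if any(g.gene_class == "III" for g in it.genes) else "uniform"
            all_items.append((it, cls))
        for cls_name in ("bg", "g1", "g2", "g3"):
            for gid in ids[sp][cls_name]:
                if gid in blocked_ids:
                    continue
                p = payload_by_id[gid]
                it = _Item(anchor=0, kind="gene", genes=[p], reps=[None])
                all_items.append((it, "weighted" if p.gene_class == "III" else "uniform"))
        rep_items: list[_Item] = []
        if is_ref:
            reps = _make_rep_copies(rng, spec.rep, pools["intergenic"], sp)
            g3_slots: list[_Item] = [
                it for it, _cls in all_items if any(g.gene_class == "III" for g in it.genes)
            ]
            slot_order = [
                (i, j)
                for i in rng.permutation(len(g3_slots))
                for j in range(len(g3_slots[int(i)].genes))
                if g3_slots[int(i)].genes[j].gene_class == "III"
            ]
            slot_cursor = 0
            for rep in reps:
                rep.adjacent = rng.random() < spec.rep.adjacency_prob
                if rep.adjacent and slot_cursor < len(slot_order):
                    i, j = slot_order[slot_cursor]
                    g3_slots[int(i)].reps[j] = rep
                    slot_cursor += 1
                else:
                    rep.adjacent = False
                    rep_items.append(_Item(anchor=0, kind="rep", rep=rep))

        # chromosome assignment and anchors
        if is_ref:
            mds_targets = [layout.mds_length] * C
            regions = [_region_intervals(L, layout.region) for L in mds_targets]
            wp, ws, wa = layout.placement_weights
            weight_map = {"pericentromeric": wp, "subtelomeric": ws, "arm": wa}
        else:
            # plain MAC scaffolds sized to the items placed on them
            mds_targets = [0] * C
        assignments: list[tuple[_Item, str, int]] = []
        for it, cls in all_items + [(it, "weighted") for it in rep_items]:
            c = int(rng_global.integers(0, C))
            assignments.append((it, cls, c))
        if not is_ref:
            per_chrom_bp = [0] * C
            for it, _cls, c in assignments:
                per_chrom_bp[c] += sum(g.item_length for g in it.genes) + sum(
                    len(r.codes) for r in it.reps if r is not None
                )
            mds_targets = [max(300_000, bp * 3 + 50_000) for bp in per_chrom_bp]
        for it, cls, c in assignments:
            if is_ref:
                weights = weight_map if cls == "weighted" else None
                anchor, region = _sample_anchor(rng_global, regions[c], weights)
                it.anchor, it.region = anchor, region
            else:
                it.anchor = int(rng_global.integers(0, mds_targets[c]))
            items_per_chrom[c].append(it)

        genome_seqs: dict[str, str] = {}
        sp_genes: list[GeneModel] = []
        sp_mask: list[MaskHit] = []
        sp_reps: list[RepCopy] = []
        chrom_lengths: dict[str, int] = {}
        centromeres: dict[str, tuple[int, int]] = {}
        ies_out: dict[str, list[tuple[int, int, str]]] = {}
        for c, chrom in enumerate(chrom_names):
            asm = _ChromAssembler(chrom, layout, rng, pools, is_ref, mds_targets[c], profile)
            asm.run(items_per_chrom[c])
            codes = asm.sequence_codes
            genome_seqs[chrom] = _decode(codes)
            chrom_lengths[chrom] = len(codes)
            sp_genes.extend(asm.genes)
            sp_mask.extend(asm.mask_hits)
            sp_reps.extend(asm.reps)
            all_gene_truth.extend(asm.gene_truth)
            all_rep_truth.extend(asm.rep_truth)
            if is_ref:
                # decoy germline repeat families so the flanking ranking is
                # a real contest (random placement, no REP association)
                for fam, every in (("REP2_frag", 300_000), ("Low_complexity", 200_000)):
                    for _ in range(max(1, len(codes) // every)):
                        s = int(rng.integers(0, max(1, len(codes) - 500)))
                        L = int(rng.integers(100, 400))
                        sp_mask.append(MaskHit(chrom, s, s + L, fam, float(rng.integers(200, 400))))
                ies_sorted = sorted(asm.ies)
                ies_out[chrom] = [(s, e, "IES") for s, e in ies_sorted]
                # centromere: MIC interval around the MDS midpoint
                mds_mid = mds_targets[c] // 2
                cum = 0
                mic_mid = mds_mid
                for s, e in ies_sorted:
                    if s - cum <= mds_mid:
                        cum += e - s
                        mic_mid = mds_mid + cum
                    else:
                        break
                hw = layout.centromere_halfwidth
                centromeres[chrom] = (max(0, mic_mid - hw), min(len(codes), mic_mid + hw))

        genome = Genome(species=sp, sequences=genome_seqs)
        fasta = f"{sp}.fasta"
        gff = f"{sp}.gff3"
        mask_bed = f"{sp}.mask.bed"
        tio.write_fasta(genome, outdir / fasta)
        tio.write_gff3(sp_genes, outdir / gff)
        tio.write_mask_bed(sp_mask, outdir / mask_bed)
        entry = {
            "name": sp,
            "fasta": fasta,
            "gff3": gff,
            "mask_bed": mask_bed,
            "crs_families": [f"CRS{i + 1}" for i in range(profile.n_crs_families)],
            "is_reference": bool(is_ref),
        }
        manifest["species"].append(entry)
        for model in sp_genes:
            if model.domains:
                domain_rows[model.gene_id] = set(model.domains)
        if is_ref:
            reference = sp
            manifest["reference_species"] = sp
            manifest["ref_sizes"] = "ref.sizes.tsv"
            manifest["ref_centromeres"] = "ref.centromeres.bed"
            manifest["ref_ies"] = "ref.ies.bed"
            manifest["rep_bed"] = "ref.rep.bed"
            with open(outdir / "ref.sizes.tsv", "w") as fh:
                for chrom in chrom_names:
                    fh.write(f"{chrom}\t{chrom_lengths[chrom]}\n")
            tio.write_bed_intervals(
                {c: [(s, e, "centromere")] for c, (s, e) in centromeres.items()},
                outdir / "ref.centromeres.bed",
            )
            tio.write_bed_intervals(ies_out, outdir / "ref.ies.bed")
            from tetlrr.te import write_rep_bed

            write_rep_bed(sp_reps, outdir / "ref.rep.bed")

    # ortholog groups, domains, values, truth
    universe = {sp: set(gids for cls in ids[sp].values() for gids in cls) for sp in ids}
    oc = OrthologClusters(clusters, universe)
    tio.write_orthomcl_groups(oc, outdir / "groups.txt")
    tio.write_domain_table(domain_rows, outdir / "domains.tsv")

    # species-specific truth for the value models
    category = {cid: sum(1 for sp in by_sp if by_sp[sp]) for cid, by_sp in clusters.items()}
    expanded_genes = {g for members in expansion_members.values() for g in members}
    fpkm: dict[str, float] = {}
    kaks: dict[str, float] = {}
    for gid in sorted(payload_by_id):
        cid = gene_cluster[gid]
        specific = cid is None or category[cid] == 1 or gid in expanded_genes
        fpkm[gid] = round(float(rng_global.lognormal(np.log(5.0 if specific else 20.0), 1.0)), 3)
        kaks[gid] = round(
            float(min(2.0, rng_global.lognormal(np.log(0.3 if specific else 0.05), 0.4))), 4
        )
    tio.write_value_table(PerGeneValueTable(fpkm, "fpkm"), outdir / "fpkm.tsv")
    tio.write_value_table(PerGeneValueTable(kaks, "ka_ks"), outdir / "kaks.tsv")

    import pandas as pd

    pd.DataFrame(all_gene_truth).sort_values(["species", "scaffold", "start"]).to_csv(
        outdir / "truth_genes.tsv", sep="\t", index=False
    )
    rep_cols = [
        "rep_id", "scaffold", "start", "end", "strand", "adjacent", "functional",
        "orf1_intact", "orf2_intact",
    ]
    pd.DataFrame(all_rep_truth, columns=rep_cols).sort_values(["scaffold", "start"]).to_csv(
        outdir / "truth_reps.tsv", sep="\t", index=False
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return Bundle(outdir, manifest)


def make_fixture(name: str, outdir: str | Path, seed: int = 42) -> Bundle:
    """Generate (or reuse) one of the named fixture bundles.

    ``toy`` (~30 genes, 2 species), ``default`` (~2,000 LRR genes, 3
    species), ``stress`` (10 species spanning ortholog categories I-X).
    An existing bundle at ``outdir`` generated with the same name and seed
    is reused.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    outdir = Path(outdir)
    marker = outdir / "manifest.yaml"
    if marker.exists():
        bundle = Bundle.open(outdir)
        if bundle.manifest.get("fixture") == name and bundle.manifest.get("seed") == seed:
            return bundle
    bundle = generate(FIXTURES[name](), seed, outdir)
    bundle.manifest["fixture"] = name
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
    return bundle
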