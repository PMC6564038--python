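"""Readers and writers for the external formats and the internal data model.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive)
and RepeatMasker ``.out`` (1-based) are converted at the boundary.  "Exon"
throughout the package means CDS segment: intron phases and translation are
defined only on coding sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

logger = logging.getLogger("tetlrr")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Scaffold id -> nucleotide sequence (uppercase A/C/G/T/N) for one species."""

    species: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for scaffold {sid!r}")

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.sequences

    def length(self, scaffold: str) -> int:
        return len(self.sequences[scaffold])


@dataclass(frozen=True)
class GeneModel:
    """One gene's stranded, ordered CDS exon intervals on a scaffold.

    ``exons`` are (start, end) 0-based half-open scaffold intervals listed in
    transcription order: ascending start for ``+`` genes, descending for
    ``-`` genes.
    """

    gene_id: str
    species: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    domains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.gene_id}: bad exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        spans = sorted(self.exons)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def intron_lengths(self) -> list[int]:
        """Genomic intron lengths in transcription order (len = n_exons - 1)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append(s2 - e1 if self.strand == "+" else s1 - e2)
        return out

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons: CDS plus introns."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def start(self) -> int:
        """Leftmost genomic CDS coordinate (used for positioning on tracks)."""
        return self.span[0]

    def exon_sequences(self, genome: Genome) -> list[str]:
        """Coding-strand exon sequences in transcription order."""
        chrom = genome.sequences[self.scaffold]
        out = []
        for s, e in self.exons:
            seq = chrom[s:e]
            out.append(seq if self.strand == "+" else revcomp(seq))
        return out

    def cds_sequence(self, genome: Genome) -> str:
        return "".join(self.exon_sequences(genome))


@dataclass(frozen=True)
class MaskHit:
    """A repeat-family hit (RepeatMasker-style) on a scaffold."""

    scaffold: str
    start: int
    end: int
    family: str
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative mask score {self.score} on {self.scaffold}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad mask interval ({self.start}, {self.end})")


class OrthologClusters:
    """Cluster id -> {species -> [gene ids]} plus each species' gene universe."""

    def __init__(
        self,
        clusters: Mapping[str, Mapping[str, Sequence[str]]],
        universe: Mapping[str, Iterable[str]],
    ) -> None:
        self.universe: dict[str, set[str]] = {sp: set(g) for sp, g in universe.items()}
        self.clusters: dict[str, dict[str, list[str]]] = {}
        seen: dict[str, str] = {}
        for cid, by_sp in clusters.items():
            self.clusters[cid] = {}
            for sp, genes in by_sp.items():
                if sp not in self.universe:
                    raise ValueError(f"cluster {cid}: unknown species tag {sp!r}")
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g!r} appears in clusters {seen[g]} and {cid}")
                    seen[g] = cid
                    if g not in self.universe[sp]:
                        raise ValueError(f"cluster {cid}: gene {g!r} absent from {sp} universe")
                self.clusters[cid][sp] = list(genes)

    @property
    def species(self) -> list[str]:
        return sorted(self.universe)

    def gene_to_cluster(self) -> dict[str, str]:
        out = {}
        for cid, by_sp in self.clusters.items():
            for genes in by_sp.values():
                for g in genes:
                    out[g] = cid
        return out

    def singletons(self, species: str) -> set[str]:
        clustered = set()
        for by_sp in self.clusters.values():
            clustered.update(by_sp.get(species, ()))
        return self.universe[species] - clustered


@dataclass
class PerGeneValueTable:
    """Gene id -> numeric value with a kind tag (ka_ks, fpkm, other)."""

    values: dict[str, float]
    kind: str = "other"

    def __post_init__(self) -> None:
        import math

        for g, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for gene {g!r}")
            if self.kind == "fpkm" and v < 0:
                raise ValueError(f"negative FPKM for gene {g!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID = set("ACGTN")


def read_fasta(path: str | Path, species: str = "") -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased, U is mapped to T, and any residual
    non-A/C/G/T/N symbol is mapped to N (the substitution count is logged).
    Duplicate scaffold ids and empty records raise.
    """
    sequences: dict[str, str] = {}
    substituted = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        if not set(seq) <= _VALID:
            cleaned = "".join(c if c in _VALID else "N" for c in seq)
            substituted += sum(1 for a, b in zip(seq, cleaned) if a != b)
            seq = cleaned
        sequences[rec.id] = seq
    if substituted:
        logger.info("read_fasta(%s): %d non-ACGTN symbols mapped to N", path, substituted)
    return Genome(species=species, sequences=sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid in genome.sequences:
            fh.write(f">{sid}\n")
            seq = genome.sequences[sid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, genome: Genome | None = None, species: str = "") -> list[GeneModel]:
    """Parse gene models from a GFF3 file (gene/mRNA/CDS features).

    When a gene has several transcripts the one with the longest total CDS is
    kept (ties: lexicographically smallest transcript id).  Genes whose CDS
    length is not divisible by 3 are excluded with a warning; a CDS outside
    the scaffold bounds (when ``genome`` is given) is an error.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##gff-version 3"):
        raise ValueError(f"{path}: missing '##gff-version 3' header")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    if not species and genome is not None:
        species = genome.species
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        candidates: list[tuple[int, str, list]] = []
        if transcripts:
            for t in transcripts:
                cds = list(db.children(t, featuretype="CDS"))
                if cds:
                    candidates.append((sum(c.end - c.start + 1 for c in cds), t.id, cds))
        else:
            cds = list(db.children(gene, featuretype="CDS"))
            if cds:
                candidates.append((sum(c.end - c.start + 1 for c in cds), gene.id, cds))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1]))
        total, _tid, cds = candidates[0]
        if total % 3 != 0:
            warnings.warn(
                f"gene {gene.id}: CDS length {total} not divisible by 3; excluded",
                stacklevel=2,
            )
            continue
        # GFF3 1-based inclusive -> 0-based half-open
        intervals = sorted((c.start - 1, c.end) for c in cds)
        if genome is not None:
            if gene.seqid not in genome:
                raise ValueError(f"gene {gene.id}: scaffold {gene.seqid!r} not in genome")
            if intervals[-1][1] > genome.length(gene.seqid):
                raise ValueError(f"gene {gene.id}: CDS outside scaffold bounds")
        if gene.strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                scaffold=gene.seqid,
                strand=gene.strand,
                exons=tuple(intervals),
            )
        )
    return models


def _gff3_phases(lengths: Sequence[int]) -> list[int]:
    """GFF3 phase column per CDS segment in transcription order."""
    phases, cum = [], 0
    for length in lengths:
        phases.append((3 - cum % 3) % 3)
        cum += length
    return phases


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "tetlrr") -> None:
    """Write gene models as gene/mRNA/CDS rows, deterministically sorted."""
    rows = []
    for g in sorted(genes, key=lambda g: (g.scaffold, g.span[0], g.gene_id)):
        span_s, span_e = g.span
        rows.append((g.scaffold, "gene", span_s + 1, span_e, g.strand, ".", f"ID={g.gene_id}"))
        tid = f"{g.gene_id}.t1"
        rows.append((g.scaffold, "mRNA", span_s + 1, span_e, g.strand, ".", f"ID={tid};Parent={g.gene_id}"))
        phases = _gff3_phases(g.exon_lengths)
        for i, ((s, e), ph) in enumerate(zip(g.exons, phases), 1):
            rows.append((g.scaffold, "CDS", s + 1, e, g.strand, str(ph), f"ID={tid}.cds{i};Parent={tid}"))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold, ftype, start, end, strand, phase, attrs in rows:
            fh.write(f"{scaffold}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attrs}\n")


# ---------------------------------------------------------------------------
# repeat-mask tables
# ---------------------------------------------------------------------------

MASK_DIALECTS = ("bed6+family", "repeatmasker_out")


def read_mask_table(path: str | Path, dialect: str = "bed6+family") -> list[MaskHit]:
    """Read repeat-family hits from BED6 (family in col 4, score col 5) or a
    RepeatMasker ``.out`` file (1-based begin converted to 0-based)."""
    if dialect not in MASK_DIALECTS:
        raise ValueError(f"unknown mask dialect {dialect!r}; choose from {MASK_DIALECTS}")
    hits: list[MaskHit] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if dialect == "bed6+family":
                if fields[0].startswith(("#", "track")):
                    continue
                scaffold, start, end, family = fields[0], int(fields[1]), int(fields[2]), fields[3]
                score = float(fields[4]) if len(fields) > 4 else 0.0
                strand = fields[5] if len(fields) > 5 else "+"
            else:  # repeatmasker_out
                if fields[0] in ("SW", "score") or not fields[0][0].isdigit():
                    continue
                score = float(fields[0])
                scaffold = fields[4]
                start, end = int(fields[5]) - 1, int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                family = fields[9]
            hits.append(MaskHit(scaffold, start, end, family, score, strand))
    return hits


def write_mask_bed(hits: Sequence[MaskHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.scaffold, h.start, h.end, h.family)):
            fh.write(f"{h.scaffold}\t{h.start}\t{h.end}\t{h.family}\t{h.score:g}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# OrthoMCL groups
# ---------------------------------------------------------------------------


def read_orthomcl_groups(path: str | Path, universe: Mapping[str, Iterable[str]]) -> OrthologClusters:
    """Parse an OrthoMCL ``groups.txt`` dialect: ``cid: spA|g1 spB|g2 ...``."""
    clusters: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            by_sp: dict[str, list[str]] = {}
            for token in rest.split():
                sp, _, gid = token.partition("|")
                if not gid:
                    raise ValueError(f"cluster {cid}: malformed member {token!r}")
                by_sp.setdefault(sp, []).append(gid)
            clusters[cid] = by_sp
    return OrthologClusters(clusters, universe)


def write_orthomcl_groups(clusters: OrthologClusters, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(clusters.clusters):
            members = []
            for sp in sorted(clusters.clusters[cid]):
                members.extend(f"{sp}|{g}" for g in clusters.clusters[cid][sp])
            fh.write(f"{cid}: {' '.join(members)}\n")


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------


def read_value_table(path: str | Path, kind: str = "other") -> PerGeneValueTable:
    """Two-column TSV ``gene<TAB>value`` (header optional)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("gene", "gene_id"):
                continue
            values[fields[0]] = float(fields[1])
    return PerGeneValueTable(values, kind)


def write_value_table(table: PerGeneValueTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for g in sorted(table.values):
            fh.write(f"{g}\t{table.values[g]:g}\n")


def read_domain_table(path: str | Path) -> dict[str, set[str]]:
    """TSV ``gene<TAB>domain[;domain...]`` -> gene id -> set of domain labels."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("gene", "gene_id"):
                continue
            labels = {d for d in fields[1].split(";") if d}
            out.setdefault(fields[0], set()).update(labels)
    return out


def write_domain_table(domains: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomains\n")
        for g in sorted(domains):
            fh.write(f"{g}\t{';'.join(sorted(domains[g]))}\n")


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """BED3/4 -> chrom -> sorted list of (start, end, name)."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track")):
                continue
            name = fields[3] if len(fields) > 3 else ""
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2]), name))
    for chrom in out:
        out[chrom].sort()
    return out


def write_bed_intervals(intervals: Mapping[str, Sequence[tuple[int, int, str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e, name in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n" if name else f"{chrom}\t{s}\t{e}\n")
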