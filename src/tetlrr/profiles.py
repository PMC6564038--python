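"""Position profiles, consensus calls and near-identity clustering of the
naturally aligned 90-bp exons.

Because every array exon is exactly 90 bp long, the exons align without any
alignment step.  With phase-2 flanking introns the first nucleotide and the
last two belong to junction codons shared with neighbouring exons, so the
amino-acid view of an exon is the 29 codons spanned by nucleotides 2..88.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import binom

from tetlrr.architecture import GENETIC_CODES, array_exon_indices
from tetlrr.io import GeneModel, Genome

logger = logging.getLogger("tetlrr")

NT_SYMBOLS = ("A", "C", "G", "T")


@dataclass
class ExonMatrix:
    """Rows of exactly-90-nt exon sequences with per-row metadata.

    ``meta`` has one row per sequence with columns gene_id, species, group,
    family and exon_index.  ``aa_view()`` yields the 29-residue translations
    of nucleotides 2..88 under the ciliate nuclear code.
    """

    sequences: list[str]
    meta: pd.DataFrame
    target_len: int = 90

    def __post_init__(self) -> None:
        for s in self.sequences:
            if len(s) != self.target_len:
                raise ValueError(f"row length {len(s)} != {self.target_len}")
        if len(self.meta) != len(self.sequences):
            raise ValueError("metadata rows != sequence rows")

    def __len__(self) -> int:
        return len(self.sequences)

    def aa_view(self, code: str = "ciliate") -> list[str]:
        table = GENETIC_CODES[code]
        return [str(Seq(s[1 : self.target_len - 2]).translate(table=table)) for s in self.sequences]

    def subset(self, mask: np.ndarray) -> "ExonMatrix":
        seqs = [s for s, keep in zip(self.sequences, mask) if keep]
        return ExonMatrix(seqs, self.meta[mask].reset_index(drop=True), self.target_len)


@dataclass
class PositionProfile:
    """Per-column symbol frequencies; each column sums to 1."""

    freqs: pd.DataFrame  # index: symbols; columns: 1-based positions
    n: int
    level: str  # "nt" or "aa"


def build_exon_matrix(
    genes: Sequence[GeneModel],
    genomes: Mapping[str, Genome],
    target_len: int = 90,
    group_of: Mapping[str, str] | None = None,
    family_of: Mapping[str, str] | None = None,
    groups: Iterable[str] | None = None,
    species: Iterable[str] | None = None,
    families: Iterable[str] | None = None,
    arrays_only: bool = False,
    min_run: int = 3,
) -> ExonMatrix:
    """One row per exactly-``target_len`` exon passing the filters, in
    coding-strand orientation.  Raises if no row survives."""
    groups = set(groups) if groups is not None else None
    species = set(species) if species is not None else None
    families = set(families) if families is not None else None
    seqs: list[str] = []
    meta_rows: list[dict] = []
    for gene in genes:
        if species is not None and gene.species not in species:
            continue
        grp = group_of.get(gene.gene_id, "") if group_of else ""
        if groups is not None and grp not in groups:
            continue
        fam = family_of.get(gene.gene_id, "") if family_of else ""
        if families is not None and fam not in families:
            continue
        keep = (
            array_exon_indices(gene, target_len, min_run)
            if arrays_only
            else {i + 1 for i, L in enumerate(gene.exon_lengths) if L == target_len}
        )
        if not keep:
            continue
        exon_seqs = gene.exon_sequences(genomes[gene.species])
        for idx in sorted(keep):
            seqs.append(exon_seqs[idx - 1])
            meta_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "species": gene.species,
                    "group": grp,
                    "family": fam,
                    "exon_index": idx,
                }
            )
    if not seqs:
        raise ValueError(
            "build_exon_matrix: no exons pass the filter "
            f"(groups={groups}, species={species}, families={families})"
        )
    return ExonMatrix(seqs, pd.DataFrame(meta_rows), target_len)


def position_profile(matrix: ExonMatrix, level: str = "nt", code: str = "ciliate") -> PositionProfile:
    """Column-wise symbol frequencies of the nucleotide or amino-acid view.

    At the nt level only A/C/G/T are counted (N is ignored and the column
    renormalized); at the aa level the observed residue alphabet is used,
    with glutamine from TAA/TAG reported as Q by the ciliate code.
    """
    if len(matrix) == 0:
        raise ValueError("position_profile: empty matrix")
    if level == "nt":
        rows = matrix.sequences
        symbols = list(NT_SYMBOLS)
    elif level == "aa":
        rows = matrix.aa_view(code)
        symbols = sorted({c for r in rows for c in r})
    else:
        raise ValueError(f"unknown level {level!r}")
    ncol = len(rows[0])
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), ncol)
    freqs = np.zeros((len(symbols), ncol))
    for i, sym in enumerate(symbols):
        freqs[i] = (arr == sym.encode()).sum(axis=0)
    col_totals = freqs.sum(axis=0)
    col_totals[col_totals == 0] = 1.0
    freqs /= col_totals
    df = pd.DataFrame(freqs, index=symbols, columns=range(1, ncol + 1))
    return PositionProfile(freqs=df, n=len(rows), level=level)


def consensus(profile: PositionProfile) -> str:
    """Per-column argmax; ties broken by the fixed symbol order of the
    profile index (A<C<G<T for nt, alphabetical for aa)."""
    df = profile.freqs.sort_index()
    return "".join(df.index[np.argmax(df[c].to_numpy())] for c in df.columns)


def codon_index_of_nt(position_1based: int) -> int:
    """Map an exon nucleotide position to its codon index in the 29-residue
    frame of a phase-2-flanked 90-bp exon.

    Codon *k* spans nucleotides 3k-1..3k+1, so position 48 is the centre of
    codon 16.  Positions 1, 89 and 90 belong to junction codons and raise.
    """
    if not 2 <= position_1based <= 88:
        raise ValueError(f"position {position_1based} is a junction nucleotide or out of frame")
    return (position_1based - 2) // 3 + 1


def conserved_positions(
    profile: PositionProfile, symbol: str = "L", min_freq: float = 0.5
) -> list[int]:
    """Columns (ascending) where the symbol's frequency reaches ``min_freq``."""
    if symbol not in profile.freqs.index:
        return []
    row = profile.freqs.loc[symbol]
    return [int(c) for c in profile.freqs.columns if row[c] >= min_freq]


def two_sample_logo(
    matrix_a: ExonMatrix,
    matrix_b: ExonMatrix,
    level: str = "nt",
    alpha: float = 1e-5,
    code: str = "ciliate",
) -> pd.DataFrame:
    """Per-position enriched/depleted symbol calls (A versus B).

    For each column and symbol, the count k among the |A| rows of sample A
    is tested against the symbol's frequency in sample B as the null
    proportion (floored/capped by the pseudo-frequency 1/(|B|+2) so the
    binomial tails never degenerate): one-sided tails P[X >= k]
    (enrichment) and P[X <= k] (depletion).  Calls are rows with p < alpha;
    effect = freq_A - freq_B.
    """
    prof_a = position_profile(matrix_a, level, code)
    prof_b = position_profile(matrix_b, level, code)
    n_a, n_b = prof_a.n, prof_b.n
    if min(n_a, n_b) < 20:
        warnings.warn(f"two_sample_logo: small sample (|A|={n_a}, |B|={n_b}); underpowered", stacklevel=2)
    symbols = sorted(set(prof_a.freqs.index) | set(prof_b.freqs.index))
    fa = prof_a.freqs.reindex(symbols, fill_value=0.0)
    fb = prof_b.freqs.reindex(symbols, fill_value=0.0)
    pseudo = 1.0 / (n_b + 2)
    p0 = fb.to_numpy().clip(pseudo, 1.0 - pseudo)
    k = np.rint(fa.to_numpy() * n_a).astype(int)
    p_enriched = binom.sf(k - 1, n_a, p0)
    p_depleted = binom.cdf(k, n_a, p0)
    effect = fa.to_numpy() - fb.to_numpy()
    calls = []
    for i, sym in enumerate(symbols):
        for j, col in enumerate(fa.columns):
            if p_enriched[i, j] < alpha:
                calls.append((int(col), sym, "enriched", float(p_enriched[i, j]), float(effect[i, j])))
            elif p_depleted[i, j] < alpha:
                calls.append((int(col), sym, "depleted", float(p_depleted[i, j]), float(effect[i, j])))
    return pd.DataFrame(calls, columns=["position", "symbol", "direction", "p", "effect"])


def _pairwise_hamming_edges(rows: list[str], max_mismatch: int, block: int = 512):
    """Yield (i, j) pairs of rows at Hamming distance <= max_mismatch."""
    n = len(rows)
    if n < 2:
        return
    L = len(rows[0])
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(n, L)
    for i0 in range(0, n, block):
        a = arr[i0 : i0 + block]
        for j0 in range(i0, n, block):
            b = arr[j0 : j0 + block]
            # mismatches between all pairs in the two blocks
            d = (a[:, None, :] != b[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d <= max_mismatch)
            for i, j in zip(ii, jj):
                gi, gj = i0 + int(i), j0 + int(j)
                if gi < gj:
                    yield gi, gj


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_near_identical(matrix: ExonMatrix, max_mismatch: int = 2) -> list[list[int]]:
    """Single-linkage clusters of rows at pairwise Hamming distance <=
    ``max_mismatch`` (>= 97% identity over 90 bp when ``max_mismatch=2``).

    Returns connected components as lists of row indices, sorted by size
    descending (ties: smallest member index).
    """
    n = len(matrix)
    dsu = _DSU(n)
    for i, j in _pairwise_hamming_edges(matrix.sequences, max_mismatch):
        dsu.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(dsu.find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: (-len(c), c[0]))


def cluster_table(matrix: ExonMatrix, clusters: Sequence[Sequence[int]]) -> pd.DataFrame:
    """Tabulate clusters with their member genes and scaffolds/chromosome
    labels (largest first)."""
    rows = []
    for rank, members in enumerate(clusters, 1):
        sub = matrix.meta.iloc[list(members)]
        rows.append(
            {
                "cluster_rank": rank,
                "size": len(members),
                "n_genes": sub["gene_id"].nunique(),
                "genes": ";".join(sorted(sub["gene_id"].unique())),
                "species": ";".join(sorted(sub["species"].unique())),
            }
        )
    return pd.DataFrame(rows)


def family_consensus_distance_matrix(
    matrices: Mapping[tuple[str, str] | str, ExonMatrix], min_rows: int = 3
) -> pd.DataFrame:
    """Pairwise Hamming/L distances between per-group consensus sequences.

    Groups with fewer than ``min_rows`` rows are excluded with a warning.
    The resulting labelled square matrix (zero diagonal, symmetric) can be
    exported with :func:`write_phylip` for external tree building.
    """
    labels, seqs = [], []
    for key in sorted(matrices, key=str):
        m = matrices[key]
        if len(m) < min_rows:
            warnings.warn(f"group {key!r} has {len(m)} rows (<{min_rows}); excluded", stacklevel=2)
            continue
        labels.append("|".join(key) if isinstance(key, tuple) else str(key))
        seqs.append(consensus(position_profile(m, "nt")))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with enough rows")
    L = len(seqs[0])
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j])) / L
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=labels, columns=labels)


def write_phylip(dist: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled square distance matrix in PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for label in dist.index:
            name = str(label)[:32].replace(" ", "_")
            vals = " ".join(f"{v:.6f}" for v in dist.loc[label])
            fh.write(f"{name}  {vals}\n")
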