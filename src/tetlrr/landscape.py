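"""Germline (MIC) chromosome landscapes in IES-omitted coordinates.

The MAC-destined sequence (MDS) coordinate of a MIC position is the
position minus the total IES bp strictly before it; positions inside an
IES collapse to the IES's left edge and are flagged.  Chromosomes are cut
into ~1-Mb bins of MDS sequence, and each MDS position is labelled
pericentromeric (within a half-width of the centromere midpoint),
subtelomeric (terminal stretch at either end) or arm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu

from tetlrr.io import GeneModel, read_bed_intervals

logger = logging.getLogger("tetlrr")

REGIONS = ("pericentromeric", "subtelomeric", "arm")


@dataclass
class RegionParams:
    """Region definitions in MDS coordinates.

    ``peri_halfwidth`` bp on each side of the centromere midpoint (default
    1 Mb, i.e. a ~2 Mb pericentromeric span) and ``subtel_len`` bp at each
    chromosome end (default 1 Mb); the pericentromeric label takes
    precedence when the parameters overlap.  These spans are deliberately
    coarse, descriptive cut-offs, and are configurable.
    """

    peri_halfwidth: int = 1_000_000
    subtel_len: int = 1_000_000


class ChromosomeLandscape:
    """Chromosome lengths, centromere intervals and IES intervals (MIC
    coordinates), with the machinery for IES-omitted (MDS) positions."""

    def __init__(
        self,
        lengths: Mapping[str, int],
        centromeres: Mapping[str, tuple[int, int]],
        ies: Mapping[str, Sequence[tuple[int, int]]],
    ) -> None:
        self.lengths = dict(lengths)
        self.centromeres = dict(centromeres)
        self.ies: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, length in self.lengths.items():
            intervals = sorted(ies.get(chrom, ()))
            prev_end = 0
            for s, e in intervals:
                if s < prev_end:
                    raise ValueError(f"{chrom}: IES intervals overlap or are unsorted")
                if not 0 <= s < e <= length:
                    raise ValueError(f"{chrom}: IES interval ({s}, {e}) out of bounds")
                prev_end = e
            cs, ce = self.centromeres.get(chrom, (0, 0))
            if not 0 <= cs <= ce <= length:
                raise ValueError(f"{chrom}: centromere out of bounds")
            self.ies[chrom] = intervals
            self._starts[chrom] = np.array([s for s, _ in intervals], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in intervals], dtype=np.int64)
            lens = self._ends[chrom] - self._starts[chrom]
            self._cum[chrom] = np.concatenate([[0], np.cumsum(lens)])

    @classmethod
    def from_files(
        cls,
        sizes_path: str | Path,
        centromere_bed: str | Path | None = None,
        ies_bed: str | Path | None = None,
    ) -> "ChromosomeLandscape":
        """``sizes_path`` is a two-column TSV (chrom, length); centromeres
        and IESs are BED files."""
        lengths: dict[str, int] = {}
        with open(sizes_path) as fh:
            for line in fh:
                fields = line.split()
                if len(fields) >= 2 and not fields[0].startswith("#"):
                    lengths[fields[0]] = int(fields[1])
        centromeres = {}
        if centromere_bed is not None:
            for chrom, ivs in read_bed_intervals(centromere_bed).items():
                centromeres[chrom] = (ivs[0][0], ivs[0][1])
        ies = {}
        if ies_bed is not None:
            for chrom, ivs in read_bed_intervals(ies_bed).items():
                ies[chrom] = [(s, e) for s, e, _ in ivs]
        return cls(lengths, centromeres, ies)

    def ies_bp(self, chrom: str) -> int:
        return int(self._cum[chrom][-1]) if len(self._cum[chrom]) else 0

    def mds_length(self, chrom: str) -> int:
        """Total MDS (IES-omitted) length of the chromosome."""
        return self.lengths[chrom] - self.ies_bp(chrom)

    def mds_coordinate(self, chrom: str, position: int) -> tuple[int, bool]:
        """(IES-omitted position, inside-IES flag).

        Positions inside an IES map to the IES's left edge in MDS
        coordinates and are flagged.
        """
        if not 0 <= position <= self.lengths[chrom]:
            raise ValueError(f"{chrom}: position {position} out of bounds [0, {self.lengths[chrom]}]")
        starts, ends, cum = self._starts[chrom], self._ends[chrom], self._cum[chrom]
        i = int(np.searchsorted(starts, position, side="right"))
        if i > 0 and position < ends[i - 1]:  # inside IES i-1
            return int(starts[i - 1] - cum[i - 1]), True
        return int(position - cum[i]), False

    def centromere_midpoint_mds(self, chrom: str) -> int:
        """Midpoint of the centromere interval, after IES omission."""
        cs, ce = self.centromeres[chrom]
        mid, _ = self.mds_coordinate(chrom, (cs + ce) // 2)
        return mid


def region_of(
    landscape: ChromosomeLandscape,
    chrom: str,
    mds_position: int,
    params: RegionParams | None = None,
) -> str:
    """Region label of an MDS position (pericentromeric > subtelomeric > arm)."""
    params = params or RegionParams()
    mid = landscape.centromere_midpoint_mds(chrom)
    if abs(mds_position - mid) <= params.peri_halfwidth:
        return "pericentromeric"
    L = landscape.mds_length(chrom)
    if mds_position < params.subtel_len or mds_position >= L - params.subtel_len:
        return "subtelomeric"
    return "arm"


@dataclass
class BinTrack:
    """Per-chromosome per-bin values over MDS coordinates; bins tile each
    chromosome's MDS length (the last bin may be short)."""

    bin_width: int
    mode: str
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.values):
            for i, v in enumerate(self.values[chrom]):
                rows.append({"chrom": chrom, "bin": i, "start": i * self.bin_width, "value": v})
        return pd.DataFrame(rows)


def bin_values(
    items: Iterable[tuple[str, int, float | None]],
    landscape: ChromosomeLandscape,
    bin_width: int = 1_000_000,
    mode: str = "count",
    all_items: Iterable[tuple[str, int]] | None = None,
) -> BinTrack:
    """Aggregate (chrom, MIC position[, value]) items into MDS bins.

    ``mode``: "count" (items per bin), "median" (median of values per bin)
    or "fraction_of_bin_genes" (item count divided by the count of
    ``all_items`` in the bin).  Items inside an IES are excluded.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if mode not in ("count", "median", "fraction_of_bin_genes"):
        raise ValueError(f"unknown mode {mode!r}")
    n_bins = {
        chrom: max(1, -(-landscape.mds_length(chrom) // bin_width)) for chrom in landscape.lengths
    }
    per_bin: dict[str, list[list[float]]] = {c: [[] for _ in range(n)] for c, n in n_bins.items()}
    for chrom, pos, *rest in items:
        mds, inside = landscape.mds_coordinate(chrom, pos)
        if inside:
            continue
        b = min(mds // bin_width, n_bins[chrom] - 1)
        per_bin[chrom][b].append(rest[0] if rest and rest[0] is not None else 1.0)
    track = BinTrack(bin_width=bin_width, mode=mode)
    if mode == "fraction_of_bin_genes":
        denom = bin_values(((c, p, None) for c, p in all_items), landscape, bin_width, "count")
    for chrom, bins in per_bin.items():
        if mode == "count":
            track.values[chrom] = np.array([float(len(b)) for b in bins])
        elif mode == "median":
            track.values[chrom] = np.array([float(np.median(b)) if b else np.nan for b in bins])
        else:
            d = denom.values[chrom]
            track.values[chrom] = np.array(
                [len(b) / d[i] if d[i] else np.nan for i, b in enumerate(bins)]
            )
    return track


def regions_of_genes(
    genes: Iterable[GeneModel],
    landscape: ChromosomeLandscape,
    params: RegionParams | None = None,
) -> pd.DataFrame:
    """Per-gene MDS position and region label (genes positioned by CDS
    start; genes inside an IES are flagged and given no region)."""
    rows = []
    for g in genes:
        if g.scaffold not in landscape.lengths:
            continue
        mds, inside = landscape.mds_coordinate(g.scaffold, g.start)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.scaffold,
                "mds_position": mds,
                "inside_ies": inside,
                "region": "" if inside else region_of(landscape, g.scaffold, mds, params),
            }
        )
    return pd.DataFrame(rows)


def region_enrichment(
    subset_regions: Sequence[str], all_regions: Sequence[str]
) -> tuple[pd.DataFrame, float | None]:
    """2x3 subset-vs-complement counts across regions with a chi-squared p.

    ``all_regions`` must contain the subset.  Regions empty in both rows
    are dropped; if fewer than two informative regions remain the test is
    skipped (p = None) with a warning.
    """
    sub = pd.Series(subset_regions).value_counts()
    tot = pd.Series(all_regions).value_counts()
    table = pd.DataFrame(
        {r: [int(sub.get(r, 0)), int(tot.get(r, 0)) - int(sub.get(r, 0))] for r in REGIONS},
        index=["subset", "complement"],
    )
    informative = [r for r in REGIONS if table[r].sum() > 0]
    if len(informative) < 2 or table.loc["subset"].sum() == 0 or table.loc["complement"].sum() == 0:
        warnings.warn("region_enrichment: degenerate table; test skipped", stacklevel=2)
        return table, None
    _, p, _, _ = chi2_contingency(table[informative])
    return table, float(p)


def value_comparison(values_by_region: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Mann-Whitney U tests of per-gene values between
    regions (pairs with an empty side are skipped)."""
    out: dict[tuple[str, str], float] = {}
    regions = [r for r in sorted(values_by_region) if len(values_by_region[r])]
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1 :]:
            _, p = mannwhitneyu(values_by_region[r1], values_by_region[r2], alternative="two-sided")
            out[(r1, r2)] = float(p)
    return out


def ies_gene_association(
    landscape: ChromosomeLandscape, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associate each IES with its nearest gene on either side (edge
    distance) or with the gene containing it within an intron.

    Returns (per-IES table, per-gene table with a ``flanked_by_ies`` flag:
    some IES lies between the gene and an adjacent gene, or within one of
    its introns).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.scaffold, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.span[0])
    flagged: set[str] = set()
    ies_rows = []
    for chrom in sorted(landscape.ies):
        chrom_genes = by_chrom.get(chrom, [])
        starts = np.array([g.span[0] for g in chrom_genes], dtype=np.int64)
        ends = np.array([g.span[1] for g in chrom_genes], dtype=np.int64)
        for ies_s, ies_e in landscape.ies[chrom]:
            containing = ""
            left = right = ""
            # gene containing the IES (within an intron: inside the span but
            # outside every exon)
            if len(chrom_genes):
                cand = np.nonzero((starts <= ies_s) & (ends >= ies_e))[0]
                for ci in cand:
                    g = chrom_genes[ci]
                    if all(e <= ies_s or s >= ies_e for s, e in g.exons):
                        containing = g.gene_id
                        flagged.add(g.gene_id)
                        break
                if not containing:
                    # nearest gene ending at or before the IES start
                    lefts = np.nonzero(ends <= ies_s)[0]
                    if len(lefts):
                        left = chrom_genes[lefts[np.argmax(ends[lefts])]].gene_id
                        flagged.add(left)
                    rights = np.nonzero(starts >= ies_e)[0]
                    if len(rights):
                        right = chrom_genes[rights[np.argmin(starts[rights])]].gene_id
                        flagged.add(right)
            ies_rows.append(
                {
                    "chrom": chrom,
                    "start": ies_s,
                    "end": ies_e,
                    "containing_gene": containing,
                    "nearest_left": left,
                    "nearest_right": right,
                }
            )
    gene_rows = [
        {"gene_id": g.gene_id, "flanked_by_ies": g.gene_id in flagged}
        for chrom_genes in by_chrom.values()
        for g in chrom_genes
    ]
    return pd.DataFrame(ies_rows), pd.DataFrame(gene_rows)


def plot_bin_track(track: BinTrack, path: str | Path, title: str = "") -> None:
    """Simple linear per-chromosome plot of a bin track (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(track.values)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.6 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        v = track.values[chrom]
        x = (np.arange(len(v)) + 0.5) * track.bin_width / 1e6
        ax.bar(x, v, width=track.bin_width / 1e6 * 0.9)
        ax.set_ylabel(chrom, fontsize=7)
    axes[-1, 0].set_xlabel("MDS position (Mb)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def region_bed(
    landscape: ChromosomeLandscape, params: RegionParams | None = None
) -> dict[str, list[tuple[int, int, str]]]:
    """Region intervals per chromosome in MDS coordinates (BED-ready)."""
    params = params or RegionParams()
    out: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in sorted(landscape.lengths):
        L = landscape.mds_length(chrom)
        mid = landscape.centromere_midpoint_mds(chrom)
        peri = (max(0, mid - params.peri_halfwidth), min(L, mid + params.peri_halfwidth))
        intervals = []
        points = sorted(
            {0, L, min(params.subtel_len, L), max(0, L - params.subtel_len), max(0, peri[0]), min(L, peri[1] + 1)}
        )
        for a, b in zip(points, points[1:]):
            if a >= b:
                continue
            label = region_of(landscape, chrom, (a + b) // 2, params)
            intervals.append((a, b, label))
        # merge adjacent same-label intervals
        merged: list[tuple[int, int, str]] = []
        for iv in intervals:
            if merged and merged[-1][2] == iv[2] and merged[-1][1] == iv[0]:
                merged[-1] = (merged[-1][0], iv[1], iv[2])
            else:
                merged.append(iv)
        out[chrom] = merged
    return out
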