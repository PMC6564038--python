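"""Ortholog categories, species-specific gene calls, inparalog-expansion
tests and tandem-duplication statistics.

An ortholog cluster's *category* is the number of species with at least one
member (rendered as Roman numerals I..X for the canonical 10-species set).
Species-specific genes are the union of singletons, category-I cluster
members, and the members contributed by a species to clusters in which that
species shows a significant inparalog expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from tetlrr.io import OrthologClusters

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def roman(n: int) -> str:
    """Roman numeral for a category number (display only; supports 1..20)."""
    if 1 <= n <= 10:
        return _ROMAN[n - 1]
    if 11 <= n <= 20:
        return "X" + _ROMAN[n - 11]
    return str(n)


@dataclass(frozen=True)
class ExpansionCall:
    cluster_id: str
    species: str
    count: int
    total: int
    p_value: float  # Bonferroni-corrected
    flagged: bool


def categorize(clusters: OrthologClusters) -> pd.DataFrame:
    """Per-cluster category and per-species member counts.

    Returns a frame indexed by cluster id with one count column per species
    plus ``category`` (number of species present) and ``total``.
    """
    species = clusters.species
    rows = []
    for cid in sorted(clusters.clusters):
        by_sp = clusters.clusters[cid]
        counts = {sp: len(by_sp.get(sp, ())) for sp in species}
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"cluster {cid} has zero genes")
        rows.append({"cluster_id": cid, **counts, "category": sum(1 for c in counts.values() if c), "total": total})
    df = pd.DataFrame(rows).set_index("cluster_id")
    df["category_roman"] = [roman(int(c)) for c in df["category"]]
    return df


def expansion_test(
    clusters: OrthologClusters, alpha: float = 0.01, min_total: int = 5
) -> list[ExpansionCall]:
    """Flag species whose inparalog count within a cluster is larger than
    expected under a uniform split across the cluster's species.

    For each cluster with total N >= ``min_total`` spanning >= 2 species and
    each species with count k, the one-sided tail P[X >= k] with
    X ~ Binomial(N, 1/S_present) is Bonferroni-corrected over the
    S_present species of the cluster; calls with corrected p < alpha are
    flagged.  Category-I clusters are skipped (they are species-specific
    wholesale).
    """
    calls: list[ExpansionCall] = []
    for cid in sorted(clusters.clusters):
        by_sp = clusters.clusters[cid]
        present = sorted(sp for sp, genes in by_sp.items() if genes)
        total = sum(len(by_sp[sp]) for sp in present)
        if total < min_total or len(present) < 2:
            continue
        s = len(present)
        for sp in present:
            k = len(by_sp[sp])
            p_raw = float(binom.sf(k - 1, total, 1.0 / s))
            p_corr = min(1.0, p_raw * s)
            calls.append(ExpansionCall(cid, sp, k, total, p_corr, p_corr < alpha))
    return calls


def species_specific_genes(
    clusters: OrthologClusters,
    calls: Sequence[ExpansionCall],
    species: str,
    categories: pd.DataFrame | None = None,
) -> set[str]:
    """Singletons + category-I cluster members + members of clusters where
    the species is flagged as expanded (set union; each gene counted once)."""
    if categories is None:
        categories = categorize(clusters)
    out = set(clusters.singletons(species))
    flagged_clusters = {c.cluster_id for c in calls if c.flagged and c.species == species}
    for cid, by_sp in clusters.clusters.items():
        if int(categories.loc[cid, "category"]) == 1 or cid in flagged_clusters:
            out.update(by_sp.get(species, ()))
    return out


@dataclass(frozen=True)
class TandemGroup:
    scaffold: str
    label: str  # cluster id, or "__singleton__" for unclustered genes
    members: tuple[str, ...]  # in annotation order


def tandem_clusters(
    gene_order: Mapping[str, Sequence[str]],
    gene_to_cluster: Mapping[str, str | None],
    max_gap: int = 0,
) -> list[TandemGroup]:
    """Tandem duplication groups along each scaffold's annotation order.

    Two genes of the same cluster are tandem-linked when at most ``max_gap``
    other genes lie between them (``max_gap=0`` is the strict criterion, 3
    the relaxed one); groups are the resulting chains with >= 2 members.
    Unclustered genes (mapped to None) are linked to other unclustered genes
    under the same rule, mirroring how singleton tandem arrangements are
    counted.  Strand is ignored.  A gene present in the order but missing
    from the cluster map raises.
    """
    groups: list[TandemGroup] = []
    for scaffold in sorted(gene_order):
        order = gene_order[scaffold]
        positions: dict[str, list[tuple[int, str]]] = {}
        for pos, gid in enumerate(order):
            if gid not in gene_to_cluster:
                raise ValueError(f"gene {gid!r} missing from the cluster map")
            cid = gene_to_cluster[gid]
            label = "__singleton__" if cid is None else cid
            positions.setdefault(label, []).append((pos, gid))
        for label in sorted(positions):
            chain: list[str] = []
            last_pos = None
            for pos, gid in positions[label]:
                if last_pos is not None and pos - last_pos - 1 <= max_gap:
                    chain.append(gid)
                else:
                    if len(chain) >= 2:
                        groups.append(TandemGroup(scaffold, label, tuple(chain)))
                    chain = [gid]
                last_pos = pos
            if len(chain) >= 2:
                groups.append(TandemGroup(scaffold, label, tuple(chain)))
    return groups


def percent_tandem_by_category(
    categories: pd.DataFrame,
    clusters: OrthologClusters,
    tandem_groups: Sequence[TandemGroup],
) -> dict[int, float | None]:
    """Percentage of clustered genes belonging to some tandem group, by
    category (None where a category has no genes)."""
    tandem_genes = {g for grp in tandem_groups for g in grp.members}
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for cid, by_sp in clusters.clusters.items():
        cat = int(categories.loc[cid, "category"])
        for genes in by_sp.values():
            for g in genes:
                totals[cat] = totals.get(cat, 0) + 1
                if g in tandem_genes:
                    hits[cat] = hits.get(cat, 0) + 1
    max_cat = max(len(clusters.species), max(totals, default=0))
    return {
        cat: (100.0 * hits.get(cat, 0) / totals[cat]) if totals.get(cat) else None
        for cat in range(1, max_cat + 1)
    }


def expansion_calls_table(calls: Sequence[ExpansionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "species": c.species,
                "count": c.count,
                "total": c.total,
                "p_value": c.p_value,
                "flagged": c.flagged,
            }
            for c in calls
        ]
    )
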