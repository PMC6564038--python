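"""LRR gene identification and sorting into three age groups.

Group I genes lack 90-bp exons and are not masked by any LRR-gene repeat
family (CRS); group II genes carry 90-bp exons but are unmasked; group III
genes carry 90-bp exons and are masked, marking them as the youngest,
recently expanded cohort.  Masked genes without 90-bp exons fall in an
explicit "unclassified" bucket rather than being forced into the scheme.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

from tetlrr.io import GeneModel, MaskHit

logger = logging.getLogger("tetlrr")

GROUPS = ("I", "II", "III", "unclassified")

_ACCESSION_RE = re.compile(r"^[A-Za-z]+\d+(\.\d+)?$")


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    group: str
    best_family: str | None
    masked_bp: int
    best_family_score: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def identify_lrr_genes(
    domain_table: Mapping[str, Iterable[str]], lrr_labels: Iterable[str]
) -> set[str]:
    """Gene ids whose domain annotation matches any LRR label.

    Labels that look like accessions (letters followed by digits, e.g.
    ``PF13855``) are matched exactly (case-insensitive); free-text labels
    are matched as case-insensitive substrings of the domain names.
    """
    if not domain_table:
        logger.warning("identify_lrr_genes: empty domain table")
        return set()
    labels = [(lab, bool(_ACCESSION_RE.match(lab))) for lab in lrr_labels]
    hits: set[str] = set()
    for gene, domains in domain_table.items():
        for dom in domains:
            dom_l = dom.lower()
            for lab, is_acc in labels:
                lab_l = lab.lower()
                if (is_acc and dom_l == lab_l) or (not is_acc and lab_l in dom_l):
                    hits.add(gene)
                    break
            else:
                continue
            break
    return hits


def _family_coverage(
    gene: GeneModel, tree: IntervalTree | None
) -> dict[str, tuple[int, float]]:
    """family -> (bp of the gene span covered, sum of overlapping hit scores)."""
    if tree is None:
        return {}
    span_s, span_e = gene.span
    by_family: dict[str, list[tuple[int, int, float]]] = {}
    for iv in tree.overlap(span_s, span_e):
        family, score = iv.data
        s, e = max(iv.begin, span_s), min(iv.end, span_e)
        by_family.setdefault(family, []).append((s, e, score))
    out: dict[str, tuple[int, float]] = {}
    for family, pieces in by_family.items():
        pieces.sort()
        covered, cur_s, cur_e = 0, None, None
        score_sum = 0.0
        for s, e, score in pieces:
            score_sum += score
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        out[family] = (covered, score_sum)
    return out


def _mask_trees(hits: Iterable[MaskHit], families: set[str] | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for h in hits:
        if families is not None and h.family not in families:
            continue
        trees.setdefault(h.scaffold, IntervalTree()).addi(h.start, h.end, (h.family, h.score))
    return trees


def assign_best_family(coverage: Mapping[str, tuple[int, float]]) -> tuple[str, float]:
    """Family with the largest score sum (ties: larger masked bp, then
    lexicographically smallest family id)."""
    if not coverage:
        raise ValueError("assign_best_family: no overlapping mask hits")
    best = sorted(coverage.items(), key=lambda kv: (-kv[1][1], -kv[1][0], kv[0]))[0]
    return best[0], best[1][1]


def classify_groups(
    lrr_genes: Sequence[GeneModel],
    mask_hits: Iterable[MaskHit],
    families: Iterable[str] | None = None,
    target_len: int = 90,
    min_masked_bp: int = 50,
) -> list[GroupAssignment]:
    """Sort LRR genes into groups I/II/III/unclassified.

    A gene is *masked* when the bp of its genomic span (CDS plus introns)
    covered by hits of any single family reaches ``min_masked_bp``.  Group I
    = no ``target_len`` exon and unmasked; group II = has such exons,
    unmasked; group III = has such exons and masked (assigned to its
    best-scoring family); masked genes without such exons are
    "unclassified".
    """
    fam_set = set(families) if families is not None else None
    trees = _mask_trees(mask_hits, fam_set)
    out: list[GroupAssignment] = []
    for gene in lrr_genes:
        coverage = _family_coverage(gene, trees.get(gene.scaffold))
        eligible = {f: cv for f, cv in coverage.items() if cv[0] >= min_masked_bp}
        masked = bool(eligible)
        has_target = target_len in gene.exon_lengths
        total_bp = max((cv[0] for cv in coverage.values()), default=0)
        if has_target and masked:
            group = "III"
            family, score = assign_best_family(eligible)
        elif has_target:
            group, family, score = "II", None, 0.0
        elif masked:
            group = "unclassified"
            family, score = assign_best_family(eligible)
        else:
            group, family, score = "I", None, 0.0
        out.append(GroupAssignment(gene.gene_id, group, family, total_bp, score))
    return out


def group_summary(
    assignments: Sequence[GroupAssignment],
    species_specific: set[str],
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Per-group counts and species-specific fractions, with pairwise
    chi-squared tests of the specific/conserved composition.

    Returns (summary frame indexed by group, {(groupA, groupB): p-value}).
    Pairs involving an empty group are skipped.
    """
    rows = []
    comp: dict[str, tuple[int, int]] = {}
    for grp in GROUPS:
        ids = [a.gene_id for a in assignments if a.group == grp]
        n_spec = sum(1 for g in ids if g in species_specific)
        comp[grp] = (n_spec, len(ids) - n_spec)
        rows.append(
            {
                "group": grp,
                "n_genes": len(ids),
                "n_species_specific": n_spec,
                "species_specific_fraction": n_spec / len(ids) if ids else float("nan"),
            }
        )
    pvals: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(GROUPS):
        for g2 in GROUPS[i + 1 :]:
            a, b = comp[g1], comp[g2]
            if sum(a) == 0 or sum(b) == 0:
                continue
            table = [[a[0], a[1]], [b[0], b[1]]]
            if any(sum(col) == 0 for col in zip(*table)):
                pvals[(g1, g2)] = 1.0
                continue
            _, p, _, _ = chi2_contingency(table)
            pvals[(g1, g2)] = float(p)
    return pd.DataFrame(rows).set_index("group"), pvals


def assignments_table(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "group": a.group,
                "best_family": a.best_family or "",
                "masked_bp": a.masked_bp,
                "best_family_score": a.best_family_score,
            }
            for a in assignments
        ]
    )
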