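"""REP retrotransposon analysis: 54-bp tail scanning, functional-copy
bookkeeping and colocalization with LRR repeat units.

The REP element is a LINE-like (non-LTR) retrotransposon whose 3' end
carries a highly conserved 54-bp "tail" that survives in the somatic
genome; tail copies are found by Hamming-window scanning on both strands.
A copy is *functional* iff both of its ORFs are intact.  Colocalization is
measured as edge distance between REP copies and repeat-family mask hits
(by default the LRR-repeat family) within a configurable window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tetlrr.io import Genome, MaskHit, revcomp
from tetlrr.landscape import BinTrack, ChromosomeLandscape, bin_values

TAIL_LENGTH = 54


@dataclass(frozen=True)
class TailQuery:
    """A 54-nt tail query scanned on both strands with a mismatch budget."""

    sequence: str
    max_mismatches: int = 5

    def __post_init__(self) -> None:
        if len(self.sequence) != TAIL_LENGTH:
            raise ValueError(f"tail query must be {TAIL_LENGTH} nt, got {len(self.sequence)}")
        if "N" in self.sequence:
            raise ValueError("tail query must not contain N")
        if not 0 <= self.max_mismatches < TAIL_LENGTH:
            raise ValueError("max mismatches must be in [0, query length)")


@dataclass(frozen=True)
class TailHit:
    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class RepCopy:
    """An annotated REP locus; functional iff both ORFs are intact."""

    rep_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    orf1_intact: bool
    orf2_intact: bool

    @property
    def functional(self) -> bool:
        return self.orf1_intact and self.orf2_intact


def _scan_one_strand(arr: np.ndarray, query: str, max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    n_windows = len(arr) - len(query) + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mm = np.zeros(n_windows, dtype=np.int16)
    for j, ch in enumerate(query.encode()):
        mm += arr[j : j + n_windows] != ch
    pos = np.nonzero(mm <= max_mm)[0]
    return pos, mm[pos].astype(np.int64)


def _merge_hits(hits: list[TailHit]) -> list[TailHit]:
    """Merge overlapping same-strand hits keeping the lowest-mismatch
    (ties: leftmost) window."""
    merged: list[TailHit] = []
    for strand in "+-":
        group = sorted((h for h in hits if h.strand == strand), key=lambda h: h.start)
        best = None
        cur_end = -1
        for h in group:
            if best is None or h.start >= cur_end:
                if best is not None:
                    merged.append(best)
                best, cur_end = h, h.end
            else:
                cur_end = max(cur_end, h.end)
                if h.mismatches < best.mismatches:
                    best = h
        if best is not None:
            merged.append(best)
    return sorted(merged, key=lambda h: (h.scaffold, h.start, h.strand))


def scan_tail(genome: Genome, query: TailQuery) -> list[TailHit]:
    """All length-54 windows on either strand within the mismatch budget.

    The reverse strand is scanned with the reverse-complemented query so
    hit intervals always refer to forward-strand coordinates.  Overlapping
    same-strand windows are merged, keeping the lowest-mismatch one.
    """
    L = len(query.sequence)
    rc = revcomp(query.sequence)
    out: list[TailHit] = []
    for scaffold in sorted(genome.sequences):
        arr = np.frombuffer(genome.sequences[scaffold].encode(), dtype=np.uint8)
        hits: list[TailHit] = []
        pos, mm = _scan_one_strand(arr, query.sequence, query.max_mismatches)
        hits.extend(TailHit(scaffold, int(p), int(p) + L, "+", int(m)) for p, m in zip(pos, mm))
        pos, mm = _scan_one_strand(arr, rc, query.max_mismatches)
        hits.extend(TailHit(scaffold, int(p), int(p) + L, "-", int(m)) for p, m in zip(pos, mm))
        out.extend(_merge_hits(hits))
    return out


def _nearest_by_family(
    hits: Sequence[MaskHit], start: int, end: int, window: int, family: str | None
) -> tuple[tuple[str, int] | None, tuple[str, int] | None, bool]:
    """(nearest family+distance on the left, same on the right, whether the
    designated ``family`` lies within ``window`` on at least one side).
    Overlapping hits count as distance 0 on both sides."""
    left = right = None
    family_near = False
    for h in hits:
        if h.end <= start:
            d = start - h.end
        elif h.start >= end:
            d = h.start - end
        else:
            d = 0
        if d > window:
            continue
        if h.family == family:
            family_near = True
        if h.end <= start or d == 0:
            if left is None or d < left[1]:
                left = (h.family, d)
        if h.start >= end or d == 0:
            if right is None or d < right[1]:
                right = (h.family, d)
    return left, right, family_near


def flanking_elements(
    rep_copies: Sequence[RepCopy],
    mask_hits: Iterable[MaskHit],
    window: int = 1000,
    lrr_family: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float | None]:
    """Nearest mask family within ``window`` bp on each side of every REP
    copy, a per-family flanking summary, and the fraction of copies
    colocalized with ``lrr_family``.

    A copy is *colocalized* when a hit of the designated family lies
    within the window on at least one side (whether or not a hit of some
    other family is closer).  Returns (per-copy frame, summary frame
    sorted by one-side count, the colocalization fraction or None when no
    family was designated).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_scaffold: dict[str, list[MaskHit]] = {}
    for h in mask_hits:
        by_scaffold.setdefault(h.scaffold, []).append(h)
    rows = []
    for rep in rep_copies:
        left, right, near = _nearest_by_family(
            by_scaffold.get(rep.scaffold, ()), rep.start, rep.end, window, lrr_family
        )
        rows.append(
            {
                "rep_id": rep.rep_id,
                "scaffold": rep.scaffold,
                "functional": rep.functional,
                "left_family": left[0] if left else "",
                "left_distance": left[1] if left else -1,
                "right_family": right[0] if right else "",
                "right_distance": right[1] if right else -1,
                "lrr_within_window": near,
            }
        )
    per_copy = pd.DataFrame(rows)
    summary_rows = []
    if len(per_copy):
        families = sorted(
            set(per_copy["left_family"]) | set(per_copy["right_family"]) - {""}
        )
        for fam in families:
            if not fam:
                continue
            on_left = per_copy["left_family"] == fam
            on_right = per_copy["right_family"] == fam
            one_side = on_left | on_right
            both = on_left & on_right
            summary_rows.append(
                {
                    "family": fam,
                    "n_one_side": int(one_side.sum()),
                    "n_both_sides": int(both.sum()),
                    "n_one_side_functional": int((one_side & per_copy["functional"]).sum()),
                    "n_one_side_nonfunctional": int((one_side & ~per_copy["functional"]).sum()),
                }
            )
    summary = pd.DataFrame(
        summary_rows, columns=["family", "n_one_side", "n_both_sides", "n_one_side_functional", "n_one_side_nonfunctional"]
    ).sort_values(["n_one_side", "family"], ascending=[False, True]).reset_index(drop=True)
    fraction = None
    if lrr_family is not None and len(per_copy):
        fraction = float(per_copy["lrr_within_window"].mean())
    return per_copy, summary, fraction


def colocalization_sensitivity(
    rep_copies: Sequence[RepCopy],
    mask_hits: Sequence[MaskHit],
    lrr_family: str,
    windows: Sequence[int] = (250, 500, 1000, 2000),
) -> pd.DataFrame:
    """Colocalization fraction as a function of the flanking window."""
    rows = []
    for w in windows:
        _, _, frac = flanking_elements(rep_copies, mask_hits, window=w, lrr_family=lrr_family)
        rows.append({"window": w, "colocalization_fraction": frac})
    return pd.DataFrame(rows)


def tail_distribution_track(
    hits: Sequence[TailHit], landscape: ChromosomeLandscape, bin_width: int = 1_000_000
) -> BinTrack:
    """Per-bin counts of tail hits in MDS coordinates."""
    items = [(h.scaffold, h.start, None) for h in hits if h.scaffold in landscape.lengths]
    return bin_values(items, landscape, bin_width, "count")


def read_rep_bed(path: str | Path) -> list[RepCopy]:
    """BED6+2 with ORF1/ORF2 intactness flags (1/0) in columns 7-8."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track")):
                continue
            out.append(
                RepCopy(
                    rep_id=fields[3],
                    scaffold=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5] if len(fields) > 5 else "+",
                    orf1_intact=bool(int(fields[6])) if len(fields) > 6 else True,
                    orf2_intact=bool(int(fields[7])) if len(fields) > 7 else True,
                )
            )
    return out


def write_rep_bed(copies: Sequence[RepCopy], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(copies, key=lambda r: (r.scaffold, r.start)):
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{r.rep_id}\t0\t{r.strand}"
                f"\t{int(r.orf1_intact)}\t{int(r.orf2_intact)}\n"
            )


def find_intact_orf(seq: str, min_len: int = 300, code: str = "ciliate") -> bool:
    """Helper: does any forward reading frame contain an uninterrupted
    ATG..stop ORF of at least ``min_len`` nt under the selected code?"""
    stops = {"TGA"} if code == "ciliate" else {"TAA", "TAG", "TGA"}
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in stops and start is not None:
                if i + 3 - start >= min_len:
                    return True
                start = None
    return False
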