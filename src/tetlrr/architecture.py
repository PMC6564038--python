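"""Quantitative gene-structure analysis: intron phases, exact-length exon
arrays, length landscapes with peak detection, repeat-unit lengths, reading
frames of array exons, GC content and leucine codon usage.

The central objects are arrays of exactly 90-bp CDS exons.  Because 90 is a
multiple of 3, every intron inside such an array carries the same phase as
the intron preceding the first array exon; a phase-2 flank means each exon
contributes 29 complete codons plus one nucleotide to each of the two
junction codons it shares with its neighbours (31 touched residues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.signal import find_peaks

from tetlrr.io import GeneModel, Genome

#: NCBI translation-table numbers for the supported genetic codes.  The
#: ciliate nuclear code reads TAA/TAG as glutamine and only TGA as stop;
#: it is the default because *Tetrahymena* uses it.
GENETIC_CODES = {"ciliate": 6, "standard": 1}

LEUCINE_CODONS = ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")


@dataclass(frozen=True)
class ExonRecord:
    """One CDS exon with the phases of its flanking introns (None at gene ends)."""

    gene_id: str
    index: int  # 1-based, transcription order
    length: int
    sequence: str
    phase_before: int | None
    phase_after: int | None

    def __post_init__(self) -> None:
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(f"{self.gene_id} exon {self.index}: length != |sequence|")
        for p in (self.phase_before, self.phase_after):
            if p is not None and p not in (0, 1, 2):
                raise ValueError(f"{self.gene_id} exon {self.index}: bad phase {p}")


@dataclass
class LengthHistogram:
    """1-bp histogram with smoothed-peak detection.

    Peaks are local maxima of the moving-average-smoothed counts with
    prominence at least ``prominence_frac`` of the global smoothed maximum;
    ``primary`` is the highest peak, ``secondary`` the rest ordered by
    prominence.
    """

    counts: dict[int, int]
    total: int
    primary: int | None
    secondary: list[int] = field(default_factory=list)


def intron_phases(gene: GeneModel) -> list[int]:
    """Phase of each intron in transcription order.

    The phase of intron *i* is the cumulative length of exons 1..*i* mod 3:
    phase 2 means the intron interrupts a codon after its second nucleotide.
    A single-exon gene yields an empty list.
    """
    phases, cum = [], 0
    for length in gene.exon_lengths[:-1]:
        cum += length
        phases.append(cum % 3)
    return phases


def find_exact_length_arrays(
    gene: GeneModel, target_len: int = 90, min_run: int = 3
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive exons of exactly ``target_len`` bp.

    Returns (start exon index, run length) pairs (1-based, transcription
    order) for maximal runs of at least ``min_run`` exons.
    """
    runs: list[tuple[int, int]] = []
    start = None
    lengths = gene.exon_lengths
    for i, length in enumerate(lengths + [None]):  # sentinel terminates last run
        if length == target_len:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                runs.append((start + 1, i - start))
            start = None
    return runs


def array_exon_indices(gene: GeneModel, target_len: int = 90, min_run: int = 3) -> set[int]:
    """1-based indices of exons belonging to some exact-length array."""
    out: set[int] = set()
    for start, n in find_exact_length_arrays(gene, target_len, min_run):
        out.update(range(start, start + n))
    return out


STRATA = (
    "lrr_preceding_target",
    "lrr_without_target_exons",
    "nonlrr_preceding_target",
    "all_introns",
)


def phase_bias_report(
    genes: Iterable[GeneModel], lrr_ids: set[str], target_len: int = 90
) -> pd.DataFrame:
    """Phase composition of introns in four strata.

    Strata: introns immediately preceding ``target_len`` exons in LRR genes;
    all introns of LRR genes that lack any ``target_len`` exon; introns
    preceding ``target_len`` exons in non-LRR genes; all introns.  The
    "preceding" intron of an exon is the one immediately 5' of it in
    transcription order.  Returns a frame indexed by stratum with columns
    phase0/1/2, n and phase2_pct (NaN for an empty stratum).
    """
    counts = {s: [0, 0, 0] for s in STRATA}
    for gene in genes:
        phases = intron_phases(gene)
        lengths = gene.exon_lengths
        is_lrr = gene.gene_id in lrr_ids
        has_target = target_len in lengths
        for i, ph in enumerate(phases):  # intron i precedes exon i+2 (1-based)
            counts["all_introns"][ph] += 1
            precedes_target = lengths[i + 1] == target_len
            if is_lrr and precedes_target:
                counts["lrr_preceding_target"][ph] += 1
            if is_lrr and not has_target:
                counts["lrr_without_target_exons"][ph] += 1
            if not is_lrr and precedes_target:
                counts["nonlrr_preceding_target"][ph] += 1
    rows = []
    for s in STRATA:
        c = counts[s]
        n = sum(c)
        rows.append(
            {
                "stratum": s,
                "phase0": c[0],
                "phase1": c[1],
                "phase2": c[2],
                "n": n,
                "phase2_pct": 100.0 * c[2] / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def length_histogram(
    values: Iterable[int], smooth_window: int = 5, prominence_frac: float = 0.1
) -> LengthHistogram:
    """Build a 1-bp histogram and detect its primary and secondary peaks."""
    vals = np.asarray(list(values), dtype=int)
    if vals.size == 0:
        raise ValueError("length_histogram: empty input")
    if (vals <= 0).any():
        raise ValueError("length_histogram: values must be positive integers")
    lo, hi = int(vals.min()), int(vals.max())
    counts = np.bincount(vals - lo, minlength=hi - lo + 1).astype(float)
    # pad so edge modes are detectable local maxima
    pad = max(smooth_window, 1)
    padded = np.concatenate([np.zeros(pad), counts, np.zeros(pad)])
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(padded, kernel, mode="same")
    peaks, props = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    half = smooth_window // 2
    resolved: list[tuple[float, int]] = []  # (prominence, value)
    for p, prom in zip(peaks, props["prominences"]):
        idx = p - pad
        # snap to the raw-count argmax within the smoothing window
        w0, w1 = max(0, idx - half), min(len(counts), idx + half + 1)
        if w1 <= w0 or counts[w0:w1].max() == 0:
            continue
        value = lo + w0 + int(np.argmax(counts[w0:w1]))
        resolved.append((float(prom), value))
    # deduplicate snapped values, keep the most prominent occurrence
    best: dict[int, float] = {}
    for prom, value in resolved:
        best[value] = max(best.get(value, 0.0), prom)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    primary = ordered[0][0] if ordered else None
    secondary = [v for v, _ in ordered[1:]]
    hist = {int(v): int(c) for v, c in zip(range(lo, hi + 1), counts) if c}
    return LengthHistogram(counts=hist, total=int(vals.size), primary=primary, secondary=secondary)


def repeat_unit_lengths(gene: GeneModel, target_len: int = 90, min_run: int = 3) -> list[int]:
    """Lengths of intragenic repeat units: array exon + the intron separating
    it from the next array exon.

    One unit is reported per consecutive pair of array exons, so an array of
    *n* exons yields *n* - 1 units (the last exon of an array has no
    following intra-array intron).
    """
    introns = gene.intron_lengths
    units: list[int] = []
    for start, n in find_exact_length_arrays(gene, target_len, min_run):
        for i in range(start, start + n - 1):  # 1-based exon i paired with i+1
            units.append(gene.exon_lengths[i - 1] + introns[i - 1])
    return units


def translate_cds(seq: str, code: str = "ciliate") -> str:
    """Translate a CDS under the selected genetic code.

    An internal stop is flagged with a warning and truncates the
    translation; a terminal stop is silently dropped.
    """
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    table = GENETIC_CODES[code]
    protein = str(Seq(seq).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        pos = protein.index("*")
        warnings.warn(
            f"internal stop codon at residue {pos + 1} under {code} code; translation truncated",
            stacklevel=2,
        )
        protein = protein[:pos]
    return protein


def exon_translation_frame(
    length: int, phase_before: int, phase_after: int
) -> tuple[int, int]:
    """(complete codons inside the exon, amino acids touched by the exon).

    ``phase_before``/``phase_after`` are the phases of the flanking introns;
    both must be defined (terminal exons have no such frame).  For the
    canonical 90-bp exon with phase-2 flanks this is (29, 31): nucleotides
    2..88 encode 29 full codons, and the first and last junction codons each
    borrow nucleotides from the neighbouring exons.
    """
    if phase_before is None or phase_after is None:
        raise ValueError("terminal exon: flanking intron phases undefined")
    if (phase_before + length) % 3 != phase_after:
        raise ValueError(
            f"inconsistent phases: ({phase_before} + {length}) % 3 != {phase_after}"
        )
    leading = (3 - phase_before) % 3  # nt completing the upstream junction codon
    full = (length - leading) // 3
    trailing = (length - leading) % 3  # nt starting the downstream junction codon
    touched = full + (1 if leading else 0) + (1 if trailing else 0)
    return full, touched


def exon_frame(exon: ExonRecord) -> tuple[int, int]:
    """:func:`exon_translation_frame` applied to an :class:`ExonRecord`."""
    return exon_translation_frame(exon.length, exon.phase_before, exon.phase_after)


def exon_records(gene: GeneModel, genome: Genome | None = None) -> list[ExonRecord]:
    """Per-exon records with flanking-intron phases for one gene."""
    phases = intron_phases(gene)
    seqs = gene.exon_sequences(genome) if genome is not None else [""] * gene.n_exons
    records = []
    for i, (length, seq) in enumerate(zip(gene.exon_lengths, seqs)):
        records.append(
            ExonRecord(
                gene_id=gene.gene_id,
                index=i + 1,
                length=length,
                sequence=seq,
                phase_before=phases[i - 1] if i > 0 else None,
                phase_after=phases[i] if i < len(phases) else None,
            )
        )
    return records


def gc_content(seq: str) -> float:
    """(G + C) / (length - N); raises on an empty or all-N sequence."""
    n_count = seq.count("N")
    denom = len(seq) - n_count
    if denom == 0:
        raise ValueError("gc_content: no informative (non-N) positions")
    return (seq.count("G") + seq.count("C")) / denom


def leucine_codon_usage(cds_sequences: Iterable[str]) -> dict[str, float]:
    """Fraction of each leucine codon among all leucine codons in the CDSs."""
    counts = dict.fromkeys(LEUCINE_CODONS, 0)
    for cds in cds_sequences:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        return dict.fromkeys(LEUCINE_CODONS, 0.0)
    return {c: counts[c] / total for c in LEUCINE_CODONS}


def architecture_table(
    genes: Sequence[GeneModel], target_len: int = 90, min_run: int = 3
) -> pd.DataFrame:
    """Per-gene architecture summary (one row per gene)."""
    rows = []
    for g in genes:
        runs = find_exact_length_arrays(g, target_len, min_run)
        phases = intron_phases(g)
        rows.append(
            {
                "gene_id": g.gene_id,
                "species": g.species,
                "scaffold": g.scaffold,
                "n_exons": g.n_exons,
                "cds_length": g.cds_length,
                "n_target_exons": g.exon_lengths.count(target_len),
                "n_arrays": len(runs),
                "arrays": ";".join(f"{s}:{n}" for s, n in runs),
                "n_introns": g.n_exons - 1,
                "n_phase2": phases.count(2),
            }
        )
    return pd.DataFrame(rows)
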