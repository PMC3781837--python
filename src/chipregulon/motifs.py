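"""Scanning for the short asymmetric binding motif (default GACAC).

The consensus is non-palindromic, so forward-strand occurrences (GACAC)
and reverse-strand occurrences (GTGTC read on the forward strand) are
distinct and both biologically meaningful; the scanner reports both,
allowing overlaps.  Near-consensus sites one substitution away (e.g. GACGC
and GACAG, variants observed at footprinted promoters) can be admitted
with ``max_mismatch=1``.  Unknown bases (N) never match, even within a
mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence

__all__ = [
    "MotifHit",
    "scan_sequence",
    "count_genome_motifs",
    "annotate_peaks_with_motifs",
    "orientation_summary",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(motif: str) -> bool:
    return motif == reverse_complement(motif)


@dataclass(frozen=True)
class MotifHit:
    """One motif match.

    ``position`` is the 1-based coordinate of the match's first base on the
    forward strand.  ``strand`` '+' means the motif itself occurs on the
    forward strand; '-' means the forward strand carries its reverse
    complement.  ``sequence`` is the matched word as read on the motif
    strand (so a 0-mismatch '-' hit reads identically to the motif).
    """

    position: int
    strand: str
    sequence: str
    mismatches: int
    offset_to_peak: int | None = None


def _mismatch_profile(arr: np.ndarray, word: bytes) -> np.ndarray:
    """Mismatch count of every length-k window of ``arr`` against ``word``.

    Windows containing N are marked with a large count so they never match.
    """
    k = len(word)
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mm = np.zeros(n, dtype=np.int64)
    has_n = np.zeros(n, dtype=bool)
    n_byte = ord("N")
    for j in range(k):
        col = arr[j : j + n]
        mm += col != word[j]
        has_n |= col == n_byte
    mm[has_n] = k + 1
    return mm


def scan_sequence(
    seq: str,
    motif: str = "GACAC",
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All motif occurrences in ``seq``, overlaps allowed.

    Reverse-strand hits are found by scanning the forward sequence for the
    reverse complement of the motif.  Hits are sorted by position, then
    strand ('+' first).
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    k = len(motif)

    strands = [("+", motif.encode())]
    if both_strands and not is_palindromic(motif):
        strands.append(("-", reverse_complement(motif).encode()))
    elif both_strands and is_palindromic(motif):
        # a palindromic motif reads the same on both strands; scanning the
        # reverse complement would double-count every hit
        pass

    hits: list[MotifHit] = []
    for strand, word in strands:
        mm = _mismatch_profile(arr, word)
        for i in np.flatnonzero(mm <= max_mismatch):
            matched = seq[i : i + k].upper()
            if strand == "-":
                matched = reverse_complement(matched)
            hits.append(MotifHit(position=int(i) + 1, strand=strand,
                                 sequence=matched, mismatches=int(mm[i])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def count_genome_motifs(
    genome: GenomeSequence | str, motif: str = "GACAC"
) -> tuple[int, int, int]:
    """Exact occurrence counts of a motif on both strands of a chromosome.

    Returns (forward, reverse, total).  For a non-palindromic motif the
    total is simply the sum; a palindromic motif occurs identically on
    both strands, so its forward count is reported once and the total
    equals it (no double counting).
    """
    seq = genome.seq if isinstance(genome, GenomeSequence) else genome
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    motif = motif.upper()
    fwd = int(np.count_nonzero(_mismatch_profile(arr, motif.encode()) == 0))
    if is_palindromic(motif):
        return fwd, fwd, fwd
    rev = int(np.count_nonzero(
        _mismatch_profile(arr, reverse_complement(motif).encode()) == 0))
    return fwd, rev, fwd + rev


def annotate_peaks_with_motifs(
    peak_positions: Sequence[int],
    genome: GenomeSequence,
    motif: str = "GACAC",
    window: int = 100,
    max_mismatch: int = 0,
) -> dict[int, MotifHit | None]:
    """Nearest motif hit within ±window of each peak position.

    Preference order on competing hits: fewer mismatches, then smaller
    |offset| from the peak, then '+' strand.  Peaks with no hit in the
    window map to None.
    """
    hits = scan_sequence(genome.seq, motif=motif, max_mismatch=max_mismatch)
    positions = np.array([h.position for h in hits], dtype=np.int64)
    out: dict[int, MotifHit | None] = {}
    for peak in peak_positions:
        lo = np.searchsorted(positions, peak - window)
        hi = np.searchsorted(positions, peak + window, side="right")
        best = None
        best_key = None
        for h in hits[lo:hi]:
            offset = h.position - peak
            key = (h.mismatches, abs(offset), 0 if h.strand == "+" else 1)
            if best_key is None or key < best_key:
                best_key = key
                best = replace(h, offset_to_peak=offset)
        out[int(peak)] = best
    return out


def orientation_summary(
    peak_motifs: Mapping[int, MotifHit | None],
    target_strands: Mapping[int, str],
    expression_classes: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Tally motif orientation relative to each peak's target gene.

    Orientation is gene-anchored: a motif on the same strand as the target
    gene's reading direction counts as the consensus word upstream
    ('motif_up'); the opposite strand counts as its reverse complement
    upstream ('revcomp_up'); peaks without a hit count as 'none'.  Rows are
    overall plus one per expression class when classes are supplied;
    stratified counts sum to the overall row.
    """
    def orient(peak: int) -> str:
        hit = peak_motifs.get(peak)
        if hit is None:
            return "none"
        gene_strand = target_strands.get(peak)
        if gene_strand is None:
            return "none"
        return "motif_up" if hit.strand == gene_strand else "revcomp_up"

    categories = ["motif_up", "revcomp_up", "none"]
    peaks = list(peak_motifs)
    rows = []

    def tally(subset: Iterable[int], label: str) -> dict:
        counts = {c: 0 for c in categories}
        for p in subset:
            counts[orient(p)] += 1
        n = sum(counts.values())
        row = {"stratum": label, "n": n}
        for c in categories:
            row[f"count_{c}"] = counts[c]
            row[f"frac_{c}"] = counts[c] / n if n else float("nan")
        return row

    rows.append(tally(peaks, "overall"))
    if expression_classes:
        for cls in sorted(set(expression_classes.values())):
            subset = [p for p in peaks if expression_classes.get(p) == cls]
            rows.append(tally(subset, cls))
    return pd.DataFrame(rows)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": h.position,
                "strand": h.strand,
                "sequence": h.sequence,
                "mismatches": h.mismatches,
                "offset_to_peak": h.offset_to_peak,
            }
            for h in hits
        ]
    )
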