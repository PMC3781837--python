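"""Gene-anchored annotation of significant grid positions.

Each significant position becomes a record carrying its flanking genes and
signed distances to their start codons, and then passes through the
filtering chain used to define a regulon:

1. positions more than 300 nt upstream of the nearest start codon are set
   aside (they cannot be assigned to a promoter with any confidence);
2. positions also significant in the mock-IP control are discarded as
   antibody/background artefacts;
3. among the positions assigned to one transcription unit, only the most
   significant is kept (one summit per unit);
4. positions between divergent genes are resolved using expression data —
   the flanking gene whose expression actually responds to the regulator
   is taken as the target; if both or neither respond, both genes are
   retained and the record is flagged ambiguous.

Distance convention (matching the sign printed in the study tables this
mirrors): positive = the position lies upstream of the start codon, in the
promoter region; negative = downstream of the start codon, inside the
gene.  Only genes whose reading direction faces the position ("head
toward": the position sits upstream of, or within, the gene) receive a
distance; a gene presenting its 3' end is recorded as a flanking neighbour
but is never a promoter-proximal candidate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel

__all__ = [
    "PeakRecord",
    "flanking_genes",
    "build_peak_records",
    "filter_far_upstream",
    "subtract_control",
    "veto_control_peaks",
    "assign_divergent_targets",
    "summit_per_transcription_unit",
    "records_to_frame",
]


@dataclass
class PeakRecord:
    """One significant grid position with gene context and per-condition stats."""

    position: int
    d: dict[str, float] = field(default_factory=dict)          # condition -> difference
    p_adj: dict[str, float] = field(default_factory=dict)      # condition -> adjusted p
    significant: dict[str, bool] = field(default_factory=dict)  # condition -> p_adj <= alpha
    left_gene: str | None = None
    right_gene: str | None = None
    distance_left: int | None = None
    distance_right: int | None = None
    assigned_targets: list[str] = field(default_factory=list)
    ambiguous: bool = False
    excluded_reason: str | None = None  # None | 'upstream_gt_300' | 'control_significant'

    def min_p_adj(self, exclude: Iterable[str] = ()) -> float:
        """Smallest adjusted p across conditions not in ``exclude``."""
        vals = [p for c, p in self.p_adj.items()
                if c not in exclude and not np.isnan(p)]
        return min(vals) if vals else float("nan")

    def max_abs_d(self, exclude: Iterable[str] = ()) -> float:
        vals = [abs(v) for c, v in self.d.items()
                if c not in exclude and not np.isnan(v)]
        return max(vals) if vals else 0.0


def _promoter_distance(gene: GeneModel, position: int) -> int | None:
    """Signed distance from position to the gene's start codon.

    Positive when the position is upstream of the start codon, negative
    when inside the gene, ``None`` when the position faces the gene's 3'
    end (not a promoter-proximal candidate).
    """
    if gene.strand == "+":
        if position > gene.end:
            return None  # beyond the 3' end
        return gene.start - position
    else:
        if position < gene.start:
            return None
        return position - gene.end


def flanking_genes(
    position: int, genes: Sequence[GeneModel]
) -> tuple[str | None, str | None, int | None, int | None]:
    """Nearest genes left and right of a position, with promoter distances.

    ``genes`` must be sorted by start.  Left = last gene starting at or
    before the position; right = first gene starting after it.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    starts = [g.start for g in genes]
    i = bisect.bisect_right(starts, position)  # genes[:i] start <= position
    left = genes[i - 1] if i > 0 else None
    right = genes[i] if i < len(genes) else None
    dist_left = _promoter_distance(left, position) if left else None
    dist_right = _promoter_distance(right, position) if right else None
    return (
        left.gene_id if left else None,
        right.gene_id if right else None,
        dist_left,
        dist_right,
    )


def build_peak_records(
    sig_by_condition: Mapping[str, Sequence[tuple[int, float, float]]],
    tracks_by_condition: Mapping[str, "object"],
    genes: Sequence[GeneModel],
    alpha: float = 1e-4,
    control_condition: str | None = None,
) -> list[PeakRecord]:
    """Merge per-condition sigDiff lists into per-position peak records.

    A record is created for every grid position significant in at least one
    non-control condition; ``tracks_by_condition`` (condition ->
    DifferenceTrack) supplies the difference and adjusted p of every
    condition at those positions, so each record carries the full
    per-condition evidence (including the control, used later for
    exclusion).
    """
    positions: set[int] = set()
    for cond, sig in sig_by_condition.items():
        if control_condition is not None and cond == control_condition:
            continue
        positions.update(pos for pos, _, _ in sig)

    # index every track by grid position once
    lookup: dict[str, dict[int, tuple[float, float]]] = {}
    for cond, track in tracks_by_condition.items():
        p_adj = track.p_adj if track.p_adj is not None else np.full(
            track.d.shape, np.nan)
        lookup[cond] = {
            int(p): (float(dv), float(pa))
            for p, dv, pa in zip(track.grid_positions, track.d, p_adj)
        }

    records = []
    for pos in sorted(positions):
        rec = PeakRecord(position=pos)
        for cond, table in lookup.items():
            dv, pa = table.get(pos, (float("nan"), float("nan")))
            rec.d[cond] = dv
            rec.p_adj[cond] = pa
            rec.significant[cond] = bool(not np.isnan(pa) and pa <= alpha)
        (rec.left_gene, rec.right_gene,
         rec.distance_left, rec.distance_right) = flanking_genes(pos, genes)
        records.append(rec)
    return records


def filter_far_upstream(
    records: Sequence[PeakRecord], max_upstream: int = 300
) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Separate records more than ``max_upstream`` nt from any start codon.

    A record is kept iff at least one available promoter distance is
    <= ``max_upstream``; negative (intragenic) distances always satisfy
    this — peaks just inside a coding region stay in the analysis set.
    """
    kept, removed = [], []
    for rec in records:
        dists = [d for d in (rec.distance_left, rec.distance_right)
                 if d is not None]
        if dists and min(dists) <= max_upstream:
            kept.append(rec)
        else:
            rec.excluded_reason = "upstream_gt_300"
            removed.append(rec)
    return kept, removed


def subtract_control(
    records: Sequence[PeakRecord], control_condition: str
) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Drop records that are also significant in the mock-IP control.

    A position enriched without the tagged factor reflects antibody
    cross-reaction or shearing artefacts, not binding.  Excluded records
    are returned separately for the audit output.
    """
    kept, excluded = [], []
    for rec in records:
        if rec.significant.get(control_condition, False):
            rec.excluded_reason = "control_significant"
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def veto_control_peaks(
    summits: Sequence[PeakRecord],
    records_all: Sequence[PeakRecord],
    control_condition: str,
    step: int,
) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Peak-level control veto on selected summits.

    A physical peak spans a contiguous run of significant grid positions
    (spacing ``step``).  A peak that also appears in the mock-IP control is
    an artefact in its entirety, so a summit is vetoed when *any* position
    of its contiguous run is control-significant — not only the summit
    itself.  Per-position vetoing would let a borderline tail position of a
    control-shared peak (significant in IP, adjusted p just above threshold
    in the control) survive as the neighbouring unit's "summit".
    """
    ordered = sorted(records_all, key=lambda r: r.position)
    run_id = {}
    current = -1
    prev_pos = None
    run_has_control: dict[int, bool] = {}
    for rec in ordered:
        if prev_pos is None or rec.position - prev_pos > step:
            current += 1
            run_has_control[current] = False
        run_id[id(rec)] = current
        if rec.significant.get(control_condition, False):
            run_has_control[current] = True
        prev_pos = rec.position

    kept, excluded = [], []
    for rec in summits:
        if run_has_control.get(run_id.get(id(rec), -2), False):
            rec.excluded_reason = "control_significant"
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def assign_divergent_targets(
    records: Sequence[PeakRecord],
    expression_classes: Mapping[str, str] | None = None,
) -> list[PeakRecord]:
    """Assign each record its target gene(s).

    A record with one promoter-proximal flanking gene gets that gene.  A
    record between divergent genes (two promoter distances) is resolved by
    expression: if exactly one flanking gene responds to the regulator
    (class != 'unchanged'), it is the target; otherwise both are retained
    and the record is flagged ambiguous.  Genes absent from the expression
    table are treated as unchanged (with a warning).
    """
    import warnings

    expression_classes = expression_classes or {}
    warned: set[str] = set()

    def expr_class(gene_id: str) -> str:
        if gene_id not in expression_classes:
            if expression_classes and gene_id not in warned:
                warnings.warn(
                    f"gene {gene_id} absent from expression matrix; "
                    "treated as unchanged", stacklevel=3)
                warned.add(gene_id)
            return "unchanged"
        return expression_classes[gene_id]

    out = []
    for rec in records:
        candidates = []
        if rec.distance_left is not None and rec.left_gene is not None:
            candidates.append(rec.left_gene)
        if rec.distance_right is not None and rec.right_gene is not None:
            candidates.append(rec.right_gene)
        if len(candidates) <= 1:
            rec.assigned_targets = candidates
            rec.ambiguous = False
        else:
            responding = [g for g in candidates
                          if expr_class(g) != "unchanged"]
            if len(responding) == 1:
                rec.assigned_targets = responding
                rec.ambiguous = False
            else:
                rec.assigned_targets = candidates
                rec.ambiguous = True
        out.append(rec)
    return out


def summit_per_transcription_unit(
    records: Sequence[PeakRecord],
    operons: Mapping[str, str] | None = None,
    control_condition: str | None = None,
) -> list[PeakRecord]:
    """Keep the most significant record per assigned transcription unit.

    ``operons`` maps gene_id -> operon_id; genes without an entry are their
    own unit.  "Most significant" = smallest adjusted p over non-control
    conditions; ties broken by larger maximum |difference|, then by smaller
    genomic position.  A record assigned to two units (unresolved divergent
    pair) survives if it is the best for either unit.
    """
    operons = operons or {}
    exclude = (control_condition,) if control_condition else ()

    def unit_of(gene_id: str) -> str:
        return operons.get(gene_id, gene_id)

    def sort_key(rec: PeakRecord):
        return (rec.min_p_adj(exclude=exclude), -rec.max_abs_d(exclude=exclude),
                rec.position)

    best: dict[str, PeakRecord] = {}
    for rec in records:
        for gene_id in rec.assigned_targets:
            unit = unit_of(gene_id)
            if unit not in best or sort_key(rec) < sort_key(best[unit]):
                best[unit] = rec
    keep = {id(rec) for rec in best.values()}
    return [rec for rec in records if id(rec) in keep]


def records_to_frame(
    records: Sequence[PeakRecord],
    conditions: Sequence[str],
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Flatten records into a table (one row per record).

    Columns mirror the per-position layout of the study tables this
    pipeline reproduces: position, per-condition difference / adjusted p /
    peak flag, flanking genes with distances, assigned targets, and — when
    the annotation is supplied — coordinates and product of the first
    assigned target.
    """
    gene_index = {g.gene_id: g for g in genes} if genes else {}
    rows = []
    for rec in records:
        row: dict = {"position": rec.position}
        for c in conditions:
            row[f"diff_{c}"] = rec.d.get(c, float("nan"))
            row[f"apv_{c}"] = rec.p_adj.get(c, float("nan"))
            row[f"pk_{c}"] = rec.significant.get(c, False)
        row.update(
            left_gene=rec.left_gene or "",
            right_gene=rec.right_gene or "",
            distance_left=rec.distance_left,
            distance_right=rec.distance_right,
            assigned_targets=";".join(rec.assigned_targets),
            ambiguous=rec.ambiguous,
            excluded_reason=rec.excluded_reason or "",
        )
        if gene_index and rec.assigned_targets:
            g = gene_index.get(rec.assigned_targets[0])
            if g is not None:
                row.update(target_start=g.start, target_end=g.end,
                           target_strand=1 if g.strand == "+" else -1,
                           target_product=g.product)
        rows.append(row)
    return pd.DataFrame(rows)
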