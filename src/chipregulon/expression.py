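"""Expression time-course integration and regulator-response classification.

Consumes an already-normalized log2 expression matrix in long format
(gene_id, strain, time_h, replicate, log2_value) for a wild-type and a
regulator-null mutant strain.  Replicates are averaged into per-condition
coefficients, optionally re-centred per gene on the median across
conditions, and mutant − WT log2 fold changes are computed per time point.

A gene is called *repressed by the regulator* when its expression rises at
least 2-fold (log2FC >= +1) in the mutant at some time point — losing a
repressor raises expression — and *activated by the regulator* when it
falls at least 2-fold (log2FC <= −1); otherwise it is *unchanged*.  The
2-fold rule is applied cell-wise (any single time point suffices), and a
profile crossing both thresholds is classified by its larger excursion and
flagged mixed.  Because the fold change is a within-gene difference, the
classification is invariant to per-gene median normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionClass",
    "validate_matrix",
    "combine_replicates",
    "median_normalize",
    "log_fold_changes",
    "classify_targets",
    "regulon_summary",
]

ACTIVATED = "activated_by_regulator"
REPRESSED = "repressed_by_regulator"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    logfc: dict          # time -> mutant − WT log2 fold change
    max_abs_logfc: float
    label: str           # ACTIVATED | REPRESSED | UNCHANGED
    mixed: bool
    supporting_times: tuple  # times where |logFC| crossed the threshold


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format expression matrix contract."""
    required = {"gene_id", "strain", "time_h", "replicate", "log2_value"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"expression matrix missing columns: {sorted(missing)}")
    if matrix.duplicated(["gene_id", "strain", "time_h", "replicate"]).any():
        raise ValueError("duplicate (gene, strain, time, replicate) cells")
    if not np.isfinite(matrix["log2_value"]).all():
        raise ValueError("non-finite expression values")
    if "WT" not in set(matrix["strain"]):
        raise ValueError("wild-type strain ('WT') absent from matrix")
    return matrix


def combine_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 value per (gene, strain, time): replicate combination.

    Returns a tidy frame with columns gene_id, strain, time_h, mean_log2.
    """
    validate_matrix(matrix)
    means = (
        matrix.groupby(["gene_id", "strain", "time_h"], sort=True)["log2_value"]
        .mean()
        .reset_index()
        .rename(columns={"log2_value": "mean_log2"})
    )
    return means


def median_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene normalization to the median across all condition means.

    Subtracting each gene's median centres its profile without touching
    within-gene contrasts; mutant − WT fold changes are unaffected.
    """
    counts = means.groupby("gene_id")["mean_log2"].transform("size")
    if (counts < 2).any():
        raise ValueError("median normalization needs >= 2 conditions per gene")
    med = means.groupby("gene_id")["mean_log2"].transform("median")
    out = means.copy()
    out["mean_log2"] = means["mean_log2"] - med
    return out


def log_fold_changes(means: pd.DataFrame, mutant: str = "mutant") -> pd.DataFrame:
    """Mutant − WT log2 fold change per gene per time point.

    Returns a genes × times frame (index gene_id, columns time_h).
    Positive values mean higher expression in the mutant.
    """
    wide = means.pivot_table(index="gene_id", columns=["strain", "time_h"],
                             values="mean_log2")
    strains = wide.columns.get_level_values(0).unique()
    if mutant not in strains or "WT" not in strains:
        raise ValueError(f"need both 'WT' and {mutant!r} strains")
    wt = wide["WT"]
    mut = wide[mutant]
    if set(wt.columns) != set(mut.columns):
        raise ValueError(
            "time points differ between strains: "
            f"WT {sorted(wt.columns)} vs {mutant} {sorted(mut.columns)}"
        )
    if wt.isna().any().any() or mut.isna().any().any():
        raise ValueError("missing condition means for some gene/time cells")
    return mut[sorted(wt.columns)] - wt[sorted(wt.columns)]


def classify_targets(
    logfc: pd.DataFrame, fc_threshold_log2: float = 1.0
) -> dict[str, ExpressionClass]:
    """Classify each gene's response to losing the regulator.

    A gene crossing +threshold at any time is repressed by the regulator;
    crossing −threshold, activated; a profile crossing both is labelled by
    the larger |excursion| and flagged mixed; otherwise unchanged.
    """
    out: dict[str, ExpressionClass] = {}
    for gene_id, row in logfc.iterrows():
        vals = row.to_numpy(dtype=float)
        times = tuple(row.index)
        up = vals >= fc_threshold_log2
        down = vals <= -fc_threshold_log2
        max_abs = float(np.max(np.abs(vals))) if len(vals) else 0.0
        if up.any() and down.any():
            label = REPRESSED if np.max(vals) >= -np.min(vals) else ACTIVATED
            mixed = True
            support = tuple(t for t, u, dn in zip(times, up, down) if u or dn)
        elif up.any():
            label, mixed = REPRESSED, False
            support = tuple(t for t, u in zip(times, up) if u)
        elif down.any():
            label, mixed = ACTIVATED, False
            support = tuple(t for t, dn in zip(times, down) if dn)
        else:
            label, mixed, support = UNCHANGED, False, ()
        out[str(gene_id)] = ExpressionClass(
            gene_id=str(gene_id),
            logfc={t: float(v) for t, v in zip(times, vals)},
            max_abs_logfc=max_abs, label=label, mixed=mixed,
            supporting_times=support,
        )
    return out


def regulon_summary(
    classes: Mapping[str, ExpressionClass],
    target_gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and fractions of each response class among assigned targets."""
    ids = list(target_gene_ids) if target_gene_ids is not None else list(classes)
    labels = [classes[g].label for g in ids if g in classes]
    n = len(labels)
    rows = []
    for label in (ACTIVATED, REPRESSED, UNCHANGED):
        count = sum(1 for l in labels if l == label)
        rows.append({"class": label, "count": count,
                     "fraction": count / n if n else float("nan")})
    return pd.DataFrame(rows)
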