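"""Windowed local-enrichment statistics and significance calling.

The peak statistic works on a fixed genomic grid (every ``step`` nucleotides,
default 25).  At each grid centre the *local enrichment ratio* is the sum of
per-base coverage in a small centred window (default 51 nt) divided by the
sum in a large centred window (default 2001 nt).  Because the numerator
window is contained in the denominator window the ratio lies in [0, 1], and
it is invariant to library size: multiplying a track by any positive
constant leaves it unchanged.  Input (total DNA) tracks computed the same
way capture shearing and copy-number bias, so the per-position difference

    d = ratio_IP - ratio_total

is centred near zero away from binding sites.  The differences over the
whole chromosome are treated as draws from a normal distribution whose mean
and standard deviation are estimated empirically from the track itself;
upper-tail probabilities of the standardized differences give per-position
raw p-values, which are then adjusted for multiplicity with the Hochberg
step-up procedure (family-wise error control, as in R's
``p.adjust(method="hochberg")``).  Positions whose adjusted p-value is at or
below ``alpha`` (default 1e-4) are the significant positions ("sigDiff")
passed to peak annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CoverageTrack

__all__ = [
    "StatParams",
    "EnrichmentTrack",
    "DifferenceTrack",
    "local_enrichment",
    "difference_track",
    "normal_pvalues",
    "hochberg_adjust",
    "significant_positions",
    "call_condition",
]


@dataclass(frozen=True)
class StatParams:
    """Tunable parameters of the windowed statistic.

    fg_window : odd width (nt) of the numerator window, default 51
    step      : grid spacing (nt), default 25; grid centres sit at
                phase, phase + step, ... (``phase`` defaults to ``step``)
    bg_window : odd width (nt) of the denominator window, default 2001
    alpha     : adjusted-p significance threshold (inclusive), default 1e-4
    tail      : 'upper' (IP > input; default) or 'two_sided'
    edge      : 'truncate' (default) sums windows over their intersection
                with the chromosome; 'drop' discards grid positions whose
                background window is clipped
    """

    fg_window: int = 51
    step: int = 25
    bg_window: int = 2001
    alpha: float = 1e-4
    tail: Literal["upper", "two_sided"] = "upper"
    edge: Literal["truncate", "drop"] = "truncate"
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.fg_window % 2 == 0 or self.bg_window % 2 == 0:
            raise ValueError("fg_window and bg_window must be odd")
        if self.fg_window > self.bg_window:
            raise ValueError("fg_window must not exceed bg_window")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("upper", "two_sided"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.edge not in ("truncate", "drop"):
            raise ValueError(f"unknown edge policy {self.edge!r}")

    @property
    def grid_phase(self) -> int:
        return self.step if self.phase is None else self.phase


@dataclass
class EnrichmentTrack:
    """Local-enrichment ratios on the step grid.

    ``grid_positions`` are 1-based window centres; ``ratios`` holds one
    value per centre, NaN where the background-window sum is zero (coverage
    deserts are *missing*, never zero, so they cannot masquerade as
    depletion downstream).
    """

    grid_positions: np.ndarray
    ratios: np.ndarray
    sample_label: str = ""
    condition_label: str = ""


@dataclass
class DifferenceTrack:
    """IP − total enrichment differences with significance annotation."""

    grid_positions: np.ndarray
    d: np.ndarray
    mu_hat: float | None = None
    sigma_hat: float | None = None
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    condition_label: str = ""


def _window_sums(csum: np.ndarray, centers: np.ndarray, half: int, length: int
                 ) -> np.ndarray:
    """Sum of coverage over [center-half, center+half] ∩ [1, length].

    ``csum`` is the 0-prefixed cumulative sum of the per-base vector.
    """
    lo = np.maximum(centers - half, 1)
    hi = np.minimum(centers + half, length)
    return csum[hi] - csum[lo - 1]


def local_enrichment(track: CoverageTrack, params: StatParams | None = None
                     ) -> EnrichmentTrack:
    """Compute the windowed local-enrichment ratio on the step grid.

    O(n) via cumulative sums.  Windows are truncated at chromosome ends by
    default so near-terminal genes remain callable (``edge='drop'`` removes
    clipped positions instead).
    """
    params = params or StatParams()
    length = track.length
    if length < params.bg_window:
        raise ValueError(
            f"genome length {length} shorter than background window "
            f"{params.bg_window}"
        )
    centers = np.arange(params.grid_phase, length + 1, params.step, dtype=np.int64)
    if params.edge == "drop":
        half_bg = params.bg_window // 2
        keep = (centers - half_bg >= 1) & (centers + half_bg <= length)
        centers = centers[keep]

    csum = np.concatenate(([0], np.cumsum(track.values, dtype=np.float64)))
    fg = _window_sums(csum, centers, params.fg_window // 2, length)
    bg = _window_sums(csum, centers, params.bg_window // 2, length)

    ratios = np.full(centers.shape, np.nan)
    nonzero = bg > 0
    ratios[nonzero] = fg[nonzero] / bg[nonzero]
    if not nonzero.any():
        import warnings

        warnings.warn("all background-window sums are zero; every ratio is missing",
                      stacklevel=2)
    return EnrichmentTrack(grid_positions=centers, ratios=ratios,
                           sample_label=track.sample_label,
                           condition_label=track.condition_label)


def difference_track(ip: EnrichmentTrack, total: EnrichmentTrack) -> DifferenceTrack:
    """Subtract input-DNA enrichment from IP enrichment, elementwise.

    Positions missing (NaN) in either input are missing in the output.
    """
    if ip.grid_positions.shape != total.grid_positions.shape or np.any(
        ip.grid_positions != total.grid_positions
    ):
        raise ValueError("IP and total tracks are on different grids")
    return DifferenceTrack(
        grid_positions=ip.grid_positions.copy(),
        d=ip.ratios - total.ratios,
        condition_label=ip.condition_label or total.condition_label,
    )


def normal_pvalues(track: DifferenceTrack, params: StatParams | None = None
                   ) -> DifferenceTrack:
    """Fit a normal law to the differences and attach raw tail p-values.

    The differences are standardized by their genome-wide empirical mean
    and sample standard deviation (ddof=1); the default upper tail tests
    IP > input, the only direction meaningful for a binding factor.
    """
    params = params or StatParams()
    d = track.d
    ok = ~np.isnan(d)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing differences to fit a normal")
    mu = float(np.mean(d[ok]))
    sigma = float(np.std(d[ok], ddof=1))
    if sigma == 0.0:
        raise ValueError("differences are constant; sigma_hat = 0")
    z = (d - mu) / sigma
    p_raw = np.full(d.shape, np.nan)
    if params.tail == "upper":
        p_raw[ok] = stats.norm.sf(z[ok])
    else:
        p_raw[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return replace(track, mu_hat=mu, sigma_hat=sigma, p_raw=p_raw)


def hochberg_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjustment, identical to R ``p.adjust("hochberg")``.

    For ascending order statistics p_(1) <= ... <= p_(n):
    adjusted_(i) = min_{j >= i} ((n - j + 1) * p_(j)), capped at 1.
    NaNs pass through and do not count toward n.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    out = np.full(p_raw.shape, np.nan)
    ok = ~np.isnan(p_raw)
    if not ok.any():
        return out
    vals = p_raw[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size == 1:
        out[ok] = vals
        return out
    out[ok] = multipletests(vals, method="simes-hochberg")[1]
    return out


def significant_positions(track: DifferenceTrack, params: StatParams | None = None
                          ) -> list[tuple[int, float, float]]:
    """Positions whose adjusted p-value is <= alpha, in genomic order.

    Returns (position, d, p_adj) triples — the contents of a sigDiff file.
    The threshold is inclusive.
    """
    params = params or StatParams()
    if track.p_adj is None:
        raise ValueError("adjusted p-values not computed; run the p-value steps first")
    with np.errstate(invalid="ignore"):
        mask = track.p_adj <= params.alpha
    mask &= ~np.isnan(track.p_adj)
    idx = np.flatnonzero(mask)
    return [
        (int(track.grid_positions[i]), float(track.d[i]), float(track.p_adj[i]))
        for i in idx
    ]


def call_condition(ip: CoverageTrack, total: CoverageTrack,
                   params: StatParams | None = None) -> DifferenceTrack:
    """Convenience: enrichment → difference → p-values → Hochberg, one call."""
    params = params or StatParams()
    diff = difference_track(local_enrichment(ip, params),
                            local_enrichment(total, params))
    diff = normal_pvalues(diff, params)
    diff.p_adj = hochberg_adjust(diff.p_raw)
    return diff
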