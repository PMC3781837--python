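"""Synthetic study generator: genome, annotation, coverage, expression.

Emulates the inputs of a developmental ChIP-seq + transcriptomics study of
a GC-rich, single-chromosome actinomycete:

* a linear chromosome with i.i.d. bases at a stated GC content (default
  0.72, typical of *Streptomyces*), genes of alternating strand separated
  by geometric intergenic gaps;
* the exact binding motif (``GACAC``, or its reverse complement ``GTGTC``
  for reverse-orientation sites) planted 20–250 nt upstream of each
  designated target gene's start codon, with accidental motif occurrences
  scrubbed within ±150 nt of each planting site so planted sites are
  locally unique (genome-wide motif counts stay realistic);
* Poisson-distributed per-base coverage whose mean follows a smooth
  sinusoidal "shear bias" profile (relaxed DNA shears more readily, raising
  input background), with Gaussian-shaped IP enrichment peaks at the
  planted sites in the conditions where the factor is active — by default
  binding is concentrated at the onset of sporulation.  A mock-IP control
  condition carries no true peaks;
* a genes × (strain, time, replicate) log2 expression matrix in which
  targets shift in the regulator-null mutant after a stated onset time.

All randomness derives from one integer seed; each operation draws from a
deterministic sub-stream so regenerating any single piece is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneModel, GenomeSequence

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "GroundTruth",
    "simulate_genome",
    "simulate_coverage",
    "simulate_expression",
    "simulate_study",
]

MOTIF = "GACAC"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_activity() -> dict[str, float]:
    # fraction of targets bound per condition: binding is concentrated at
    # the onset of sporulation (F), partial during vegetative growth (V)
    # and mid-sporulation (S); the mock-IP control (C) has none.
    return {"V": 0.25, "F": 1.0, "S": 0.5, "C": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe one desk-scale study: a 200-kb chromosome at GC 0.72
    carrying 120 genes, 10 of them regulator targets, sequenced to a mean
    input depth of 50 reads/nt with 8-fold summit enrichment, profiled at
    the six 2-hourly time points 10–20 h with 3 replicates per strain, the
    mutant effect (±2 log2 units) switching on at 14 h.
    """

    genome_length: int = 200_000
    gc_content: float = 0.72
    n_genes: int = 120
    gene_length_mean: int = 900
    intergenic_mean: int = 250
    n_targets: int = 10
    peak_enrichment_factor: float = 8.0
    peak_sd: float = 100.0
    background_mean_depth: float = 50.0
    shear_bias_amplitude: float = 0.3
    shear_bias_wavelength: float = 20_000.0
    timepoint_activity: Mapping[str, float] = field(default_factory=_default_activity)
    expr_effect_log2: float = 2.0
    expr_noise_sd: float = 0.3
    class_fractions: tuple[float, float, float] = (0.40, 0.35, 0.25)
    times: tuple[int, ...] = (10, 12, 14, 16, 18, 20)
    n_replicates: int = 3
    onset_time: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        for name in ("genome_length", "n_genes", "gene_length_mean",
                     "intergenic_mean", "n_targets", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_enrichment_factor < 1.0:
            raise ValueError("peak_enrichment_factor must be >= 1")
        if not (0.0 <= self.shear_bias_amplitude < 1.0):
            raise ValueError("shear_bias_amplitude must lie in [0, 1)")
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic sub-stream ``stream`` of the study seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth bookkeeping for one planted binding site."""

    gene_id: str
    motif_position: int      # 1-based first base of the planted 5-mer
    motif_strand: str        # '+' = GACAC on forward strand, '-' = GTGTC
    summit_position: int     # 1-based centre of the planted IP peak
    offset_upstream: int     # nt from motif centre to the target start codon
    expr_effect: float       # signed log2 shift in the mutant (0 = none)


@dataclass
class GroundTruth:
    sites: list[PlantedSite]
    active: dict[str, list[bool]]  # condition -> per-site active flag

    @property
    def target_gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sites):
            row = {
                "gene_id": s.gene_id,
                "motif_position": s.motif_position,
                "motif_strand": s.motif_strand,
                "summit_position": s.summit_position,
                "offset_upstream": s.offset_upstream,
                "expr_effect": s.expr_effect,
            }
            for cond, flags in self.active.items():
                row[f"active_{cond}"] = flags[i]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _choose_targets(rng: np.random.Generator, n_genes: int, n_targets: int
                    ) -> list[int]:
    """Pick target gene indices so no two share one intergenic gap.

    With the alternating strand layout (even index = '+', odd = '-') a
    minus-strand gene at odd index i and the plus-strand gene at i + 1
    diverge into the same gap; planting both would stack two sites in one
    regulatory region, so such pairs are excluded.
    """
    order = rng.permutation(n_genes)
    chosen: set[int] = set()
    for i in order:
        i = int(i)
        if i % 2 == 1 and (i + 1) in chosen:
            continue
        if i % 2 == 0 and (i - 1) in chosen:
            continue
        chosen.add(i)
        if len(chosen) == n_targets:
            break
    if len(chosen) < n_targets:
        raise ValueError("cannot place that many targets without shared gaps")
    return sorted(chosen)


def _scrub_accidental_motifs(
    bases: np.ndarray,
    rng: np.random.Generator,
    gc: float,
    lo: int,
    hi: int,
    protected: list[tuple[int, int]],
) -> None:
    """Remove GACAC/GTGTC occurrences in bases[lo:hi] (0-based slice).

    Occurrences overlapping a ``protected`` interval (previously planted
    sites) are left intact.  Redrawing one base can create a new occurrence
    nearby, so the scan repeats until the window is clean.
    """
    fwd = MOTIF.encode()
    rev = _revcomp(MOTIF).encode()
    for _ in range(20):  # redraws converge quickly; bound the loop anyway
        dirty = False
        window = bases[lo:hi].tobytes()
        for j in range(len(window) - 4):
            word = window[j : j + 5]
            if word != fwd and word != rev:
                continue
            abs_start = lo + j
            if any(s <= abs_start < e or s < abs_start + 5 <= e
                   for s, e in protected):
                continue
            bases[abs_start + 2] = _draw_bases(rng, 1, gc)[0]
            dirty = True
        if not dirty:
            return
    raise RuntimeError("motif scrubbing failed to converge")


def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Generate the chromosome, gene models and planted ground truth."""
    rng = config.rng(0)
    bases = _draw_bases(rng, config.genome_length, config.gc_content)

    # lay out genes left to right with geometric gaps and alternating strand
    genes: list[GeneModel] = []
    target_idx = _choose_targets(rng, config.n_genes, config.n_targets)
    target_set = set(target_idx)
    pos = 1
    for i in range(config.n_genes):
        gap = int(rng.geometric(1.0 / config.intergenic_mean))
        # a gap is a planting region if the gene after it is a '+' target
        # or the gene before it is a '-' target (promoter faces the gap)
        if (i in target_set and i % 2 == 0) or (
            (i - 1) in target_set and (i - 1) % 2 == 1
        ):
            gap = max(gap, 320)  # room for a planted site <= 300 nt upstream
        length = max(90, int(rng.geometric(1.0 / config.gene_length_mean)))
        start = pos + gap
        end = start + length - 1
        if end > config.genome_length - 400:
            raise ValueError(
                f"genome too short: ran out of room at gene {i + 1} of "
                f"{config.n_genes}"
            )
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gene_id=f"sg{i + 1:04d}", start=start, end=end,
                               strand=strand, product=f"synthetic product {i + 1}"))
        pos = end

    # make sure the gap after a trailing '-' target exists
    # (the layout loop already guarantees interior gaps)

    # plant motifs upstream of the designated targets
    motif_arr = np.frombuffer(MOTIF.encode(), dtype="S1")
    rc_arr = np.frombuffer(_revcomp(MOTIF).encode(), dtype="S1")
    sites: list[PlantedSite] = []
    protected: list[tuple[int, int]] = []  # 0-based [start, end) of planted 5-mers
    for i in target_idx:
        gene = genes[i]
        offset = int(rng.integers(20, 251))  # nt upstream of the start codon
        if gene.strand == "+":
            motif_center = gene.start - offset
        else:
            motif_center = gene.end + offset
        motif_start = motif_center - 2  # 1-based first base of the 5-mer
        strand = "+" if rng.random() < 0.5 else "-"

        planted = motif_arr if strand == "+" else rc_arr
        bases[motif_start - 1 : motif_start + 4] = planted
        protected.append((motif_start - 1, motif_start + 4))

        # scrub accidental motif copies within ±150 nt so the planted site
        # is locally unique (genome-wide counts stay realistic)
        lo = max(0, motif_start - 1 - 150)
        hi = min(config.genome_length, motif_start + 4 + 150)
        _scrub_accidental_motifs(bases, rng, config.gc_content, lo, hi, protected)

        sites.append(PlantedSite(
            gene_id=gene.gene_id, motif_position=motif_start,
            motif_strand=strand, summit_position=motif_center,
            offset_upstream=offset, expr_effect=0.0,
        ))

    # per-condition activity and signed expression effects
    act_rng = config.rng(1)
    active: dict[str, list[bool]] = {}
    for cond, frac in config.timepoint_activity.items():
        if frac >= 1.0:
            flags = [True] * len(sites)
        elif frac <= 0.0:
            flags = [False] * len(sites)
        else:
            k = max(1, int(round(frac * len(sites))))
            chosen = set(act_rng.choice(len(sites), size=k, replace=False).tolist())
            flags = [j in chosen for j in range(len(sites))]
        active[cond] = flags

    f_act, f_rep, _ = config.class_fractions
    classes = act_rng.choice(3, size=len(sites),
                             p=[f_act, f_rep, 1.0 - f_act - f_rep])
    signed = []
    for s, c in zip(sites, classes):
        # class 0: activated by the regulator -> expression falls in the
        # mutant (negative logFC); class 1: repressed -> rises; class 2: none
        effect = (-config.expr_effect_log2 if c == 0
                  else config.expr_effect_log2 if c == 1 else 0.0)
        signed.append(PlantedSite(
            gene_id=s.gene_id, motif_position=s.motif_position,
            motif_strand=s.motif_strand, summit_position=s.summit_position,
            offset_upstream=s.offset_upstream, expr_effect=effect,
        ))

    genome = GenomeSequence(chrom_id="synchrom", seq=bases.tobytes().decode())
    return genome, genes, GroundTruth(sites=signed, active=active)


# ---------------------------------------------------------------------------
# Coverage


def _lambda_background(config: SimulationConfig, length: int) -> np.ndarray:
    p = np.arange(1, length + 1, dtype=float)
    return config.background_mean_depth * (
        1.0 + config.shear_bias_amplitude
        * np.sin(2.0 * np.pi * p / config.shear_bias_wavelength)
    )


def simulate_coverage(
    genome: GenomeSequence,
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Draw (IP, total) Poisson coverage tracks for one condition.

    total(p) ~ Poisson(lam(p)) with a sinusoidal shear-bias mean profile;
    ip(p) ~ Poisson(lam(p) * (1 + sum of Gaussian peak bumps)) where each
    active planted site contributes (factor - 1) * exp(-(p - summit)^2 /
    (2 sd^2)), so the IP/total mean ratio at a summit equals the
    enrichment factor.
    """
    if condition not in truth.active:
        raise ValueError(
            f"condition {condition!r} not in ground truth "
            f"(have {sorted(truth.active)})"
        )
    cond_index = sorted(truth.active).index(condition)
    rng = config.rng(100 + cond_index)
    lam = _lambda_background(config, genome.length)

    bump = np.zeros(genome.length)
    for site, is_active in zip(truth.sites, truth.active[condition]):
        if not is_active:
            continue
        centre = site.summit_position
        lo = max(1, int(centre - 6 * config.peak_sd))
        hi = min(genome.length, int(centre + 6 * config.peak_sd))
        p = np.arange(lo, hi + 1, dtype=float)
        bump[lo - 1 : hi] += (config.peak_enrichment_factor - 1.0) * np.exp(
            -((p - centre) ** 2) / (2.0 * config.peak_sd**2)
        )

    total = rng.poisson(lam)
    ip = rng.poisson(lam * (1.0 + bump))
    return (
        CoverageTrack(chrom_id=genome.chrom_id, values=ip,
                      sample_label="IP", condition_label=condition),
        CoverageTrack(chrom_id=genome.chrom_id, values=total,
                      sample_label="total", condition_label=condition),
    )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Long-format log2 expression matrix for WT and mutant time courses.

    WT profiles are flat per-gene baselines; in the mutant each target is
    shifted by its signed effect at every time point at or after
    ``onset_time``.  Independent Gaussian noise (sd ``expr_noise_sd``) is
    added per replicate measurement.
    """
    rng = config.rng(200)
    times = np.asarray(config.times, dtype=float)
    effects = {s.gene_id: s.expr_effect for s in truth.sites}
    baseline = {g.gene_id: float(rng.normal(8.0, 1.0)) for g in genes}

    rows = []
    for g in genes:
        eff = effects.get(g.gene_id, 0.0)
        for strain in ("WT", "mutant"):
            for t in times:
                mean = baseline[g.gene_id]
                if strain == "mutant" and t >= config.onset_time:
                    mean += eff
                noise = rng.normal(0.0, config.expr_noise_sd,
                                   size=config.n_replicates)
                for r in range(config.n_replicates):
                    rows.append((g.gene_id, strain, float(t), r + 1,
                                 mean + noise[r]))
    return pd.DataFrame(
        rows, columns=["gene_id", "strain", "time_h", "replicate", "log2_value"]
    )


def simulate_study(config: SimulationConfig):
    """Generate every input of one synthetic study.

    Returns (genome, genes, truth, coverage, expression) where ``coverage``
    maps condition -> (ip, total) tracks for every condition named in the
    config.
    """
    genome, genes, truth = simulate_genome(config)
    coverage = {
        cond: simulate_coverage(genome, truth, config, cond)
        for cond in config.timepoint_activity
    }
    expression = simulate_expression(genes, truth, config)
    return genome, genes, truth, coverage, expression
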