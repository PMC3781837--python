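# Methods

## The peak statistic

The statistic works on per-base read depth over one linear chromosome
(1-based, inclusive coordinates throughout; 0-based half-open only at
BED/bedGraph boundaries). At every grid centre x (default: every 25 nt,
phase 25) the local enrichment ratio is the coverage sum over a small
centred window divided by the sum over a large centred window (defaults
51 nt and 2001 nt, both odd so the centre is unambiguous). Because the
numerator window is contained in the denominator window the ratio lies
in [0, 1], and it is invariant to multiplying a track by any positive
constant — no library-size normalization is needed. The large window
also makes the ratio insensitive to the smooth coverage undulations that
chromatin shearing bias produces: relaxed DNA shears more readily and
inflates local background, but it inflates numerator and denominator
alike.

The per-position difference d(x) = r_IP(x) − r_input(x) removes what
shearing structure remains (the input library shares it). The
differences across the whole chromosome are then modelled as normal with
parameters fitted empirically: μ̂ = mean(d), σ̂ = sample sd (n − 1
denominator). Raw p-values are the upper-tail probabilities of the
standardized differences; the upper tail is the default because
enrichment of IP over input is the only signal a binding factor can
produce (a two-sided option exists behind `StatParams.tail`). Raw
p-values are adjusted with the Hochberg step-up rule — adjusted_(i) =
min_{j≥i}((n − j + 1)·p_(j)) capped at 1, identical to R's
`p.adjust(method="hochberg")` and routed through statsmodels'
`simes-hochberg` implementation — and positions with adjusted P ≤ α
(default 10⁻⁴, threshold inclusive) are reported.

Empirical standardization is a deliberate reading: evaluating a normal
tail on the raw differences with default (0, 1) parameters would be
meaningless, since the differences have magnitudes of order 10⁻²;
standardizing by the genome-wide moments is the only parameterization
under which the procedure calls peaks at all. The moments are plain
(non-robust): with peaks occupying a small fraction of grid positions
they inflate σ̂ slightly, which is conservative. P-values are computed
per condition (per difference track), each with its own fitted moments.

### Numerical choices

- **Window sums** use one cumulative-sum pass, O(n) per track; windows
  are truncated to the chromosome at the ends (`edge="truncate"`), so
  near-terminal genes stay callable; `edge="drop"` removes clipped grid
  positions instead.
- **Coverage deserts**: a zero denominator yields a missing value (NaN),
  never 0 — deserts must not masquerade as depletion. Missing values
  propagate through differencing, are excluded from the moment fit and
  from the multiplicity count n, and can never be significant.
- **Degenerate inputs**: all-zero coverage warns and returns all-missing;
  constant differences (σ̂ = 0) and fewer than two non-missing
  differences are errors.
- **Grid phase** is configurable; the default grid is step, 2·step, …

## Peak annotation

Significant positions are anchored to the annotation: the flanking gene
on each side, and for each flanking gene whose reading direction faces
the position a signed distance to its start codon (positive = upstream,
negative = inside the gene; a gene presenting its 3′ end gets no
distance and can never be a target). A position is kept iff at least one
available distance is ≤ 300 nt; negative distances always qualify —
peaks just inside a coding region (e.g. at a promoter internal to the
upstream gene) are real regulatory signals. Positions between divergent
genes carry two distances; the expression data decide the target (the
gene whose class is not `unchanged`); if both or neither respond, both
genes are retained and the record flagged ambiguous.

One summit is kept per transcription unit: the record with the smallest
adjusted p over non-control conditions, ties broken by larger |d|, then
by smaller position. Transcription units default to single genes; an
operon table (gene_id → operon_id) collapses members when supplied,
because operon context is curation knowledge an automatic pipeline
cannot infer. Peaks are single grid positions, not merged intervals.

The mock-IP control (an untagged strain processed identically) vetoes
artefact peaks. The veto runs **after** summit selection and is
**peak-level**: a summit is discarded when any position of its contiguous
run of significant grid positions is significant in the control, because
a peak that appears in the control is an artefact in its entirety.
Per-position vetoing at a fixed threshold is subtly wrong in two ways —
run before summit selection, a control-shared peak's borderline flank
(significant in IP, adjusted p just above threshold in the control by
sampling noise) gets promoted to the unit's "summit"; applied only at
the summit itself, the same borderline flank survives whenever it crosses
into a neighbouring unit. The contiguous-run rule removes both failure
modes without introducing a distance parameter, while F-specific noise
calls away from any control signal are untouched (the control has no
business vetoing positions where it saw nothing).

## Motif scanning

The consensus (GACAC by default) is non-palindromic, so forward hits and
reverse-strand hits (GTGTC on the forward strand) are distinct;
palindromic motifs are detected and counted once. Scanning allows
overlaps, reports 0- or 1-mismatch hits (N never matches, even within a
mismatch budget), and peak annotation picks the hit within ±100 nt of
the summit preferring exact over 1-mismatch, then nearer, then '+'
strand. The ±100 nt window spans the numerator window plus grid
uncertainty and is exposed as a parameter, since "close to the peak" is
a judgement call, as is whether orientation tallies should search the
whole intergenic region instead. Orientation is gene-anchored: a hit on
the target gene's coding strand counts as consensus-upstream, the
opposite strand as reverse-complement-upstream.

## Expression integration

Input is an already-normalized log2 expression matrix in long format
(gene, strain ∈ {WT, mutant}, time, replicate). Upstream probe-level
processing (RMA, linear-model replicate fitting) is out of scope;
replicates are combined by the arithmetic mean, which is what the
consumed coefficients amount to. Per-gene median centring (subtracting
each gene's median across condition means) is provided for plotting
parity but cancels in the mutant − WT fold change, and the
classification is provably invariant to it (asserted by test). The
2-fold rule is cell-wise: crossing |log2FC| ≥ 1 at any single time point
suffices, matching per-cell highlighting rather than a whole-profile
test; profiles crossing both thresholds are classified by the dominant
excursion and flagged mixed. Sign convention: positive logFC (higher in
the mutant) ⇒ the factor normally represses.

## The synthetic generator

`SimulationConfig` defaults define one desk-scale study, chosen to mimic
a GC-rich streptomycete chromosome and a developmental ChIP time course:

| parameter | default | meaning |
|---|---|---|
| genome_length | 200 000 nt | chromosome length |
| gc_content | 0.72 | i.i.d. base composition |
| n_genes / gene_length_mean / intergenic_mean | 120 / 900 nt / 250 nt | alternating-strand layout, geometric lengths and gaps |
| n_targets | 10 | genes with a planted binding site |
| peak_enrichment_factor | 8 | IP/input mean ratio at the summit |
| peak_sd | 100 nt | Gaussian summit width (shearing to 300–1000 bp fragments) |
| background_mean_depth | 50 reads/nt | sequencing depth |
| shear_bias_amplitude / wavelength | 0.3 / 20 000 nt | sinusoidal multiplier on the Poisson mean |
| timepoint_activity | V 25 %, F 100 %, S 50 %, C 0 % | fraction of sites bound per condition — binding concentrated at the onset of sporulation; the control has none |
| expr_effect_log2 / expr_noise_sd | ±2 / 0.3 | planted mutant shift and per-replicate noise |
| class_fractions | 0.40 / 0.35 / 0.25 | activated / repressed / unchanged targets |
| times / n_replicates / onset_time | 10–20 h by 2 h / 3 / 14 h | expression design |

Coverage is Poisson with a smooth sinusoidal shear-bias multiplier — the
simplest structure that makes the input-DNA correction non-trivial —
and Gaussian enrichment bumps at planted summits. Motifs are planted
20–250 nt upstream of each target's start codon (orientation random),
after scrubbing accidental consensus occurrences within ±150 nt of the
planting site so planted sites are locally unique; scrubbing is local
only, so genome-wide motif counts stay realistic. Target placement
avoids two sites sharing one divergent intergenic gap. All randomness
flows from a single seed through deterministic per-operation sub-streams.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: read-level errors and mappability, fragment
size distributions, replicate ChIP libraries and batch effects,
operonic co-transcription, autocorrelated expression baselines, and
genuine binding-affinity variation (all planted summits share one
enrichment factor). Recovery rates on this generator are best-case;
the calibration result (family-wise false-call control under the null)
is the property expected to transfer most directly.

## Problem sizes in the test and acceptance runs

The suite exercises oracle equivalence on 100 random 10-kb tracks and
1000 random p-vectors, null calibration on 200 seeded 200-kb no-peak
studies, parameter recovery on 20 studies with 10 planted peaks each,
and expression-class recovery on 50 studies (500 planted effects) —
sizes at which each check completes in seconds while keeping the
binomial error of the measured rates well inside the asserted margins.
`scripts/acceptance.py` re-measures the same quantities from scratch
under a caller-supplied seed.

## Known limitations

- Single chromosome per run; multi-record inputs are rejected rather
  than merged.
- Per-base depth from full read spans (no fragment extension or 5′-end
  counting); whether real pipelines count spans or ends changes peak
  shape slightly and is worth a sensitivity check when porting.
- No replicate-aware calling and no FDR option — the adjustment is
  family-wise (Hochberg), which is what the file chain this mirrors
  used; with ~8000 grid tests per 200-kb chromosome it is conservative.
- Hochberg's validity assumes non-negative dependence; windowed ratios
  on overlapping windows are positively correlated, which is the
  favourable case, but heavy-tailed coverage artefacts (repeats,
  copy-number variation) are not modelled and would inflate calls on
  real genomes without the input correction.
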