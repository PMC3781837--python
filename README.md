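# chipregulon

Windowed-ratio ChIP-seq peak calling and regulon inference for bacterial
transcription factors, with a fully seeded synthetic-study generator.

## The problem

Defining the regulon of a developmental transcription factor in a
bacterium like *Streptomyces* takes two data sets: genome-wide binding
(ChIP-seq of the factor against a non-immunoprecipitated *input* control,
which corrects for chromatin shearing and copy-number bias) and
transcriptional consequence (expression time courses of the wild type
versus the factor-null mutant). `chipregulon` implements the complete
analysis chain between aligned reads and a per-target regulon table, for
a single linear chromosome:

1. **Peak statistic.** Per-base coverage is reduced on a 25-nt grid to a
   *local enrichment ratio*

   r(x) = Σ_{|i−x|≤25} c(i) / Σ_{|i−x|≤1000} c(i)

   (a 51-nt window over a 2001-nt window, both centred on the grid point
   x). The ratio is scale-free, so IP and input libraries need no depth
   normalization. The per-position difference d(x) = r_IP(x) − r_input(x)
   is standardized by its genome-wide empirical mean μ̂ and standard
   deviation σ̂, upper-tail normal p-values p(x) = 1 − Φ((d(x) − μ̂)/σ̂)
   are adjusted with the Hochberg step-up procedure (as in R's
   `p.adjust(method="hochberg")`), and positions with adjusted P ≤ 10⁻⁴
   are significant.
2. **Gene anchoring.** Each significant position gets its flanking genes
   and signed distances to their start codons (positive = upstream /
   promoter-proximal, negative = inside the gene). Positions more than
   300 nt upstream of every nearby start codon are set aside; one summit
   (the most significant position) is kept per transcription unit; summits
   that are also significant in a mock-IP control are discarded.
3. **Motif annotation.** The short asymmetric consensus (GACAC by
   default; reverse complement GTGTC) is scanned on both strands, exactly
   or with one mismatch (near-consensus sites of the GACGC/GACAG type),
   and each peak is annotated with its nearest hit within ±100 nt.
4. **Expression integration.** Replicate log2 expression values are
   averaged per condition, mutant − WT log2 fold changes computed per
   time point, and each target classified by the 2-fold rule: logFC ≥ +1
   at any time ⇒ repressed by the factor, ≤ −1 ⇒ activated, otherwise
   unchanged.

The `synthetic` module generates complete studies with known ground truth
(planted motifs, summits, and signed expression effects) so every stage
is testable without any external data.

## Worked example

```python
from chipregulon import (SimulationConfig, StatParams, call_condition,
                         significant_positions, simulate_coverage,
                         simulate_genome)

config = SimulationConfig(seed=1)          # 200-kb chromosome, 10 targets
genome, genes, truth = simulate_genome(config)
ip, total = simulate_coverage(genome, truth, config, "F")

track = call_condition(ip, total, StatParams())
sig = significant_positions(track)
print(track.mu_hat, track.sigma_hat, len(sig))
```

Running `python examples/simulate_and_call_peaks.py` prints:

```
fitted null: mu_hat=-3.970e-05  sigma_hat=8.075e-03
significant grid positions (adjusted P <= 0.0001): 83
planted summit -> nearest significant position (distance):
  sg0003:    2015 ->    2025 (+10 nt)
  sg0005:    6750 ->    6750 (+0 nt)
  ...
```

The fitted null says the enrichment differences scatter around zero with
sd ≈ 0.008; the 83 significant grid positions all cluster at the ten
planted peaks (each summit recovered within one 25-nt grid step), and a
200-kb no-peak chromosome yields none. `examples/full_regulon_report.py`
chains all stages and prints the stage counts, the per-target table
(position, assigned gene, distance, motif and offset, expression class)
and the activated/repressed/unchanged split; the other examples
demonstrate motif scanning and expression classification in isolation.

A thin CLI mirrors the library for file-based runs:

```sh
chipregulon simulate --seed 1 --outdir study/
chipregulon report --outdir study/
```

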