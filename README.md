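# scrunchkit

Quantitative analysis of planarian locomotion for behavioral phenotyping.
Freshwater planarians (*Dugesia japonica*, *Schmidtea mediterranea*) normally
glide on beating cilia at constant body length; noxious stimuli trigger
**scrunching**, a muscle-driven escape gait of large, asymmetric body-length
oscillations, while disrupted cilia produce the gentler, near-symmetric
**peristalsis**. Telling these gaits apart quantitatively — rather than by
eye — is the core task this package automates, together with the supporting
statistics used in chemical-exposure and RNAi knockdown experiments.

## What it computes

From a recording of a single worm (image stack at a known frame rate) or a
pre-extracted length-vs-time trace, the pipeline measures the four gait
parameters over a window of at least four consecutive oscillation cycles:

- **frequency** `f` — oscillation cycles per second, from the
  trough-to-trough span;
- **maximum elongation** `A` — per-cycle `(L_peak − L_trough) / L_peak`,
  averaged over cycles;
- **relative speed** `v = f · A` — body lengths per second (an exact
  identity, per trace);
- **asymmetry** `a` — fraction of each cycle spent elongating; `a > 0.5`
  is the scrunching hallmark.

A trace is labeled gliding / peristalsis / scrunching by a nearest-centroid
rule on the standardized distance
`d_g = sqrt(Σ_k ((x_k − μ_k,g) / σ_k,g)²)` to published per-species
reference values (packaged with the library), with Welch or pooled t-tests
from summary statistics as an accompanying report. Additional modules cover
15-second-interval behavior scoring with two-reviewer averaging and Fisher's
exact window tests, and qPCR ΔΔCt knockdown quantification
(`relative expression = 2^(−ΔΔCt)`) with standard-curve primer efficiency
`E% = (10^(−1/slope) − 1) · 100`.

Because no raw recordings are publicly deposited, the package includes a
first-class synthetic-data generator: parameterized length waveforms for all
three gaits and rendered 8-bit image stacks, each carrying its exact ground
truth, so every stage is validated end to end.

## Worked example

```
$ scrunchkit run --gait scrunching --seed 1 --out demo/
[run] INFO: simulated and rendered
[run] INFO: extracted trace
[run] INFO: final label: scrunching
scrunching
```

This simulates a scrunching worm (frequency 0.72 cycles/s, maximum
elongation 0.52, asymmetry 0.59 — the *D. japonica* regime), renders it to a
TIFF stack, re-extracts the normalized length trace by segmentation and
moment-based ellipse fitting, quantifies the cycles and classifies the gait.
`demo/summary.json` holds the recovered parameters; for seed 1 the pipeline
reports frequency 0.720, maximum elongation 0.519, speed 0.373 and asymmetry
0.588 over 21 cycles — within a few percent of the generating values — and
the label `scrunching`. The same stages are available individually
(`simulate`, `extract`, `quantify`, `classify`, `score`, `qpcr`), and as
library functions:

```python
import scrunchkit as sk

params = sk.PRESETS["scrunching"]
trace, truth = sk.generate_length_trace(params)
summary = sk.quantify_trace(trace)        # GaitSummary(f, A, v, a, ...)
refs = sk.load_reference_table()
label = sk.classify(summary, refs, species="D_japonica").label
```

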