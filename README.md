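# mdplaque

Analysis toolkit for intravital calcium-imaging recordings of the macula densa
(MD) plaque — a ~25-cell salt-sensing niche at the glomerular vascular pole —
plus a ground-truth simulator for validating every stage of the pipeline.

The pipeline quantifies:

- **Per-cell Ca²⁺ transients** on F/F0-normalized traces: noise-referenced
  peak detection, FWHM by interpolated half-height crossings, firing
  frequency, peak fold-change and cumulative activity.
- **The MD "connectome"**: all-pairs Pearson correlation of the cell traces,
  a thresholded adjacency graph (strict `r > 0.35` by default), degrees, and
  hub / lone / regular cell classification, with heatmap and GraphML export.
- **Whole-plaque oscillation**: mean-F/F0 signal, dominant frequency,
  inter-peak-interval CV and spectral entropy (regular vs. irregular
  "chaotic-like" firing), and cross-correlation coupling between the Ca²⁺
  signal and a paired arteriole-diameter trace.
- **Synthetic plaques** (`mdplaque.simulate`): a coupled-oscillator generative
  model — a latent ~0.03 Hz pacemaker drive plus per-cell Gamma-ISI renewal
  firing, Gaussian fluorescence bumps (~2 s FWHM, ~4-fold peaks), class-wise
  coupling (pacemakers, followers, lone cells) and an in-phase vasomotion
  signal — with `wt`, `ngfr_ko` (4× firing rate, irregular ISIs, halved
  coupling) and `cc4dp_multiclass` presets, planted ground truth, and optional
  rendering to image stacks + ROI masks for end-to-end tests.

## CLI

```sh
# generate a synthetic WT plaque recording (traces.csv, metadata.json,
# diameter.csv, ground_truth.json; --render adds TIFF stack + label mask)
mdplaque simulate --preset wt --seed 7 --out sim/

# full pipeline: normalize -> transients -> connectome -> oscillation
mdplaque analyze sim/traces.csv --metadata sim/metadata.json \
    --diameter sim/diameter.csv --out analysis/

# individual stages
mdplaque transients sim/traces.csv --out out/
mdplaque connectome sim/traces.csv --r-threshold 0.35 --out out/
mdplaque oscillation sim/traces.csv --diameter sim/diameter.csv --out out/
mdplaque report analysis/cell_metrics.csv --group-col cell_class --out report.csv
```

`analyze` writes every stage artifact plus `manifest.json` containing the
resolved configuration; identical inputs and configuration give byte-identical
tabular outputs. Stage parameters can be set in a YAML file (flat
`stage.param` keys, e.g. `detect.k_mad`, `connectome.r_threshold`) passed via
`--config`; CLI flags override file values.

## Library

```python
from mdplaque import simulate, traces, transients, connectome, oscillation

cfg = simulate.preset("wt"); cfg.seed = 7
rec = simulate.simulate_plaque(cfg)
norm = traces.normalize(rec.traces, traces.estimate_baseline(rec.traces))
events = transients.detect_transients(norm)
corr = connectome.pairwise_correlation(norm)
graph = connectome.threshold_graph(corr, r_threshold=0.35)
labels = connectome.classify_hub_lone(graph)
```

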