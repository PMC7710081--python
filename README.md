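# tactilepop

Simulation of the population of FA-1 first-order tactile neurons innervating
a fingertip skin patch, and a synaptic-integration readout that discriminates
the orientation of edges moving across the skin.

What's inside:

- **Spiking neuron model** (`tactilepop.neuron_model`): each model neuron
  innervates a set of mechanoreceptors (MRs) on a 0.1 mm grid. MR drive is
  the local stimulus amplitude times a sigmoid of the perpendicular distance
  to the moving edge (zero beyond `r1 + r2`). Spikes are generated per
  axonal branch by a phase accumulator with linear input→rate (gain 1),
  saturation at the neuron's maximal rate, an adaptation rule (fires only on
  increasing drive) and a 0.01 mm indentation threshold. The default
  **reset** scheme propagates each spike back to all branches and restarts
  their initiation; *mixing* and *summation* variants are available as
  diagnostics.
- **Stimuli & noise** (`tactilepop.skin_stimulus`): moving oriented edges
  (30 mm/s, 0.5 mm amplitude) with unlimited or windowed (5–50 ms)
  presentation, dot stimuli, and additive amplitude noise in 0.4 × 0.4 mm
  tiles (uniform in ±level% of the stimulus amplitude, clamped so the
  stimulus stays non-negative).
- **GA fitting** (`tactilepop.fitting`): fits MR locations and the two
  responsivity distances to multi-trial rate curves at ±22.5°/±45° (R² of
  smoothed rate curves, averaged over orientations), cross-validates at 0°,
  tests at 30°, and applies the published model-selection ladder over MR
  counts. Includes shuffled-location null models and the nearest-edge
  baseline.
- **Population** (`tactilepop.population`): randomly rotated variants of the
  base neurons tiled over a 12 × 12 mm patch at 140 neurons/cm².
- **Readout** (`tactilepop.readout`): PSP kernels (difference of
  exponentials, τ_rise 0.5 ms; τ_decay 3 ms "AMPA" / 65 ms "NMDA"),
  convolution of population spike trains, and a two-unit classifier (signed
  weights in [−1, 1], decision by the unit with the larger maximum summed
  PSP) trained by a GA.
- **Experiments & analysis** (`tactilepop.experiments`,
  `tactilepop.analysis`): ±θ discrimination with train/test splits and
  repeated classifier training; key-synapse identification by bootstrap over
  classifier ensembles with Bonferroni correction, classifier-unit receptive
  field maps, and weight correlations between oppositely tuned units.
- **Synthetic recordings** (`tactilepop.synthetic_data`): ground-truth model
  neurons plus jittered multi-trial spike "recordings" following the same
  orientation protocol, so fitting and discrimination are fully testable
  without any external data.

## CLI

The `tactilepop` entry point chains the pipeline; every run writes a
`manifest.json` with seeds and a config digest so runs are reproducible.

```sh
tactilepop synth --neurons 3 --trials 7 --seed 1 --out data/
tactilepop fit --dataset data/neuron00 --n-mr 10,20 --ga-pop 100 \
    --iterations 500 --seed 1 --out models/neuron00.json
tactilepop population --models models/ --density 140 --seed 1 --out pop.json
tactilepop simulate --pop pop.json --theta 20 --noise 5 --out raster.csv
tactilepop discriminate --pop pop.json --theta 20 --noise 5 \
    --channels ampa --repeats 20 --seed 1 --out results/
tactilepop analyze --classifiers results/ --out report/
```

Models, populations and classifiers are stored as versioned JSON; spike
trains as CSV (`trial_id, orientation_deg, spike_time_ms`).

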