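# optonet

Simulation and analysis of **all-optical neural-network assays**: wide-field
calcium-imaging recordings of dissociated neuronal cultures that co-express a
channelrhodopsin (for blue-light stimulation) and a red genetically encoded
calcium indicator (for readout). A staircase of blue pulses drives the
culture — either full-field or through a circular spatial mask — while the
indicator reports each neuron's activity at 10 frames/s, and the analysis
chain turns the movie into a functional-connectivity estimate of the network.

The package is aimed at people building or validating such assays: it ships a
ground-truthed synthetic-data generator that emulates the acquisition (so
every analysis stage can be scored against a planted truth without any real
recording) together with the full analysis pipeline:

1. **Segmentation** — cell bodies detected on the temporal-mean image by a
   circular Hough transform; each soma becomes a circular ROI.
2. **ΔF/F** — the photobleaching baseline of each raw trace is estimated by
   two-pass ("double") exponential-decay fitting, `F_base(t) = a·e^(−t/τ) + c`,
   with transient frames excluded from the refit; then
   `ΔF/F(t) = (F(t) − F_base(t)) / F_base(t)`.
3. **Events** — calcium transients characterized by amplitude (peak ΔF/F over
   baseline), rise time (time-to-peak) and fall time (exponential-decay fit of
   the post-peak segment).
4. **Zones** — ROIs partitioned into *stimulated* (inside the mask radius r),
   *zone 1* (r < d ≤ 2r; 600 μm for the standard 300 μm mask) and *zone 2*
   (beyond), with per-pulse peak ΔF/F summarised as mean ± SEM per zone —
   quantifying how far evoked excitation spreads through the network.
5. **Connectivity** — for each pair of neurons the maximum over short lags of
   the normalized cross-correlation of their ΔF/F traces, tested against a
   null built from 100 circular time-shift reshuffles; significant pairs form
   a binary adjacency matrix **A**, summarised by the

   **mean global connectivity**  MGC = mean(Σⱼ A(i,j)) / (N − 1),

   the mean node degree divided by N − 1: 0 for an empty graph and 1 when
   every node is connected to every other node.

## Worked example

Simulate the standard assay (60 neurons in an 832 × 702 μm field, 10 pulses
of 100 ms in 7 mW/cm² steps 5.5 s apart, 600 frames at 10 Hz, 300 μm mask),
analyse the rendered movie, and score the recovery against the planted truth:

```python
from optonet.pipeline import RunConfig, run_benchmark

report = run_benchmark(RunConfig(seed=7))
for key in ("segmentation_precision", "segmentation_recall",
            "dff_rmse", "mgc_inferred"):
    print(key, report[key])
```

```
segmentation_precision 1.0
segmentation_recall 1.0
dff_rmse 0.049384169401021125
mgc_inferred 1.0
```

All 60 planted somata are found with no false detections; the recovered ΔF/F
traces sit within 0.05 RMSE of the planted ground truth; and the inferred
mean global connectivity is 1.0 — the optogenetic drive plus synaptic spread
(transmission probability 0.5 on a 15%-dense graph) synchronises the whole
culture, so every pair is functionally connected. Re-running with synaptic
transmission disabled (`cfg.network.transmission_prob = 0.0`, emulating a
recording under glutamatergic blockers) drops `mgc_inferred` to 0.31: only
the co-stimulated neurons inside the mask remain correlated.

The same pipeline is available from the shell:

```sh
optonet simulate --seed 7 --out run/sim
optonet analyze run/sim/movie.tif --seed 7 --out run/analysis
optonet benchmark --seed 7 --out run/benchmark
```

with every parameter configurable through a YAML file (`--config`); stage
outputs are written as TIFF / CSV / JSON with a manifest carrying the config
hash, and a single seed fans out deterministically to every stage.

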