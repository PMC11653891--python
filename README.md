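# caimetrics

Quantitative analysis of miniscope calcium-imaging recordings of neuronal
ensembles — the kind of data produced by head-mounted miniature fluorescence
microscopes imaging GCaMP6f-expressing hippocampal CA1 neurons in freely
moving mice, after source extraction (e.g. CNMF/Minian) has reduced the
movie to per-neuron fluorescence traces and ROI centroids.

The package answers the questions such experiments pose: how active is each
neuron and the ensemble as a whole, how strongly are neuron pairs
co-activated, how are correlated pairs arranged in space, which neurons
respond to a perturbation such as acute stress when tracked across days,
and does the ensemble's overall state return to baseline.

## What it computes

Given a trace matrix `F ∈ R^{T×N}` (frames × neurons, 15 frames/s) the
pipeline proceeds:

1. **Binarization** — four rule-based active-state detectors produce
   `B ∈ {0,1}^{T×N}`:
   *spike* (rise phase only: smoothed first difference above a robust noise
   floor, with `cold`/`warm` run filtering; defaults window = 10, cold = 0,
   warm = 50 frames), *full* (trace > median + 3·MAD), *signal*
   (z-scored trace > 2), *diff* (z-scored first difference > 2), plus the
   *active accuracy* |a∧b| / |a∨b| overlap of two binary traces.
2. **Activity metrics** — burst rate (activations/min per neuron, an
   activation being one contiguous active run); network spike rate
   NSR(t) = 100·|{i : neuron i active in 1-s interval t}| / N; network spike
   peak max_t NSR(t); network spike duration (seconds with NSR above
   2.5, 5, 10, 15, 20, 25 %); distribution histograms (1/3 events/min and
   2.5-percentage-point bins).
3. **Correlation network** — zero-lag Pearson `r_ij` between binarized
   traces; mean coefficient above a threshold; network degree (fraction of
   pairs with `r > θ` for θ = 0.00 … 0.30, step 0.05); per-neuron
   connectivity; a data-derived *strong-correlation* threshold (mean 95th
   percentile over baseline recordings, snapped to the 0.05 grid — 0.3 is
   the usual operating point); clusters linking pairs above the 80th
   percentile of all pair coefficients, with intra/inter-cluster means.
4. **Spatial statistics** — Euclidean centroid distance and radial distance
   `| ‖p_i − c‖ − ‖p_j − c‖ |` (c = ensemble center of mass) for weakly
   (0 < r ≤ 0.3) versus strongly (r > 0.3) correlated pairs.
5. **Cross-session tracking** — greedy nearest-centroid matching within
   7 px; burst rates normalized to a baseline day; neurons classified
   activated (> 1.75), inhibited (< 0.5) or non-responsive.
6. **Ensemble state** — each recording summarized as a fixed-schema vector
   of all metrics across all four binarization methods, standardized and
   projected by PCA into 2-D, with ranked feature loadings.
7. **Group statistics** — normality-gated parametric/nonparametric
   comparisons (t-test/ANOVA + Tukey/Dunnett vs Mann-Whitney/Kruskal-Wallis
   + Dunn) as thin plumbing over scipy/statsmodels.

A seeded synthetic-recording generator (Poisson events, GCaMP6f-like
difference-of-exponentials transients, controllable pairwise event sharing,
multi-session series with per-state rate multipliers, centroid jitter and
dropout) provides ground truth for every stage; see `docs/methods.md`.

## Worked example

```python
import caimetrics as cm

cfg = cm.SimConfig(n_neurons=50, duration_s=300, rate_per_min=1.27,
                   noise_sd=0.05, seed=8)
traces, truth = cm.simulate_recording(cfg)
raster = cm.binarize_matrix(traces, "spike")
rates = cm.burst_rate(raster)
print(f"true mean rate      {truth.rate_per_min.mean():.3f} events/min")
print(f"recovered mean rate {rates.mean():.3f} events/min")
print(f"network spike peak  {cm.network_spike_peak(raster):.1f} % of neurons")
nsd = cm.network_spike_duration(raster)
print(f"time above 5% co-activity {nsd[5.0]:.0f} s of 300 s")
graph = cm.pairwise_pearson(raster)
print(f"mean pair correlation {graph.pair_values().mean():+.4f}")
print(f"network degree at r>0 {cm.network_degree(graph)[0.0]:.3f}")
```

prints

```
true mean rate      1.368 events/min
recovered mean rate 1.280 events/min
network spike peak  14.0 % of neurons
time above 5% co-activity 90 s of 300 s
mean pair correlation +0.0009
network degree at r>0 0.191
```

The recovered burst rate tracks the realized Poisson rate (the small
deficit comes from the `warm` gap-merging joining events closer than
~3.3 s); the network spike peak says at most 14 % of the 50 neurons were
co-active within any one second; pair correlations of independent neurons
center on zero, with 19 % of pairs above it by chance.

The same steps are scriptable from a shell via the `caimetrics` command
(`simulate`, `binarize`, `metrics`, `correlate`, `distances`, `track`,
`pca`, `report`); run `caimetrics --help`.

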