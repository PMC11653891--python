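# Methods

This note documents the models, conventions and numerical choices behind
`caimetrics`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what each procedure assumes, which knobs matter,
and what the synthetic benchmark does and does not demonstrate.

## Scope and data model

The pipeline starts where source extraction ends. Inputs are a fluorescence
trace matrix (frames × neurons, arbitrary units, 15 frames/s by default), a
table of ROI centroids in pixels, and a manifest labelling recordings by
mouse and experimental state (five baseline days, a stress session, 3 h and
10 days after). Raw movies, motion correction and CNMF demixing are out of
scope. Recordings are trimmed to their middle segment before analysis
(default: drop the first and last 60 s, so a 7-min recording yields the
5-min fragment all metrics are computed on). Frames are 0-based internally;
reported times are in seconds.

## Synthetic recordings

Because suitable public recordings with ground truth do not exist at this
granularity, every stage is validated against a generator that emulates the
statistical structure the analysis assumes:

- **Events.** Each neuron fires as a homogeneous Poisson process with a
  configurable rate (default setting used throughout the benchmark:
  1.27 events/min at baseline, a plausible CA1 operating point), thinned to
  unique frame indices.
- **Coupling.** A pair (i, j, f) rebuilds j's train: each of i's events is
  copied into j with probability f, each of j's own events survives with
  probability 1 − f. Coupled events coincide exactly (no jitter), which
  makes the induced binarized Pearson correlation monotone in f by
  construction and easy to reason about in tests; f = 1 duplicates the
  train, f = 0 leaves it independent.
- **Transients.** Each event adds a difference-of-exponentials kernel
  A·(e^(−t/τ_d) − e^(−t/τ_r)) normalized to unit continuous peak, with
  τ_r = 0.1 s and τ_d = 0.6 s — fast-indicator (GCaMP6f-like) kinetics,
  stated assumptions exposed in `SimConfig` since real recordings' kinetics
  and SNR vary. Per-event amplitudes are LogNormal(0, 0.25) so transients
  are not degenerately identical (set `amplitude_sigma=0` to disable);
  overlapping transients sum; Gaussian noise of SD `noise_sd` (default
  0.05, i.e. 5 % of the unit peak) is added per frame.
- **Sessions.** A multi-session series draws base rates and positions once
  per mouse, multiplies rates by a per-state factor (benchmark: stress 2.0,
  3 h 1.8, 10 days 1.0 — the direction and rough magnitude of an acute
  stress response), jitters centroids (SD 1–2 px) and drops each neuron
  independently per session (default 10 %). Neuron ids are stable across a
  mouse's sessions, so the planted identity is available to score matching.

What the generator does **not** emulate: neuropil contamination, motion
artifacts, indicator saturation, bursty (non-Poisson) firing, distance- or
topology-dependent correlation structure, and slow drift of baseline
fluorescence. Passing the benchmark therefore shows the pipeline's
arithmetic and its noise robustness in a controlled regime, not performance
on every pathology of real data.

Determinism: all draws flow from one `numpy` Generator seeded from
`SimConfig.seed`; identical seeds give bit-identical traces, onsets and
positions.

## Binarization

- **spike** marks the rapid-growth phase of a transient. The trace is
  smoothed by a centred moving average (`window` = 10 frames; edges use a
  truncated window rather than padding, which is deterministic and
  shift-free; even windows are asymmetric by one frame). Candidate active
  frames are those where the smoothed first difference exceeds
  `slope_z` × (1.4826·MAD of the smoothed differences), with `slope_z` = 4.
  The noise floor is essential: the sign of a smoothed derivative is a coin
  flip wherever the trace is flat, so a plain positive-difference rule
  would mark half of all quiescent frames on any noisy recording. Because
  the floor is proportional to the MAD it vanishes on noise-free traces,
  where the rule reduces exactly to "strictly positive first difference".
  Runs shorter than `cold` frames (default 0: the minimum active-phase
  duration) are then deleted, and passive gaps shorter than `warm` frames
  (default 50: the minimum passive-phase duration) merge their flanking
  runs, in that order. The warm merge means events closer than ~3.3 s are
  counted once; at 1.27 events/min this biases recovered rates about 6 %
  low, a property of the parameterization rather than a defect of the
  implementation. Activation counts are non-increasing in `warm` when
  `cold` = 0 and non-increasing in `cold` when `warm` = 0; joint
  monotonicity in both does not hold in general (deleting a short bridge
  run can split a would-be merge), so the property tests quantify each
  parameter at the other's default.
- **full** thresholds at median + 3·MAD. When the MAD is zero (mostly-flat
  trace) it falls back to mean + 3·SD, and when the SD is also zero the
  trace is constant and everything is inactive — the rule is total on
  degenerate inputs. Note the fallback can place the cut exactly at a
  plateau's height when the plateau occupies enough of the trace; the
  strict `>` then excludes it.
- **signal** thresholds the z-scored raw intensity at z = 2;
  **diff** the z-scored first difference at z = 2. Both return all-zero for
  zero-variance input. Thresholds z = 2 and k_MAD = 3 are package defaults,
  exposed in the API and CLI.
- An *activation* is one contiguous active run (0→1 transition; a run
  starting at frame 0 counts). *Active accuracy* is the Jaccard overlap of
  two binary vectors, 0 by convention when neither is ever active.

## Activity metrics

"Active in an interval" means at least one active frame inside it (the
natural reading of counting active neurons per 1-s section); the trailing
partial interval is dropped (a 5-min recording at 1 s divides evenly, so
this only matters for unusual inputs). Histograms use left-closed
right-open bins anchored at zero — burst rates in 1/3 events/min bins, NSR
in 2.5-point bins over [0, 100] with the last bin closed so a fully active
interval is counted. Network spike duration is reported in seconds
(per-threshold count of 1-s intervals with NSR strictly above threshold); a
percent-of-recording variant is available via `as_fraction=True`.

## Correlation network

Pearson coefficients are computed between binarized frame vectors. A neuron
whose binarized trace is constant (typically: no events) has no defined
correlation; such entries are stored as 0 with `defined=False` and are
**excluded** from all percentiles and means rather than zero-filled, since
zero-filling would bias threshold estimation downward. Denominators that
count "all pairs" (network degree, connectivity) still use the full pair
count, so undefined pairs can only lower a degree, never raise it.

Percentiles use linear interpolation between order statistics throughout
(the numpy default; the convention is part of the contract, e.g. with six
pair values the 80th percentile lands exactly on the second-largest value
and the strict rule then keeps only the top edge). The strong-correlation
threshold is the mean per-recording 95th percentile over all baseline
recordings — taken over all defined off-diagonal coefficients, not only
positive ones — snapped to the nearest multiple of the 0.05 threshold
grid with exact ties rounding up. Clusters link pairs strictly above the
80th percentile of all defined pair coefficients and are read off as
connected components with at least two members; this minimal relational
closure is the weakest rule consistent with a pairwise "stronger than 80 %
of connections" criterion. Intra-cluster values average within-cluster
pairs; inter-cluster values average, per clustered neuron, its
coefficients with all out-of-cluster neurons.

## Spatial statistics

The center of mass is the unweighted centroid of all neuron positions (ROI
areas are unavailable after extraction). The radial distance never exceeds
the Euclidean distance (triangle inequality through the center). The weak
band is (0, strong-threshold] by default — negative and zero coefficients
belong to neither band — and is configurable, since "weakly correlated"
has no canonical lower bound. Distances are reported in pixels.

## Cross-session tracking

Matching is greedy on global nearest centroid distance with a 7 px
acceptance radius and deterministic lexicographic tie-breaking; it is a
transparent substitute for footprint-based probabilistic registration,
justified here because the acceptance radius is the only exposed parameter
and centroids are all that survives extraction. Expected failure mode:
neurons that happen to sit within the jitter scale of each other can swap
(~0.5 % of neurons at 100 neurons per 600×600 px field with 2 px jitter);
this is inherent to any centroid-only matcher, so accuracy claims are
evaluated pooled over many simulated fields. Multi-session designs are
matched pairwise against the designated reference session (baseline day 5),
not chained transitively.

Rates are normalized per neuron to the reference session; neurons silent at
baseline are excluded (their ratio is undefined), with the exclusion count
returned. Classification uses strict thresholds — activated > 1.75,
inhibited < 0.5, non-responsive on the closed interval between — so
boundary values fall in the middle band and the partition is exhaustive
and exclusive.

## Ensemble state (PCA)

Each recording becomes a 100-feature vector: for each of the four
binarization methods, mean burst rate, mean NSR, network spike peak, six
network-spike-duration values, seven network-degree values, mean pair
correlation, mean connectivity at the strong threshold, intra/inter-cluster
means, four band-distance means, and mean pairwise active accuracy
(25 features × 4 methods, fixed ordering via `feature_schema()`).
Distributional metrics enter as scalar summaries (means); undefined entries
(e.g. an empty strong band) are NaN and are imputed with the feature's
cross-recording mean — variance-neutral under standardization — with
imputation counts recorded in the projection. Features are standardized to
zero mean and unit variance (PCA on the correlation matrix; the features
mix units, so unstandardized PCA would be dominated by large-scale
features); zero-variance features are dropped and logged. Component signs
follow the largest-|loading|-positive convention, making projections
reproducible bit for bit and invariant (up to that fixed sign) to
recording order.

## Group statistics

`compare_groups` is declared plumbing: Shapiro-Wilk below 50 samples per
group, Kolmogorov-Smirnov otherwise, Bartlett for variance homogeneity;
the parametric branch (t-test / one-way ANOVA with Tukey or Dunnett) is
taken only when every group passes both at α, otherwise Mann-Whitney /
Kruskal-Wallis with Dunn's rank post-hoc (Holm-adjusted z-tests on mean
ranks with tie correction — composed from scipy/statsmodels primitives, as
no installed package ships Dunn's test). The branch taken is recorded in
the report and is a deterministic function of the data and α. The post-hoc
choice is per-comparison configuration, not a global rule.

## Benchmark problem sizes

The shipped test-suite and acceptance-script simulations use 25–100 neurons
per recording, 5-minute recordings at 15 fps, 8–24 recordings per PCA, and
50 pooled fields for tracking — small enough to run in seconds while
leaving the statistical assertions (3-SE bands, ≥0.9 precision/recall,
≥99 % pooled tracking accuracy, positive silhouette) well-powered.

## Known limitations

- The spike detector's `warm` merge undercounts genuinely close events by
  design; rate estimates inherit a small negative bias at high rates.
- The "signal is less strict than full" intuition holds for roughly
  symmetric noise but can invert on strongly skewed traces (median + 3·MAD
  can sit below mean + 2·SD); neither detector's active set provably
  contains the other's.
- Centroid-only tracking cannot distinguish neurons closer than the
  registration jitter.
- Correlation statistics are zero-lag only; no lagged, partial or
  model-based connectivity is attempted.
- PCA is linear by construction; group separation along PC1 is a property
  of rate-sensitive features, not evidence against nonlinear structure.
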