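# Methods

This note documents the models and conventions implemented in `fcdyn`,
the parameters that matter, and the choices made where the underlying
method description left the design genuinely open.

## Sliding-window connectivity

A window of `window_size` N volumes is advanced by `step_size` volumes;
each position yields one R×R matrix of pairwise Pearson correlations of
the ROI signals inside the window, giving `W = ⌊(T−N)/step⌋ + 1` matrices
(no partial windows: trailing volumes not covered by a full window are
dropped).  Each window is identified with its **last** volume — the FC
estimate "at time t" uses the current and previous N−1 volumes — and the
1-based index of that volume is stored with the series so that masks can
address windows in scan time.  Setting `window_size = T` reduces the
analysis to the ordinary static correlation matrix.

With a Gaussian taper, the correlation is a weighted Pearson coefficient
with weights `exp(−(i−c)²/2σ²)` centred on the window midpoint and
normalised to sum 1.  The default σ = N/6 TRs places ±3σ at the window
edges; uniform weights recover the plain correlation exactly.  A window in
which an ROI is constant has no defined correlation for that ROI's edges;
those entries are stored as NaN ("missing") rather than 0, because 0 is a
meaningful correlation value, and missing edges are never kept by any
binarization rule.

Defaults (window 17 TRs, step 1 TR at TR = 1 s) follow the usual
guidance: at least ~15 volumes per window for a stable correlation
estimate, and a window shorter than one task block so that mid-block
dynamics remain visible.  A 300-volume scan yields 284 matrices.

## Temporal filtering

Frequency-domain filtering is zero-phase hard masking of FFT bins.
Cutoffs are specified as **periods in seconds** (e.g. a high-pass at 75 s
passes fluctuations faster than 1/75 Hz).  A hard brick-wall cutoff was
chosen over an IIR/FIR design because it is fully reproducible with no
order/ripple parameters to pick.  High-/band-pass zero the DC bin (mean
removed); low-pass keeps it.

The wavelet route computes a maximal overlap discrete wavelet transform
multiresolution analysis (MODWT MRA) per ROI: the series is extended to
length 2T by reflection, analysed circularly via the MODWT transfer
functions (orthonormal filter pair rescaled by 1/√2, evaluated at dyadic
strides in the Fourier domain), and truncated back to T.  Because the
squared gains of the L detail bands and the level-L smooth tile the
spectrum exactly, the MRA components add back to the input to machine
precision; the filter output is simply the sum of the selected detail
series.  The level-j detail occupies the nominal band [fs/2^(j+1),
fs/2^j]; at TR = 1 s, levels {3,4,5} cover 1/64–1/8 Hz (≈0.016–0.125 Hz),
the band usually quoted as carrying most task-related haemodynamic
signal.  The wavelet family is unspecified in the method description; the
default is the least-asymmetric orthogonal wavelet of length 8 (`sym8`),
configurable.  The level-L approximation (slow drift) is **zeroed** by
default when reconstructing from selected levels, since the canonical
level selection names only details 3–5; `keep_approximation=True`
restores it.

## Task design, HRF, and the temporal inclusive mask

The block design (condition vector of 0/1 per block, durations in TRs) is
expanded to a per-TR boxcar and convolved with the canonical double-gamma
HRF — the difference of a gamma density peaking near 5 s (shape 6,
scale 1) and an undershoot gamma (shape 16, scale 1) scaled by the 6:1
peak:undershoot ratio, sampled at the TR over 32 s and unit-sum
normalised.  The convolution, truncated to the scan length, is the
estimated activation curve.  Two normalisations are implemented:
**global** (divide by the curve's own maximum, so values lie in [0,1]) —
the default — and **single-event** (divide by the peak response to a
one-TR stimulus, under which sustained blocks plateau above 1).

Two criteria mark task-stimulation-related windows:

* **Activation-level**: the window's estimated activation exceeds a
  threshold (default 0.8).
* **Condition-coverage**: at least X% (default 80) of the window's
  volumes fall under the selected condition.

When both are enabled (the default) they are combined with a logical AND.

### The frozen alignment convention

A 17-volume window spans 17 s of scan time, so "the window's activation"
and "the window's condition" require a convention.  The defaults freeze
the following pair, chosen once for internal consistency and because it
reproduces the canonical worked example (79 of 284 windows for the
5×30 s task / 5×30 s rest design at the default thresholds):

* the activation criterion uses the **mean of the normalised activation
  curve over the window's volumes** ("window-mean").  Under it, the
  selected windows form a run of 17 per 30-TR task block — the windows
  whose span sits inside the block's haemodynamic plateau — plus a final
  run truncated to 11 by the end of the scan: 17×4 + 11 = 79;
* the coverage criterion counts volumes against the **haemodynamically
  aligned condition**: a volume is "task" while the estimated activation
  exceeds half its maximum.  The BOLD response lags the stimulus by
  ~6 s, so evaluating coverage on the raw boxcar would clip the tail of
  every activation run by the haemodynamic delay and make the AND depend
  on an arbitrary relative offset between the two criteria; lag-aligning
  the condition makes coverage a consistent superset of the plateau
  windows.

Per-volume alternatives remain available and are not hidden behind the
defaults: `activation_mask(..., convention="last"|"center")` reads the
curve at a single representative volume, and `coverage_mask(...,
on="design")` counts raw boxcar volumes (under which the canonical design
gives 97 windows at 80%, and exactly the 14 fully-interior windows per
30-TR block at 100%).  Raising either threshold never adds windows, and
the combined mask is always a subset of each single-criterion mask.

Masks can also be set manually (explicit window indices) and round-trip
through a JSON file that records the design, thresholds and convention
flags alongside the selected indices.

## Binarization

Given a correlation matrix (diagonal ignored; NaN entries never kept;
`use_abs` optionally takes |r| first):

* **absolute** — edge iff r > τ, τ ∈ [−1, 1]; strict inequality for
  determinism at ties.
* **proportional** — edge iff r > τ · max off-diagonal r of that matrix
  (the diagonal is excluded from the reference, else the rule would be
  vacuous).
* **cost** — keep the top `round(τ · n(n−1)/2)` off-diagonal values;
  ties broken by descending value then lexicographic node-pair order; a
  request exceeding the number of finite entries is capped with a
  warning.

The default sweep is absolute thresholds 0.5–0.85 in steps of 0.01
(36 levels).

## Graph metrics

All metrics operate on undirected binary graphs (symmetric 0/1 adjacency,
zero diagonal).  Shortest-path distances d_ij are **edge counts** from
per-node BFS.  Conventions for disconnected graphs, stated prominently
because they matter at sparse thresholds:

* unreachable pairs contribute **0** to global and nodal efficiency
  (the 1/d_ij term vanishes);
* the characteristic path length averages over **reachable ordered pairs
  only**; with no reachable pair it is undefined (NaN in tables).

Definitions: E_glob is the mean of 1/d_ij over ordered pairs; network
local efficiency is the mean over nodes of the global efficiency of each
node's neighbour-induced subgraph (nodes with <2 neighbours contribute
0); C(i) = 2·(triangles through i)/(k_i(k_i−1)) with C(i)=0 for k_i<2 —
on binary graphs the cube-root-product triple sum reduces to exactly this
triangle count — and the network clustering coefficient is the plain mean
of C(i) over all nodes; transitivity is 3·triangles / connected triples
(0 with a warning when no triple exists); assortativity is the Pearson
correlation of endpoint degrees over both orientations of every edge
(NaN, not an exception, when the degrees are constant); betweenness
B(i) sums, over ordered pairs j≠k (both ≠ i), the **number** of shortest
j–k paths through i divided by the total number of shortest j–k paths,
normalised by (n−1)(n−2) — computed with Brandes' accumulation.  The
path-count reading is the only one under which the per-pair ratio is
well defined when several shortest paths exist.

Modularity Q is maximised by deterministic greedy agglomeration: starting
from singletons, repeatedly merge the connected pair of communities with
the largest ΔQ = e_cd/m − k_c k_d/(2m²) (ties broken by lowest community
index pair), tracking the best partition seen; the result is never below
the single-module partition's Q = 0.  An exhaustive search over all set
partitions (`method="exact"`) is available for small n and is what the
test suite compares against.

### Random-network normalisation

γ = C/C_rand and λ = L/L_rand divide by the mean clustering and path
length of an ensemble (default 20) of **uniform random simple graphs with
exactly the same node and edge counts** as the network under test;
σ = γ/λ.  The literal same-(n, m) null was kept as the default;
degree-preserving rewiring is available as an alternative
(`method="rewire"`) since it is common practice.  Ensembles are seeded
and deterministic; per-window/threshold seeds are derived from the run
seed so parallel and serial evaluation orders give identical output.

## Stability statistics

The temporal dynamics of a metric trajectory are summarised by the sample
variance (N−1 denominator) of the finite values over the masked windows;
at least two usable windows are required.  Group curves report the
pointwise mean and SEM = sd/√n_subjects.  Task-masked and full-duration
variances are compared with a two-sided paired-sample t-test on the
per-subject differences; a positive t means lower variance under the
mask.  Variances are computed per threshold; the group summary averages
them over thresholds within subject before pairing (both views are
written out).  No multiple-testing correction is applied across metrics
by default; a Bonferroni flag exists.

## Synthetic data generator

ROI channels share a latent standard-normal signal z(t) with
condition-dependent weight:

    x_r(t) = noise_sd · ( √rho(t) · z(t) + √(1−rho(t)) · e_r(t) )

with rho(t) = rho_task during task volumes and rho_rest during rest, and
e_r independent standard normal.  Every channel has variance noise_sd²
at all times, any two channels have population correlation exactly
rho(t), and the full-duration correlation converges to the
duration-weighted mixture of the two couplings.  This parametrisation
requires rho ∈ [0, 1) (a common positive coupling shared by all ROIs).
`hrf_smoothing` optionally replaces the step profile by the HRF-convolved
(max-normalised) boxcar, emulating the sluggish haemodynamic transition
between coupling states.  Defaults emulate the canonical paradigm: 10
ROIs, five 30 s task / five 30 s rest blocks at TR = 1 s (300 volumes),
rho_task = 0.6, rho_rest = 0.2, noise_sd = 1.

The volume generator paints these series into non-overlapping ROI voxels
of a small grid plus optional i.i.d. voxel noise, so atlas extraction can
be tested end to end.

What the generator does **not** emulate: physiological drift and other
1/f noise, motion spikes, spatial autocorrelation, regionally
heterogeneous HRFs, or negative couplings.  Passing tests therefore
demonstrate the pipeline's algorithmic correctness and its qualitative
behaviour under condition-dependent coupling, not performance on real
fMRI noise.

## Problem sizes and numerical choices

The test suite and the acceptance script run on simulated subjects of the
canonical 300-volume, 10-ROI configuration; the stability check uses 20
subjects (seeds 1–20) with global efficiency at a single absolute
threshold of 0.4, the midpoint between the rest (0.2) and task (0.6)
couplings, where the binarized network is dense in task windows and
sparse in rest windows.  Exhaustive graph oracles (Floyd–Warshall,
triple scans, full shortest-path enumeration, all set partitions for
modularity) are run on ≥200 random graphs with n ≤ 8.  Floating-point
conventions: correlations are clipped to [−1, 1]; matrices are
symmetrised as (M + Mᵀ)/2 before use; window means and variances use
two-pass formulas via numpy; the activation-mask comparisons sit ≥0.016
away from the 0.8 threshold and ≥0.005 away from the half-max coverage
boundary on the canonical design, so the 79-window count is stable to
floating-point perturbation.

## Known limitations

* Only block designs are supported (no jittered event-related designs,
  parametric modulators, or HRF derivative regressors).
* Graph metrics are for binary undirected networks; weighted and
  directed variants, rich-club coefficients and MST backbones are out of
  scope.
* No fMRI preprocessing (motion correction, slice timing, registration,
  smoothing): inputs are assumed preprocessed and, for atlas extraction,
  already in the atlas space (exact grid match is required; no
  resampling is performed).
* The greedy modularity maximiser is a heuristic; exact search is
  exponential and only exposed for small graphs.
* State clustering of FC patterns (k-means brain states, HMMs) is out of
  scope.
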