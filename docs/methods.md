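# Methods

This note documents the models, estimators and numerical choices behind
`saltpepper`, and what the synthetic benchmark does and does not
establish about real recordings.

## The analysis problem

Two-photon calcium imaging of mouse V1 during a rapid Hartley-grating
sequence yields, per cell, a fluorescence trace contaminated by neuropil
and drift. The question is whether the joint orientation/spatial-frequency
tuning of nearby cells is more similar than that of distant cells — i.e.
whether the "salt-and-pepper" description of rodent V1 is strictly true.
The pipeline estimates a phase-pooled Fourier-plane tuning kernel per cell
and quantifies how kernel similarity decays with cortical distance and
depth.

## Stimulus model

Hartley basis images `cas(2*pi*(kx*x + ky*y)/n)` are indexed by integer
`(kx, ky)`. On a 60 x 34 cm screen viewed at 20 cm (112 x 80 degrees of
visual angle) the spatial frequency of index `(kx, ky)` is
`hypot(kx/width_deg, ky/height_deg)` cycles per degree; the sequence draws
uniformly from all indices with SF <= 0.15 cpd (DC excluded), at 4
updates/s. Orientation convention: the grating is perpendicular to its
wave vector, reduced mod 180 deg, with 0 deg = horizontal. `(kx, ky)` and
`(-kx, -ky)` differ only in spatial phase, so tuning kernels live on the
folded half-plane ("phase pooling"); kernels are symmetrized back to the
full plane only for display. Stimulus-to-imaging alignment assigns each
imaging frame (15.5 Hz) the condition on screen at that frame's time.

## Preprocessing

*Neuropil correction.* `corrected = raw - (alpha + beta * neuropil)` with
`(alpha, beta)` from least-absolute-deviations (median) regression, which
ignores the sparse positive transients; `beta` is clipped to [0, 2].

*Noise.* `sigma = 1.4826 * MAD(diff(trace)) / sqrt(2)`. Differencing
suppresses drift and transients; the 1.4826 factor makes the estimate a
Gaussian-consistent s.d., which the deconvolution's noise-ball constraint
requires; `sqrt(2)` undoes the variance doubling of differencing.

*Spike inference.* The calcium impulse response is exponential with
half-decay `tau_1/2 = 135 ms` (a configurable constant), discretized as
AR(1) with `gamma = 2**(-dt/tau_1/2)` (~0.718 at 15.5 Hz; the trace halves
every ~2.09 frames). Spikes solve the constrained program

    min sum(s)   s.t.  s >= 0,  c_t = gamma*c_{t-1} + s_t,
                       || y - c - drift ||_2 <= sigma * sqrt(T),

with the drift an unconstrained natural cubic spline with 10 equally
spaced knots. The solver eliminates the drift analytically (projector
orthogonal to the spline column space) and minimizes the penalized form
`0.5*||P(y - c)||^2 + lam * sum(s)` by accelerated projected gradient
(FISTA with function restart); the projection onto the AR(1) cone is an
exact pool-adjacent-violators pass (the substitution `u_t = c_t/gamma^t`
turns the dynamics into a weighted isotonic chain, where clipping negative
pools at zero is exact). The penalty `lam` — the dual variable of the
noise ball — is bisected until the residual meets `sigma*sqrt(T)`. Plain
block-coordinate alternation between spikes and drift is *not* used: the
spline and the slowly decaying cone directions are nearly collinear and
alternation stalls far from the optimum. On short traces the solver
matches a dense generic convex solve of the same program to ~1e-6
relative. Note the program is always feasible (raising baseline calcium
plus the spline constant can track any trace), so the "infeasible" fallback
is defensive only.

*Cell classification.* Non-excess kurtosis (`m4/m2^2`, Gaussian = 3) of
the *corrected fluorescence* separates sparse, transient-dominated
pyramidal traces from tonic interneuron-like traces; cells below 15 are
flagged as putative interneurons and excluded by the corresponding
robustness filter.

## Kernel estimation

Per cell, inferred spikes are modelled as

    y(t) = sum_tau v(tau) * w(cond(t - tau)) + b + a*r(t) + noise

with `w` on the folded grid (~320 cells at the default geometry), `v` a
unit-norm temporal kernel over 8 lags (~0.5 s), and `r(t)` the running
indicator. Fitting is alternating least squares:

- (w, b, a)-step: exact penalized least squares; the penalty is
  `lambda * ||Lap w||^2` with `Lap` the 4-neighbour graph Laplacian on the
  folded lattice (neighbours across the fold seam mapped to their
  representatives, absent neighbours treated as reflecting).
- (v, b, a)-step: exact minimization over the unit sphere via the secular
  equation of the trust-region subproblem, so the objective is
  non-increasing at every half-step. The sign of `v` is fixed so its
  largest-magnitude element is positive.

Because one Hartley condition persists ~3.9 imaging frames, the lagged
regressors are nearly collinear and the bilinear problem has sticky local
basins; a delta initialization demonstrably lands in them. The default
start is a generic causal rise-and-decay profile `v0 ∝ tau*exp(-tau/2)`,
and the final fit multi-starts over decay scales {1, 1.5, 2, 3} frames,
keeping the best penalized objective. On noiseless synthetic cells this
recovers both kernels to correlation 1.000.

The penalty strength is selected by fivefold cross-validation over
contiguous time blocks (random frame splits would leak through temporal
autocorrelation) on a log grid `{1e1 ... 1e5}`, ties towards smoother.
Model quality is `r_L = sqrt(max(0, 1 - SSE_L/SSE_B))` with `SSE_L` the
pooled held-out SSE at the selected penalty and `SSE_B` the equally
cross-validated SSE of the stimulus-free baseline `y = b + a*r(t)`; this
makes `r_L` behave like a correlation coefficient and exactly zero for
cells the model does not predict. Cells pass selection at `r_L >= 0.15`;
a field is analysed when more than 20 cells pass.

## Clustering statistics

Tuning similarity is the Pearson correlation of flattened kernels;
cortical distance is the in-plane centroid distance, depth difference the
plane separation. Pairs are formed within fields only. Similarity is
binned in seven 30-um bins over [0, 210) um; each bin is compared to the
farthest bin by a one-sided Wilcoxon rank-sum test (exact by enumeration
for n + m <= 12 without ties, otherwise normal approximation with tie and
continuity corrections). The decay is summarized by least-squares fitting
`c + A*exp(-d/lambda)` to the bin means, multi-started over
`lambda0 in {10, 20, 40, 80, 160}` um; the 95% CI of `lambda` comes from
a percentile bootstrap that resamples pairs, rebins and refits (200
replicates by default), propagating pair-level noise. A fit whose
amplitude is negligible against the bin-mean scatter (or negative) is
flagged unidentifiable and its CI set to the start-grid span.

When pairs are pooled across several fields (as in a multi-experiment
analysis), `fit_exponential_decay_pooled` fits the pooled bin means but
bootstraps whole *fields* rather than pairs: each field's realized
preference map fixes its local decay, so pairs within a field are
dependent and a pair-level bootstrap would understate the uncertainty of
the length constant. In simulation, pooling 10 replicate fields with the
field bootstrap covers the generative 40-um length constant in ~90% of
replicates, which a single-field pair bootstrap cannot.

Additional tests: one-sided rank-sum comparing preference differences
(|d ori| or |d log2 SF|) for pairs closer than 50 um versus farther than
150 um; per-field Pearson correlation of similarity with distance
(one-sided negative); and per-depth-separation similarity curves
(0/40/80/120 um). For the per-field correlation, the classical
t-distribution p-value assumes independent observations, but pair
similarities sharing a cell are dependent; in simulation this roughly
doubles the nominal type-I rate on salt-and-pepper nulls. The default
p-value is therefore a cell-label permutation test (positions shuffled
across cells, preserving the dyadic dependence; exactly calibrated,
measured ~5% at alpha = 0.05), with `method="t"` available for the
classical value.
Robustness filters re-run the binned analysis after (i) kurtosis >= 15,
(ii) peak SF > 0.025 cpd, (iii) dropping the smallest 20% of ROIs (ties
broken by cell id).

## Synthetic data generator

The generator is the package's stand-in for the unreleased recordings and
defines the benchmark conditions:

- *Preference maps.* Complex Gaussian white noise smoothed with an
  isotropic Gaussian of s.d. `map_length_um`; orientation is half the
  argument of the smoothed field (correct wrapping on [0, 180)); log SF is
  an independently smoothed field scaled to mean ln(0.04 cpd), s.d. 0.45.
  `map_length_um = 0` gives a salt-and-pepper map. The default of 38 um
  was calibrated once so that the *ensemble* kernel-similarity decay —
  pairs pooled over 60 replicate sheets, fitted with the exponential over
  the 0-210 um range — has a length constant of ~40 um; this is the
  regime the clustering-recovery benchmark tests. A single 250-um field
  does not pin the length constant well: its realized map fixes a local
  decay, and per-sheet fits ranged from ~19 to ~97 um in simulation.
- *Cells.* 50 cells per plane on a 250-um field with 8-um minimum soma
  separation (dart throwing); log-normal ROI areas (median 110 um^2).
  All planes share one map ("columnar"); with probability
  `column_decorrelation` a cell instead samples an independent per-plane
  map, which decorrelates depth while leaving in-plane statistics intact.
- *Kernels.* A Gaussian bump in (orientation, log2 SF) — bandwidths 20 deg
  and 0.7 octaves — plus `low_sf_bias_weight = 0.35` times a fixed low-SF
  template shared by all cells. The shared template produces the non-zero
  similarity asymptote at large distances seen in the real curves.
- *Spiking.* Rectified-linear LNP: the separable drive minus its own mean
  (spiking threshold), scaled so a typical cell's mean evoked rate is
  0.5 Hz (log-normal spread, s.d. 1.0 in logs), plus 0.05 Hz baseline and
  0.3 Hz during running bouts (two-state Markov, ~8 s bouts); Poisson
  counts per frame. The threshold keeps firing sparse and cortex-like; the
  rectified-linear (not exponential) nonlinearity keeps the regression
  estimand proportional to the ground-truth kernel.
- *Fluorescence.* AR(1) calcium with 4 fluorescence units per spike;
  shared neuropil = slow low-pass noise + 0.3 x mean population calcium,
  added with weight 0.7; slow sinusoidal drift (amplitude 0.3, random
  phase); i.i.d. Gaussian noise (s.d. 0.25). These values were chosen once
  so that (i) pyramidal trace kurtosis exceeds 15 in >90% of cells while
  interneuron-like traces sit near 3, and (ii) the r_L of responsive
  cells straddles the 0.15 selection threshold, so the selection stage is
  actually exercised.
- *Interneurons.* 10% of cells pool the temporally smoothed mean rate of
  their 10 nearest pyramidal neighbours plus a 20 Hz tonic baseline,
  giving dense near-Gaussian traces with kurtosis ~3 (as for PV cells).

What the generator does **not** emulate: imaging motion artefacts and
registration errors, eye movements and pupil-linked gain changes,
non-exponential indicator kinetics and saturation, correlated (shared
variability) noise beyond the neuropil term, complex-cell phase
nonlinearities, and non-stationary behavioural states beyond the binary
running offset. Benchmarks passing on synthetic data therefore validate
the estimators' correctness and calibration under the stated model, not
robustness to those real-world effects.

## Problem sizes and defaults used by the benchmark scripts

The acceptance script analyses one 50-cell, 20-minute field end to end
(~18,600 frames, ~320 grid cells, 8 lags), a 25-cell untuned control
field, 600 salt-and-pepper fields for type-I calibration, 10 pooled
sheets for the length-constant benchmark, and five replicate 4-plane
sheets per columnar condition; the test suite uses the same field plus
20 pooled-replicate batches for length-constant recovery. These
sizes give stable statistics while keeping a full run in minutes on one
CPU core.

## Known limitations

- `tau_1/2` is a constant, not re-estimated per dataset; miscalibration
  biases spike timing more than kernel shape (the temporal kernel absorbs
  modest mismatch).
- The locomotion term is an additive offset only; multiplicative gain
  changes would bias `b`/`a` but not the stimulus kernel under the linear
  model.
- The exponential-decay fit treats bin means as homoscedastic; bins are
  approximately balanced by design, and the bootstrap CI does not rely on
  that assumption.
- With very few significant cells the first distance bin can be sparsely
  populated and its rank-sum test underpowered; fields are gated at > 20
  significant cells for this reason.
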