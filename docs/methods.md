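# Methods

This note documents the models, measurement conventions, numerical choices
and known limitations behind `mtkymo`. The package analyzes in vitro TIRF
reconstitution data of dynamic microtubules and microtubule-associated
protein (MAP) binding; because such experiments are scored from kymographs
with many small manual conventions, every convention here is explicit and
fixed, and a matched simulator provides ground truth for validating each
measurement stage by parameter recovery.

## The two-state dynamic-instability model

`simgen.simulate_dynamic_instability` draws end trajectories from the
classical two-state model: a microtubule end grows at speed `v_g` (nm/s)
until a catastrophe, which arrives as a Poisson event with rate `f_c` (s⁻¹)
in growth; it then shrinks at `v_s` until either a rescue (rate `f_r` in
shrinkage) or the seed boundary at position 0, where depolymerization stops
and growth resumes (stabilized seeds are not consumed). Positions are
sampled on the camera frame grid (default 5 s, 160 nm pixels); exact phase
boundaries and corner positions are recorded as ground truth. Optional
Gaussian position noise is applied to the rendered samples only — truth
stays noiseless — so noisy traces may dip slightly below the seed boundary,
as localization noise does in real data.

Defaults (`v_g = 7.6`, `v_s = 100` nm/s, `f_c = 0.004`, `f_r = 0.02` s⁻¹)
are a regime typical of plus-end dynamics near 9 µM tubulin and are the
conditions used by the recovery analyses; 30-min movies and n = 500
trajectories give a few thousand catastrophes, enough that counting errors
are at the few-percent level.

## Phase segmentation

`dynamics.segment_phases` reconstructs growth/shrink phases from a sampled
trajectory:

1. interval displacement signs define candidate runs;
2. direction reversals with net displacement below `min_event_displacement`
   (default 3 px = 480 nm) are merged away — this threshold exists to reject
   camera-noise reversals, so analyses of noiseless simulated traces set it
   to 0;
3. boundary samples that lie on the neighboring run's fitted line are
   reassigned ("peeling"), and samples on neither line are detached as
   orphan points;
4. runs whose interior samples are not collinear within a tolerance are
   split at the largest residual step: an excursion faster than the frame
   interval leaves no sign reversal, only an offset between the lines before
   and after, and is re-inserted as a short bridge segment;
5. phase boundaries are refined to intersections of the per-phase fitted
   lines;
6. a final repair pass resolves flagged descending segments whose slope is
   far below the estimated shrinkage speed into the peak (after growth) or
   valley (after shrinkage) vertex that frame sampling hid, using the two
   speeds estimated from the reliable phases. The reconstruction is the
   unique single-transition path consistent with the segment's endpoints.

The collinearity tolerance defaults to `max(5·σ̂, 1 nm)` with `σ̂` estimated
from the trace's second differences, so it adapts to the noise level; at
high noise the offset/repair machinery is effectively inert and detection
reduces to smoothed sign runs with the 480 nm threshold.

Segments whose slope is not identifiable from the samples (fewer than four
samples, unresolved mixtures, bridges) carry `rate_ok=False`: they count
toward lengths, durations and transition counts but are excluded from the
pooled speeds. A four-sample run's two interior points are always collinear,
so such runs are additionally required to have at least one boundary sample
on the same line before their slope is trusted.

**Resolution limit.** At a 5 s frame interval, an excursion that starts and
ends between two samples with a cancelling displacement (e.g. a rescue,
<5 s of growth, catastrophe and seed return, all within ~40 nm) is
information-theoretically invisible. In the default recovery regime these
account for roughly 2% of catastrophes; the recovered catastrophe frequency
is biased low by about that much, which sits inside its ~2% counting SE at
the n = 500 study size. Events at the first/last frame of a movie are
likewise unrecoverable.

## Dynamic-instability parameters

Following standard kymograph scoring: catastrophe frequency is catastrophes
per total growth time; rescue is counted per total shrinkage length (µm);
both carry counting errors `√n` over the same denominator. Dynamicity is
total length grown plus lost over total observation time, with error
`pixel_size · N / T` (`N` = marked points). Speeds pool per-phase slopes
weighted by duration (growth) or length (shrinkage) with a weighted sample
SE; pooling across replicate days uses inverse-variance weights
(`1/SE²`, combined SE `1/√Σw`). A shrink phase that reaches the seed
(final position within `seed_tolerance_nm`, default 40 nm ≈ `v_g` × frame)
terminates without a rescue; a trailing shrink phase is censored. The
exposure-style estimators (events over total time or length) remain
unbiased under this censoring.

## Sliding-window end velocities and end intensity

Velocity windows are 120 s, anchored at the first sample, non-overlapping;
a trailing window shorter than 60 s is dropped. Slopes use centered
least-squares sums, which are exact on noiseless lines. Windows before the
first positive-velocity window are eliminated so every trajectory starts in
growth; later negative windows are retained, and windows strictly below
−2.5 nm/s are classified as shrinking and excluded from growth statistics.

Per kymograph line, end intensity = mean over `lattice_len = 5` pixels
ending at the tracked end minus mean over `bg_len = 5` solution pixels
starting `gap = 3` pixels beyond the end; frames with fewer than 5
background pixels inside the image are dropped (an end less than 8 px from
the edge). Sub-pixel end positions round to the nearest pixel. The
measurement is invariant to any constant added to the channel. Raw
background-subtracted units are reported; absolute a.u. scales depend on
instrument settings that the package does not model.

## Nucleation sigmoid

A seed is nucleated if any extension is strictly longer than 480 nm within
the 15-min window. The fraction–concentration data are fitted with
`y = x^s / (C^s + x^s)` by nonlinear least squares (`C₀` = concentration
nearest fraction 0.5, `s₀ = 4`, bounds `C ∈ (0, 10·max x]`, `s ∈ (0, 50]`
to avoid the flat-likelihood region at small steepness; unweighted by
default, binomial-error weighting optional). Per-condition errors are
`√N/total`, with `1/total` when no seed nucleated. 95% CIs use a parametric
binomial bootstrap (counts resampled from the fitted curve at the observed
totals, 199 refits, percentile interval, internally seeded and therefore
deterministic): per-condition binomial noise is strongly heteroscedastic
and the linearized covariance CI undercovers (~86% instead of 95% in
simulation at 10⁴ seeds/condition; the bootstrap reaches ~93%).

## Single-molecule binding and cooperativity

`simgen.simulate_binding` is a Gillespie simulation on a 1-D lattice of
8 nm sites (one dimer length; protofilament multiplicity is ignored because
the measured quantities are per-µm line densities). Arrivals are Poisson
with per-site rate `k_on · conc · 0.008 µm · (1 + coop_on · ρ±2)` where
`ρ±2` is the occupied fraction within two sites; residences are exponential
with rate `k_off / (1 + coop_off · n_nn)` with `n_nn` the occupied nearest
neighbors. `coop_on = coop_off = 0` recovers independent binding with mean
dwell `1/k_off`. Molecules bound at the movie end are emitted as censored
events; the default analysis policy excludes censored events, matching how
complete events are read off kymographs (an include-as-lower-bound option
exists). Only a `labeled_fraction` of molecules is reported, emulating
spiking experiments; the subsample is unbiased, so it changes event counts
but not dwell statistics.

Two standard conditions are provided: the control (5 nM, fully labeled,
independent; `k_off = 1/12 s⁻¹` gives the observed ~12 s control residence)
and the spiking condition (5 nM labeled + 1 µM unlabeled, `coop_on = 3`,
`coop_off = 6`). The cooperativity factors were chosen so the simulated
lattice loads on the few-minute scale and saturates around 5 min, and so
dwell means lengthen between consecutive 5-min intervals with a rank-sum
p ≪ 0.001 against the control — the qualitative behavior of cooperative
MAP accumulation. The model exaggerates absolute spiking dwell times
(~50–90 s rather than tens of seconds): with nearest-neighbor
stabilization, any stable pair already enjoys the full neighbor effect, so
matching both the slow build-up and the modest dwell magnitudes is not
possible in this one-parameter-pair form; the direction, the significance
structure, and the control regime are faithful. Dwell-time experiments
pool events over several fields of view; `simulate_binding_experiment`
mirrors that by pooling independent lattices, which suppresses the large
per-lattice fluctuations caused by a few dominant clusters.

Association rates are events per second per µm of lattice per nM of the
*observed* (labeled) species, with counting SE. The rank-sum comparison
uses the exact null distribution for small tie-free samples and the
tie-corrected normal approximation otherwise.

## Curvature

Curvature magnitude is `1/R` of the circumcircle through three neighboring
points of a boxcar-smoothed (window 5) polyline; endpoints copy the nearest
interior value; collinear triples give 0. Smoothing windows shrink
symmetrically at the trace ends so endpoint positions are not dragged
inward. At 160 nm point spacing the window-5 smoothing biases κ upward by
~0.6% at R = 2 µm, growing to a few percent by R = 1 µm; for tightly curled
segments either disable smoothing (exact on noiseless traces) or trace more
densely. With 10 nm point noise, smoothing window 5 keeps the mean κ within
~5% at R = 2 µm.

Samples pool across microtubules into 0.1 µm⁻¹ bins — bin `k` covers
`(k·w, (k+1)·w]`, centers at `(k+0.5)·w`, boundary samples to the lower bin —
and intensity outliers are flagged per bin beyond 3 scaled MADs from the
bin median (the convention of common outlier routines; a clean normal
sample yields a ~0.3% flag rate). The intensity–curvature association is an
unweighted OLS on the bin means (means only, so per-bin sample counts do
not enter), reported as slope with 95% CI and two-sided p.

## Lattice-level statistics

The microtubule mask is an Otsu threshold on the time-averaged tubulin
channel dilated by 1 px: manual masking is not reproducible, so the rule is
fixed. Inputs are assumed registered. Rolling-ball background subtraction
(radius 5 px) is morphological: ridges narrower than the ball survive,
plateaus wider than ~2 radii are treated as background. Seed-vs-GDP region
means are compared per microtubule with Welch's unequal-variance t-test
(identical degenerate samples return p = 1 rather than NaN). Stretch
profiles are 20-px probe linescans centered on the initiation point, taken
once the stretch reaches 2 µm, normalized to the center value, and oriented
so positive offsets point toward growth.

The severing statistic normalizes every microtubule to its own 0–60 s
baseline, averages the non-coated (control) records per field of view,
finds the first time the control mean stays below 20% for two consecutive
frames, samples every record at that time, removes 3-scaled-MAD outliers,
and combines microtubules by inverse-variance weights. Fields whose control
never crosses threshold are excluded with a log entry. The severing
simulator gives each control microtubule Poisson severing times (default
0.01 s⁻¹) that each remove a uniform 20–50% of the remaining polymer —
stepwise intensity loss — while protected (coated) microtubules keep full
intensity plus measurement noise.

## What the simulator does and does not emulate

The generators reproduce: piecewise-linear end trajectories with the four
dynamic-instability parameters; exponential and neighbor-cooperative
binding kinetics with censoring; camera sampling, Gaussian PSF, shot-like
additive noise and partial labeling in rendered kymographs; damage sites as
low-tubulin-intensity segments with probe enrichment; severing as stepwise
loss. They do not model GTP-hydrolysis mechanics, 3-D lattice geometry,
protofilament number, photobleaching/blinking, drift (inputs are assumed
registered), or the true nucleation statistics of probe stretches
(stretches are emulated simply as segments of elevated occupancy).
Passing recovery tests therefore demonstrates that the measurement code
implements its stated conventions correctly at realistic noise and sampling
— not that those conventions are optimal for any particular real dataset.

## Numerical conventions

- All file-format coordinates are physical units (s, nm, µm); pixels appear
  only inside image-facing code.
- Every stochastic routine takes a mandatory integer seed and uses a single
  `numpy` Generator stream; no global RNG state. Fixed seed ⇒ bit-identical
  output, which the pipeline's provenance record (config hash + seed +
  versions) makes auditable.
- Analysis problem sizes used throughout (500 trajectories × 30 min;
  ~50 seeds/condition × 8 concentrations; ~150–200 events per dwell
  interval; 17 traces × 60 points; 3 fields × 40 microtubules) match the
  scale at which the corresponding assays are typically scored.
- Degenerate inputs fail loudly with named errors (empty annotation sets,
  zero growth time with recorded catastrophes, missing CSV columns, masks
  that cover nothing, controls that never cross threshold).
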