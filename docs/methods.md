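# Methods

This note documents the models and procedures implemented in `flyseize`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer would want recorded.

## Coordinate conventions and inputs

Trajectories are uniformly sampled centroid time series in millimetres, with
the origin at the arena centre and y increasing upward, at a fixed frame
rate (default 30 fps). The canonical file dialect is CSV with header
`frame,time_s,fly_id,x_mm,y_mm`; a tab-separated pixel-unit dialect is read
with an explicit calibration and origin conversion. Missing frames are
linearly interpolated and flagged in a gap mask; a fly whose longest gap
exceeds 1 s (configurable) is rejected. Out-of-arena points are clipped to
the boundary with a warning.

The default temperature protocol is a 10-min assay: 180 s at a 21 °C
baseline, 90 s ramp, 120 s high-temperature period (36–39 °C), 210 s return,
with 2-min analysis windows at 30–150 s (baseline) and 270–390 s (high
temperature). All phases and windows are configurable.

## Locomotion metrics

Per-frame speed is the frame-to-frame displacement times the frame rate,
median-filtered over 5 frames to suppress single-frame tracker jitter
(disable with `smoothing_frames=1`). Over an analysis window:

* **average speed** (mm/s), **total distance** (mm, sum of frame
  displacements), **percent active time** (% frames with speed above a
  1 mm/s threshold; the threshold is a configuration choice, not a measured
  constant — sub-millimetre jitter should not count as activity);
* **path linearity**: the window is split into consecutive non-overlapping
  2-s sub-windows; each contributes |end − start| / path length. Motionless
  sub-windows make this 0/0; rather than defining the ratio as 0 or 1
  (either would bias group medians), sub-windows with path length below a
  0.5-mm movement floor are excluded, and the metric is undefined if none
  remain. The triangle inequality bounds every ratio by 1.
* **percent time in center**: the fraction of frames inside the concentric,
  geometrically similar region scaled by 0.5 in linear dimension (25 % of a
  disc's area). The exact center definition used by upstream tools is not
  standardized; the fraction is configurable.
* **high-velocity events**: rising crossings of mean + 10 SD of the fly's
  speed, with the baseline computed over the *entire recording* (so a brief
  window of seizure activity does not inflate its own threshold). Crossings
  separated by a below-threshold dip shorter than 10 frames are merged into
  one event; whether the original assays debounced is unstated, so the gap
  is configurable.

Total distance is invariant under rigid motion of the coordinates; percent
active time is monotone non-increasing in the activity threshold; the
event count is invariant under time translation. These are asserted as
property tests.

## The three-state behavioral classifier

**Windowing.** Trajectories are split into 2-s windows: non-overlapping for
training ("sequential" windows), stride 1 for frame-wise decoding. Windows
with more than 25 % interpolated frames are dropped from training; during
decoding, frames whose centred window fails the rule fall back to the
nearest valid window.

**Features.** Each window is translated to its centroid and rotated so its
own first principal axis lies along +x, with the 180° ambiguity fixed so net
displacement points in +x (windows with zero net displacement keep the raw
orientation — a documented tie-break; pure rotations only, so mirror-image
paths stay distinct). The aligned windows, flattened to 2W-vectors, get a
dataset-level PCA basis; features are the top K = 5 projections scaled to
unit training variance. K and the window length are configurable. The
feature construction for the original MATLAB classifier this design follows
is not published in detail; rigid alignment + dataset PCA is the minimal
reading of "aligned and scaled according to principal components".

**Model.** A 3-state Gaussian HMM with diagonal covariances (ridge 1e-6)
trained by Baum–Welch, 10 seeded restarts (restart *r* uses `seed + r`),
best final log-likelihood retained; the winning restart's per-iteration
log-likelihood trace, seed policy and convergence flag are stored in the
model metadata. EM guarantees a non-decreasing trace up to the
regularization: the covariance ridge can introduce oscillation below the
convergence tolerance, which is why the monotonicity test uses a small
relative slack.

**Initialization.** Unsupervised EM on these features has a stubborn
failure mode: the maximum-likelihood 3-state solution dedicates a state to
*transition windows* (windows straddling a bout change) and merges the two
low-motion regimes, which destroys the pausing/immobilized distinction.
End-to-end training therefore initializes every restart from a coarse
kinematic sketch — 2-means on log net displacement separates walking from
low-motion windows, and a second 2-means on log path length separates
twitchy immobilization from quiet pauses — and lets Baum–Welch refine from
there (restarts perturb the initialization). Training remains unsupervised;
the initialization encodes only which *kinds* of motion regimes the three
states should anchor to. `train_classifier` without an explicit
initialization uses plain k-means, which suffices when emission clusters
are well separated (as in the parameter-recovery tests).

**State labeling.** After training, the state with the greatest expected
within-window *net displacement* (posterior-weighted) is labeled walking;
of the two low-motion states, the one with the higher self-transition
probability (longer dwell) is immobilized, the other pausing, with
deterministic index tie-breaks. Net displacement, not raw path length, is
the walking discriminator: residual twitch jitter accumulates as much raw
path over 2 s as slow walking does, while translating the fly almost
nowhere.

**Decoding.** Stride-1 sliding windows are projected to features and passed
through forward–backward; each frame reports the max-posterior state of its
centred window and that posterior as confidence (posteriors over the three
states sum to 1 to 1e-9). Because the transition matrix is estimated at the
2-s window step but decoding advances one frame at a time, the matrix is
rescaled to the frame step (matrix 1/W power via eigendecomposition,
clipped to the simplex) so dwell expectations keep their trained time
scale. Decoding is invariant to rigid motion of the arena coordinates since
alignment removes pose.

A structural limit worth stating: a frame's centred 2-s window mixes
neighboring bouts, so labels smear by up to ±1 s around every true state
transition (a window containing real travel is, correctly, most likely
under the walking state). Frame-accurate boundaries for sub-second pauses
are therefore out of reach of this window length regardless of the model;
bout totals and incidence, the quantities of interest, are robust to it.

**Immobilization summaries.** Within an analysis window: total immobilized
time, longest bout, incidence (any contiguous bout ≥ 2 s), and the onset
time of the first qualifying bout; cohorts export the cumulative fraction
of flies with onset ≤ t. The model container (JSON, versioned; loader
refuses mismatched versions) serializes the HMM, feature basis, label map
and training metadata, and round-trips decoding bit-identically.

## Spike-train analysis

ISI⁻¹ for spike *i* is the reciprocal of the interval to its successor;
CV₂ for a consecutive ISI⁻¹ pair (a, b) is 2|a−b|/(a+b) — in [0, 2), zero
iff the pair is equal. The phase trajectory pairs each CV₂ with the first
member's ISI⁻¹.

**Burst counting** is loop counting in that phase plane: a burst opens when
a point enters the entry region (ISI⁻¹ ∈ [3, 20] Hz, CV₂ ≤ 0.3 — anchored
to the stereotypic ~7 Hz / CV₂ ≈ 0.04 bursting signature with headroom to
the ~20 Hz intra-burst rates) and closes when a point violates the looser
exit region (CV₂ ≥ 0.6 or ISI⁻¹ outside [1, 30] Hz). Loops separated by
less than 1 s merge (a single outlier point inside a burst briefly leaves
the region without ending it); merged candidates need ≥ 5 spikes and ≥ 1 s
duration — bursts are sustained episodes of seconds, while grooming bouts
are sub-second by definition, so the duration floor removes chance
in-region runs inside grooming. All bounds live in `BurstRegion` and are
configuration; the original loop-counter's exact criteria are not
published, so this is a parameterized reconstruction.

**Spike detection** thresholds the polarity-corrected trace at
median + 6·σ̂, with σ̂ the MAD-based robust SD (MAD × 1.4826) so bursts do
not inflate the noise estimate; each supra-threshold excursion yields one
spike at its local extremum, with a 5-ms refractory period. A fixed
threshold mode bypasses the estimate. **Overall firing frequency** is spike
count over interval length (default: the full 240-s recording; whether a
settling period should be excluded is unstated upstream, so none is).
**Bilateral synchrony** is reported descriptively as an overlap fraction:
bursts dilated by 1 s, directed overlap fractions averaged over both
directions, undefined (not 0) when either channel has no bursts.

## Synthetic generators

All generators are pure functions of (parameters, seed) and return ground
truth sufficient to score every detector without annotation.

**Locomotion** is semi-Markov with explicit dwell times, so immobilization
bouts can be long and controllable independently of the 2-s analysis
window. Walking is a correlated random walk (speed ~ N(μ, σ) clipped at 0,
heading diffusion, wall reflection with scatter); pauses and immobilization
hold an anchor position with Gaussian per-frame jitter. Immobilization is
distinguished by slightly larger jitter plus sparse twitch events
(~1.5 Hz, ~0.6 mm), mirroring "twitching without walking"; sustained fast
jitter would register as activity, which immobilized flies do not show.
Entry into immobilization is a constant phase-specific hazard acting on
active (walking/pausing) time, with exponential dwell once entered — a
two-level continuous-time Markov chain whose expected occupancy has the
closed form used by the calibration tests:
E[immobilized in T] = (a/(a+b))·(T − (1 − e^{−(a+b)T})/(a+b)) with entry
rate a and exit rate b = 1/dwell. Seizure-like scenarios overlay
high-velocity events (4 frames at 75 mm/s) and spin bouts (1-mm-radius
circling, 2 rev/s) during active high-temperature time.

Scenario presets: `control_like` (pauses truncated below 1.5 s, no
immobilization hazard), `glial_oe_like` (high-temperature entry hazard
0.025 s⁻¹ with 50-s mean dwell — expected immobilized time ≈ 54 s of the
120-s window, in the neighborhood of the tens-of-seconds immobilization
this phenotype shows; bursting spike mode; survival hazard ln 2/10 d⁻¹ for
a configured 10-d median lifespan), `neuronal_oe_like` (intermediate
locomotor phenotype, rare short immobilization, no bursting, ln 2/2 d⁻¹),
and `well_separated` — a scoring scenario with fast persistent walking,
long (10–14 s mean) dwells and amplified immobilization jitter, stated
explicitly as the condition under which frame-wise classifier accuracy is
evaluated: it minimizes the window-boundary ambiguity that realistic brief
pauses necessarily carry.

**Spike trains**: grooming bouts arrive as a Poisson process (0.05 Hz),
last 0.2–0.8 s and fire irregularly at a 60-Hz mean with an 8-ms floor, so
instantaneous rates approach 100 Hz; seizure bursts arrive at their own
rate, last U(5, 15) s at ~7 Hz with small ISI jitter (CV 0.04), are kept
fully inside the recording, separated by ≥ 2 s, copied to both channels
with 10-ms per-spike bilateral jitter (near-1 synchrony at 1-s tolerance),
and suppress grooming within 1 s — a seizing fly does not groom
mid-discharge. **Voltage synthesis** convolves spikes with a biphasic
template (0.4-ms crest) and adds Gaussian noise of SD 1/SNR.
**Survival** is exponential with per-group hazards, censored at 14 d.

What the generators do *not* emulate: posture, leg kinematics, tracker
identity swaps, temperature-dependent kinematic drift within a phase,
non-exponential immobilization latencies, burst-internal frequency
modulation, or electrode artifacts. Passing tests therefore demonstrate
that the estimators recover the statistical structure they target, not that
they are validated on real recordings.

## Statistics

Omnibus comparisons use tie-corrected Kruskal–Wallis H; post hoc pairwise
comparisons are two-sided rank-sum tests — exact when the combined sample
is ≤ 20 without ties, normal approximation with tie/continuity correction
otherwise — over a *declared* comparison family (the family is an analysis
choice, e.g. overexpression vs matched control, not automatically all
pairs), adjusted by hand-implemented Holm–Bonferroni step-down (sort
ascending, multiply the i-th smallest by m−i, running maximum, cap at 1;
cross-checked against statsmodels). Fisher's exact test is the two-sided
hypergeometric sum (scipy, verified against full enumeration for all 2×2
tables with n ≤ 20). Survival uses the standard log-rank chi-square (1 df,
lifelines) with Kaplan–Meier medians, undefined when survival never drops
below 0.5; all-censored input is an error, not a silent zero. Box
summaries report 5/25/50/75/95 percentiles with linear (inclusive)
interpolation — the rule is pinned because it affects medians at small n.
Significance stars follow the * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001 convention.

## Pipelines and reproducibility

`run_behavior_analysis` and `run_ephys_analysis` execute single-process,
deterministic runs from one YAML configuration: simulate or load inputs,
compute all per-fly tables, train or load the classifier, and write data
tables plus a manifest (config hash excluding the output path, master seed,
package version). Identical configuration and seed reproduce every output
byte-identically; per-fly seeds derive deterministically from the master
seed. Plotting is deliberately left to the user — every figure-ready
quantity is exported as a table first.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use: 20-fly cohorts per group at
600 s (full protocol) for specificity and contrast; 20 flies at 180 s of
the scoring scenario (~108,000 frames) for balanced accuracy; 10,000
simulated feature windows for transition-matrix recovery; 200 seeded trains
for the burst sweep; 50 random 8-window sequences against 3⁸-path
enumeration; 1,000 replicates for null calibration. These sizes were chosen
so every check runs comfortably on a single CPU while keeping Monte-Carlo
error well below the tested tolerances.
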