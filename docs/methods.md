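# Methods

## Kinetic model

The conformational chain is a continuous-time Markov process on three states
R, RA, RAA (zero, one, two occupied glutamate sites) with generator

    Q = [ −2·kon·c     2·kon·c        0      ]
        [   koff    −(koff+kon·c)   kon·c    ]
        [    0         2·koff      −2·koff   ]

for two identical, independent sites at ligand concentration c (µM). Defaults
are kon = 1.0 µM⁻¹s⁻¹ and koff = 0.46 s⁻¹, chosen so that the per-site
dissociation constant Kd = koff/kon is 0.46 µM and dwell times at ~300 nM
fall in the seconds range, i.e. are resolvable at 100-ms frames. The
stationary law is Binomial(2, θ) with θ = c/(c + Kd); the doubly-bound
occupancy θ² reaches half-maximum at c = Kd/(√2 − 1) ≈ 2.414·Kd, which is why
a logistic fit to the ideal two-site occupancy cannot have EC50 = Kd — the
EC50 of the activated-state dose–response and the kinetic Kd are related but
not equal quantities.

## Synthetic traces

State paths are exact Gillespie realizations of Q, started from the
stationary distribution (the relevant ensemble for molecules already at
equilibrium when recording starts). Rendering inverts the analysis-side
corrections exactly: for true FRET E and total corrected intensity T,
the corrected donor is γ·I_D = T·(1−E)/(1+χ) and the acceptor
I_A = T·(E+χ)/(1+χ), with crosstalk χ = 0.105 and γ = 1.1, so that at zero
noise `compute_fret` returns E to machine precision. Per frame the rendered
intensities are the *time-weighted average* over the frame (motion blur):
a transition inside a frame produces one intermediate-valued frame, the
mechanism behind rare apparent direct high↔low jumps in idealized data.

Photophysics: single-step exponential bleach times (donor mean 80 s,
acceptor mean 120 s, background 0 — these are generator conventions, not
measured quantities; real bleach statistics depend on dye and excitation).
After acceptor bleach the rendered FRET is 0 with the donor persisting;
after donor bleach both channels sit at background. Per-channel additive
Gaussian noise (default 33 a.u. at T = 500) yields a single-state FRET
distribution of SD ≈ 0.055, the narrow-peak regime; the mapping from channel
noise to FRET width is the delta-method propagation implemented in
`EmissionParams.fret_noise_sd`. A bad-trace mode (second directly-excited
acceptor, or multiplicative intensity drift) exists solely to exercise the
selection filter. No camera physics (EMCCD excess noise, pixelation) and no
blinking are modeled.

Randomness: each trace draws from a seed derived from
(master seed, movie, trace index), so any subset is reproducible.

## Processing and selection

FRET is computed as E = (I_A − 0.105·I_D)/(I_D + I_A) after scaling the donor
channel by γ — the standard placement of the detection-efficiency
correction, and the same convention the generator uses, making the
round trip exact. Frames with non-positive total are marked undefined (NaN),
never silently zero.

Photobleach steps are found by exhaustive single change-point scans
(between-segment mean difference normalized by the pooled variance — a
two-sample t statistic maximized over split points), applied recursively for
step counting. Donor bleaching is detected on the γ-corrected *total*
intensity, which is constant through both FRET transitions and acceptor
bleaching and drops only when the donor dies; acceptor bleaching is detected
on the acceptor channel restricted to the pre-donor-bleach window. A
detected step counts as a *bleach* step only if the post-step segment level
falls below 0.3× the maximum segment level: FRET state transitions move the
acceptor channel between state levels but never to the crosstalk-only
baseline, so they are not counted. The significance threshold (t ≈ 8) is far
above the flat-trace null maximum (~3.5 at 600 frames) and far below the
bleach-step statistic (tens).

Selection keeps traces with exactly one donor and one acceptor bleach step,
coefficient of variation of the corrected total before acceptor bleach
≤ 0.15 (a concrete reading of "stable total intensity"), and ≥ 20 s of
usable FRET; every rejection carries a reason code. When a donor bleach
exists, the post-bleach mean of each channel is subtracted as background.
Histograms cover [−0.2, 1.2] at bin width 0.02, use the first 20 s of each
selected trace, are normalized per movie, and are averaged across movies
with per-bin SEM.

## Histogram fits and dose–response

Gaussian analysis is a weighted least-squares *curve fit to the binned
density* (equal weights by default, Poisson optional), not sample-based
mixture estimation — per-movie histograms are the replication unit, which
makes the movie-to-movie SEM the natural error bar. Fits are multi-started
from k-quantile means; means are bounded to [0, 1] and SDs to [0.01, 0.2] to
prevent collapse; components are reported in descending-mean order. The
global fit shares means (and by default SDs — state distributions should not
change with concentration) across a histogram series with free per-histogram
areas. Two caveats are inherent to this estimator: components may become
degenerate when a peak is absent from all histograms (an unconstrained
component can park anywhere or split an existing peak, which is why
"the low-FRET component" should be read among components carrying
non-negligible area), and the FRET noise distribution — a ratio of
Gaussians — is slightly skewed, so a 3-component fit to a single skewed peak
may shave a few thousandths off the lowest mean.

The dose–response model is the three-parameter logistic
f(c) = fmax / (1 + (EC50/c)^h) applied to the low-FRET (activated-state)
area. Zero-added-ligand points cannot sit on a log axis and the 3-parameter
form has zero baseline by construction, so they are excluded from the fitted
abscissa. Data that do not span the transition raise an explicit
unidentifiability error rather than returning an arbitrary EC50.

## SKM idealization

Segmental k-means alternates (i) Viterbi segmentation under Gaussian
emissions and the current transition matrix with (ii) re-estimation of state
means, variances, and transition probabilities from the segmentation, until
the labels stop changing; the joint path likelihood is non-decreasing and is
asserted per iteration in tests. Exact Viterbi ties prefer staying in the
current state, minimizing spurious transitions. Transition probabilities are
re-estimated from segment counts by default (full SKM) with an option to
hold them fixed and uniform. A state left with no frames is dropped with a
warning. Because a single 20–60-s trace rarely visits all three states, the
ensemble mode shares emission and transition parameters across all traces of
a dataset while segmenting each trace individually — this is the mode the
pipeline uses. A zero-FRET class (initial mean 0) is added only when
post-acceptor-bleach frames are present in the input; `remove_zero_state`
truncates trailing zero-state frames and, for internal (blink-like) zero
runs, keeps the longer fragment.

Transition-density plots count one point per label change at (mean FRET of
the preceding dwell, mean FRET of the following dwell) and report the total
transitions and transitions per second. Dwell-time histograms are available
with Sigworth–Sine-style logarithmic binning for display; fitting always
uses raw dwells.

## Dead time and the dwell likelihood

Dwells shorter than the 200-ms dead time are merged into the preceding dwell
(the first into the following one), iteratively, with same-state neighbors
coalesced — this conserves total idealized time, and the likelihood
conditions on t ≥ τ_d for consistency. Because each FRET class contains
exactly one kinetic state, the aggregated-state interval likelihood
factorizes exactly into truncated-exponential dwell densities with branching
probabilities: a non-censored dwell of length t in state i ending in j
contributes log q_ij − λ_i(t − τ_d) with λ_i = −Q_ii; the final dwell of a
trace (ended by photobleaching, not by a transition) contributes the
survivor term −λ_i(t − τ_d). The first dwell's *entry* is censored, but by
memorylessness its residual duration is exponential with the same rate and
its exit is observed, so it enters with the full term; a switch excludes
first/last dwells entirely. Observed transitions with zero scheme rate
(apparent direct jumps created by merging away a sub-dead-time middle dwell)
keep the exit-time density and marginalize the destination, keeping the
likelihood finite without inventing probability for a forbidden edge.

This conditioning is a first-order missed-event treatment: merging
concatenates dwells across missed visits (R + short-RA + R becomes one long
R dwell), which a truncated exponential cannot fully represent. At the
default rates this biases individual rate estimates downward by roughly
10–15 % and the forward/backward rate *ratios* and Kd by a few percent —
parameter-recovery tests bound Kd within 15 % and the 2:1 ratio structure
within 20 % at the default data scale, and those bands are what passing
tests demonstrate. An exact missed-event interval likelihood
(Roux–Sauvé-style e-rates) would remove this bias and is the natural
extension.

Optimization runs in log-rate space (positivity without constraints) with
five multi-starts perturbed by ±0.5 decade, L-BFGS-B, bounds 10⁻⁴–10⁴ on
each rate; standard errors come from the inverse observed information
(central-difference Hessian in log10 space, mapped by the delta method), and
Kd = koff/kon gets its SE the same way including the covariance term. A rate
within 0.05 decades of a bound is flagged as pinned — the "very
low-probability transition" failure mode. `compare_schemes` fits each scheme
independently (linear/triangular × constrained/free), reports Δloglik
against the linear free model, and never aborts on a per-scheme failure. On
linear-truth data the triangular direct rates pin at the lower bound when
fitted to exact dwell sequences; on dead-time-merged sequences the apparent
direct transitions let the direct rate sit just off the bound — both
outcomes reject the triangular scheme, by pinning or by parsimony.

## Pipeline and determinism

The orchestration layer runs simulate → process → histfit → doseresponse →
idealize → kinetics with every stage reading its inputs from disk (TSV
tables, JSON sidecars), so any suffix of the chain can be re-run. Reports
are pure functions of (config, seed): no timestamps or machine state enter
output files, and re-running with the same seed produces byte-identical
reports. Default generator conditions follow the study design: 5 movies ×
120 traces per condition, 60-s traces at 100-ms frames; the kinetics
dataset in the acceptance script uses 20 movies (2400 traces), of which the
bleaching-based selection retains ~3–5 %, leaving ≈ 1500 dwells — enough to
put the stochastic error of Kd at a few percent.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes —
the concentration-dependent chain, narrow Gaussian-noise FRET peaks,
crosstalk/γ distortions, single-step bleaching, movie grouping. Passing
recovery tests therefore demonstrates that the analysis chain is correct and
internally consistent at realistic noise and data volumes. They do not
validate the instrument model against real recordings: real traces carry
non-Gaussian camera noise, baseline drift, blinking, heterogeneous
labeling, and state connectivity that may violate the 1:1 state↔FRET-class
assumption. Quantities fit to real data by the original workflow (e.g. an
empirical EC50 near 0.6 µM with Hill slope ≈ 1.35) are properties of those
recordings, not of the ideal scheme, and are deliberately not targets here.
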