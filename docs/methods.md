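# Methods

## Promoter models and the waiting-time law

A promoter is a continuous-time Markov chain over (OFF, ON) or
(OFF, ON, PAUSE) — state order fixed in that sequence throughout the
package — with initiation events emitted as a Poisson process of rate
`k_ini` while the chain occupies ON. Initiation does not change the
promoter state. The 3-state topology is the *non-obligatory pause*
chain OFF ⇌ ON ⇌ PAUSE (no direct OFF–PAUSE transition): only some
initiation attempts are followed by entry into the long-lived paused
state.

The interval between successive initiations is the first-event time of
a Markov-modulated Poisson process started in ON (the post-event state
is exactly ON because initiation occurs only there). With Q the
generator and R = diag(0, k_ini[, 0]),

    S(t) = ⟨ON| exp((Q − R) t) |1⟩,

a sum of `n_states` exponentials whose exponents are the eigenvalues of
Q − R. Exponents are stored as negative reals sorted descending
(slowest first), amplitudes sum to one. Repeated eigenvalues (relative
gap < 1e-10) raise a dedicated error: the distinct-exponential mixture
does not exist there, and the equal-timescale limit is exactly the
mixed-gamma family of `burstkin.gaps`.

The inverse maps (distribution parameters → rates) are closed forms in
the amplitude-weighted power sums S₁..S₃ and, for three states, the
symmetric functions of the exponents. We evaluate the symmetric
functions as elementary symmetric polynomials obtained from the power
sums by Newton's identities (e₁ = L₁, e₂ = (L₁²−L₂)/2,
e₃ = (L₁³−3L₁L₂+2L₃)/6); written with plain power sums in place of
e₁..e₃ the three-state discriminant goes negative on valid models, so
the elementary-symmetric reading is the correct one (verified by exact
round trips against the forward map: relative error ≲ 1e-8 over 1000
random models per state count; the 3-state branch expressions are
evaluated in 80-bit extended precision because the discriminant
cancels catastrophically when the two inactive states have similar
exit rates). The two square-root branches of the 3-state inversion
label the two inactive states; output is canonicalized so that PAUSE
is the longer-lived one (T_PAUSE ≥ T_OFF). Inversions whose
denominators or discriminant fall within 1e-12 of zero, or that yield
nonpositive rates, are flagged invalid rather than returned.

## Synthetic traces

The single-polymerase kernel is the trapezoid implied by reporter
geometry: zero until the polymerase reaches the stem-loop cassette
(41 bp), linear ramp while the 24 loops are transcribed (1292 bp,
uniform loop spacing assumed), plateau of one polymerase unit until it
leaves the gene (4526 bp downstream), zero afterwards (retention time
0 s, kept as a parameter). Elongation speed is fixed at 45 bp/s;
frames are sampled every 3.86 s. Events whose kernels extend past the
movie end contribute truncated signal.

Cohort generation draws a postmitotic onset delay per nucleus from the
mixed-gamma model, simulates the promoter chain by the Gillespie
algorithm from that onset (initial state drawn from the stationary
distribution), convolves, then degrades: additive Gaussian noise of
constant SD in polymerase units (the real noise law is unknown to us;
Gaussian is the simplest stand-in and validation relies on noiseless
and low-noise regimes), negatives clipped, and frames below the
detection floor (default 3 polymerases, mimicking spot-detection
limits) zeroed. Defaults: 200 nuclei, 1800 s movies, noise SD 0.5,
onset mixture (p₁, p₂, b) = (0.2, 0.5, 60 s). What the generator does
not emulate: photobleaching, focus drift, segmentation/tracking
errors, sister-chromatid structure (sisters are treated as one summed
site), or intensity calibration error — passing tests therefore
validate the inference chain, not robustness to those artifacts.

## Deconvolution

Candidate initiation times live on a 30 bp ≡ 2/3 s grid (finer than
the minimum polymerase spacing, so at most one event per position);
the grid extends one kernel duration before the trace so signal
already present at the first frame is explainable. The search
minimizes the plain sum of squared residuals between the trace and the
reconstruction (trace values are near-linear in event count, so no log
term is used).

The search combines: (a) a nonnegative-least-squares relaxation over
continuous occupancies, rounded cluster-by-cluster to integer event
counts — cluster gaps of up to two positions are closed first, counts
are reconciled against the (near-integer) total mass, and stacked mass
is spread to neighbouring positions; (b) a greedy matching-pursuit
seed; (c) greedy polishing sweeps (single-event shifts within ±15
steps, joint moves of adjacent pairs within ±3 steps and triples
within ±2 steps to unwind compensating misplacements, additions,
removals); (d) a genetic algorithm (population 100, up to 300
generations, early stop after 10 flat generations) over occupancy
chromosomes with one-point crossover and add/remove/shift mutations;
and (e) a few forced-add repairs and jittered re-polish restarts. For
noiseless traces with events on the grid and spacing ≥ 2 steps this
recovers counts exactly and times within one step. Off-grid event
times are recoverable only to ~1–2 steps: positions within a frame
interval (3.86 s ≫ 0.67 s) are nearly indistinguishable after
sampling, so sub-step timing is limited by the camera, not the search.
GA hyperparameters and the fitness function are our own choices; runs
are deterministic given the seed.

## Waiting times and survival estimation

Traces are windowed to their stable part (first to last frame at or
above 1/5 of the trace maximum). Waiting times are differences of
consecutive event times inside the window; the final interval (last
event → window end) is appended right-censored by default — dropping
it (flag `--no-censoring`/`censor_final=False`) biases long waiting
times downward, exactly the tail that distinguishes a third state.
The interval from window start to the first event is discarded (it is
not a renewal interval from an observed event).

The product-limit estimate comes from lifelines; the 95% band is plain
Greenwood with normal approximation, clipped to [0, 1] (log-log
available as an option). Pointwise Greenwood coverage at the sample
sizes used here is ≈ 95–96% (measured in the acceptance script).

## Multiexponential regression

Objective: O = (α/n)Σ(S−Sₑ)² + ((1−α)/n)Σ(log S − log Sₑ)², α = 0.6.
Grid points where Sₑ = 0 are excluded (no log), as are points with
fewer than 30 subjects at risk — the log-scale variance of the KM
estimate there grows like 1/at-risk, and without this floor the few
extreme-tail points dominate the objective and visibly bias the slow
timescale (the bias *grows* with sample size, since the observed tail
extends). The evaluation grid is thinned rank-uniformly to ≤ 2000
points for the optimizer; the acceptance check uses the full grid.

Optimization: free coordinates are log(−λᵢ) and N−1 amplitude logits
(softmax), removing all hard constraints; Nelder-Mead from 30 starts
with exponent guesses log-spaced across the observed time range and
amplitudes initialized by nonnegative least squares at fixed
exponents. Distinct local optima are retained; per-parameter error
intervals are min/max over solutions with objective ≤ 2× the best
(the overflow ratio), and the kinetics report propagates every such
solution through the inversion for rate- and derived-quantity
envelopes.

Acceptance of a fit: the parametric curve must lie inside the
pointwise Greenwood band at grid times ≥ the 10 s cutoff. Because a
pointwise band is not a simultaneous band, even the generating curve
grazes outside on a dense grid; we allow up to 5% of grid points
outside (the nominal pointwise miss rate) before rejecting. The margin
is wide: fits of a wrong model violate at 60–70% of grid points in the
regimes tested. N is increased from 2 until acceptance (N ≤ 4); the
10 s cutoff matches the modified KS test and reflects that the
deconvolution grid distorts the shortest intervals (sub-grid event
pairs cannot be resolved).

The obligatory-pause fit restricts the N = 3 family to the manifold
ΣᵢAᵢλᵢ = 0 (waiting-time density zero at t = 0: every initiation must
traverse the pause). Free coordinates are the three exponents and A₁;
A₂ is solved from the constraint. Exponents are confined to a broad
margin around the observed time range — otherwise the optimizer
satisfies the constraint in the degenerate limit λ₃ → −∞, A₃ → 0,
which is just an unconstrained biexponential in disguise.

The modified KS test compares observed Δt > 10 s against the fitted
law truncated at the cutoff and renormalized. It is one-sided with
statistic D⁻ = sup (F_fit − F_emp), detecting data with a heavier tail
than the fit — the direction in which an unmodelled promoter state
manifests; the p-value is uniform under the null (checked by
simulation).

## Postmitotic gaps

Onset delays are modelled as a mixture of 1, 2 or 3 sequential
exponential steps with common mean b: survival
S(t) = p₁e^{−t/b} + p₂(1 − P(2, t/b)) + p₃(1 − P(3, t/b)) with P the
regularized lower incomplete gamma (the conventional γ(3,·)/2 form is
exactly the regularization by Γ(3) = 2 — stated to forestall a
factor-2 bug). This is verified to equal the equal-timescale limit of
the three-exponential family (Erlang/Jordan form, written
independently as truncated exponential series) to 1e-6 on a test
grid. Fitting reuses the mixed objective on the KM estimate of the
onsets, with the same at-risk floor; recovery bias at n = 10⁴ is
below 1% on b and below 0.05 on the mixture weights. Mixtures with
more than three steps are not supported. Onset in the cohort
generator is defined as the sampled delay itself; for measured traces
the first frame above the detection floor for two consecutive frames
is used.

## Problem sizes and reproducibility

Defaults used by the test suite and the acceptance script: parameter
recovery from 3×10⁵ sampled waiting times; state-count selection on
20 replicates of 10⁴ waiting times per model; 50 noiseless traces of
~560 s for deconvolution accuracy; 100 replicates of 10⁴ exponential
draws for band coverage; 10 replicates of 10⁴ delays for gap
recovery. Every stochastic stage takes an explicit seed (pipeline runs
record it in `run_log.json` and re-running from the log reproduces the
outputs); the acceptance script derives all sub-seeds from its single
`--seed`.

## Known limitations

- Rates are identifiable only through the waiting-time law; models
  with more than three states, initiation from several states, or
  time-varying rates are out of scope, as is the obligatory-pause
  *generator* (only its constrained distribution fit is implemented —
  the state topology needed for simulation is not pinned down by the
  distribution constraint alone).
- Sub-grid (< 2/3 s) inter-initiation intervals are unresolvable by
  construction; at high initiation rates this removes ~5–8% of the
  shortest intervals and slightly distorts full-pipeline rate
  estimates relative to fitting on true event times.
- The error intervals are optimization envelopes (spread of
  near-optimal solutions), not sampling confidence intervals; with
  clean well-identified data they collapse to points.
- The noise model and detection floor are simplified stand-ins for
  microscopy reality; see the synthetic-traces section.
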