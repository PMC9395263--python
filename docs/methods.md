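# Methods

`rloopmt` re-creates, on synthetic data, a single-molecule magnetic-tweezers
analysis of Cas12a R-loop dynamics and DNA cleavage: discrete R-loop states
are identified in bead-height traces with a Gaussian-emission hidden Markov
model, ensemble plasmid-cleavage time courses are fitted to an ordered
two-step kinetic model, and single-molecule cleavage traces are annotated
with post-nick "clamp" events. Real tweezers data is not redistributable, so
every analysis runs on data from the package's own generators, which carry
ground-truth labels; all quantitative claims are therefore
parameter-recovery results, plus the printed calibrations and arithmetic
that need no data.

## Signal model and conventions

A tethered 2-kb DNA under 0.3 pN is supercoiled by magnet rotation. On the
negative, constant-torque branch of the hat curve the extension is linear in
the effective linking difference:

    extension(t) = intercept + slope * (applied_turns(t) + rloop_turns(t))

capped at the relaxed-DNA plateau once the effective linking difference
reaches zero. The analysis inverts this fit (ordinary least squares over a
user-chosen window, default −12…−4 applied turns) to express traces in
turns:

    turns(t) = (extension(t) − intercept) / slope − applied_turns(t)

With this sign convention R-loop formation under negative turns gives
*positive* turn values (formation increases extension). Formation of the
full 20-bp R-loop changes the linking difference by 1.8 turns; this single
calibration converts turns to unwound base pairs
(`bp = turns × 20 / 1.8`), so the 2.0-turn extended state corresponds to
20 + 2 bp and 2.3 turns to roughly 25–26 bp.

Rotation is rate-limited (10 turns/s), so each applied-turns change is a
linear ramp; event windows start only after the ramp plus a settle pad
(default 0.2 s) to exclude the unwinding transient.

## Trace generation

R-loop dynamics are a continuous-time Markov chain over turn-valued states,
realised by the Gillespie algorithm; emissions are the state position plus
white Gaussian noise at the camera rate (60 Hz default). The default WT
state set is {0, 0.45, 0.90, 1.35, 1.8, 2.0} turns: the basal state, three
evenly interpolated intermediates (placeholders — only the 1.8-turn main
state is a measured calibration), and a breathing state 0.2 turns (~2 bp)
beyond it. The mutant-style set is {0, 1.35, 2.0, 2.3} with the 2.0-turn
state dominant. Rate matrices are nearest-neighbour chains built by
detailed balance from a target stationary distribution (WT weights
0.04/0.06/0.10/0.15/0.55/0.10; mutant 0.05/0.15/0.55/0.25), with downward
rates of 0.5 /s (WT) or 0.25 /s (mutant) giving dwell times of roughly one
to several seconds. Bead noise is white in turn space; 1/f camera and
Brownian structure are deliberately not modelled, so passing tests
demonstrate estimator correctness under the assumed noise, not robustness
to instrument drift.

Emission sd defaults: 0.12 turns at 60 Hz for WT-style runs; 0.2 turns for
the mutant-style runs, chosen so the filtered 10 Hz noise matches the
~0.3–0.5-turn FWHM scale of measured state peaks.

### A note on boxcar decimation and "ghost" states

Filtering 60 Hz traces to 10 Hz by non-overlapping block means (the
display-style filter; it keeps step edges sharp) averages across state
transitions, producing samples part-way between levels. At low emission
noise these boundary samples are so improbable under any state Gaussian
that the maximum-likelihood k-state fit genuinely prefers devoting a broad
extra state to them over splitting a close pair of real levels — a property
of the blurred data, not of the optimiser (verified by comparing
truth-initialised EM likelihoods). Real traces dwell long enough, and are
noisy enough, that the artifact is minor there. Consequently the
*pipeline-level* recovery studies (which keep the full 60 Hz → 10 Hz chain)
measure quantities robust to this artifact — pooled peak positions of
heavily occupied states — while the *operation-level* state-count recovery
tests generate at the analysis rate directly, so that every sample is a
clean state emission. Population pooling also clusters per-event state
positions by 1-D mean-shift (bandwidth 0.08 turns) rather than
single-linkage, so a handful of between-level fits cannot chain two heavy
states into one cluster.

## State identification

Each formation event (one negative-turns phase, trimmed of its rotation
transient) is fitted with a Gaussian-emission HMM by
expectation–maximisation (hmmlearn), best of `n_restarts` (default 5)
restarts by log-likelihood. Initial means are diversified across restarts:
a greedy divisive scheme (repeatedly split the cluster with the largest
within-cluster SSE, then Lloyd refinement), plain 1-D k-means, quantiles,
and random data points — the divisive start is what reliably separates
close, heavy level pairs. Transition matrices start sticky (0.9 diagonal);
covariances share a single initial value.

The state count follows the peak-separation rule: k = 1…k_max (default 6)
are fitted, each model's Viterbi-assigned per-state histograms are fitted
with Gaussians (lmfit), and the largest k whose occupied states (≥ 20
samples) are pairwise separated by more than 0.1 turns is accepted —
smaller separations merge the Gaussian peaks. Separation is checked on
adjacent sorted positions, which is equivalent to all pairs. No information
criterion is involved; k = 1 is always admissible.

Per event, the occupancy P_r of a state is its Viterbi dwell time divided
by the event duration (reported both including the basal state in the
normalisation and renormalised over R-loop states only, since either
convention is defensible). The R-loop size is the maximum fitted position
among states dwelling at least 0.5 s in the event — the minimum-dwell
threshold excludes single-sample excursions — and the "main" size is the
position of the most-occupied non-basal state; both variants are exposed.
Rupture events are entries into the basal state (the state nearest 0
turns), and the rupture probability divides their count by the trace time.
Population tables pool events by mean-shift clustering of positions, report
duration-weighted pooled P_r, and fit one Gaussian over the concatenated
per-state samples (FWHM = 2√(2 ln 2) σ). Box statistics use
linear-interpolation quantiles (median, IQR, 10/90% whiskers, mean).

## Cleavage kinetics

Supercoiled plasmid (SC) is nicked to open circle (OC) at rate k_NTS, then
linearised (LIN) at rate k_TS; a fraction `1 − f_active` never reacts. The
closed-form solution of the two rate equations (with the confluent limit at
k_NTS = k_TS) is used for fitting, with a Runge–Kutta integration of the
same scheme as an independent oracle in the tests (agreement < 1e-6).
Fitting is unweighted least squares over all three species simultaneously;
the default mode fits each repeat separately and averages the rate
constants (standard error of the mean across repeats), with a pooled
shared-parameter mode also available. `f_active` is a bounded fit parameter
by default and can be fixed at 1. The fold ratio k_NTS/k_TS carries a
first-order propagated standard error. Simulated time courses draw
per-time-point multinomial samples (default 500 molecules, 8 log-spaced
times spanning both rates, 3 repeats); the generator's 23/5/2 rate-ratio
conditions use k_NTS = 0.23 /s throughout.

## Clamp traces and their annotation

After the non-target strand is nicked, free rotation at the nick should
make the tether insensitive to magnet rotation; clamping of the downstream
DNA by the enzyme isolates the nick in a topological domain so rotation
challenges trap supercoils and shorten the DNA. The generator's event
grammar: R-loop formation (k_rloop), nick (k_nick, releasing the trapped
supercoils to full length in a single camera-limited step unless the clamp
closes within one frame), then alternating clamp closures (k_close) that
are stable with probability p_stable and otherwise reopen (k_open),
releasing any trapped torque in 1–5 discrete steps (uniform by default,
~0.2–0.5 s apart); a stable clamp persists until target-strand cleavage
(k_ts_cut) breaks the tether (bead loss, end of trace). While clamped, the
trapped linking difference is `applied(t) − applied(t_close)`, so an
alternating ±12-turn challenge schedule alternately traps 24 turns and
unwinds them again — a persistent clamp is therefore only *visible* while
torque is trapped. Defaults (k_close = 1.0 /s, k_open = 1.2 /s,
p_stable = 0.15, k_ts_cut = 0.2 /s, challenges every 6 s) put the
open/close dynamics well inside a challenge period, the regime in which
unstable clamps show the characteristic shorten-then-step-release
signature within each challenge.

Step detection is a two-sample sliding-window mean comparison (window =
min_dwell × rate, default 0.1 s) with threshold 3× a robust noise sd
(median absolute first difference); contiguous supra-threshold regions
yield one step each at the argmax, and same-sign steps closer than
min_dwell are merged. The classifier finds the nick (first large upward
step landing at full length), marks every post-nick excursion below full
length as a clamped interval, counts release steps from upward steps
outside rotation ramps, merges shortened regions separated by
rotation-bounded torque-free gaps (a rotation-driven return to full length
is not a clamp release), and calls the final interval stable when it
persists to bead loss. Torque sign at the double-strand break is the sign
of the trapped linking difference of the stable clamp (0 when |trapped| <
0.5 turns, covering the zero-torque cleavage case). Traces that do not end
in bead loss are censored, never classified stable.

Annotation recovery is scored at observable decision points: at each
challenge (just after the ramp) the truth's clamp state is compared with
the classified interval type, skipping challenges within a guard second of
a ground-truth event boundary, closures that occurred mid-ramp (partial
trapping sits at the detection threshold), and clamps holding zero trapped
turns at the evaluation point (full length either way); stable-vs-unstable
is additionally compared per trace when the stable clamp was
torque-challenged and still held torque at the cut. Confusion under the
default conditions is ~1–3% (bound: 5% over 200 traces).

The two-proportion z-test (pooled standard error, one-tailed) and the
cleavage-locus arithmetic (1-based positions from the PAM-proximal edge of
the protospacer; 5′ overhang = TS − NTS position, so TS loci 22/23/24
against NTS 18 give 4/5/6 nt) complete the comparison toolbox.

## Problem sizes and numerics

Recovery studies use 30 traces × 60 s per condition, 100 replicates for
the kinetic fold-ratio study and 200 traces for clamp confusion; these
sizes give stable medians while keeping a full run of the analysis scripts
and acceptance checks in a few minutes on one CPU. EM uses up to 200
iterations at tolerance 1e-4 with a 1e-10 covariance floor (noiseless
traces are handled by short-circuiting degenerate fits to sample moments);
least-squares fits run at tolerance 1e-14. All randomness flows through
`numpy.random.default_rng`; one master seed spawns per-trace streams, so
every output is bit-reproducible.

## Known limitations

* Intermediate-state positions (between basal and the full R-loop) are
  generator placeholders; only the 1.8-turn/20-bp calibration and the
  2.0/2.3-turn extended states are anchored to measured values.
* The generator does not model torque-dependent rates, bead Brownian
  dynamics, drift, or sequence-level RNA–DNA annealing; recovery results
  say nothing about robustness to those effects.
* Observed clamp lifetimes mix clamp-opening stochastics with chemical
  cleavage rates; the annotation reports waiting times without decomposing
  the two.
* Boxcar decimation's transition smearing (above) biases state-count
  selection on fast-switching, low-noise traces; pooled positions of
  heavily occupied states are unaffected.
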