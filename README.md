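# rloopmt

Analysis of Cas12a R-loop dynamics and DNA cleavage from single-molecule
magnetic-tweezers traces, built as a fully synthetic, ground-truth-labelled
re-creation of the measurement pipeline.

Cas12a recognises DNA by forming an R-loop (crRNA paired to the target
strand, non-target strand displaced) and then cleaves the two strands in
obligatory order: non-target strand (NTS) first, target strand (TS)
second. In a tweezers assay the R-loop absorbs DNA linking number, so bead
height reports R-loop size in turns — the full 20-bp R-loop corresponds to
a change of 1.8 turns — and, once Mg²⁺ permits cleavage, the response of a
nicked tether to rotation reveals whether the enzyme "clamps" the
downstream DNA, trapping supercoils in a topological domain until TS
cleavage breaks the tether.

The package provides, for users who analyse such traces or want a tested
reference implementation:

* **`rloopmt.synthetic`** — generators for every input: continuous-time
  Markov chain R-loop traces with Gaussian bead noise at 60 Hz, hat-curve
  extension rendering, multinomial SC/OC/LIN cleavage time courses, and
  clamp-event cleavage traces, all with ground-truth labels.
* **`rloopmt.preprocess`** — 10 Hz boxcar filtering, hat-curve linear
  fitting, extension→turns conversion, per-event window sorting.
* **`rloopmt.states`** — Gaussian-HMM fitting (EM, diversified restarts),
  Viterbi decoding, per-state Gaussian peak fitting, state-count selection
  by the >0.1-turn peak-separation rule, occupancies P_r, R-loop sizes,
  rupture rates, population tables, and the 1.8-turn/20-bp calibration
  (`turns_to_bp`).
* **`rloopmt.kinetics`** — the ordered two-step cleavage model
  SC →(k_NTS)→ OC →(k_TS)→ LIN with active fraction f:
  SC = (1−f) + f·e^(−k_NTS t), OC = f·k_NTS/(k_TS−k_NTS)·(e^(−k_NTS t) −
  e^(−k_TS t)); per-repeat least-squares fits and the k_NTS/k_TS fold
  ratio.
* **`rloopmt.clamp`** — step detection, nick/clamp/release/bead-loss
  annotation, release-step histograms, 5′-overhang arithmetic from
  cleavage loci, one-tailed two-proportion z-test.

A thin CLI (`rloop-mt simulate-traces|analyze-traces|fit-kinetics|...`)
wraps `rloopmt.pipeline`; the numbered scripts under `analysis/` run the
whole study.

## Worked example

```
python analysis/01_simulate_datasets.py   # writes scratch/data/
python analysis/02_identify_states.py     # writes results/states/
python analysis/03_fit_cleavage_kinetics.py
python analysis/04_classify_clamp_events.py
python analysis/05_calibration_and_overhangs.py
```

Output of the state and kinetics steps on the default seeds:

```
wt: main R-loop state at 1.800 turns (generator truth 1.8); state-count tally: 5 states 17%, 6 states 83%
w355a: main R-loop state at 2.000 turns (generator truth 2.0); state-count tally: 4 states 20%, 5 states 37%, 6 states 43%

ratio23: k_NTS = 0.2324/s, k_TS = 0.01012/s, fold ratio = 22.97 ± 0.25 (truth 23.0)
ratio5:  k_NTS = 0.2353/s, k_TS = 0.04502/s, fold ratio = 5.23 ± 0.16 (truth 5.0)
ratio2:  k_NTS = 0.2366/s, k_TS = 0.12252/s, fold ratio = 1.93 ± 0.05 (truth 2.0)
```

The first block says the full preprocessing + HMM pipeline recovers the
main R-loop state at the 20-bp calibration position (1.8 turns) from noisy
60 Hz traces, and the extended state of the mutant-style condition at 2.0
turns; the tallies count how many discrete states the separation rule
accepted per event. The second block shows the two-step fit recovering the
NTS/TS rate constants and their fold ratio (the 23/5/2 conditions mirror
the three crRNA 3′-end scenarios). The clamp step reports the fraction of
traces ending in a stable clamp, the 1–5-step torque-release histogram,
and an annotation-vs-truth confusion of about 1% over the observable
comparisons; the calibration step prints the 2.0-turn state as 20 + 2
unwound bp and the TS loci 22/23/24 as 4/5/6-nt 5′ overhangs.

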