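#!/usr/bin/env python
"""Generate every dataset the downstream analyses consume.

Writes, under scratch/data/:
  wt/      -- 30 WT-style R-loop formation traces (main state at the
              1.8-turn / 20-bp calibration), 60 Hz, with truth labels
  w355a/   -- 30 mutant-style traces (extended states at 2.0 / 2.3 turns)
  kinetics/-- three-repeat SC/OC/LIN time courses at rate ratios 23, 5, 2
  clamps/  -- 40 single-molecule cleavage traces with clamp events

Everything is seeded; manifests record the exact parameters.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from rloopmt import pipeline  # noqa: E402

SEED = 2026
DATA = ROOT / "scratch" / "data"


def main() -> None:
    cfg_wt = {"seed": SEED, "n_traces": 30, "duration_s": 60.0,
              "preset": "wt_crrna24", "n_timecourse_repeats": 0}
    pipeline.cmd_simulate(cfg_wt, DATA / "wt")
    print(f"wrote WT formation traces -> {DATA / 'wt'}")

    cfg_mut = {"seed": SEED + 1, "n_traces": 30, "duration_s": 60.0,
               "preset": "w355a_crrna24", "n_timecourse_repeats": 0}
    pipeline.cmd_simulate(cfg_mut, DATA / "w355a")
    print(f"wrote mutant formation traces -> {DATA / 'w355a'}")

    for name, ratio in (("ratio23", 23.0), ("ratio5", 5.0), ("ratio2", 2.0)):
        cfg = {"seed": SEED + 2, "n_traces": 0, "duration_s": 1.0,
               "k_nts": 0.23, "k_ts": 0.23 / ratio, "f_active": 1.0,
               "n_timecourse_repeats": 3, "n_molecules": 500}
        pipeline.cmd_simulate(cfg, DATA / "kinetics" / name)
        print(f"wrote {name} time courses -> {DATA / 'kinetics' / name}")

    cfg_clamp = {"seed": SEED + 3, "n_traces": 0, "duration_s": 1.0,
                 "n_timecourse_repeats": 0, "n_clamp_traces": 40}
    pipeline.cmd_simulate(cfg_clamp, DATA / "clamps")
    print(f"wrote clamp traces -> {DATA / 'clamps'}")


if __name__ == "__main__":
    sys.exit(main())
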