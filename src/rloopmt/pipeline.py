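"""Pipeline orchestration: configurable commands over the library.

Each command takes a flat configuration mapping (typically loaded from a
YAML file of scalar keys), writes its outputs as TSV/JSON under an output
directory, and records a manifest sufficient to reproduce the run bit for
bit (seed, parameters, package version).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, synthetic, tabular
from .benchmarks import analyze_formation_traces, simulate_formation_traces
from .clamp import classify_clamp_intervals, detect_steps, release_step_histogram
from .kinetics import fit_timecourse, fold_ratio, model_fractions
from .states import aggregate_population

log = logging.getLogger("rloopmt")

__all__ = [
    "load_config",
    "require",
    "cmd_simulate",
    "cmd_analyze_traces",
    "cmd_fit_kinetics",
    "cmd_annotate_clamps",
]

_PRESETS = {
    "wt_crrna24": synthetic.wt_crrna24_params,
    "w355a_crrna24": synthetic.w355a_crrna24_params,
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def require(config: dict, *keys):
    for k in keys:
        if k not in config:
            raise KeyError(f"missing required config key: {k!r}")
    return [config[k] for k in keys]


def _manifest(config: dict, extra: dict | None = None) -> dict:
    m = {"version": __version__, "config": dict(config)}
    m.update(extra or {})
    return m


def cmd_simulate(config: dict, outdir) -> Path:
    """Generate formation traces, cleavage time courses and clamp traces.

    Required keys: ``seed``, ``n_traces``, ``duration_s``.  Optional:
    ``preset`` (wt_crrna24 | w355a_crrna24), ``n_timecourse_repeats``,
    ``k_nts``, ``k_ts``, ``f_active``, ``n_molecules``, ``n_clamp_traces``.
    Deterministic under the seed.
    """
    seed, n_traces, duration = require(config, "seed", "n_traces",
                                       "duration_s")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = config.get("preset", "wt_crrna24")
    if preset not in _PRESETS:
        raise KeyError(f"unknown preset {preset!r}")
    params = _PRESETS[preset]()

    traces = simulate_formation_traces(params, int(n_traces),
                                       float(duration), int(seed))
    schedule = synthetic.formation_schedule(phase=float(duration))
    for i, tr in enumerate(traces):
        tabular.write_trace(outdir / f"trace_{i:03d}.tsv", tr)
    tabular.write_schedule(outdir / "schedule.tsv", schedule)
    log.info("wrote %d formation traces to %s", len(traces), outdir)

    n_rep = int(config.get("n_timecourse_repeats", 3))
    if n_rep > 0:
        k_nts = float(config.get("k_nts", 0.23))
        k_ts = float(config.get("k_ts", 0.01))
        f_active = float(config.get("f_active", 1.0))
        times = np.geomspace(0.5 / k_nts, 5.0 / k_ts,
                             int(config.get("n_times", 8)))
        tcs = synthetic.simulate_timecourse(
            k_nts, k_ts, f_active, times,
            int(config.get("n_molecules", 500)), n_repeats=n_rep,
            seed=int(seed) + 1)
        tabular.write_timecourses(outdir / "timecourses.tsv", tcs)

    n_clamp = int(config.get("n_clamp_traces", 0))
    if n_clamp > 0:
        cparams = synthetic.ClampSimParams(seed=int(seed) + 2)
        cschedule = synthetic.clamp_challenge_schedule()
        rng = np.random.default_rng(int(seed) + 2)
        for i in range(n_clamp):
            tr, ann = synthetic.simulate_clamp_trace(cparams, cschedule,
                                                     rng=rng)
            tabular.write_trace(outdir / f"clamp_{i:03d}.tsv", tr)
        tabular.write_schedule(outdir / "challenge_schedule.tsv", cschedule)

    manifest = _manifest(config, {
        "n_traces_written": len(traces),
        "state_positions_turns": params.state_positions,
        "rate_matrix_per_s": params.rate_matrix,
    })
    tabular.write_manifest(outdir / "manifest.json", manifest)
    return outdir / "manifest.json"


def cmd_analyze_traces(config: dict, indir, outdir) -> pd.DataFrame:
    """Full trace analysis: filter, convert, model-select, summarise.

    Writes per-event statistics, the population state table, and the
    accepted-state-count tally (the 3/4/5-state proportions).
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = sorted(indir.glob("trace_*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no trace_*.tsv files found in {indir}")
    traces = [tabular.read_trace(p) for p in paths]

    events, samples, selections = analyze_formation_traces(
        traces,
        target_rate=float(config.get("target_rate_hz", 10.0)),
        k_max=int(config.get("k_max", 6)),
        min_separation=float(config.get("min_separation_turns", 0.1)),
        n_restarts=int(config.get("n_restarts", 5)),
        seed=int(config.get("seed", 0)))

    ev_rows = []
    for p, ev, sel in zip(paths, events, selections):
        ev_rows.append({
            "trace": p.name,
            "accepted_k": sel.accepted_k,
            "n_occupied": ev.state_count,
            "rloop_size_turns": ev.rloop_size,
            "main_size_turns": ev.main_size,
            "rupture_count": ev.rupture_count,
            "positions_turns": ";".join(f"{x:.4f}" for x in ev.positions),
            "occupancy": ";".join(f"{x:.4f}" for x in ev.occupancy),
        })
    ev_df = pd.DataFrame(ev_rows)
    with (outdir / "events.tsv").open("w") as fh:
        fh.write("# per-event HMM statistics; positions [turns], "
                 "occupancy [fraction], sizes [turns]\n")
        ev_df.to_csv(fh, sep="\t", index=False)

    pop = aggregate_population(events, samples)
    with (outdir / "population.tsv").open("w") as fh:
        fh.write("# population state table; positions [turns], "
                 "pooled_pr [fraction], fwhm [turns]\n")
        pop.table.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    tally = ev_df["accepted_k"].value_counts().sort_index()
    tally_df = pd.DataFrame({"n_states": tally.index,
                             "n_events": tally.values,
                             "fraction": tally.values / tally.values.sum()})
    with (outdir / "state_count_tally.tsv").open("w") as fh:
        fh.write("# accepted state-count tally per event [count, fraction]\n")
        tally_df.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    tabular.write_manifest(outdir / "analysis_manifest.json", _manifest(
        config, {"n_events": len(events),
                 "rloop_size_stats": pop.rloop_size_stats,
                 "main_size_stats": pop.main_size_stats}))
    return ev_df


def cmd_fit_kinetics(config: dict, timecourse_path, outdir) -> dict:
    """Fit SC->OC->LIN time courses and report rates and fold ratio."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = tabular.read_timecourses(timecourse_path)
    fit = fit_timecourse(data, mode=config.get("fit_mode", "per_repeat"),
                         fix_f_active=config.get("fix_f_active"))
    ratio, ratio_se = fold_ratio(fit)

    rows = [{"repeat": tc.repeat_id, "k_nts_per_s": f.k_nts,
             "k_ts_per_s": f.k_ts, "f_active": f.f_active}
            for tc, f in zip(data, fit.per_repeat)] if fit.per_repeat else []
    rows.append({"repeat": "mean", "k_nts_per_s": fit.k_nts,
                 "k_ts_per_s": fit.k_ts, "f_active": fit.f_active})
    with (outdir / "kinetic_fit.tsv").open("w") as fh:
        fh.write("# two-step cleavage fit; rates [per s], "
                 "f_active [fraction]\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.6g")

    # model curves at the averaged parameters (overlay data)
    t_grid = np.geomspace(max(min(data[0].times[data[0].times > 0],
                                  default=1e-2), 1e-2),
                          data[0].times[-1], 50) \
        if np.any(data[0].times > 0) else np.linspace(0, 1, 50)
    sc, oc, lin = model_fractions(fit.k_nts, fit.k_ts, fit.f_active, t_grid)
    with (outdir / "fit_curves.tsv").open("w") as fh:
        fh.write("# model fractions at averaged parameters [fraction]\n")
        pd.DataFrame({"time_s": t_grid, "frac_sc": sc, "frac_oc": oc,
                      "frac_lin": lin}).to_csv(fh, sep="\t", index=False,
                                               float_format="%.6g")

    report = {"k_nts_per_s": fit.k_nts, "k_ts_per_s": fit.k_ts,
              "f_active": fit.f_active, "fold_ratio": ratio,
              "fold_ratio_se": ratio_se, "stderr": fit.stderr,
              "mode": fit.mode, "n_repeats": len(data)}
    tabular.write_manifest(outdir / "kinetics_report.json",
                           _manifest(config, report))
    return report


def cmd_annotate_clamps(config: dict, indir, outdir) -> pd.DataFrame:
    """Annotate clamp traces and pool release-step statistics."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = sorted(indir.glob("clamp_*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no clamp_*.tsv files found in {indir}")
    schedule = tabular.read_schedule(indir / "challenge_schedule.tsv")

    rows, anns = [], []
    for p in paths:
        tr = tabular.read_trace(p)
        steps = detect_steps(tr, min_dwell=float(config.get("min_dwell_s",
                                                            0.1)))
        ann = classify_clamp_intervals(tr, schedule, steps)
        anns.append(ann)
        rows.append({
            "trace": p.name,
            "nick_time_s": ann.nick_time,
            "n_unstable": ann.n_unstable,
            "stable": ann.has_stable,
            "bead_loss_time_s": ann.bead_loss_time,
            "torque_sign_at_dsb": ann.torque_sign_at_dsb,
            "release_steps": ";".join(map(str, ann.release_steps)),
        })
    df = pd.DataFrame(rows)
    with (outdir / "clamp_annotations.tsv").open("w") as fh:
        fh.write("# clamp-event annotations; times [s]\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.3f")

    with_release = [a for a in anns if a.release_steps]
    extra = {"n_traces": len(paths)}
    if with_release:
        counts, fracs = release_step_histogram(with_release)
        with (outdir / "release_step_histogram.tsv").open("w") as fh:
            fh.write("# release-step histogram [count, fraction]\n")
            pd.DataFrame({"n_steps": np.arange(1, 6), "count": counts,
                          "fraction": fracs}).to_csv(
                fh, sep="\t", index=False, float_format="%.4f")
        extra["n_release_events"] = int(counts.sum())
    tabular.write_manifest(outdir / "clamp_manifest.json",
                           _manifest(config, extra))
    return df
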