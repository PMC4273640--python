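"""End-to-end orchestration: simulate a session to disk, analyze it back.

``run_simulate`` produces the behavioral log, the event markers, one
conductance trace per subject and the injected-SCR ground truth.
``run_analyze`` re-reads those files, runs the SCR pipeline per subject,
tests the five standard condition contrasts (officials' choices in T0 and
T1, firms' bid decisions in T0 and T1, and bribing vs honest winners
waiting for the loser's audit decision), summarizes behavior and the
arousal/response-time rank correlation, and writes everything as
delimited text plus a JSON manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import edasynth, io, pipeline, stats
from .simulate import (
    EventMarker,
    SessionConfig,
    simulate_session,
    summarize_behavior,
)

__all__ = ["CONTRASTS", "run_simulate", "run_analyze"]

logger = logging.getLogger(__name__)

#: (name, time-locking event type, condition A, condition B)
CONTRASTS = [
    ("officials_choice_T0", "decision_screen_on",
     "T0:choice_bribe_max", "T0:choice_quality_max"),
    ("officials_choice_T1", "decision_screen_on",
     "T1:choice_bribe_max", "T1:choice_quality_max"),
    ("firms_bid_T0", "decision_screen_on", "T0:bid_bribe", "T0:bid_no_bribe"),
    ("firms_bid_T1", "decision_screen_on", "T1:bid_bribe", "T1:bid_no_bribe"),
    ("winners_wait_T1", "inspection_wait_on",
     "T1:wait_bribed", "T1:wait_honest"),
]


def run_simulate(
    config: SessionConfig,
    out_dir,
    write_traces: bool = True,
) -> dict:
    """Simulate one session and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, markers = simulate_session(config)
    if not records:
        raise ValueError("simulation produced an empty log (n_triplets=0?)")

    outputs = []
    io.write_period_records(records, out / "periods.tsv")
    io.write_markers(markers, out / "markers.tsv")
    outputs += ["periods.tsv", "markers.tsv"]

    if write_traces:
        traces_dir = out / "traces"
        traces_dir.mkdir(exist_ok=True)
        truth_all = []
        subjects = sorted({m.subject for m in markers})
        amp_model = edasynth.default_amplitude_model()
        for i, subj in enumerate(subjects):
            sub_markers = [m for m in markers if m.subject == subj]
            rng = np.random.default_rng([config.seed, i])
            trace, truth = edasynth.synthesize_trace(
                sub_markers, amplitudes=amp_model, rng=rng
            )
            io.write_trace(trace, traces_dir / f"{subj}.tsv")
            outputs.append(f"traces/{subj}.tsv")
            truth_all.extend(truth)
        io.write_ground_truth(truth_all, out / "scr_truth.tsv")
        outputs.append("scr_truth.tsv")

    io.dump_session_config(config, out / "config.yaml")
    outputs.append("config.yaml")
    io.write_manifest(
        out / "manifest.json", config, config.seed, [], outputs
    )
    return {"out_dir": str(out), "n_records": len(records),
            "n_markers": len(markers), "outputs": outputs}


def _decision_rts(markers: list[EventMarker]) -> dict[str, float]:
    """event_id of a decision_screen_on -> response time (s)."""
    rts: dict[str, float] = {}
    by_subject: dict[str, list[EventMarker]] = {}
    for m in sorted(markers, key=lambda m: (m.subject, m.time_s)):
        by_subject.setdefault(m.subject, []).append(m)
    for ms in by_subject.values():
        for i, m in enumerate(ms):
            if m.event_type != "decision_screen_on":
                continue
            made = next(
                (x for x in ms[i + 1:] if x.event_type == "decision_made"),
                None,
            )
            if made is not None:
                rts[m.event_id] = made.time_s - m.time_s
    return rts


def run_analyze(
    in_dir,
    out_dir,
    seed: int = 0,
    config: pipeline.PipelineConfig = pipeline.PipelineConfig(),
    contrasts=CONTRASTS,
    n_surrogates: int = 200,
    q: float = 0.05,
) -> dict:
    """Analyze a simulated (or recorded) session directory."""
    ind = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers = io.read_markers(ind / "markers.tsv")
    records = io.read_period_records(ind / "periods.tsv")

    outputs = []
    report_lines = ["physioecon analysis report", ""]

    # behavioral summary
    if records:
        summary = summarize_behavior(records)
        report_lines.append("Behavior")
        for trt, mb in sorted(summary["mean_bribe"].items()):
            report_lines.append(f"  mean bribe {trt}: {mb:.3f}")
        for trt, d in sorted(summary["official_decisions"].items()):
            if d["n_non_tie"]:
                report_lines.append(
                    f"  officials {trt}: {100 * d['share_bribe_max']:.2f}% "
                    f"monetary-max, {100 * d['share_quality_max']:.2f}% "
                    f"pro-social ({d['n_non_tie']} non-tie, {d['n_tie']} ties)"
                )
        if np.isfinite(summary["inspection_share"]):
            report_lines.append(
                f"  inspection share: {100 * summary['inspection_share']:.2f}%"
            )
        if np.isfinite(summary["inspecting_losers_bribed_share"]):
            report_lines.append(
                "  inspecting losers who had bribed: "
                f"{100 * summary['inspecting_losers_bribed_share']:.2f}%"
            )
        report_lines.append("")

    if not markers:
        report_lines.append("No event markers: no contrasts computed.")
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        io.write_manifest(out / "manifest.json", config, seed,
                          ["markers.tsv", "periods.tsv"], ["report.txt"])
        return {"contrasts": {}, "report": str(out / "report.txt")}

    # per-subject pipeline
    subjects = sorted({m.subject for m in markers})
    traces_dir = ind / "traces"
    filtered: dict[str, edasynth.EDATrace] = {}
    all_scrs: list[pipeline.SCREvent] = []
    missing = []
    for subj in subjects:
        path = traces_dir / f"{subj}.tsv"
        if not path.exists():
            missing.append(subj)
            continue
        trace = io.read_trace(path, subject=subj)
        ftrace = pipeline.lowpass(trace, config)
        filtered[subj] = ftrace
        scrs = pipeline.detect_scrs(ftrace, config)
        sub_markers = [m for m in markers if m.subject == subj]
        all_scrs.extend(pipeline.associate(scrs, sub_markers, config))
    if missing:
        logger.warning("missing traces for %d subjects: %s",
                       len(missing), ", ".join(missing))
        report_lines.append(
            f"Missing traces skipped: {', '.join(missing)}")

    io.write_scr_events(all_scrs, out / "scr_events.tsv")
    outputs.append("scr_events.tsv")

    # condition contrasts
    results = {}
    for name, etype, cond_a, cond_b in contrasts:
        sets_a, sets_b, ids_a, ids_b = [], [], [], []
        for subj, ftrace in filtered.items():
            ms = [m for m in markers
                  if m.subject == subj and m.event_type == etype]
            ea = pipeline.build_epochs(ftrace, ms, cond_a, config)
            eb = pipeline.build_epochs(ftrace, ms, cond_b, config)
            if ea.n_events:
                sets_a.append(ea.data)
                ids_a += [subj] * ea.n_events
            if eb.n_events:
                sets_b.append(eb.data)
                ids_b += [subj] * eb.n_events
        fs = config_fs = next(iter(filtered.values())).sampling_rate if filtered else 0
        na = sum(x.shape[0] for x in sets_a)
        nb = sum(x.shape[0] for x in sets_b)
        if na < 2 or nb < 2:
            report_lines.append(
                f"Contrast {name}: insufficient epochs ({na} vs {nb}); skipped."
            )
            continue
        ep_a = pipeline.EpochSet(cond_a, np.vstack(sets_a), fs, ids_a)
        ep_b = pipeline.EpochSet(cond_b, np.vstack(sets_b), fs, ids_b)
        res = stats.waveform_permutation_test(
            ep_a, ep_b, n_surrogates=n_surrogates, q=q,
            seed=seed + len(results), subject_ids=ids_a + ids_b,
        )
        res.to_frame().to_csv(out / f"contrast_{name}.tsv",
                              sep="\t", index=False, float_format="%.6g")
        outputs.append(f"contrast_{name}.tsv")
        results[name] = res
        report_lines.append(f"Contrast {name} ({cond_a} vs {cond_b}):")
        report_lines.extend("  " + l for l in res.summary().splitlines()[1:])
        report_lines.append("")

    # arousal vs response time (linked decision SCR amplitude vs RT)
    rts = _decision_rts(markers)
    pairs = [
        (s.amplitude, rts[s.linked_event])
        for s in all_scrs
        if s.linked_event in rts
    ]
    if len(pairs) >= 3:
        amp, rt = zip(*pairs)
        rho = stats.spearman_rho(amp, rt)
        report_lines.append(
            f"Arousal vs response time: {rho.summary()}"
        )
    else:
        report_lines.append(
            "Arousal vs response time: insufficient linked SCRs."
        )

    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    outputs.append("report.txt")
    io.write_manifest(
        out / "manifest.json", config, seed,
        [str(ind / "markers.tsv"), str(ind / "periods.tsv")], outputs,
    )
    return {"contrasts": results, "report": str(out / "report.txt"),
            "n_scrs": len(all_scrs), "missing_traces": missing}
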