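#!/usr/bin/env python
"""Extract per-trial kinematics from the simulated raw recordings.

For every participant under ``scratch/study/``: calibrate the trace on
rest windows, remove gravity per trial, integrate acceleration over [R, A],
detrend the speed magnitude and extract TPV%, applying the 5–95% inclusion
band.  Writes the pooled per-trial table to ``scratch/kinematics.csv`` and
the per-condition descriptive summary to ``results/descriptives.csv``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from reachkin.compare import descriptives
from reachkin.io import read_events, read_trace
from reachkin.pipeline import PipelineConfig, process_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.parse_args()

    study = ROOT / "scratch" / "study"
    traces = sorted(study.glob("p*_trace.csv"))
    if not traces:
        raise SystemExit("no simulated study found; run 01_simulate_study.py first")

    cfg = PipelineConfig()
    frames = []
    for trace_path in traces:
        pid = trace_path.name.split("_")[0]
        trace = read_trace(trace_path)
        events = read_events(study / f"{pid}_events.csv")
        frames.append(process_session(trace, events, cfg, pid))
    kin = pd.concat(frames, ignore_index=True)
    kin.to_csv(ROOT / "scratch" / "kinematics.csv", index=False)

    desc = descriptives(kin)
    desc["by_condition"].round(2).to_csv(ROOT / "results" / "descriptives.csv",
                                         index=False)
    (ROOT / "results" / "trial_counts.json").write_text(
        json.dumps(desc["counts"], indent=2) + "\n")

    c = desc["counts"]
    print(f"processed {len(traces)} sessions, {len(kin)} trials")
    print(f"  {c['correct']} correct, {c['incorrect']} incorrect, "
          f"{c['omission']} omissions, {c['anticipation']} anticipations")
    print(f"  TPV exclusions (outside 5-95%): {c['tpv_excluded']}")
    for _, row in desc["by_condition"].iterrows():
        print(f"  {row['condition']:>12}: RT {row['rt_mean']:.0f} ms, "
              f"MD {row['md_mean']:.0f} ms, TPV {row['tpv_mean']:.1f}% "
              f"(n={int(row['tpv_n'])})")
    print("  tables -> results/descriptives.csv, results/trial_counts.json")


if __name__ == "__main__":
    main()
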