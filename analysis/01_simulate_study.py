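#!/usr/bin/env python
"""Simulate the full 19-participant Go/No-Go accelerometer study.

Writes each participant's raw wrist-sensor trace and event log (the exact
CSV dialects the real device/task software would export) under
``scratch/study/`` and a per-session trial-count summary under
``results/session_counts.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reachkin.io import write_events, write_trace
from reachkin.session import BetaGlmmParams, SubjectEffects, gen_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--participants", type=int, default=19)
    args = ap.parse_args()

    out = ROOT / "scratch" / "study"
    out.mkdir(parents=True, exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)

    glmm = BetaGlmmParams()
    ss = np.random.SeedSequence(args.seed).spawn(args.participants + 1)
    rng_subj = np.random.default_rng(ss[-1])

    rows = []
    for i in range(args.participants):
        pid = f"p{i + 1:02d}"
        b = rng_subj.normal(0.0, glmm.sigma_b)
        sess = gen_session(
            glmm=glmm,
            subject=SubjectEffects(participant=pid, tpv_intercept_shift=b),
            seed=int(ss[i].generate_state(1)[0] % (2**31)),
        )
        write_trace(sess.trace, out / f"{pid}_trace.csv")
        write_events(sess.events, out / f"{pid}_events.csv")
        sess.truth.to_csv(out / f"{pid}_truth.csv", index=False)
        counts = sess.truth["validity"].value_counts()
        rows.append(dict(
            participant=pid,
            total=int(counts.sum()),
            valid_correct=int(counts.get("valid_correct", 0)),
            valid_incorrect=int(counts.get("valid_incorrect", 0)),
            omission=int(counts.get("omission", 0)),
            anticipation=int(counts.get("anticipation", 0)),
            trace_minutes=round(sess.trace.time_s[-1] / 60, 2),
        ))

    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "session_counts.csv", index=False)
    tot = summary[["total", "valid_correct", "valid_incorrect",
                   "omission", "anticipation"]].sum()
    print(f"simulated {args.participants} sessions (seed {args.seed})")
    print(f"  trials: {tot['total']} total, "
          f"{tot['valid_correct']} correct, {tot['valid_incorrect']} incorrect, "
          f"{tot['omission']} omissions, {tot['anticipation']} anticipations")
    print(f"  raw data -> {out}")
    print(f"  summary  -> results/session_counts.csv")


if __name__ == "__main__":
    main()
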