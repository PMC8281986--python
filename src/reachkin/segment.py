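"""Event-log parsing, trial validity classification and timing measures.

A trial carries up to four timestamps — P (hand on start sensor), S
(stimulus onset), R (release), A (answer touch).  Reaction time is R−S,
movement duration is A−R, and the foreperiod (StimulusRandomTime) is S−P.
Trials are classified as valid (correct/incorrect), omissions (no answer
inside the response window) or anticipations (release before the stimulus;
the task then shows no stimulus at all, so S and A are absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_CORRECT = "valid_correct"
VALID_INCORRECT = "valid_incorrect"
OMISSION = "omission"
ANTICIPATION = "anticipation"
VALIDITY_TAGS = (VALID_CORRECT, VALID_INCORRECT, OMISSION, ANTICIPATION)


class EventFormatError(ValueError):
    """Malformed or non-monotonic event record."""


@dataclass
class TrialEvents:
    """One trial's timestamps (seconds) and response metadata."""

    trial: int
    block: int
    condition: str
    P: float
    S: float | None = None
    R: float | None = None
    A: float | None = None
    response: str = ""
    correct: bool | None = None


@dataclass
class TrialTiming:
    """Derived per-trial timing measures, in milliseconds."""

    rt_ms: float
    md_ms: float
    srt_ms: float


def _opt(value) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def parse_events(records) -> list[TrialEvents]:
    """Parse event rows (DataFrame or CSV path) into TrialEvents.

    Missing timestamps are preserved as absent.  Orderings that can never
    occur (S before P, A before S, A before R) raise a format error naming
    the trial; R before S is left to the classifier, which tags it as an
    anticipation.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    out = []
    for _, row in records.iterrows():
        trial = int(row["trial"])
        P = _opt(row.get("P_s"))
        if P is None:
            raise EventFormatError(f"trial {trial}: missing P timestamp")
        S, R, A = (_opt(row.get(k)) for k in ("S_s", "R_s", "A_s"))
        for name, v in (("S", S), ("R", R), ("A", A)):
            if v is not None and v < P:
                raise EventFormatError(f"trial {trial}: {name} precedes P")
        if A is not None and S is not None and A < S:
            raise EventFormatError(f"trial {trial}: A precedes S")
        if A is not None and R is not None and A < R:
            raise EventFormatError(f"trial {trial}: A precedes R")
        correct = row.get("correct")
        if correct is None or (not isinstance(correct, str) and pd.isna(correct)):
            correct_b = None
        elif isinstance(correct, str):
            correct_b = None if correct == "" else correct.lower() in ("1", "true")
        else:
            correct_b = bool(correct)
        out.append(
            TrialEvents(
                trial=trial,
                block=int(row.get("block", 1)),
                condition=str(row["condition"]),
                P=P, S=S, R=R, A=A,
                response="" if pd.isna(row.get("response")) else str(row.get("response", "")),
                correct=correct_b,
            )
        )
    return out


def classify_trial(ev: TrialEvents, response_window_ms: float = 2000.0) -> str:
    """Assign exactly one validity tag to a trial.

    Anticipation: release before the stimulus (or a release with no stimulus
    ever shown).  Omission: no answer within the response window after the
    stimulus (the window boundary itself counts as valid).  Otherwise the
    trial is valid and split by the correctness flag.
    """
    if ev.R is not None and (ev.S is None or ev.R < ev.S):
        return ANTICIPATION
    if ev.S is None:
        # no stimulus and no release: treat as an aborted/omitted trial
        return OMISSION
    if ev.A is None or (ev.A - ev.S) * 1000.0 > response_window_ms:
        return OMISSION
    return VALID_CORRECT if ev.correct else VALID_INCORRECT


def timing(ev: TrialEvents) -> TrialTiming:
    """RT, MD and StimulusRandomTime of a valid trial, in ms."""
    if ev.S is None or ev.R is None or ev.A is None:
        raise EventFormatError(f"trial {ev.trial}: timing requires S, R and A")
    rt = (ev.R - ev.S) * 1000.0
    md = (ev.A - ev.R) * 1000.0
    if rt < 0:
        raise EventFormatError(f"trial {ev.trial}: negative reaction time")
    if md <= 0:
        raise EventFormatError(f"trial {ev.trial}: non-positive movement duration")
    return TrialTiming(rt_ms=rt, md_ms=md, srt_ms=(ev.S - ev.P) * 1000.0)


def timing_table(events: list[TrialEvents], response_window_ms: float = 2000.0) -> pd.DataFrame:
    """Per-trial timing table: trial, condition, validity, RT/MD/SRT in ms."""
    rows = []
    for ev in events:
        tag = classify_trial(ev, response_window_ms)
        if tag in (VALID_CORRECT, VALID_INCORRECT):
            tm = timing(ev)
            rt, md, srt = tm.rt_ms, tm.md_ms, tm.srt_ms
        else:
            rt = md = float("nan")
            srt = (ev.S - ev.P) * 1000.0 if ev.S is not None else float("nan")
        rows.append(dict(trial=ev.trial, condition=ev.condition, validity=tag,
                         RT_ms=rt, MD_ms=md, SRT_ms=srt))
    return pd.DataFrame(rows)
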