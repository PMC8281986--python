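"""Go/No-Go session simulator.

Emits what the experiment actually records: a continuous wrist-accelerometer
trace plus a per-trial event log with the four task timestamps

* P — hand pressed onto the start sensor,
* S — central stimulus onset (P plus a uniform 0–2,000 ms foreperiod),
* R — hand released from the start sensor (S + reaction time),
* A — answer key touched (R + movement duration).

The dominant cue appears on 75% of trials by default; sessions run until 160
valid (correct or incorrect) trials exist or 180 total trials have elapsed.
Anticipations (release before the stimulus: S and A missing) and omissions
(no answer inside the 2,000 ms response window: R and A missing) are injected
at configurable rates.  Per-condition RT/MD generating distributions are
lognormal with moments matched to the descriptive statistics of the study the
package emulates (dominant RT 558±136 ms, MD 500±167 ms; non-dominant RT
601±163 ms, MD 591±207 ms).

Each valid trial's true time-to-peak-velocity fraction is drawn from a
logit-link beta model with a participant-level random intercept, and the
corresponding asymmetric reach is written into the acceleration timeline, so
ground truth is available for every downstream recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401 (logit used in defaults)

from .profiles import gen_asymmetric_reach
from .sensor import AccelTrace, SensorParams, sense_array

CONDITIONS = ("dominant", "non-dominant")

EVENT_COLUMNS = [
    "trial",
    "block",
    "condition",
    "P_s",
    "S_s",
    "R_s",
    "A_s",
    "response",
    "correct",
]


@dataclass
class TaskParams:
    """Parameters of the Go/No-Go reaching task and its trial mix."""

    n_valid_trials: int = 160
    max_total_trials: int = 180
    p_dominant: float = 0.75
    response_window_ms: float = 2000.0
    foreperiod_range_ms: tuple = (0.0, 2000.0)
    rt_mean_ms: dict = field(
        default_factory=lambda: {"dominant": 558.0, "non-dominant": 601.0}
    )
    rt_sd_ms: dict = field(
        default_factory=lambda: {"dominant": 136.0, "non-dominant": 163.0}
    )
    md_mean_ms: dict = field(
        default_factory=lambda: {"dominant": 500.0, "non-dominant": 591.0}
    )
    md_sd_ms: dict = field(
        default_factory=lambda: {"dominant": 167.0, "non-dominant": 207.0}
    )
    p_anticipation: float = 0.007
    p_omission: float = 0.034
    p_incorrect: float = 0.018
    reach_amplitude_m: float = 0.35
    initial_rest_s: float = 2.0
    intertrial_rest_s: float = 0.8
    return_delay_s: float = 0.2
    return_duration_s: float = 0.45

    def __post_init__(self):
        if not 0.0 < self.p_dominant < 1.0:
            raise ValueError("p_dominant must lie strictly between 0 and 1")
        if self.n_valid_trials > self.max_total_trials:
            raise ValueError("n_valid_trials cannot exceed max_total_trials")
        if self.n_valid_trials < 1:
            raise ValueError("need at least one valid trial")
        if self.p_anticipation + self.p_omission >= 1.0:
            raise ValueError("invalid-trial rates must sum below 1")
        lo, hi = self.foreperiod_range_ms
        if not 0 <= lo <= hi:
            raise ValueError("invalid foreperiod range")


@dataclass
class BetaGlmmParams:
    """Generating parameters of the logit-link beta model for TPV.

    The linear predictor is
    ``intercept + beta_condition·[non-dominant] + beta_srt·z(SRT)
    + beta_interaction·[non-dominant]·z(SRT) + b_participant`` with
    ``b ~ N(0, sigma_b²)``; TPV ~ Beta(mu·phi, (1-mu)·phi).  Defaults put the
    marginal means at 40% (dominant) and 45% (non-dominant), the two
    condition means of the emulated study.
    """

    intercept: float = float(logit(0.40))
    beta_condition: float = float(logit(0.45) - logit(0.40))
    beta_srt: float = 0.0
    beta_interaction: float = 0.0
    sigma_b: float = 0.2
    phi: float = 12.0
    #: standardization of StimulusRandomTime: mean and SD of U(0, 2000) ms
    srt_center_ms: float = 1000.0
    srt_scale_ms: float = 2000.0 / math.sqrt(12.0)

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("dispersion phi must be positive")
        if self.sigma_b < 0:
            raise ValueError("random-intercept SD must be non-negative")

    def mean(self, condition, srt_ms, b: float = 0.0) -> np.ndarray:
        nd = np.asarray(condition) == "non-dominant"
        z = (np.asarray(srt_ms, dtype=float) - self.srt_center_ms) / self.srt_scale_ms
        eta = (
            self.intercept
            + self.beta_condition * nd
            + self.beta_srt * z
            + self.beta_interaction * nd * z
            + b
        )
        return expit(eta)


@dataclass
class SubjectEffects:
    """Per-participant deviations applied by the session generator."""

    participant: str = "p01"
    tpv_intercept_shift: float = 0.0
    rt_scale: float = 1.0
    md_scale: float = 1.0


@dataclass
class Session:
    """A simulated recording: the sensor trace, the event log, and ground truth."""

    trace: AccelTrace | None
    events: pd.DataFrame
    truth: pd.DataFrame
    participant: str
    seed: int


def _lognormal_ms(mean_ms: float, sd_ms: float):
    s2 = math.log1p((sd_ms / mean_ms) ** 2)
    return math.log(mean_ms) - s2 / 2.0, math.sqrt(s2)


def draw_conditions(n: int, p_dominant: float, rng: np.random.Generator) -> np.ndarray:
    """Draw the cue condition for ``n`` trials (dominant with prob. p_dominant)."""
    return np.where(
        rng.random(n) < p_dominant, CONDITIONS[0], CONDITIONS[1]
    )


def _draw_rt_md(task: TaskParams, cond: str, subj: SubjectEffects, rng) -> tuple:
    mu_rt, s_rt = _lognormal_ms(task.rt_mean_ms[cond] * subj.rt_scale, task.rt_sd_ms[cond])
    mu_md, s_md = _lognormal_ms(task.md_mean_ms[cond] * subj.md_scale, task.md_sd_ms[cond])
    for _ in range(1000):
        rt = rng.lognormal(mu_rt, s_rt)
        md = rng.lognormal(mu_md, s_md)
        # answers must land inside the response window to count as valid
        if rt + md <= task.response_window_ms and md >= 100.0:
            return rt, md
    return 0.45 * task.response_window_ms, 0.45 * task.response_window_ms


def gen_session(
    task: TaskParams | None = None,
    sensor: SensorParams | None = None,
    glmm: BetaGlmmParams | None = None,
    subject: SubjectEffects | None = None,
    seed: int = 0,
    include_trace: bool = True,
) -> Session:
    """Simulate one participant's full Go/No-Go session.

    Trials are generated until ``n_valid_trials`` valid ones exist or
    ``max_total_trials`` is reached.  Returns the sensed trace (unless
    ``include_trace`` is False), the event log in the standard CSV dialect,
    and a ground-truth table with the generating RT/MD/TPV of every trial.
    """
    task = task or TaskParams()
    sensor = sensor or SensorParams()
    glmm = glmm or BetaGlmmParams()
    subject = subject or SubjectEffects()

    streams = np.random.SeedSequence(seed).spawn(7)
    rng_cond, rng_fp, rng_val, rng_rtmd, rng_tpv, rng_noise, rng_misc = (
        np.random.default_rng(s) for s in streams
    )

    b_subj = subject.tpv_intercept_shift

    cursor = task.initial_rest_s
    fp_lo, fp_hi = (v / 1000.0 for v in task.foreperiod_range_ms)
    win_s = task.response_window_ms / 1000.0

    event_rows = []
    truth_rows = []
    movements = []  # (start_s, duration_s, tpv_frac, direction)

    n_valid = 0
    n_total = 0
    while n_valid < task.n_valid_trials and n_total < task.max_total_trials:
        n_total += 1
        cond = str(draw_conditions(1, task.p_dominant, rng_cond)[0])
        fp = rng_fp.uniform(fp_lo, fp_hi)
        P = cursor
        S = P + fp
        u = rng_val.random()

        block = 1 if n_valid < task.n_valid_trials / 2 else 2
        row = dict(
            trial=n_total, block=block, condition=cond,
            P_s=P, S_s=None, R_s=None, A_s=None, response="", correct=None,
        )

        if u < task.p_anticipation:
            # early release during the foreperiod: trial aborted, no stimulus
            R = P + max(0.05, rng_misc.uniform(0.1, 0.9) * fp)
            md = _draw_rt_md(task, cond, subject, rng_rtmd)[1] / 1000.0
            row.update(R_s=R)
            movements.append((R, md, 0.5, 1.0))
            movements.append((R + md + task.return_delay_s, task.return_duration_s, 0.5, -1.0))
            cursor = R + md + task.return_delay_s + task.return_duration_s + task.intertrial_rest_s
            truth_rows.append(dict(trial=n_total, condition=cond, validity="anticipation",
                                   rt_ms=np.nan, md_ms=np.nan, srt_ms=fp * 1000.0,
                                   true_tpv_frac=np.nan))
        elif u < task.p_anticipation + task.p_omission:
            row.update(S_s=S)
            cursor = S + win_s + task.intertrial_rest_s
            truth_rows.append(dict(trial=n_total, condition=cond, validity="omission",
                                   rt_ms=np.nan, md_ms=np.nan, srt_ms=fp * 1000.0,
                                   true_tpv_frac=np.nan))
        else:
            rt_ms, md_ms = _draw_rt_md(task, cond, subject, rng_rtmd)
            R = S + rt_ms / 1000.0
            A = R + md_ms / 1000.0
            mu = float(glmm.mean(cond, fp * 1000.0, b_subj))
            tpv = float(np.clip(rng_tpv.beta(mu * glmm.phi, (1 - mu) * glmm.phi),
                                0.02, 0.98))
            correct = u >= task.p_anticipation + task.p_omission + task.p_incorrect
            row.update(S_s=S, R_s=R, A_s=A,
                       response="target" if correct else "foil", correct=correct)
            movements.append((R, md_ms / 1000.0, tpv, 1.0))
            movements.append((A + task.return_delay_s, task.return_duration_s, 0.5, -1.0))
            cursor = A + task.return_delay_s + task.return_duration_s + task.intertrial_rest_s
            n_valid += 1
            truth_rows.append(dict(
                trial=n_total, condition=cond,
                validity="valid_correct" if correct else "valid_incorrect",
                rt_ms=rt_ms, md_ms=md_ms, srt_ms=fp * 1000.0, true_tpv_frac=tpv))
        event_rows.append(row)

    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "participant", subject.participant)

    trace = None
    if include_trace:
        fs = sensor.sample_rate_hz
        total_s = cursor + 1.0
        n = int(math.ceil(total_s * fs)) + 1
        t = np.arange(n) / fs
        acc_body = np.zeros((n, 3))
        for start, dur, tpv_frac, direction in movements:
            prof = gen_asymmetric_reach(
                max(dur, 0.1), task.reach_amplitude_m, tpv_frac, fs
            )
            i0 = int(round(start * fs))
            seg = prof.acc[:, 0] * direction
            i1 = min(i0 + seg.size, n)
            acc_body[i0:i1, 0] += seg[: i1 - i0]
        trace = AccelTrace(
            time_s=t,
            acc_g=sense_array(t, acc_body, sensor, rng_noise),
            sample_rate_hz=fs,
            range_g=sensor.range_g,
            resolution_bits=sensor.resolution_bits,
        )

    return Session(trace=trace, events=events, truth=truth,
                   participant=subject.participant, seed=seed)


def gen_tpv_dataset(
    glmm: BetaGlmmParams,
    n_participants: int,
    n_trials_per: int,
    seed: int = 0,
    p_dominant: float = 0.75,
) -> pd.DataFrame:
    """Draw a trial table straight from the beta mixed model.

    Used by the inference recovery studies: participant intercepts are normal
    with SD ``sigma_b``, conditions are drawn with ``p_dominant``, foreperiods
    are uniform on 0–2,000 ms, and TPV ~ Beta(mu·phi, (1-mu)·phi) on (0, 1).
    """
    if n_participants < 2:
        raise ValueError("need at least two participants")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n_participants):
        pid = f"p{i + 1:02d}"
        b = rng.normal(0.0, glmm.sigma_b) if glmm.sigma_b > 0 else 0.0
        cond = draw_conditions(n_trials_per, p_dominant, rng)
        srt = rng.uniform(0.0, 2000.0, n_trials_per)
        mu = glmm.mean(cond, srt, b)
        tpv = rng.beta(mu * glmm.phi, (1.0 - mu) * glmm.phi)
        rows.append(pd.DataFrame(dict(participant=pid, condition=cond,
                                      srt_ms=srt, tpv=tpv)))
    out = pd.concat(rows, ignore_index=True)
    out["tpv"] = out["tpv"].clip(1e-6, 1 - 1e-6)
    return out
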