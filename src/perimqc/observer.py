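"""Synthetic perimetric observer with a latent vigilance process.

The observer detects stimuli according to a frequency-of-seeing curve
(cumulative-normal psychometric function of dB attenuation), presses the
button with a luminance-dependent response time, and occasionally guesses on
stimuli it did not detect.  A latent two-state vigilance trace modulates all
of it: during low-vigilance episodes detection reliability drops, guessing
rises, responses slow down and response-time noise inflates.  Episodes are
the ground truth the quality-analysis pipeline is meant to recover from
catch-trial errors and response-time variability.

No generative model of perimetric fatigue is established in the literature;
this module is a deliberately simple stand-in whose parameters are free.
Defaults are calibrated only to pooled summary statistics (median response
time near 355 ms) and are not population estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .protocol import (
    FN_CATCH,
    FP_CATCH,
    ProtocolConfig,
    StimulusEvent,
    StimulusSchedule,
    build_schedule,
)

__all__ = [
    "VigilanceParams",
    "VigilanceTrace",
    "ObserverParams",
    "SessionRecord",
    "simulate_vigilance",
    "detection_probability",
    "sample_response",
    "simulate_session",
    "simulate_cohort",
    "graded_rate_sampler",
]


@dataclass(frozen=True)
class VigilanceParams:
    """Parameters of the two-state vigilance process.

    episode_rate
        Expected number of low-vigilance episodes per session (Poisson).
    episode_duration_mean_s
        Mean episode duration; durations are exponential.
    episode_depth
        Drop in vigilance during an episode: v = 1 - depth inside, 1 outside.
    rt_slowdown_ms
        Additive response-time shift during an episode.
    rtv_inflation
        Multiplier (>= 1) on response-time noise during an episode.
    fp_increment
        Episode-linked increment to the guessing rate on undetected stimuli,
        scaled by (1 - v); models careless button presses while drowsy.
    """

    episode_rate: float = 3.0
    episode_duration_mean_s: float = 60.0
    episode_depth: float = 0.5
    rt_slowdown_ms: float = 40.0
    rtv_inflation: float = 2.5
    fp_increment: float = 0.15

    def __post_init__(self) -> None:
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        if self.episode_duration_mean_s <= 0:
            raise ValueError("episode_duration_mean_s must be > 0")
        if not 0.0 <= self.episode_depth <= 1.0:
            raise ValueError("episode_depth must be in [0, 1]")
        if self.rtv_inflation < 1.0:
            raise ValueError("rtv_inflation must be >= 1")
        if not 0.0 <= self.fp_increment <= 1.0:
            raise ValueError("fp_increment must be in [0, 1]")


@dataclass
class VigilanceTrace:
    """Latent vigilance over a session on a 1-s grid.

    ``v`` is 1 outside episodes and ``1 - episode_depth`` inside; ``episodes``
    holds the merged (start_s, end_s) intervals.
    """

    t: np.ndarray
    v: np.ndarray
    episodes: list[tuple[float, float]]
    depth: float
    n_drawn: int = 0  # episode starts drawn before merging overlaps

    def value_at(self, times: np.ndarray) -> np.ndarray:
        """Exact step-function evaluation from the episode intervals."""
        times = np.asarray(times, float)
        inside = np.zeros(times.shape, bool)
        for start, end in self.episodes:
            inside |= (times >= start) & (times < end)
        return np.where(inside, 1.0 - self.depth, 1.0)


def simulate_vigilance(
    params: VigilanceParams, duration_s: float, seed: int
) -> VigilanceTrace:
    """Draw a vigilance trace: Poisson episode starts, exponential durations,
    overlapping episodes merged.  Deterministic given the seed."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(params.episode_rate)
    starts = np.sort(rng.uniform(0.0, duration_s, size=n))
    durations = rng.exponential(params.episode_duration_mean_s, size=n)
    raw = [
        (float(s), float(min(s + d, duration_s)))
        for s, d in zip(starts, durations)
    ]
    merged: list[tuple[float, float]] = []
    for start, end in raw:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    t = np.arange(0.0, np.ceil(duration_s) + 1.0)
    trace = VigilanceTrace(
        t=t, v=np.ones_like(t), episodes=merged, depth=params.episode_depth,
        n_drawn=int(n),
    )
    trace.v = trace.value_at(t)
    return trace


def detection_probability(
    attenuation_db: float | np.ndarray,
    threshold_db: float,
    slope_db: float,
    v: float | np.ndarray = 1.0,
) -> float | np.ndarray:
    """Frequency-of-seeing probability, scaled by vigilance.

    ``p = v * Phi((threshold - attenuation) / slope)`` with Phi the standard
    normal CDF: p = v/2 at threshold, -> v for bright stimuli, -> 0 for
    heavily attenuated ones.
    """
    if slope_db <= 0:
        raise ValueError("slope_db must be > 0")
    return np.asarray(v, float) * ndtr(
        (threshold_db - np.asarray(attenuation_db, float)) / slope_db
    )


@dataclass(frozen=True)
class ObserverParams:
    """Behavioural parameters of a simulated observer.

    The response-time model is linear in dB attenuation (responses to dim
    stimuli are slower), with Gaussian noise; both the mean shift and the
    noise inflation during low-vigilance episodes come from
    :class:`VigilanceParams`.
    """

    threshold_db: float = 30.0
    slope_db: float = 2.5
    base_fp_rate: float = 0.03
    rt_intercept_ms: float = 312.0
    rt_db_coeff_ms: float = 5.0
    rt_sd_ms: float = 50.0
    vigilance: VigilanceParams = field(default_factory=VigilanceParams)
    seed: int = 0
    truncate_fraction: float = 0.0  # early session stop; 0 = full session

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_fp_rate <= 1.0:
            raise ValueError("base_fp_rate must be in [0, 1]")
        if self.rt_intercept_ms <= 0:
            raise ValueError("rt_intercept_ms must be > 0")
        if self.rt_sd_ms < 0:
            raise ValueError("rt_sd_ms must be >= 0")
        if not 0.0 <= self.truncate_fraction < 1.0:
            raise ValueError("truncate_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionRecord:
    """One observer's responses to one schedule.

    ``rt_ms`` is NaN exactly where ``responded`` is False; responses are
    confined to the presentation cycle (0, cycle] after stimulus onset.
    """

    schedule: StimulusSchedule
    subject_id: str
    responded: np.ndarray
    rt_ms: np.ndarray
    params: ObserverParams
    seed: int
    trace: VigilanceTrace | None = None

    def __len__(self) -> int:
        return len(self.responded)

    @property
    def duration_s(self) -> float:
        return len(self) * self.schedule.config.cycle_s

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "index": np.arange(n, dtype=int),
                "onset_s": self.schedule.onset_s[:n],
                "kind": self.schedule.kind[:n],
                "db": self.schedule.attenuation_db[:n],
                "responded": self.responded.astype(int),
                "rt_ms": self.rt_ms,
                "subject_id": self.subject_id,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the session CSV plus a JSON sidecar holding the observer
        parameters, episode ground truth and seeds."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
        sidecar = {
            "subject_id": self.subject_id,
            "seed": int(self.seed),
            "schedule_seed": int(self.schedule.seed),
            "config": self.schedule.config.to_dict(),
            "observer_params": self.params.to_dict(),
            "episodes": self.trace.episodes if self.trace is not None else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def sample_response(
    event: StimulusEvent,
    params: ObserverParams,
    v: float,
    rng: np.random.Generator,
    cycle_ms: float,
) -> tuple[bool, float]:
    """Sample one (responded, rt_ms) pair for a single presentation.

    Detection is Bernoulli with the vigilance-scaled frequency-of-seeing
    probability; undetected presentations elicit a guess with probability
    ``base_fp_rate + fp_increment * (1 - v)``.  Response times are Gaussian
    around a linear-in-dB mean (slowed and noisier inside episodes) and
    truncated to the response window (0, cycle]: draws outside the window
    count as non-responses.
    """
    vig = params.vigilance
    in_episode = v < 1.0
    p_det = float(
        detection_probability(event.attenuation_db, params.threshold_db, params.slope_db, v)
    )
    detected = rng.random() < p_det
    if not detected:
        p_guess = min(1.0, params.base_fp_rate + vig.fp_increment * (1.0 - v))
        responded = rng.random() < p_guess
    else:
        responded = True
    # draw RT unconditionally to keep the stream length fixed per event
    mu = params.rt_intercept_ms + params.rt_db_coeff_ms * event.attenuation_db
    sd = params.rt_sd_ms
    if in_episode:
        mu += vig.rt_slowdown_ms
        sd *= vig.rtv_inflation
    rt = mu + sd * rng.standard_normal()
    if responded and 0.0 < rt <= cycle_ms:
        return True, float(rt)
    return False, float("nan")


def simulate_session(
    schedule: StimulusSchedule,
    params: ObserverParams,
    subject_id: str = "S000",
) -> SessionRecord:
    """Simulate a full session; deterministic given (schedule, params.seed)."""
    vig_seed, resp_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(params.seed).spawn(2)
    )
    trace = simulate_vigilance(params.vigilance, schedule.duration_s, vig_seed)
    rng = np.random.default_rng(resp_seed)

    n = len(schedule)
    if params.truncate_fraction > 0.0:
        n = max(1, int(round(n * (1.0 - params.truncate_fraction))))
    onsets = schedule.onset_s[:n]
    db = schedule.attenuation_db[:n]
    v = trace.value_at(onsets)
    in_episode = v < 1.0
    cycle_ms = schedule.config.cycle_s * 1000.0

    p_det = detection_probability(db, params.threshold_db, params.slope_db, v)
    detected = rng.random(n) < p_det
    p_guess = np.minimum(
        1.0, params.base_fp_rate + params.vigilance.fp_increment * (1.0 - v)
    )
    guessed = ~detected & (rng.random(n) < p_guess)
    responded = detected | guessed

    mu = (
        params.rt_intercept_ms
        + params.rt_db_coeff_ms * db
        + params.vigilance.rt_slowdown_ms * in_episode
    )
    sd = params.rt_sd_ms * np.where(in_episode, params.vigilance.rtv_inflation, 1.0)
    rt = mu + sd * rng.standard_normal(n)
    in_window = (rt > 0.0) & (rt <= cycle_ms)
    responded &= in_window
    rt = np.where(responded, rt, np.nan)

    if params.truncate_fraction > 0.0:
        truncated_schedule = StimulusSchedule(
            config=schedule.config,
            seed=schedule.seed,
            onset_s=schedule.onset_s[:n],
            x_deg=schedule.x_deg[:n],
            y_deg=schedule.y_deg[:n],
            kind=schedule.kind[:n],
            attenuation_db=schedule.attenuation_db[:n],
            luminance_cdm2=schedule.luminance_cdm2[:n],
        )
    else:
        truncated_schedule = schedule

    return SessionRecord(
        schedule=truncated_schedule,
        subject_id=subject_id,
        responded=responded,
        rt_ms=rt,
        params=params,
        seed=params.seed,
        trace=trace,
    )


def graded_rate_sampler(
    max_episode_rate: float = 8.0,
    base: ObserverParams | None = None,
) -> Callable[[int, int, int], ObserverParams]:
    """Parameter sampler assigning episode rates graded linearly from 0 to
    ``max_episode_rate`` across a cohort — from fully vigilant observers to
    ones with frequent lapses."""
    base = base or ObserverParams()

    def sampler(i: int, n_subjects: int, seed: int) -> ObserverParams:
        frac = i / (n_subjects - 1) if n_subjects > 1 else 0.0
        vig = replace(base.vigilance, episode_rate=frac * max_episode_rate)
        return replace(base, vigilance=vig, seed=seed)

    return sampler


def simulate_cohort(
    n_subjects: int,
    protocol: ProtocolConfig,
    params_sampler: Callable[[int, int, int], ObserverParams] | None = None,
    seed: int = 0,
) -> list[SessionRecord]:
    """Simulate independent seeded sessions for a cohort.

    ``params_sampler(i, n_subjects, subject_seed)`` returns each observer's
    parameters; defaults to :func:`graded_rate_sampler`.  Reproducible given
    the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sampler = params_sampler or graded_rate_sampler()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children):
        sched_seed, obs_seed = (int(x % (2**31)) for x in child.generate_state(2))
        schedule = build_schedule(protocol, sched_seed)
        params = sampler(i, n_subjects, obs_seed)
        sessions.append(
            simulate_session(schedule, params, subject_id=f"S{i + 1:03d}")
        )
    return sessions
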