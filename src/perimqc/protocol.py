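"""Perimetric test protocol: decibel attenuation scale and stimulus schedules.

The protocol follows a Method-of-Constant-Stimuli (MoCS) design: a fixed set
of stimulus luminances, each presented a fixed number of times at each test
location, in seeded pseudorandom order with a constant presentation cycle
(stimulus duration + interstimulus interval).  Catch trials of two kinds are
interleaved at configurable rates to monitor response quality:

* ``fp_catch`` — a maximal-luminance (0 dB) stimulus that a normal observer
  should always see; failing to respond is an error.
* ``fn_catch`` — a heavily attenuated (40 dB) stimulus that cannot be seen;
  responding to it is an error.

Perimeters express stimulus intensity as attenuation in decibels relative to
the maximal luminance the device can produce (the anchor): ``dB =
10 * log10(anchor / luminance)``, so 0 dB is the brightest stimulus and each
10 dB is a tenfold dimming.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolConfig",
    "StimulusEvent",
    "StimulusSchedule",
    "ScheduleSummary",
    "luminance_to_db",
    "db_to_luminance",
    "build_schedule",
    "expected_catch_interval",
    "schedule_summary",
]

Location = tuple[float, float]

REGULAR = "regular"
FP_CATCH = "fp_catch"
FN_CATCH = "fn_catch"
KINDS = (REGULAR, FP_CATCH, FN_CATCH)

#: default anchor luminance (cd/m^2) corresponding to 0 dB
DEFAULT_ANCHOR = 320.0


def luminance_to_db(luminance: float, anchor: float = DEFAULT_ANCHOR) -> float:
    """Convert a stimulus luminance (cd/m^2) to dB attenuation.

    ``dB = 10 * log10(anchor / luminance)``; the anchor is the luminance of
    the maximal (0 dB) stimulus.

    Raises
    ------
    ValueError
        If either luminance or anchor is not strictly positive.
    """
    if luminance <= 0:
        raise ValueError(f"luminance must be > 0, got {luminance}")
    if anchor <= 0:
        raise ValueError(f"anchor must be > 0, got {anchor}")
    return 10.0 * math.log10(anchor / luminance)


def db_to_luminance(attenuation_db: float, anchor: float = DEFAULT_ANCHOR) -> float:
    """Convert dB attenuation back to luminance in cd/m^2 (inverse of
    :func:`luminance_to_db`)."""
    if anchor <= 0:
        raise ValueError(f"anchor must be > 0, got {anchor}")
    return anchor * 10.0 ** (-attenuation_db / 10.0)


def _default_levels() -> tuple[float, ...]:
    # 13 equal 3-dB steps spanning 3..39 dB (160 down to 0.04 cd/m^2)
    return tuple(float(3 * k) for k in range(1, 14))


@dataclass(frozen=True)
class ProtocolConfig:
    """Full MoCS protocol specification.

    Defaults reproduce a research protocol with 13 luminance levels on a
    10 cd/m^2 background, Goldmann size III stimuli at three peripheral
    locations plus a central reference, 200 ms presentations with a 1500 ms
    interstimulus interval and 25% + 25% catch-trial enrichment.
    """

    db_anchor_luminance: float = DEFAULT_ANCHOR
    background_luminance: float = 10.0
    stimulus_levels_db: tuple[float, ...] = field(default_factory=_default_levels)
    peripheral_locations: tuple[Location, ...] = (
        (-6.1, -3.5),
        (0.0, 7.0),
        (6.1, -3.5),
    )
    reference_location: Location = (0.0, 0.0)
    reps_peripheral: int = 20
    reps_reference: int = 2
    stimulus_duration_ms: float = 200.0
    interstimulus_interval_ms: float = 1500.0
    fp_catch_rate: float = 0.25
    fn_catch_rate: float = 0.25
    fp_catch_db: float = 0.0
    fn_catch_db: float = 40.0
    stimulus_size_arcmin: float = 25.7

    def __post_init__(self) -> None:
        if self.db_anchor_luminance <= 0 or self.background_luminance <= 0:
            raise ValueError("luminances must be > 0")
        levels = tuple(float(v) for v in self.stimulus_levels_db)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("stimulus_levels_db must be strictly increasing")
        object.__setattr__(self, "stimulus_levels_db", levels)
        object.__setattr__(
            self,
            "peripheral_locations",
            tuple((float(x), float(y)) for x, y in self.peripheral_locations),
        )
        if self.reps_peripheral < 0 or self.reps_reference < 0:
            raise ValueError("repetition counts must be >= 0")
        if self.stimulus_duration_ms <= 0 or self.interstimulus_interval_ms <= 0:
            raise ValueError("durations must be > 0")
        if not (0.0 <= self.fp_catch_rate and 0.0 <= self.fn_catch_rate):
            raise ValueError("catch rates must be >= 0")
        if self.fp_catch_rate + self.fn_catch_rate >= 1.0:
            raise ValueError("combined catch rate must be < 1")

    @property
    def cycle_s(self) -> float:
        """Presentation cycle length (stimulus + ISI) in seconds."""
        return (self.stimulus_duration_ms + self.interstimulus_interval_ms) / 1000.0

    @property
    def n_regular(self) -> int:
        """Regular presentations: levels x (peripheral reps + reference reps)."""
        per_level = (
            len(self.peripheral_locations) * self.reps_peripheral + self.reps_reference
        )
        return len(self.stimulus_levels_db) * per_level

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "peripheral_locations" in d:
            d["peripheral_locations"] = tuple(
                tuple(loc) for loc in d["peripheral_locations"]
            )
        if "reference_location" in d:
            d["reference_location"] = tuple(d["reference_location"])
        if "stimulus_levels_db" in d:
            d["stimulus_levels_db"] = tuple(d["stimulus_levels_db"])
        return cls(**d)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation in a schedule."""

    index: int
    onset_s: float
    location: Location
    kind: str
    attenuation_db: float
    luminance_cdm2: float


@dataclass
class StimulusSchedule:
    """An ordered, seeded sequence of stimulus presentations.

    Column-oriented storage (numpy arrays, one entry per event) keeps large
    schedules cheap; :meth:`events` offers a record view.
    """

    config: ProtocolConfig
    seed: int
    onset_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    kind: np.ndarray  # str array over KINDS
    attenuation_db: np.ndarray
    luminance_cdm2: np.ndarray

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def duration_s(self) -> float:
        """Total session duration: n_events x cycle length."""
        return len(self) * self.config.cycle_s

    def events(self) -> list[StimulusEvent]:
        return [
            StimulusEvent(
                index=i,
                onset_s=float(self.onset_s[i]),
                location=(float(self.x_deg[i]), float(self.y_deg[i])),
                kind=str(self.kind[i]),
                attenuation_db=float(self.attenuation_db[i]),
                luminance_cdm2=float(self.luminance_cdm2[i]),
            )
            for i in range(len(self))
        ]

    def to_frame(self) -> pd.DataFrame:
        # integer-dB display column matches how protocols are printed
        return pd.DataFrame(
            {
                "index": np.arange(len(self), dtype=int),
                "onset_s": self.onset_s,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "kind": self.kind,
                "db": self.attenuation_db,
                "luminance_cdm2": self.luminance_cdm2,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the schedule CSV plus a JSON sidecar (config + seed)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"config": self.config.to_dict(), "seed": int(self.seed)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusSchedule":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = ProtocolConfig.from_dict(sidecar["config"])
        return cls(
            config=config,
            seed=int(sidecar["seed"]),
            onset_s=df["onset_s"].to_numpy(float),
            x_deg=df["x_deg"].to_numpy(float),
            y_deg=df["y_deg"].to_numpy(float),
            kind=df["kind"].to_numpy(str),
            attenuation_db=df["db"].to_numpy(float),
            luminance_cdm2=df["luminance_cdm2"].to_numpy(float),
        )


def _catch_counts(config: ProtocolConfig) -> tuple[int, int, int]:
    """Total event count and per-kind catch counts for a config.

    The total N is chosen as ceil(regular / (1 - fp - fn)) so that each catch
    kind makes up its configured fraction of all presentations; rounding
    residue is absorbed by the fn-catch count.
    """
    n_regular = config.n_regular
    f = config.fp_catch_rate + config.fn_catch_rate
    if f == 0.0:
        return n_regular, 0, 0
    n_total = math.ceil(n_regular / (1.0 - f))
    n_fp = int(round(config.fp_catch_rate * n_total))
    n_fn = int(round(config.fn_catch_rate * n_total))
    n_fn += n_total - n_regular - n_fp - n_fn
    if n_fn < 0:  # pathological rounding with tiny fn rate
        n_fp += n_fn
        n_fn = 0
    return n_regular + n_fp + n_fn, n_fp, n_fn


def build_schedule(config: ProtocolConfig, seed: int) -> StimulusSchedule:
    """Build a randomized stimulus schedule with enriched catch trials.

    Regular presentations enumerate every (level x location x repetition)
    combination exactly once; catch trials are added so each kind is its
    configured fraction of the total; the whole sequence is permuted with a
    seeded generator and onsets follow the fixed presentation cycle.
    """
    locations = list(config.peripheral_locations) + [config.reference_location]
    reps = [config.reps_peripheral] * len(config.peripheral_locations) + [
        config.reps_reference
    ]

    xs: list[float] = []
    ys: list[float] = []
    dbs: list[float] = []
    kinds: list[str] = []
    for level in config.stimulus_levels_db:
        for (x, y), r in zip(locations, reps):
            xs.extend([x] * r)
            ys.extend([y] * r)
            dbs.extend([level] * r)
            kinds.extend([REGULAR] * r)

    n_total, n_fp, n_fn = _catch_counts(config)
    # catch trials are shown at the reference location
    rx, ry = config.reference_location
    xs.extend([rx] * (n_fp + n_fn))
    ys.extend([ry] * (n_fp + n_fn))
    dbs.extend([config.fp_catch_db] * n_fp + [config.fn_catch_db] * n_fn)
    kinds.extend([FP_CATCH] * n_fp + [FN_CATCH] * n_fn)

    order = np.random.default_rng(seed).permutation(n_total)
    xs_a = np.asarray(xs, float)[order]
    ys_a = np.asarray(ys, float)[order]
    dbs_a = np.asarray(dbs, float)[order]
    kinds_a = np.asarray(kinds, dtype=object)[order].astype(str)

    onsets = np.arange(n_total, dtype=float) * config.cycle_s
    lum = config.db_anchor_luminance * 10.0 ** (-dbs_a / 10.0)
    return StimulusSchedule(
        config=config,
        seed=int(seed),
        onset_s=onsets,
        x_deg=xs_a,
        y_deg=ys_a,
        kind=kinds_a,
        attenuation_db=dbs_a,
        luminance_cdm2=lum,
    )


def expected_catch_interval(config: ProtocolConfig) -> float:
    """Expected time between catch trials in seconds.

    With catch trials a fraction ``f = fp + fn`` of all presentations and a
    fixed cycle, one catch trial appears every ``cycle / f`` seconds on
    average: ~21 s at 4%+4%, ~3 s at 25%+25% with a 1.7 s cycle.
    """
    f = config.fp_catch_rate + config.fn_catch_rate
    if f <= 0:
        raise ValueError("combined catch rate must be > 0")
    return config.cycle_s / f


@dataclass
class ScheduleSummary:
    n_events: int
    n_by_kind: dict[str, int]
    n_by_level_db: dict[float, int]
    n_by_location: dict[Location, int]
    duration_s: float


def schedule_summary(schedule: StimulusSchedule) -> ScheduleSummary:
    """Per-kind / per-level / per-location counts and the total duration."""
    kinds = schedule.kind
    n_by_kind = {k: int(np.sum(kinds == k)) for k in KINDS}
    regular = kinds == REGULAR
    n_by_level: dict[float, int] = {}
    for level in schedule.config.stimulus_levels_db:
        n_by_level[level] = int(np.sum(regular & (schedule.attenuation_db == level)))
    n_by_location: dict[Location, int] = {}
    locs = list(schedule.config.peripheral_locations) + [
        schedule.config.reference_location
    ]
    for x, y in locs:
        n_by_location[(x, y)] = int(
            np.sum(regular & (schedule.x_deg == x) & (schedule.y_deg == y))
        )
    return ScheduleSummary(
        n_events=len(schedule),
        n_by_kind=n_by_kind,
        n_by_level_db=n_by_level,
        n_by_location=n_by_location,
        duration_s=schedule.duration_s,
    )
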