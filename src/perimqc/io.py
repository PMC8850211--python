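"""Reading and writing session records, series tables and reports.

Conventions: UTF-8 comma-separated CSV with a mandatory header and "."
decimals; times in seconds from session start, response times in ms.
Session CSVs carry a JSON sidecar (same stem, ``.json``) with the protocol
config, observer parameters, ground-truth episodes and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import ObserverParams, SessionRecord, VigilanceParams, VigilanceTrace
from .protocol import KINDS, ProtocolConfig, StimulusSchedule

__all__ = ["SessionValidationError", "read_session", "read_sessions", "write_series", "RunConfig"]

SESSION_COLUMNS = ["index", "onset_s", "kind", "db", "responded", "rt_ms", "subject_id"]


class SessionValidationError(ValueError):
    """A session file violates the documented schema; carries row context."""


def _observer_params_from_dict(d: dict) -> ObserverParams:
    d = dict(d)
    if isinstance(d.get("vigilance"), dict):
        d["vigilance"] = VigilanceParams(**d["vigilance"])
    return ObserverParams(**d)


def read_session(path: str | Path) -> SessionRecord:
    """Read one session CSV (+ JSON sidecar) into a validated record."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SessionValidationError(f"{path}: missing columns {missing}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SessionValidationError(f"{path}: sidecar {sidecar_path.name} not found")
    sidecar = json.loads(sidecar_path.read_text())
    config = ProtocolConfig.from_dict(sidecar["config"])

    responded = df["responded"].to_numpy(bool)
    rt = df["rt_ms"].to_numpy(float)
    for i, (resp, r) in enumerate(zip(responded, rt)):
        if resp and (np.isnan(r) or r <= 0):
            raise SessionValidationError(
                f"{path}: row {i}: responded=1 requires a positive rt_ms"
            )
        if not resp and not np.isnan(r):
            raise SessionValidationError(
                f"{path}: row {i}: rt_ms present on a non-response row"
            )
    kinds = df["kind"].to_numpy(str)
    bad = [i for i, k in enumerate(kinds) if k not in KINDS]
    if bad:
        raise SessionValidationError(f"{path}: row {bad[0]}: unknown kind {kinds[bad[0]]!r}")

    db = df["db"].to_numpy(float)
    schedule = StimulusSchedule(
        config=config,
        seed=int(sidecar.get("schedule_seed", sidecar.get("seed", 0))),
        onset_s=df["onset_s"].to_numpy(float),
        x_deg=np.zeros(len(df)),
        y_deg=np.zeros(len(df)),
        kind=kinds,
        attenuation_db=db,
        luminance_cdm2=config.db_anchor_luminance * 10.0 ** (-db / 10.0),
    )
    params = _observer_params_from_dict(sidecar["observer_params"]) if sidecar.get(
        "observer_params"
    ) else ObserverParams()
    episodes = sidecar.get("episodes")
    trace = None
    if episodes is not None:
        t = np.arange(0.0, np.ceil(schedule.duration_s) + 1.0)
        trace = VigilanceTrace(
            t=t, v=np.ones_like(t), episodes=[tuple(e) for e in episodes],
            depth=params.vigilance.episode_depth,
        )
        trace.v = trace.value_at(t)
    return SessionRecord(
        schedule=schedule,
        subject_id=str(df["subject_id"].iloc[0]),
        responded=responded,
        rt_ms=rt,
        params=params,
        seed=int(sidecar.get("seed", 0)),
        trace=trace,
    )


def read_sessions(path: str | Path) -> list[SessionRecord]:
    """Read a session file or a directory of session CSVs (sorted by name)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.glob("*.csv"))
        if not files:
            raise SessionValidationError(f"{path}: no session CSV files found")
        return [read_session(p) for p in files]
    return [read_session(path)]


def write_series(path: str | Path, subjects) -> None:
    """Write tidy per-subject series: subject_id,t_s,variable,value,flag."""
    rows = []
    for s in subjects:
        for var, values, flags in (
            ("rt", s.rt.values, s.rt.observed.astype(int)),
            ("rtv", s.rtv.values, np.zeros(len(s.rtv.values), int)),
            ("error_rate", s.error_rate.values, np.zeros(len(s.error_rate.values), int)),
            ("mask_error", s.error_mask.mask.astype(float), np.zeros(len(s.error_mask.mask), int)),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "t_s": s.rt.t,
                        "variable": var,
                        "value": values,
                        "flag": flags,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False, float_format="%.6f")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (mirrors the YAML config file)."""

    out_dir: str = "perimqc_out"
    seed: int = 0
    n_subjects: int = 48
    max_episode_rate: float = 8.0
    input_sessions: str | None = None  # analyze pre-existing data instead of simulating
    window_s: float = 60.0
    error_threshold_per_min: float = 2.0
    cutoff_mode: str = "youden"
    fixed_cutoff: float | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "protocol" in data and isinstance(data["protocol"], dict):
            data["protocol"] = ProtocolConfig.from_dict(data["protocol"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["protocol"] = self.protocol.to_dict()
        return d
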