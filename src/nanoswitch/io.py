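"""Plain-text file formats and configuration for the pipeline.

All tables are comma-delimited with a ``#``-prefixed provenance header
(seed, config hash, package version); configs are YAML whose keys match the
dataclass field names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._types import Trajectory
from .calibration import CalibrationCurve
from .errors import InputError
from .kinetics import Injection, KineticParams, RawExperiment, SampleSchedule
from .readout import ReadoutConfig

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um"]
ACTIVITY_COLUMNS = ["t_min", "injection_index", "role", "true_conc_pM",
                    "counts", "n_particles"]


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(seed, cfg_hash) -> list[str]:
    return [
        f"# nanoswitch v{__version__}",
        f"# seed: {seed}",
        f"# config_hash: {cfg_hash}",
    ]


def _write_table(df: pd.DataFrame, path, seed=None, cfg_hash="") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty or unparsable table: {path}") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed table {path}: {exc}") from exc
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise InputError(f"{path} is missing columns {sorted(missing)}")
    return df


def write_trajectories(trajectories, path, seed=None, cfg_hash="") -> None:
    frames = [
        pd.DataFrame({
            "particle_id": np.full(len(t), t.particle_id),
            "frame": t.frame, "t_s": t.t_s, "x_um": t.x_um, "y_um": t.y_um,
        })
        for t in trajectories
    ]
    _write_table(pd.concat(frames, ignore_index=True), path, seed, cfg_hash)


def read_trajectories(path) -> list[Trajectory]:
    df = _read_table(path, TRAJECTORY_COLUMNS)
    out = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(Trajectory(int(pid), grp["frame"].to_numpy(),
                              grp["t_s"].to_numpy(), grp["x_um"].to_numpy(),
                              grp["y_um"].to_numpy()))
    if not out:
        raise InputError(f"no trajectories in {path}")
    return out


def write_activity_table(records: pd.DataFrame, path, seed=None,
                         cfg_hash="") -> None:
    df = records.copy()
    if "activity" not in df.columns:
        df["activity"] = df["counts"] / df["n_particles"]
    _write_table(df, path, seed, cfg_hash)


def read_activity_table(path) -> pd.DataFrame:
    df = _read_table(path, ACTIVITY_COLUMNS)
    if "activity" not in df.columns:
        df["activity"] = df["counts"] / df["n_particles"]
    return df


def write_interval_edges(edges_s, path, seed=None, cfg_hash="") -> None:
    _write_table(pd.DataFrame({"edge_s": np.asarray(edges_s, float)}),
                 path, seed, cfg_hash)


def read_interval_edges(path) -> np.ndarray:
    return _read_table(path, ["edge_s"])["edge_s"].to_numpy()


# ---------------------------------------------------------------------------
# YAML configs

def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such config file: {path}")
    with path.open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"config root must be a mapping: {path}")
    return data


def kinetic_params_from_dict(d: dict) -> KineticParams:
    valid = {f.name for f in fields(KineticParams)}
    unknown = set(d) - valid
    if unknown:
        raise InputError(f"unknown KineticParams keys: {sorted(unknown)}")
    return KineticParams(**d)


def schedule_from_dict(d: dict) -> SampleSchedule:
    try:
        injections = tuple(Injection(**inj) for inj in d["injections"])
    except KeyError as exc:
        raise InputError(f"schedule config missing key: {exc}") from exc
    except TypeError as exc:
        raise InputError(f"bad injection entry: {exc}") from exc
    return SampleSchedule(injections, drift_rate=float(d.get("drift_rate", 0.0)))


def schedule_to_dict(schedule: SampleSchedule) -> dict:
    return {
        "drift_rate": schedule.drift_rate,
        "injections": [asdict(inj) for inj in schedule.injections],
    }


def curve_from_dict(d: dict) -> CalibrationCurve:
    try:
        return CalibrationCurve(S_min=float(d["S_min"]), S_max=float(d["S_max"]),
                                EC50_pM=float(d["EC50_pM"]), n=float(d["n"]))
    except KeyError as exc:
        raise InputError(f"curve config missing key: {exc}") from exc


def curve_to_dict(curve: CalibrationCurve) -> dict:
    return {"S_min": curve.S_min, "S_max": curve.S_max,
            "EC50_pM": curve.EC50_pM, "n": curve.n}


@dataclass
class RunConfig:
    """Resolved run configuration: CLI overrides > config file > defaults."""

    seed: int = 0
    params: KineticParams = field(default_factory=KineticParams)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    schedule_name: str | None = None
    schedule: SampleSchedule | None = None
    strategy: int = 3
    fixed_curve: CalibrationCurve | None = None
    n_particles: int = 4000
    mode: str = "counts"
    log_level: str = "INFO"

    @classmethod
    def load(cls, config_path=None, **overrides) -> "RunConfig":
        data = load_yaml(config_path) if config_path else {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        kwargs: dict = {}
        if "params" in data:
            p = data.pop("params")
            kwargs["params"] = (p if isinstance(p, KineticParams)
                                else kinetic_params_from_dict(p))
        if "readout" in data:
            r = data.pop("readout")
            kwargs["readout"] = r if isinstance(r, ReadoutConfig) else ReadoutConfig(**r)
        if "schedule" in data:
            s = data.pop("schedule")
            kwargs["schedule"] = (s if isinstance(s, SampleSchedule)
                                  else schedule_from_dict(s))
        if "fixed_curve" in data:
            c = data.pop("fixed_curve")
            kwargs["fixed_curve"] = (c if isinstance(c, CalibrationCurve)
                                     else curve_from_dict(c))
        for key in ("seed", "schedule_name", "strategy", "n_particles", "mode",
                    "log_level"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise InputError(f"unknown config keys: {sorted(data)}")
        cfg = cls(**kwargs)
        if cfg.strategy not in (1, 2, 3):
            raise InputError("strategy must be 1, 2 or 3")
        if not isinstance(cfg.seed, (int, np.integer)):
            raise InputError("seed must be an integer")
        return cfg

    def hash(self) -> str:
        return config_hash({
            "seed": self.seed,
            "params": asdict(self.params),
            "readout": asdict(self.readout),
            "schedule_name": self.schedule_name,
            "schedule": schedule_to_dict(self.schedule) if self.schedule else None,
            "strategy": self.strategy,
            "fixed_curve": curve_to_dict(self.fixed_curve) if self.fixed_curve else None,
            "n_particles": self.n_particles,
            "mode": self.mode,
        })


def write_experiment(exp: RawExperiment, out_dir, seed=None, cfg_hash="") -> dict:
    """Write all artifacts of a RawExperiment; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"activity": out_dir / "activity.csv"}
    write_activity_table(exp.records, paths["activity"], seed, cfg_hash)
    if exp.trajectories is not None:
        paths["trajectories"] = out_dir / "trajectories.csv"
        write_trajectories(exp.trajectories, paths["trajectories"], seed, cfg_hash)
    if exp.interval_edges_s is not None:
        paths["intervals"] = out_dir / "intervals.csv"
        write_interval_edges(exp.interval_edges_s, paths["intervals"], seed, cfg_hash)
    if exp.gt_states is not None:
        gt = pd.DataFrame([
            {"particle_id": seq.particle_id, "event_t_s": t}
            for seq in exp.gt_states for t in seq.utb_times()
        ], columns=["particle_id", "event_t_s"])
        paths["ground_truth_events"] = out_dir / "ground_truth_events.csv"
        _write_table(gt, paths["ground_truth_events"], seed, cfg_hash)
    return paths
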