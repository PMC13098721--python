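"""Configuration parsing, validation, presets, and burst-table I/O.

Configs are YAML mappings validated against the packaged defaults:
unknown keys are rejected and every error message names the offending
field. A fully materialized config round-trips losslessly through
``to_dict`` / ``config_from_dict`` and hashes stably for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass
import numpy as np
import pandas as pd
import yaml

from .dipole_dynamics import PAPER_ROT_UNIT_TO_RAD2_PER_NS, RotationalSpec
from .fret_core import PhysicalParams
from .linker_models import PendulumSpec, SpringModelSpec
from .photon_engine import BURST_COLUMNS, BurstConfig, ExperimentModel

__all__ = [
    "ExperimentConfig",
    "load_config",
    "config_from_dict",
    "available_presets",
    "preset_config",
    "linker_defaults",
    "write_burst_table",
    "read_burst_table",
    "write_shift_results",
]

__version__ = "0.1.0"


def _load_presets_file() -> dict:
    text = importlib.resources.files("smfretsim").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


_PRESETS_FILE = _load_presets_file()


def linker_defaults() -> dict:
    """Versioned linker-chemistry constants (bond length, angle, k_bond)."""
    return copy.deepcopy(_PRESETS_FILE["linker_defaults"])


def available_presets() -> list[str]:
    return sorted(_PRESETS_FILE["presets"])


def _deep_merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ValueError(f"unknown config key '{path}'")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key '{path}' must be a mapping")
            out[key] = _deep_merge(base[key], val, prefix=f"{path}.")
        else:
            out[key] = val
    return out


def _require_positive(d: dict, section: str, fields) -> None:
    for f in fields:
        v = d[f]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v <= 0:
            raise ValueError(f"{section}.{f} must be a positive number, got {v!r}")


def _require_nonneg(d: dict, section: str, fields) -> None:
    for f in fields:
        v = d[f]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
            raise ValueError(f"{section}.{f} must be a nonnegative number, got {v!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated, fully materialized experiment configuration."""

    raw: dict

    @property
    def model_kind(self) -> str:
        return self.raw["model"]

    @property
    def kappa2_mode(self) -> str:
        return self.raw["kappa2_mode"]

    @property
    def n_bursts(self) -> int:
        return int(self.raw["n_bursts"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def physical_params(self) -> PhysicalParams:
        p = self.raw["physical"]
        return PhysicalParams(k_D=p["k_D"], k_A=p["k_A"], R0_iso=p["R0_iso"])

    def burst_config(self) -> BurstConfig:
        b = self.raw["burst"]
        return BurstConfig(
            n_excitations=int(b["n_excitations"]),
            eff_donor=b["eff_donor"],
            eff_acceptor=b["eff_acceptor"],
            min_photons=int(b["min_photons"]),
            dt_factor=b["dt_factor"],
            horizon_factor=b["horizon_factor"],
            rep_period=b["rep_period"],
            dead_dt_stride=int(b["dead_dt_stride"]),
        )

    def rotational_specs(self) -> tuple[RotationalSpec, RotationalSpec]:
        r = self.raw["rotation"]
        scale = 1.0
        if r["units"] == "paper":
            scale = PAPER_ROT_UNIT_TO_RAD2_PER_NS
        elif r["units"] != "rad2_per_ns":
            raise ValueError(
                f"rotation.units must be 'rad2_per_ns' or 'paper', got {r['units']!r}"
            )
        return (
            RotationalSpec(D_rot=r["D_rot_donor"] * scale),
            RotationalSpec(D_rot=r["D_rot_acceptor"] * scale),
        )

    def experiment_model(self) -> ExperimentModel:
        raw = self.raw
        sep = raw["geometry"]["attach_separation"]
        attach_D = np.zeros(3)
        attach_A = np.array([0.0, 0.0, float(sep)])
        rot_D, rot_A = self.rotational_specs()
        kind = raw["model"]
        if kind in ("iso_spring", "aniso_spring"):
            s = raw["spring"]
            if kind == "iso_spring":
                spring = SpringModelSpec.isotropic(k=s["k"], sigma=s["sigma"])
            else:
                spring = SpringModelSpec.anisotropic(
                    k=s["k"], p=s["anisotropy_p"], sigma=s["sigma"],
                    stiff_axis=int(s["stiff_axis"]),
                )
            return ExperimentModel(
                kind=kind,
                attach_D=attach_D,
                attach_A=attach_A,
                spring_D=spring,
                spring_A=spring,
                rot_D=rot_D,
                rot_A=rot_A,
            )
        p = raw["pendulum"]
        pend = PendulumSpec(
            k_r=p["k_r"],
            r_eq=p["r_eq"],
            sigma_r=p["sigma_r"],
            k_theta=p["k_theta"],
            sigma_theta=p["sigma_theta"],
            sigma_phi=p["sigma_phi"],
        )
        return ExperimentModel(
            kind="pendulum",
            attach_D=attach_D,
            attach_A=attach_A,
            pend_D=pend,
            pend_A=pend,
            rot_D=rot_D,
            rot_A=rot_A,
            burn_in_time=raw["geometry"]["burn_in_time"],
        )

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _validate(cfg: dict) -> None:
    if cfg["model"] not in ("iso_spring", "aniso_spring", "pendulum"):
        raise ValueError(
            f"model must be one of iso_spring|aniso_spring|pendulum, got {cfg['model']!r}"
        )
    if cfg["kappa2_mode"] not in ("static", "dynamic"):
        raise ValueError(f"kappa2_mode must be static|dynamic, got {cfg['kappa2_mode']!r}")
    if not isinstance(cfg["n_bursts"], int) or cfg["n_bursts"] < 1:
        raise ValueError(f"n_bursts must be a positive integer, got {cfg['n_bursts']!r}")
    if not isinstance(cfg["seed"], int):
        raise ValueError(f"seed must be an integer, got {cfg['seed']!r}")
    _require_positive(cfg["physical"], "physical", ["k_D", "k_A", "R0_iso"])
    _require_positive(cfg["spring"], "spring", ["k"])
    _require_nonneg(cfg["spring"], "spring", ["sigma"])
    p = cfg["spring"]["anisotropy_p"]
    if not (0 <= p <= 1):
        raise ValueError(f"spring.anisotropy_p must lie in [0, 1], got {p!r}")
    if cfg["spring"]["stiff_axis"] not in (0, 1, 2):
        raise ValueError("spring.stiff_axis must be 0, 1 or 2")
    _require_positive(cfg["pendulum"], "pendulum", ["k_r", "r_eq"])
    _require_nonneg(cfg["pendulum"], "pendulum", ["k_theta", "sigma_r", "sigma_theta", "sigma_phi"])
    _require_positive(cfg["geometry"], "geometry", ["attach_separation"])
    _require_nonneg(cfg["geometry"], "geometry", ["burn_in_time"])
    _require_nonneg(cfg["rotation"], "rotation", ["D_rot_donor", "D_rot_acceptor"])
    if cfg["rotation"]["units"] not in ("rad2_per_ns", "paper"):
        raise ValueError(
            f"rotation.units must be 'rad2_per_ns' or 'paper', got {cfg['rotation']['units']!r}"
        )
    b = cfg["burst"]
    if not isinstance(b["n_excitations"], int) or b["n_excitations"] < 1:
        raise ValueError("burst.n_excitations must be a positive integer")
    for f in ("eff_donor", "eff_acceptor"):
        if not (0.0 <= b[f] <= 1.0):
            raise ValueError(f"burst.{f} must lie in [0, 1], got {b[f]!r}")
    if not isinstance(b["min_photons"], int) or b["min_photons"] < 0:
        raise ValueError("burst.min_photons must be a nonnegative integer")
    _require_positive(b, "burst", ["dt_factor", "horizon_factor"])
    _require_nonneg(b, "burst", ["rep_period"])
    if not isinstance(b["dead_dt_stride"], int) or b["dead_dt_stride"] < 1:
        raise ValueError("burst.dead_dt_stride must be a positive integer")


def config_from_dict(d: dict | None) -> ExperimentConfig:
    """Merge a (possibly partial) mapping over the defaults and validate."""
    base = copy.deepcopy(_PRESETS_FILE["defaults"])
    merged = _deep_merge(base, d or {})
    _validate(merged)
    return ExperimentConfig(raw=merged)


def preset_config(name: str, overrides: dict | None = None) -> ExperimentConfig:
    """Named preset merged over defaults, with optional extra overrides."""
    presets = _PRESETS_FILE["presets"]
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {available_presets()}")
    d = copy.deepcopy(presets[name])
    if overrides:
        base = copy.deepcopy(_PRESETS_FILE["defaults"])
        d = _deep_merge(base, d)
        d = _deep_merge(d, overrides)
    return config_from_dict(d)


def load_config(path) -> ExperimentConfig:
    """Load, merge over defaults, and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# delimited I/O with provenance headers
# ---------------------------------------------------------------------------


def _provenance_lines(meta: dict) -> list[str]:
    lines = [f"# smfretsim v{__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    return lines


def write_burst_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Tab-separated burst table with '#' provenance header lines."""
    df = table.copy()
    df["excluded"] = df["excluded"].astype(int)
    with open(path, "w") as fh:
        for line in _provenance_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_burst_table(path) -> pd.DataFrame:
    """Read a burst table, validating the schema."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"burst table {path} is missing columns {missing}")
    df["excluded"] = df["excluded"].astype(bool)
    return df


def write_photon_table(photons: pd.DataFrame, path, meta: dict | None = None) -> None:
    df = photons.copy()
    df["detected"] = df["detected"].astype(int)
    with open(path, "w") as fh:
        for line in _provenance_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_shift_results(delta: np.ndarray, burst_ids, path, meta: dict | None = None) -> None:
    """Per-burst shift values preceded by a '# summary' provenance line."""
    with open(path, "w") as fh:
        for line in _provenance_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("burst_id\tdelta\n")
        for bid, d in zip(burst_ids, delta):
            fh.write(f"{bid}\t{d:.10g}\n")
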