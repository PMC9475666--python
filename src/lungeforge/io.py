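"""File readers/writers and run configuration.

CSV dialect: comma-separated UTF-8 with '.' decimals; lines starting with
'#' are comments (used for unit documentation).  Readers validate and
reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lungeforge.energetics import EnergeticParams
from lungeforge.kinematics import DetectionThresholds, TagTrace
from lungeforge.morphometry import (
    DEFAULT_ALLOMETRY,
    AllometryConfig,
    PowerLaw,
    SpeciesAllometry,
    WhaleMorphometrics,
)

__all__ = [
    "read_tag_trace",
    "write_tag_trace",
    "read_morphometrics",
    "write_morphometrics",
    "RunConfig",
]

TRACE_COLUMNS = ("t", "depth", "pitch", "speed", "gyro_y")


class IOError_(ValueError):
    """Malformed input file."""


def read_tag_trace(path, sample_rate: float = 10.0) -> TagTrace:
    """Read a tag-trace CSV (columns t, depth, pitch, speed, gyro_y).

    Irregularly sampled input is resampled onto a regular grid at
    ``sample_rate`` with linear interpolation and a warning; missing
    columns and non-monotone time are hard errors.
    """
    df = pd.read_csv(path, comment="#")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise IOError_(f"tag trace {path}: missing required column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise IOError_(f"tag trace {path}: fewer than 2 samples")
    if np.any(np.diff(t) <= 0):
        raise IOError_(f"tag trace {path}: time not strictly increasing")
    dt = np.diff(t)
    channels = {c: df[c].to_numpy(dtype=float) for c in TRACE_COLUMNS[1:]}
    if np.ptp(dt) > 1e-6 or abs(dt[0] - 1.0 / sample_rate) > 1e-6:
        warnings.warn(
            f"tag trace {path}: irregular or non-{sample_rate} Hz sampling; "
            "resampling with linear interpolation",
            stacklevel=2,
        )
        grid = np.arange(t[0], t[-1] + 1e-9, 1.0 / sample_rate)
        channels = {c: np.interp(grid, t, v) for c, v in channels.items()}
        t = grid
    return TagTrace(t=t - t[0], sample_rate=sample_rate, **channels)


def write_tag_trace(trace: TagTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# t [s], depth [m, down], pitch [rad], speed [m s-1], "
                 "gyro_y [rad s-1]\n")
        pd.DataFrame({
            "t": trace.t, "depth": trace.depth, "pitch": trace.pitch,
            "speed": trace.speed, "gyro_y": trace.gyro_y,
        }).to_csv(fh, index=False, float_format="%.6f")


MORPH_COLUMNS = ("individual_id", "species", "L_body")
MORPH_OPTIONAL = ("w_max", "W_bz", "L_rbh", "A_jaw_direct")


def read_morphometrics(path) -> list[WhaleMorphometrics]:
    """Read the per-individual morphometrics CSV (SI units)."""
    df = pd.read_csv(path, comment="#")
    for col in MORPH_COLUMNS:
        if col not in df.columns:
            raise IOError_(f"morphometrics {path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in MORPH_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        out.append(WhaleMorphometrics(
            individual_id=str(row["individual_id"]),
            species=str(row["species"]),
            L_body=float(row["L_body"]),
            **kwargs,
        ))
    return out


def write_morphometrics(morphs, path) -> None:
    rows = []
    for m in morphs:
        rows.append({
            "individual_id": m.individual_id, "species": m.species,
            "L_body": m.L_body, "w_max": m.w_max, "W_bz": m.W_bz,
            "L_rbh": m.L_rbh, "A_jaw_direct": m.A_jaw_direct,
        })
    with open(path, "w") as fh:
        fh.write("# lengths/widths [m], areas [m^2]\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


# --------------------------------------------------------------------------
# run configuration


def _allometry_to_dict(cfg: AllometryConfig) -> dict:
    return {
        "O_jaw": cfg.O_jaw,
        "species": {
            name: {
                kind: dataclasses.asdict(getattr(sp, kind))
                for kind in ("mass", "vgb_length", "wetted_area")
            }
            for name, sp in cfg.species.items()
        },
    }


def _allometry_from_dict(d: dict) -> AllometryConfig:
    species = {
        name: SpeciesAllometry(**{
            kind: PowerLaw(**block[kind])
            for kind in ("mass", "vgb_length", "wetted_area")
        })
        for name, block in d["species"].items()
    }
    return AllometryConfig(species=species, O_jaw=d.get("O_jaw", 1.0514))


@dataclass
class RunConfig:
    """Complete, serializable parameter set for one pipeline run.

    The resolved config is written verbatim into every output directory so
    any run can be reproduced bit-exactly.
    """

    seed: int = 0
    n_sample: int = 30
    vpos_end: str = "half"
    max_gape_deg: float = 75.0
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    energetics: EnergeticParams = field(default_factory=EnergeticParams)
    allometry: AllometryConfig = field(default_factory=lambda: DEFAULT_ALLOMETRY)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_sample": self.n_sample,
            "vpos_end": self.vpos_end,
            "max_gape_deg": self.max_gape_deg,
            "thresholds": dataclasses.asdict(self.thresholds),
            "energetics": dataclasses.asdict(self.energetics),
            "allometry": _allometry_to_dict(self.allometry),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for key in ("seed", "n_sample", "vpos_end", "max_gape_deg"):
            if key in d:
                kwargs[key] = d[key]
        if "thresholds" in d:
            kwargs["thresholds"] = DetectionThresholds(**d["thresholds"])
        if "energetics" in d:
            kwargs["energetics"] = EnergeticParams(**d["energetics"])
        if "allometry" in d:
            kwargs["allometry"] = _allometry_from_dict(d["allometry"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
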