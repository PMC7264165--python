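"""Persistence helpers: HDF5 recordings, YAML configs, TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bands import get_band
from .simulate import CouplingSpec, SimulationConfig, SubjectRecording

__all__ = [
    "save_recordings",
    "load_recordings",
    "config_to_yaml",
    "config_from_yaml",
    "write_couplings_tsv",
    "read_couplings_tsv",
    "write_tmap_tsv",
    "write_json",
]


def save_recordings(path, recordings: list[SubjectRecording]) -> None:
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            g = f.create_group(rec.subject_id or f"sub-{i:03d}")
            g.create_dataset("data", data=rec.data)
            g.attrs["fs_hz"] = rec.fs_hz


def load_recordings(path) -> list[SubjectRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                SubjectRecording(
                    data=g["data"][()], fs_hz=float(g.attrs["fs_hz"]), subject_id=name
                )
            )
    return out


def _config_dict(config: SimulationConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "duration_s": config.duration_s,
        "fs_hz": config.fs_hz,
        "n_sensors": config.n_sensors,
        "grid_shape": list(config.grid_shape),
        "spacing_mm": config.spacing_mm,
        "grid_origin": list(config.grid_origin),
        "sensor_snr": config.sensor_snr,
        "noise_std": config.noise_std,
        "background": config.background,
        "bands": [b.name for b in config.bands],
        "rng_seed": config.rng_seed,
        "couplings": [
            {
                "node_i": c.node_i,
                "band_i": c.band_i.name,
                "node_j": c.node_j,
                "band_j": c.band_j.name,
                "rho_env": c.rho_env,
            }
            for c in config.couplings
        ],
    }


def config_to_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(config), sort_keys=False))


def config_from_yaml(path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    couplings = tuple(
        CouplingSpec(
            node_i=c["node_i"],
            band_i=get_band(c["band_i"]),
            node_j=c["node_j"],
            band_j=get_band(c["band_j"]),
            rho_env=c["rho_env"],
        )
        for c in raw.pop("couplings", [])
    )
    raw["grid_shape"] = tuple(raw.get("grid_shape", (10, 10, 5)))
    raw["grid_origin"] = tuple(raw.get("grid_origin", (0.0, 0.0, 0.0)))
    raw["bands"] = tuple(get_band(b) for b in raw.get("bands", ()))
    return SimulationConfig(couplings=couplings, **raw)


def write_couplings_tsv(path, couplings) -> None:
    pd.DataFrame(
        [
            {
                "node_i": c.node_i,
                "band_i": c.band_i.name,
                "node_j": c.node_j,
                "band_j": c.band_j.name,
                "rho_env": c.rho_env,
            }
            for c in couplings
        ],
        columns=["node_i", "band_i", "node_j", "band_j", "rho_env"],
    ).to_csv(path, sep="\t", index=False)


def read_couplings_tsv(path) -> tuple[CouplingSpec, ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        CouplingSpec(
            node_i=int(r.node_i),
            band_i=get_band(r.band_i),
            node_j=int(r.node_j),
            band_j=get_band(r.band_j),
            rho_env=float(r.rho_env),
        )
        for r in df.itertuples()
    )


def write_source_space_tsv(path, source_space) -> None:
    pd.DataFrame(
        {
            "x": source_space.coords[:, 0],
            "y": source_space.coords[:, 1],
            "z": source_space.coords[:, 2],
            "parcel_id": source_space.parcel_id,
        }
    ).to_csv(path, sep="\t", index=False)


def write_tmap_tsv(path, tmap, source_space) -> None:
    pd.DataFrame(
        {
            "source": np.arange(source_space.n_sources),
            "x": source_space.coords[:, 0],
            "y": source_space.coords[:, 1],
            "z": source_space.coords[:, 2],
            "t": tmap.t,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
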