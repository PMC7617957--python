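"""Plain-text and TIFF readers/writers for the pipeline's interchange
formats: TSV tables, SWC morphologies, single-channel TIFF images and
YAML configs."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import SpikeUnit, StimulusLog
from .histomorph import Morphology

PathLike = Union[str, Path]

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events_tsv(log: StimulusLog, path: PathLike) -> None:
    write_tsv(log.events, path)


def read_events_tsv(path: PathLike) -> StimulusLog:
    return StimulusLog(read_tsv(path))


def write_spikes_tsv(units, path: PathLike) -> None:
    """Long-format spike table: one row per spike (unit_id, time_s)."""
    rows = [
        {"unit_id": u.unit_id, "time_s": t}
        for u in units
        for t in u.spike_times
    ]
    write_tsv(pd.DataFrame(rows, columns=["unit_id", "time_s"]), path)


def read_spikes_tsv(path: PathLike) -> list:
    df = read_tsv(path)
    return [
        SpikeUnit(unit_id=str(uid), spike_times=np.sort(g["time_s"].to_numpy()))
        for uid, g in df.groupby("unit_id", sort=True)
    ]


def write_swc(morph: Morphology, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for _, row in morph.nodes.iterrows():
            fh.write(
                f"{int(row['id'])} {int(row['type'])} "
                f"{row['x']:.6f} {row['y']:.6f} {row['z']:.6f} "
                f"{row['radius']:.4f} {int(row['parent'])}\n"
            )


def read_swc(path: PathLike) -> Morphology:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append({
                "id": int(parts[0]), "type": int(parts[1]),
                "x": float(parts[2]), "y": float(parts[3]),
                "z": float(parts[4]), "radius": float(parts[5]),
                "parent": int(parts[6]),
            })
    return Morphology(nodes=pd.DataFrame(rows, columns=SWC_COLUMNS))


def write_tiff(image: np.ndarray, path: PathLike) -> None:
    """Write a single-channel image as 16-bit TIFF (values clipped)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
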