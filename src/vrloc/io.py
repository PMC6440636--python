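"""Readers and writers for the on-disk formats.

* IR datasets: a directory of per-direction stereo WAV files laid out as
  ``<condition>/az<az>_el<el>.wav`` plus an ``index.csv`` (columns
  filename, azimuth_deg, elevation_deg, condition), or a single HDF5
  container with the same fields.  Deposited measurement sets in other
  layouts are converted by writing such an index for them.
* Response logs and error tables: CSV with the behavioral column schema.
* Tracker sets: JSON or CSV (frame in {real, virtual}, point_id, x, y, z
  in meters); rigid transforms: JSON (row-major rotation + translation).
* Configs: YAML or JSON.

All angles are degrees on disk; radians exist only inside computations.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .calibration import RigidTransform, TrackerSet
from .cues import BinauralIR
from .geometry import SourcePosition

__all__ = [
    "write_ir_dataset",
    "read_ir_dataset",
    "match_pairs",
    "write_ir_hdf5",
    "read_ir_hdf5",
    "read_responses",
    "write_responses",
    "read_tracker_sets",
    "write_transform",
    "read_transform",
    "load_config",
]

log = logging.getLogger("vrloc")

INDEX_COLUMNS = ("filename", "azimuth_deg", "elevation_deg", "condition")


def _wav_name(source: SourcePosition) -> str:
    return f"az{source.azimuth:+06.1f}_el{source.elevation:+05.1f}.wav"


def write_ir_dataset(path: str | Path, irs: list[BinauralIR]) -> Path:
    """Write BRIRs as float32 stereo WAVs under ``<condition>/`` + index.csv."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for ir in irs:
        if ir.source is None:
            raise ValueError("cannot write an IR without a source direction")
        sub = root / ir.condition
        sub.mkdir(exist_ok=True)
        name = _wav_name(ir.source)
        data = np.stack([ir.left, ir.right], axis=1).astype(np.float32)
        wavfile.write(sub / name, int(ir.fs), data)
        rows.append(
            {
                "filename": f"{ir.condition}/{name}",
                "azimuth_deg": ir.source.azimuth,
                "elevation_deg": ir.source.elevation,
                "condition": ir.condition,
            }
        )
    pd.DataFrame(rows).to_csv(root / "index.csv", index=False)
    return root


def read_ir_dataset(path: str | Path) -> list[BinauralIR]:
    """Read a WAV-directory (index.csv) or HDF5 (.h5) IR dataset.

    Index rows referencing missing files produce a warning and are excluded;
    malformed index rows reject with their row number.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_ir_hdf5(path)
    index = path / "index.csv"
    if not index.exists():
        raise FileNotFoundError(f"no index.csv under {path} (and not an HDF5 file)")
    table = pd.read_csv(index)
    missing_cols = [c for c in INDEX_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"index.csv is missing columns {missing_cols}")
    irs = []
    for i, row in table.iterrows():
        try:
            az = float(row["azimuth_deg"])
            el = float(row["elevation_deg"])
            fname = str(row["filename"])
            condition = str(row["condition"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed index row {i + 1}: {exc}") from exc
        wav = path / fname
        if not wav.exists():
            warnings.warn(f"index row {i + 1}: missing file {wav}; excluded", stacklevel=2)
            continue
        fs, data = wavfile.read(wav)
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[0] == 2 and data.shape[1] != 2:
            data = data.T
        if data.shape[1] != 2:
            raise ValueError(f"{wav} is not a stereo file")
        irs.append(
            BinauralIR(
                fs=float(fs),
                left=data[:, 0],
                right=data[:, 1],
                condition=condition,
                source=SourcePosition(az, el),
            )
        )
    log.info("read %d impulse responses from %s", len(irs), path)
    return irs


def match_pairs(
    irs: list[BinauralIR],
    with_condition: str = "with_hmd",
    without_condition: str = "without_hmd",
) -> dict[tuple[float, float], tuple[BinauralIR, BinauralIR]]:
    """Match with/without-HMD entries by direction; unpaired entries warn."""
    by_dir: dict[tuple[float, float], dict[str, BinauralIR]] = {}
    for ir in irs:
        if ir.source is None:
            continue
        by_dir.setdefault(ir.source.azel, {})[ir.condition] = ir
    pairs = {}
    for azel, entry in sorted(by_dir.items()):
        if with_condition in entry and without_condition in entry:
            pairs[azel] = (entry[with_condition], entry[without_condition])
        else:
            warnings.warn(f"direction {azel}: missing pair member; excluded", stacklevel=2)
    return pairs


def write_ir_hdf5(path: str | Path, irs: list[BinauralIR]) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, ir in enumerate(irs):
            if ir.source is None:
                raise ValueError("cannot write an IR without a source direction")
            g = f.create_group(f"ir{i:04d}")
            g.create_dataset("left", data=ir.left)
            g.create_dataset("right", data=ir.right)
            g.attrs["fs"] = ir.fs
            g.attrs["condition"] = ir.condition
            g.attrs["azimuth_deg"] = ir.source.azimuth
            g.attrs["elevation_deg"] = ir.source.elevation
    return path


def read_ir_hdf5(path: str | Path) -> list[BinauralIR]:
    irs = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            irs.append(
                BinauralIR(
                    fs=float(g.attrs["fs"]),
                    left=np.asarray(g["left"]),
                    right=np.asarray(g["right"]),
                    condition=str(g.attrs["condition"]),
                    source=SourcePosition(
                        float(g.attrs["azimuth_deg"]), float(g.attrs["elevation_deg"])
                    ),
                )
            )
    return irs


def read_responses(path: str | Path) -> pd.DataFrame:
    from .behavior import RESPONSE_COLUMNS

    table = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response CSV is missing columns {missing}")
    return table


def write_responses(path: str | Path, records: pd.DataFrame) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def read_tracker_sets(path: str | Path) -> dict[str, TrackerSet]:
    """Read real/virtual tracker sets from JSON or CSV.

    JSON: ``{"real": [[x,y,z],...], "virtual": [[x,y,z],...]}``.
    CSV: columns frame, point_id, x, y, z; points ordered by point_id.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return {
            frame: TrackerSet(np.asarray(points, dtype=float))
            for frame, points in payload.items()
        }
    table = pd.read_csv(path)
    needed = {"frame", "point_id", "x", "y", "z"}
    if not needed.issubset(table.columns):
        raise ValueError(f"tracker CSV needs columns {sorted(needed)}")
    out = {}
    for frame, chunk in table.groupby("frame"):
        chunk = chunk.sort_values("point_id")
        out[str(frame)] = TrackerSet(chunk[["x", "y", "z"]].to_numpy(dtype=float))
    return out


def write_transform(path: str | Path, transform: RigidTransform, **metadata) -> Path:
    path = Path(path)
    payload = {
        "rotation": transform.rotation.tolist(),
        "translation": transform.translation.tolist(),
        **metadata,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_transform(path: str | Path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    return RigidTransform(
        np.asarray(payload["rotation"], dtype=float),
        np.asarray(payload["translation"], dtype=float),
    )


def load_config(path: str | Path) -> dict:
    """Load a run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
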