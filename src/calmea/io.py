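"""Reading and writing the package's plain-text and TIFF formats.

File layouts
------------
* traces CSV: columns ``cell_id, frame, time_s, intensity`` (long format)
* ROI CSV: columns ``cell_id, row, col, radius``
* spike CSV: columns ``electrode_id, time_s``
* image stacks: multi-page TIFF (float32)
* ground truth, calibration, metrics, run logs: JSON
* generator configs: YAML or JSON mapping of the dataclass fields
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FieldRecording
from .extraction import CellROI
from .mea import SpikeTrain
from .synthetic import BurstEvent, CaFieldConfig, CaGroundTruth, MEAConfig, MEAGroundTruth

PathLike = Union[str, Path]


def write_traces_csv(recording: FieldRecording, path: PathLike) -> None:
    n_cells, n_frames = recording.traces.shape
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(np.asarray(recording.cell_ids), n_frames),
            "frame": np.tile(np.arange(n_frames), n_cells),
            "time_s": np.tile(recording.frame_times, n_cells),
            "intensity": recording.traces.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_traces_csv(path: PathLike, stimulus_frame: int) -> FieldRecording:
    df = pd.read_csv(path)
    wide = df.pivot(index="cell_id", columns="frame", values="intensity").sort_index()
    times = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
    return FieldRecording(
        traces=wide.to_numpy(),
        stimulus_frame=stimulus_frame,
        frame_times=times,
        cell_ids=list(wide.index),
    )


def write_rois_csv(rois: Sequence[CellROI], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"cell_id": r.cell_id, "row": r.centroid[0], "col": r.centroid[1], "radius": r.radius}
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_rois_csv(path: PathLike) -> List[CellROI]:
    df = pd.read_csv(path)
    return [
        CellROI(cell_id=int(r.cell_id), centroid=(float(r.row), float(r.col)), radius=float(r.radius))
        for r in df.itertuples()
    ]


def write_spikes_csv(trains: Sequence[SpikeTrain], path: PathLike) -> None:
    rows = []
    for t in trains:
        rows.append(
            pd.DataFrame({"electrode_id": t.electrode_id, "time_s": t.times})
        )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["electrode_id", "time_s"])
    )
    out.to_csv(path, index=False)


def read_spikes_csv(path: PathLike, n_electrodes: int = 0) -> List[SpikeTrain]:
    """Read a spike-list CSV.  ``n_electrodes`` pads silent electrodes so
    the well layout is preserved even when some electrodes never fired."""
    df = pd.read_csv(path)
    ids = sorted(set(df["electrode_id"].astype(int)) | set(range(n_electrodes)))
    return [
        SpikeTrain(
            electrode_id=e,
            times=df.loc[df["electrode_id"] == e, "time_s"].to_numpy(dtype=float),
        )
        for e in ids
    ]


def write_stack_tiff(stack: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())


def write_ground_truth(truth: Union[CaGroundTruth, MEAGroundTruth], path: PathLike) -> None:
    write_json(truth, path)


def load_ca_config(path: PathLike) -> CaFieldConfig:
    data = _load_mapping(path)
    return CaFieldConfig(**data)


def load_mea_config(path: PathLike) -> MEAConfig:
    data = _load_mapping(path)
    schedule = [
        ev if isinstance(ev, BurstEvent) else BurstEvent(**ev)
        for ev in data.pop("burst_schedule", [])
    ]
    return MEAConfig(burst_schedule=schedule, **data)


def _load_mapping(path: PathLike) -> Dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
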