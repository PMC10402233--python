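"""Reading and writing the pipeline's on-disk formats.

A dataset directory holds binary PNG drawing masks plus a sidecar trial
table ``trials.csv`` (columns: participant, trial, electrode_1,
electrode_2 [optional], amplitude_x_threshold, frequency_hz, image_path)
and a per-participant implant placement YAML.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .drawing import Drawing
from .geometry import ImplantLayout, place_implant
from .synthetic import SyntheticTrial

__all__ = [
    "read_drawing",
    "load_trials",
    "load_placements",
    "write_shapes_csv",
    "write_distances_csv",
]


def read_drawing(path, trial_id=None, participant_id=None) -> Drawing:
    """Read a PNG mask as a binary drawing (foreground = any value > 127)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].max(axis=-1)
    return Drawing((arr > 127).astype(np.uint8), trial_id=trial_id,
                   participant_id=participant_id)


def load_trials(data_dir, trials_csv: str = "trials.csv") -> list[SyntheticTrial]:
    """Load a dataset directory into trial objects usable by the pipeline."""
    root = Path(data_dir)
    table = pd.read_csv(root / trials_csv, keep_default_na=False)
    trials = []
    for _, row in table.iterrows():
        e1 = str(row["electrode_1"])
        e2 = str(row.get("electrode_2", "") or "")
        key = f"{e1}+{e2}" if e2 else e1
        drawing = read_drawing(
            root / row["image_path"], trial_id=row["trial"],
            participant_id=row["participant"],
        )
        trials.append(
            SyntheticTrial(
                drawing=drawing,
                participant=str(row["participant"]),
                electrodes=key,
                amplitude=float(row["amplitude_x_threshold"]),
                frequency=float(row["frequency_hz"]),
                trial=int(row["trial"]),
            )
        )
    return trials


def load_placements(path) -> dict[str, ImplantLayout]:
    """Placement YAML -> per-participant implant layouts."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        str(pid): place_implant(
            rotation_deg=float(cfg.get("rotation_deg", 0.0)),
            center_x_um=float(cfg.get("center_x_um", 0.0)),
            center_y_um=float(cfg.get("center_y_um", 0.0)),
            eye=str(cfg.get("eye", "RE")),
        )
        for pid, cfg in raw.items()
    }


def write_shapes_csv(shapes: pd.DataFrame, path) -> None:
    shapes.to_csv(path, index=False)


def write_distances_csv(distances: pd.DataFrame, path) -> None:
    distances.to_csv(path, index=False)
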