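"""File I/O for the assay pipeline.

Primary image dialect is grayscale 16-bit TIFF; 8-bit PNG is accepted with
a logged warning about dynamic-range loss.  Tables are long/tidy CSV with
documented headers; ground truth and calibration curves travel as JSON
sidecars.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .electrophoresis import LaneProfile
from .gradient import CalibrationCurve, GradientRun

log = logging.getLogger(__name__)


def read_image(path) -> np.ndarray:
    """Read a grayscale gel/larva image (16-bit TIFF preferred).

    PNG input is accepted; 8-bit data triggers a warning because the
    chemiluminescent assays rely on 16-bit dynamic range.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"could not read image {path}: {exc}") from exc
    img = np.asarray(img)
    if img.dtype == np.uint8:
        log.warning("%s is 8-bit; 16-bit TIFF is recommended (dynamic-range loss)", path)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # collapse RGB(A) scans
        img = img[..., :3].mean(axis=-1)
    return img


def write_image(path, image: np.ndarray) -> None:
    """Write an intensity image as 16-bit grayscale TIFF (rounded/clipped)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint16:
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def write_stack(path, short_exposure: np.ndarray, long_exposure: np.ndarray) -> None:
    """Write a 2-frame (short, long) exposure stack as one 16-bit TIFF."""
    frames = np.stack(
        [
            np.clip(np.rint(np.asarray(f)), 0, 65535).astype(np.uint16)
            for f in (short_exposure, long_exposure)
        ]
    )
    tifffile.imwrite(Path(path), frames)


def read_stack(path) -> tuple[np.ndarray, np.ndarray]:
    frames = tifffile.imread(Path(path))
    if frames.ndim != 3 or frames.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-frame (short, long) stack, got {frames.shape}")
    return frames[0], frames[1]


def write_label_masks(path, masks: np.ndarray) -> None:
    """Write region masks as a label-image TIFF (0 bg, 1 viscera, 2 trunk, 3 head)."""
    tifffile.imwrite(Path(path), np.asarray(masks, dtype=np.uint8))


def read_label_masks(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def write_profile_csv(path, profiles: list[LaneProfile]) -> None:
    """Long CSV of lane profiles: columns (lane_id, row, intensity)."""
    rows = []
    for p in profiles:
        for r, v in enumerate(p.intensities):
            rows.append({"lane_id": p.lane_id, "row": r, "intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile_csv(path) -> list[LaneProfile]:
    df = pd.read_csv(path)
    missing = {"lane_id", "row", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    profiles = []
    for lane_id, sub in df.groupby("lane_id", sort=False):
        sub = sub.sort_values("row")
        profiles.append(LaneProfile(sub["intensity"].to_numpy(), lane_id=str(lane_id)))
    return profiles


def write_gradient_csv(path, run: GradientRun) -> None:
    """CSV of one run: columns (fraction_index, refractive_index, signal)."""
    run.to_frame().to_csv(path, index=False)


def read_gradient_csv(path, run_id: str | None = None) -> GradientRun:
    df = pd.read_csv(path)
    missing = {"fraction_index", "refractive_index", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"gradient CSV missing columns {sorted(missing)}")
    return GradientRun.from_frame(df, run_id=run_id or Path(path).stem)


def write_curve_json(path, curve: CalibrationCurve) -> None:
    with open(path, "w") as fh:
        json.dump(curve.to_dict(), fh, indent=2)


def read_curve_json(path) -> CalibrationCurve:
    with open(path) as fh:
        d = json.load(fh)
    return CalibrationCurve(**d)
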