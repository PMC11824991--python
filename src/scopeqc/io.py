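"""File I/O: TIFF images, CSV scan series, and key–value configs.

Pixel sizes are always taken from config/CLI arguments, never from TIFF
tags — tag dialects vary between acquisition programs. When resolution tags
are present and disagree with the configured value, a warning is emitted.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .models import ScanSeries

__all__ = [
    "read_image",
    "write_image",
    "read_scan",
    "write_scan",
    "read_config",
    "write_json",
    "SCAN_HEADERS",
    "OPTICS_CONFIG_KEYS",
]

#: accepted CSV headers per scan kind
SCAN_HEADERS = {
    "pockels": ("voltage_V", "power_mW"),
    "gdd": ("gdd_fs2", "intensity_au"),
}

#: flat key–value config schema for an optical train
OPTICS_CONFIG_KEYS = (
    "scan_focal_length_mm",
    "tube_focal_length_mm",
    "objective_focal_length_mm",
    "objective_na",
    "immersion_index",
    "scanner_half_angle_deg",
    "beam_fill_fraction",
    "wavelength_nm",
)


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write a 2-D plane or 3-D stack as (multi-page) TIFF."""
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ValueError("image must be 2-D or 3-D")
    tifffile.imwrite(str(path), data)


def read_image(path: str | Path, pixel_size_um: float | None = None) -> np.ndarray:
    """Read a (multi-page) TIFF; squeeze singleton page dimension.

    If ``pixel_size_um`` is given and the file carries resolution tags that
    disagree by more than 5 %, a consistency warning is emitted (the
    configured value always wins).
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if pixel_size_um is not None:
            tag = tf.pages[0].tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                # (1, 1) is the writer default carrying no calibration
                if num and (num, den) != (1, 1):
                    tag_um = den / num * 1e4  # px/cm convention
                    if abs(tag_um - pixel_size_um) / pixel_size_um > 0.05:
                        warnings.warn(
                            f"{path.name}: TIFF XResolution implies "
                            f"{tag_um:.3g} um/px but config says "
                            f"{pixel_size_um:.3g} um/px; using the config value",
                            stacklevel=2,
                        )
    return np.squeeze(data)


def write_scan(path: str | Path, scan: ScanSeries, kind: str) -> None:
    """Write a scan as a two-column CSV with the standard header."""
    cols = SCAN_HEADERS[kind]
    pd.DataFrame({cols[0]: scan.abscissa, cols[1]: scan.ordinate}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_scan(path: str | Path, kind: str) -> ScanSeries:
    """Read a two-column CSV scan, validating the header for ``kind``."""
    if kind not in SCAN_HEADERS:
        raise ValueError(f"unknown scan kind {kind!r}; expected {set(SCAN_HEADERS)}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected = SCAN_HEADERS[kind]
    if tuple(df.columns[:2]) != expected:
        raise ValueError(
            f"{Path(path).name}: expected columns {expected}, "
            f"found {tuple(df.columns[:2])}"
        )
    return ScanSeries(
        df[expected[0]].to_numpy(float),
        df[expected[1]].to_numpy(float),
        units=(expected[0].rsplit("_", 1)[-1], expected[1].rsplit("_", 1)[-1]),
    )


def read_config(
    path: str | Path, required: tuple[str, ...] = (), allowed: tuple[str, ...] | None = None
) -> dict:
    """Read a flat key–value config (YAML or JSON).

    Missing required keys and unknown keys are reported by name.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(cfg).__name__}")
    for key in required:
        if key not in cfg:
            raise ValueError(f"{path}: missing required config key '{key}'")
    if allowed is not None:
        unknown = set(cfg) - set(allowed)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
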