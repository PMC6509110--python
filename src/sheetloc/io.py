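"""Readers/writers (ThunderSTORM-dialect CSV, TIFF) and config validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_stack",
    "write_stack",
    "load_config",
    "validate_config",
    "FormatError",
    "ConfigError",
    "DEFAULT_CONFIG",
]


class FormatError(ValueError):
    """A localization file misses mandatory structure."""


class ConfigError(ValueError):
    """A configuration document violates the schema."""


# internal snake_case name -> ThunderSTORM-style header
_DIALECT = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "z_nm": "z [nm]",
    "sigma_x_nm": "sigma1 [nm]",
    "sigma_y_nm": "sigma2 [nm]",
    "photons": "intensity [photon]",
    "background": "offset [photon]",
    "uncertainty_xy_nm": "uncertainty_xy [nm]",
    "uncertainty_z_nm": "uncertainty_z [nm]",
}
_REVERSE = {v: k for k, v in _DIALECT.items()}
_MANDATORY = ("frame", "x [nm]", "y [nm]")


def write_localizations(table: pd.DataFrame, path: str, dialect: str = "thunderstorm") -> None:
    """Write a localization table as CSV.

    ``dialect='thunderstorm'`` renames the canonical columns to the bracketed
    unit headers; other columns pass through untouched.  ``dialect='raw'``
    writes canonical snake_case headers.
    """
    if dialect == "thunderstorm":
        table = table.rename(columns=_DIALECT)
        # ThunderSTORM quotes every header (`"x [nm]"` etc.); write the header
        # line explicitly since csv only quotes when forced to
        header = ",".join(f'"{c}"' for c in table.columns)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            table.to_csv(fh, index=False, header=False)
    elif dialect == "raw":
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_localizations(path: str, dialect: str = "thunderstorm") -> pd.DataFrame:
    """Read a localization CSV, mapping dialect headers onto internal names.

    Unknown extra columns are preserved as-is.  Missing mandatory columns
    (frame, x, y) raise :class:`FormatError` naming the column.
    """
    table = pd.read_csv(path)
    if dialect == "thunderstorm":
        for col in _MANDATORY:
            if col not in table.columns:
                raise FormatError(f"mandatory column {col!r} missing from {path}")
        table = table.rename(columns=_REVERSE)
    elif dialect == "raw":
        for col in ("frame", "x_nm", "y_nm"):
            if col not in table.columns:
                raise FormatError(f"mandatory column {col!r} missing from {path}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return table


def read_stack(path: str) -> np.ndarray:
    """Read a (multi-page) grayscale TIFF stack as (plane, y, x)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(stack: np.ndarray, path: str) -> None:
    """Write a (plane, y, x) stack as 16-bit grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "optics": {
        "wavelength_nm": 637.0,
        "na_inner": 0.42,
        "na_outer": 0.50,
        "sheet_length_um": 20.0,
        "scan_angle_deg": 32.5,
    },
    "camera": {
        "pixel_size_nm": 102.0,
        "gain": 2.0,
        "offset": 100.0,
        "read_noise": 1.6,
        "qe": 0.82,
    },
    "geometry": {
        "scan_step_nm": 316.0,
        "n_planes": 20,
        "exposure_s": 0.020,
        "sidelobe_fraction": 0.0,
        "img_shape": [64, 64],
    },
    "blinking": {
        "k_on": 0.25,
        "k_off": 50.0,
        "k_bleach": 0.0,
        "photons_per_frame_mean": 1000.0,
        "photon_dispersion": 0.3,
    },
    "simulate": {
        "enabled": True,
        "kind": "filament",
        "structure_params": {},
        "n_volumes": 5,
        "background_photons": 2.0,
        "drift_per_frame_nm": [0.0, 0.0, 0.0],
        "fiducials": 0,
    },
    "detection": {
        "filter_scale_px": 1.3,
        "threshold_k": 5.0,
        "roi_half_px": 5,
        "max_uncertainty_xy_nm": 50.0,
        "sigma_bounds_nm": [80.0, 600.0],
        "uncertainty_model": "tlw",
    },
    "drift": {
        "method": "fiducial",
        "link_radius_nm": 500.0,
        "smoothing_window": 50,
        "block_frames": 500,
        "render_pixel_nm": 10.0,
    },
    "render": {
        "pixel_nm": 20.0,
        "mode": "2d",
        "sigma_source": "per_event_uncertainty",
        "fixed_sigma_nm": 20.0,
        "frames_per_bin": 2000,
    },
    "frc": {
        "render_pixel_nm": 10.0,
        "n_splits": 5,
        "threshold": 1.0 / 7.0,
    },
    "npc": {
        "enabled": False,
        "bin_pixel_nm": 10.0,
        "area_bounds_px": [250, 300],
        "dilation_size_px": 3,
        "roi_size_px": 32,
        "n_top": 50,
        "kde_grid_nm": 2.0,
        "kde_bandwidth_rule": "silverman",
    },
    "calibration": {
        "path": None,
        "z_step_nm": 40.0,
    },
    "seeds": {"simulate": 1, "frc": 1},
    "paths": {"out_dir": "out"},
}


def _check_keys(doc: dict, schema: dict, prefix: str = "") -> None:
    for key, val in doc.items():
        if key not in schema:
            raise ConfigError(f"unknown configuration key '{prefix}{key}'")
        if isinstance(schema[key], dict) and key != "structure_params":
            if not isinstance(val, dict):
                raise ConfigError(f"configuration block {prefix}{key!r} must be a mapping")
            _check_keys(val, schema[key], prefix=f"{prefix}{key}.")


def validate_config(doc: dict) -> dict:
    """Validate a config document against the schema; unknown keys rejected.

    Returns the full config: defaults overlaid with the document's values.
    """
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(doc, DEFAULT_CONFIG)
    merged = {}
    for block, defaults in DEFAULT_CONFIG.items():
        merged[block] = dict(defaults)
        merged[block].update(doc.get(block, {}))
    return merged


def load_config(path: str) -> dict:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)
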