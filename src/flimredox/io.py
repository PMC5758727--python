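"""File formats, pipeline configuration and color-coded rendering.

TIFF carries image data (3-D cubes with pages as time bins, multi-plane
32-bit parameter maps, integer label masks), CSV is the canonical
tabular interchange, and small YAML sidecars hold acquisition metadata
(bin width, period, channel) and plane names.  The pipeline config is a
validated YAML document; invalid configs fail fast naming the offending
key.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .decay import MAP_PLANES, FitOptions, IRFModel, TimeAxis
from .roi import ROIConfig

logger = logging.getLogger("flimredox")

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "load_config",
    "write_cube",
    "read_cube",
    "write_parameter_maps",
    "read_parameter_maps",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "render_flirr_map",
    "save_render",
]


class ConfigError(ValueError):
    """Configuration failed validation; the message names the offending key."""


# ---------------------------------------------------------------------------
# TIFF + sidecar formats
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_cube(path, cube: np.ndarray, axis: TimeAxis, channel: str) -> None:
    """Write a (time, y, x) TCSPC cube as a multi-page TIFF with a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(cube).astype(np.uint16), photometric="minisblack")
    meta = {
        "n_bins": int(axis.n_bins),
        "bin_width_ns": float(axis.bin_width),
        "period_ns": float(axis.period),
        "channel": channel,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_cube(path) -> tuple[np.ndarray, TimeAxis, str]:
    path = Path(path)
    cube = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    axis = TimeAxis(
        n_bins=meta["n_bins"], period=meta["period_ns"], bin_width=meta["bin_width_ns"]
    )
    return cube, axis, meta["channel"]


def write_parameter_maps(path, maps: Mapping[str, np.ndarray]) -> None:
    """Write per-pixel parameter maps as a multi-plane 32-bit TIFF (plane names in a sidecar)."""
    path = Path(path)
    names = [n for n in MAP_PLANES if n in maps] + [
        n for n in maps if n not in MAP_PLANES
    ]
    stack = np.stack([np.asarray(maps[n], dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    _sidecar(path).write_text(yaml.safe_dump({"planes": names}))


def read_parameter_maps(path) -> dict[str, np.ndarray]:
    path = Path(path)
    stack = tifffile.imread(path)
    names = yaml.safe_load(_sidecar(path).read_text())["planes"]
    return {name: stack[i].astype(np.float64) for i, name in enumerate(names)}


def write_mask(path, mask: np.ndarray) -> None:
    """Integer-label (or binary) mask as TIFF or PNG by extension."""
    path = Path(path)
    arr = np.asarray(mask)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr.astype(np.uint16))
    else:
        tifffile.imwrite(path, arr.astype(np.int32))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path)).astype(np.int64)
    return tifffile.imread(path).astype(np.int64)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_flirr_map(
    values: np.ndarray,
    colormap: str = "viridis",
    vmin: float = 0.0,
    vmax: float = 1.2,
    invalid_color: tuple[int, int, int] = (30, 30, 30),
) -> np.ndarray:
    """Color-code a per-pixel map with a fixed value range.

    The value-to-color mapping is fixed by (vmin, vmax) so panels
    rendered with a shared range are visually comparable; out-of-range
    values clamp to the endpoints (count logged) and non-finite pixels
    take the reserved ``invalid_color``.  Returns an (H, W, 3) uint8 RGB
    array.
    """
    import matplotlib as mpl

    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot render an empty map")
    if vmax <= vmin:
        raise ConfigError("render.vmax must exceed render.vmin")
    invalid = ~np.isfinite(values)
    n_clamped = int(np.sum((values < vmin) | (values > vmax)) - np.sum(invalid & False))
    n_clamped = int(np.sum(~invalid & ((values < vmin) | (values > vmax))))
    if n_clamped:
        logger.info("%d pixels outside [%g, %g] clamped for rendering", n_clamped, vmin, vmax)
    norm = np.clip((np.where(invalid, vmin, values) - vmin) / (vmax - vmin), 0.0, 1.0)
    cmap = mpl.colormaps[colormap]
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    rgb[invalid] = invalid_color
    return rgb


def save_render(path, rgb: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), rgb)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "scene": {"shape": [96, 96], "n_cells": 4, "cell_axis_range": [14.0, 20.0]},
    "axis": {"n_bins": 128, "period_ns": 12.5},
    "irf": {"shape": "gaussian", "center_ns": 1.0, "fwhm_ns": 0.2},
    "fit": {
        "objective": "mle",
        "min_photons": {"trp": 300.0, "nadh": 300.0, "fad": 100.0},
    },
    "roi": {
        "whole_cell": {"lower": 30.0, "upper": 5000.0},
        "mito": {"lower": 150.0, "upper": 5000.0},
        "aggregation": "pooled_refit",
    },
    "categories": [
        ["Category1", 25.0, 55.0],
        ["Category2", 55.0, 85.0],
        ["Category3", 85.0, 125.0],
    ],
    "treatment": {"target_mean_pct": 70.0, "target_sd_pct": 25.0},
    "cohort": {"min_rois": 5, "donor_tau_ns": 3.1},
    "render": {"colormap": "viridis", "vmin": 0.0, "vmax": 1.2},
}


def _require(cond: bool, key: str, why: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}': {why}")


class PipelineConfig:
    """Validated pipeline configuration with typed accessors."""

    def __init__(self, data: Mapping[str, Any] | None = None):
        merged = _deep_merge(DEFAULT_CONFIG, dict(data or {}))
        self.data = merged
        self._validate()

    def _validate(self) -> None:
        d = self.data
        _require(isinstance(d["seed"], int) and d["seed"] >= 0, "seed", "must be a non-negative integer")
        shape = d["scene"]["shape"]
        _require(
            len(shape) == 2 and all(isinstance(v, int) and v > 0 for v in shape),
            "scene.shape", "must be two positive integers",
        )
        _require(d["scene"]["n_cells"] > 0, "scene.n_cells", "must be positive")
        _require(d["axis"]["n_bins"] > 0, "axis.n_bins", "must be positive")
        _require(d["axis"]["period_ns"] > 0, "axis.period_ns", "must be positive")
        _require(d["irf"]["fwhm_ns"] > 0, "irf.fwhm_ns", "must be positive")
        _require(d["fit"]["objective"] in ("mle", "neyman"), "fit.objective", "must be 'mle' or 'neyman'")
        for ch, v in d["fit"]["min_photons"].items():
            _require(v > 0, f"fit.min_photons.{ch}", "must be positive")
        for morph in ("whole_cell", "mito"):
            lo, hi = d["roi"][morph]["lower"], d["roi"][morph]["upper"]
            _require(0 <= lo < hi, f"roi.{morph}", "requires 0 <= lower < upper")
        _require(
            d["roi"]["mito"]["lower"] >= d["roi"]["whole_cell"]["lower"],
            "roi.mito.lower", "must be >= roi.whole_cell.lower",
        )
        _require(
            d["roi"]["aggregation"] in ("pixel_mean", "pooled_refit"),
            "roi.aggregation", "must be 'pixel_mean' or 'pooled_refit'",
        )
        prev_hi = -np.inf
        for entry in d["categories"]:
            _require(len(entry) == 3, "categories", "entries must be [label, lower, upper]")
            _, lo, hi = entry
            _require(lo < hi and lo >= prev_hi, "categories", "intervals must be increasing and non-overlapping")
            prev_hi = hi
        _require(d["cohort"]["min_rois"] >= 1, "cohort.min_rois", "must be >= 1")
        _require(d["cohort"]["donor_tau_ns"] > 0, "cohort.donor_tau_ns", "must be positive")
        _require(d["render"]["vmax"] > d["render"]["vmin"], "render.vmax", "must exceed render.vmin")

    # typed accessors -------------------------------------------------------

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def time_axis(self) -> TimeAxis:
        a = self.data["axis"]
        return TimeAxis(n_bins=a["n_bins"], period=a["period_ns"])

    def irf(self) -> IRFModel:
        i = self.data["irf"]
        return IRFModel(shape=i["shape"], center=i["center_ns"], fwhm=i["fwhm_ns"])

    def fit_options(self, channel: str) -> FitOptions:
        f = self.data["fit"]
        return FitOptions(
            objective=f["objective"],
            min_photons=float(f["min_photons"].get(channel, 300.0)),
        )

    def roi_config(self, morphology: str) -> ROIConfig:
        r = self.data["roi"][morphology]
        return ROIConfig(
            lower_threshold=float(r["lower"]),
            upper_threshold=float(r["upper"]),
            morphology=morphology,  # type: ignore[arg-type]
            aggregation=self.data["roi"]["aggregation"],
        )

    def category_scheme(self):
        from .cohort import CategoryScheme

        return CategoryScheme(
            intervals=tuple((str(l), float(lo), float(hi)) for l, lo, hi in self.data["categories"])
        )

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> PipelineConfig:
    """Load and validate a YAML pipeline config (defaults when ``path`` is None)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig(raw)
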