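"""2x2-pixel thresholded ROI grids inside segmented cells.

ROIs are non-overlapping 2x2-pixel blocks tiling the field of view from
pixel (0, 0).  A block is kept when all four pixels belong to the same
cell, none is nuclear, and the mean NAD(P)H photon count of the four
pixels lies within [lower_threshold, upper_threshold].  Two threshold
presets give the two morphologies of the assay: a high lower threshold
isolates the photon-dense mitochondrial regions, a low one the complete
cell area minus the nucleus.  FAD and Trp inherit the NAD(P)H-defined
footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .decay import (
    DecayHistogram,
    FitOptions,
    FitResult,
    IRFModel,
    InsufficientPhotonsError,
    TimeAxis,
    fit_biexp,
)

logger = logging.getLogger("flimredox")

__all__ = [
    "PhotonImage",
    "SegmentationMasks",
    "ROIConfig",
    "ROIRecord",
    "generate_roi_grid",
    "dual_morphology_rois",
    "aggregate_roi_parameters",
    "roi_table",
]

ROI_SIZE = 2  # pixels; the assay's fixed block edge

Morphology = Literal["mito", "whole_cell"]
CHANNELS = ("trp", "nadh", "fad")

#: per-channel map columns carried into ROI tables
PARAM_FIELDS = ("a1_pct", "a2_pct", "tau1", "tau2", "tau_m", "chi2")


@dataclass(frozen=True)
class PhotonImage:
    """Per-pixel photon counts for one spectral channel."""

    values: np.ndarray
    channel: str = "nadh"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("photon image must be 2-D")
        if np.any(values < 0):
            raise ValueError("photon counts must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SegmentationMasks:
    """Integer cell labels (0 = background) and a binary nucleus flag."""

    cell_labels: np.ndarray
    nucleus: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.cell_labels)
        nucleus = np.asarray(self.nucleus).astype(bool)
        if labels.shape != nucleus.shape:
            raise ValueError("cell_labels and nucleus masks must share a shape")
        if np.any(labels < 0):
            raise ValueError("cell labels must be non-negative integers")
        object.__setattr__(self, "cell_labels", labels.astype(np.int64))
        object.__setattr__(self, "nucleus", nucleus)


@dataclass(frozen=True)
class ROIConfig:
    """Photon thresholds and aggregation mode for one morphology preset."""

    lower_threshold: float
    upper_threshold: float
    morphology: Morphology = "whole_cell"
    aggregation: Literal["pixel_mean", "pooled_refit"] = "pixel_mean"

    def __post_init__(self) -> None:
        if not 0 <= self.lower_threshold < self.upper_threshold:
            raise ValueError("require 0 <= lower_threshold < upper_threshold")


@dataclass
class ROIRecord:
    """One 2x2-pixel region: identity, footprint, photons and aggregated fit values.

    The pixel block covers rows [2*grid_row, 2*grid_row + 2) and columns
    [2*grid_col, 2*grid_col + 2), half-open, 0-based.
    """

    cell_id: int
    grid_row: int
    grid_col: int
    morphology: Morphology
    photons: dict[str, float] = field(default_factory=dict)
    params: dict[str, dict[str, float]] = field(default_factory=dict)
    valid: bool = True
    note: str = ""

    @property
    def rows(self) -> slice:
        return slice(ROI_SIZE * self.grid_row, ROI_SIZE * (self.grid_row + 1))

    @property
    def cols(self) -> slice:
        return slice(ROI_SIZE * self.grid_col, ROI_SIZE * (self.grid_col + 1))


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, PhotonImage) else np.asarray(image, dtype=float)


def _even_crop(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    if h % 2 or w % 2:
        logger.warning("odd image dimension (%d, %d); trailing row/column ignored", h, w)
    return arr[: h - h % 2, : w - w % 2]


def generate_roi_grid(
    nadh_photons,
    masks: SegmentationMasks,
    config: ROIConfig,
) -> list[ROIRecord]:
    """Emit every 2x2 block passing the cell, nucleus and photon predicates.

    The grid is anchored at pixel (0, 0); membership requires all four
    pixels to share one nonzero cell label, no nuclear pixel, and the mean
    NAD(P)H count within the closed threshold interval.  Output is sorted
    by (cell_id, grid_row, grid_col).
    """
    photons = _values(nadh_photons)
    if photons.shape != masks.cell_labels.shape:
        raise ValueError("photon image and masks dimensions differ")
    if not masks.cell_labels.any():
        logger.warning("empty cell label mask: no ROIs generated")
        return []

    photons = _even_crop(photons)
    labels = _even_crop(masks.cell_labels)
    nucleus = _even_crop(masks.nucleus)
    h2, w2 = photons.shape[0] // ROI_SIZE, photons.shape[1] // ROI_SIZE

    lab_blocks = labels.reshape(h2, ROI_SIZE, w2, ROI_SIZE)
    same_cell = (
        (lab_blocks == lab_blocks[:, :1, :, :1]).all(axis=(1, 3))
        & (lab_blocks[:, 0, :, 0] > 0)
    )
    no_nucleus = ~nucleus.reshape(h2, ROI_SIZE, w2, ROI_SIZE).any(axis=(1, 3))
    mean_photons = photons.reshape(h2, ROI_SIZE, w2, ROI_SIZE).mean(axis=(1, 3))
    in_band = (mean_photons >= config.lower_threshold) & (mean_photons <= config.upper_threshold)

    keep = same_cell & no_nucleus & in_band
    records = [
        ROIRecord(
            cell_id=int(lab_blocks[gy, 0, gx, 0]),
            grid_row=int(gy),
            grid_col=int(gx),
            morphology=config.morphology,
            photons={"nadh": float(mean_photons[gy, gx] * ROI_SIZE * ROI_SIZE)},
        )
        for gy, gx in zip(*np.nonzero(keep))
    ]
    records.sort(key=lambda r: (r.cell_id, r.grid_row, r.grid_col))
    return records


def dual_morphology_rois(
    nadh_photons,
    masks: SegmentationMasks,
    mito_config: ROIConfig,
    wholecell_config: ROIConfig,
) -> tuple[list[ROIRecord], list[ROIRecord]]:
    """ROI sets for both morphologies from one NAD(P)H image.

    Requires the mitochondrial lower threshold at or above the whole-cell
    one, so that (with equal upper thresholds) every mitochondrial ROI is
    also a whole-cell ROI.
    """
    if mito_config.lower_threshold < wholecell_config.lower_threshold:
        raise ValueError(
            "mitochondrial lower threshold must be >= whole-cell lower threshold"
        )
    mito = generate_roi_grid(nadh_photons, masks, mito_config)
    whole = generate_roi_grid(nadh_photons, masks, wholecell_config)
    return mito, whole


def _pixel_mean_aggregate(
    roi: ROIRecord, channel_maps: dict[str, dict[str, np.ndarray]]
) -> None:
    for channel, maps in channel_maps.items():
        photons = maps["photons"][roi.rows, roi.cols].astype(float)
        roi.photons[channel] = float(photons.sum())
        converged = maps.get("converged")
        if converged is not None and not np.all(converged[roi.rows, roi.cols] > 0):
            roi.valid = False
            roi.note = f"unconverged {channel} pixel fit"
            continue
        weights = photons / photons.sum() if photons.sum() > 0 else np.full_like(photons, 0.25)
        agg: dict[str, float] = {}
        for name in PARAM_FIELDS:
            if name not in maps:
                continue
            block = maps[name][roi.rows, roi.cols]
            if np.any(~np.isfinite(block)):
                roi.valid = False
                roi.note = f"unfitted {channel} pixel"
                agg = {}
                break
            agg[name] = float(np.sum(weights * block))
        roi.params[channel] = agg


def _pooled_refit_aggregate(
    roi: ROIRecord,
    cubes: dict[str, np.ndarray],
    irf: IRFModel,
    axis: TimeAxis,
    options_by_channel: dict[str, FitOptions],
) -> None:
    for channel, cube in cubes.items():
        pooled = cube[:, roi.rows, roi.cols].sum(axis=(1, 2))
        roi.photons[channel] = float(pooled.sum())
        hist = DecayHistogram(counts=pooled, axis=axis, channel=channel)
        try:
            fit = fit_biexp(hist, irf, options_by_channel[channel])
        except InsufficientPhotonsError as exc:
            roi.valid = False
            roi.note = f"{channel}: {exc}"
            roi.params[channel] = {}
            continue
        roi.params[channel] = {
            "a1_pct": fit.a1_pct,
            "a2_pct": fit.a2_pct,
            "tau1": fit.params.tau1,
            "tau2": fit.params.tau2,
            "tau_m": fit.tau_m,
            "chi2": fit.chi2_reduced,
        }


def aggregate_roi_parameters(
    rois: Sequence[ROIRecord],
    *,
    channel_maps: dict[str, dict[str, np.ndarray]] | None = None,
    cubes: dict[str, np.ndarray] | None = None,
    irf: IRFModel | None = None,
    axis: TimeAxis | None = None,
    options: FitOptions | dict[str, FitOptions] = FitOptions(),
    mode: Literal["pixel_mean", "pooled_refit"] = "pixel_mean",
) -> list[ROIRecord]:
    """Fill each ROI's per-channel aggregated fit parameters in place.

    ``pixel_mean`` takes the photon-weighted mean of the four per-pixel
    parameter values from fitted maps; ``pooled_refit`` sums the four
    pixel histograms per channel and fits once.  Both preserve
    a1% + a2% = 1.  ROIs with unfitted or unconverged members are flagged
    invalid rather than silently dropped.
    """
    if mode == "pixel_mean":
        if channel_maps is None:
            raise ValueError("pixel_mean aggregation requires fitted channel maps")
        for roi in rois:
            _pixel_mean_aggregate(roi, channel_maps)
    elif mode == "pooled_refit":
        if cubes is None or irf is None or axis is None:
            raise ValueError("pooled_refit aggregation requires cubes, irf and axis")
        if isinstance(options, FitOptions):
            options = {ch: options for ch in cubes}
        for roi in rois:
            _pooled_refit_aggregate(roi, cubes, irf, axis, options)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return list(rois)


def roi_table(rois: Sequence[ROIRecord], fov_id: str = "fov0") -> pd.DataFrame:
    """Flatten aggregated ROIRecords into the canonical tabular layout."""
    rows = []
    for roi in rois:
        row: dict[str, object] = {
            "fov": fov_id,
            "cell_id": roi.cell_id,
            "grid_row": roi.grid_row,
            "grid_col": roi.grid_col,
            "morphology": roi.morphology,
            "valid": roi.valid,
        }
        for channel in CHANNELS:
            row[f"photons_{channel}"] = roi.photons.get(channel, np.nan)
            params = roi.params.get(channel, {})
            for name in PARAM_FIELDS:
                row[f"{channel}_{name}"] = params.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
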