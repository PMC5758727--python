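"""End-to-end orchestration of the synthetic FLIM redox assay.

Chains the stages the command line exposes individually: scene
generation, TCSPC cube simulation, per-ROI decay fitting, redox metrics
and cohort statistics.  Kept separate from the CLI so scripts can run
the identical pipeline programmatically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import cell_summaries, correlate_flirr_e, merge_categories, responder_assignments
from .io import PipelineConfig
from .metrics import DonorReference, build_redox_table
from .roi import aggregate_roi_parameters, dual_morphology_rois, roi_table
from .scene import Scene

logger = logging.getLogger("flimredox")

__all__ = ["analyze_scene", "analyze_scene_pair", "run_cohort"]


def analyze_scene(
    scene: Scene,
    config: PipelineConfig,
    condition: str,
    fov_id: str = "fov0",
    seed: int = 0,
    cubes: dict[str, np.ndarray] | None = None,
    morphologies: tuple[str, ...] = ("mito", "whole_cell"),
) -> pd.DataFrame:
    """ROI-level redox table for one scene (both morphologies).

    Simulates TCSPC cubes for the scene (unless given), thresholds the
    NAD(P)H photon image into mitochondrial and whole-cell 2x2 ROI sets,
    pools and refits each ROI's decays per channel, and attaches the
    redox metrics.  The NAD(P)H photon image used for thresholding is
    the time-summed cube, so thresholds and fits see the same photons.
    """
    axis = config.time_axis()
    irf = config.irf()
    if cubes is None:
        cubes = scene.cubes(irf, axis, seed)
    nadh_photons = cubes["nadh"].sum(axis=0)

    mito_rois, whole_rois = dual_morphology_rois(
        nadh_photons, scene.masks, config.roi_config("mito"), config.roi_config("whole_cell")
    )
    by_morph = {"mito": mito_rois, "whole_cell": whole_rois}
    options = {ch: config.fit_options(ch) for ch in cubes}
    frames = []
    for rois in (by_morph[m] for m in morphologies):
        aggregate_roi_parameters(
            rois, cubes=cubes, irf=irf, axis=axis, options=options, mode="pooled_refit"
        )
        frames.append(roi_table(rois, fov_id=fov_id))
    df = pd.concat(frames, ignore_index=True)
    df = build_redox_table(df, DonorReference(config.data["cohort"]["donor_tau_ns"]))
    df.insert(0, "condition", condition)
    return df


def analyze_scene_pair(
    control: Scene,
    treated: Scene,
    config: PipelineConfig,
    fov_id: str = "fov0",
    seed: int = 0,
) -> pd.DataFrame:
    """Redox tables for a control/treated re-imaging of one field of view."""
    ctrl = analyze_scene(control, config, "control", fov_id, seed=seed)
    rx = analyze_scene(treated, config, "treatment", fov_id, seed=seed + 1)
    return pd.concat([ctrl, rx], ignore_index=True)


def run_cohort(
    redox: pd.DataFrame,
    config: PipelineConfig,
    control: str = "control",
    treatment: str = "treatment",
) -> dict[str, pd.DataFrame]:
    """Cell summaries, responder assignments, pooled categories and correlation."""
    summaries = cell_summaries(redox, min_rois=config.data["cohort"]["min_rois"])
    scheme = config.category_scheme()
    assignments = responder_assignments(summaries, scheme, control, treatment, morphology="mito")
    merged = (
        merge_categories(assignments, redox)
        if len(assignments)
        else pd.DataFrame(columns=["category", "condition", "morphology", "fov", "cell_id", "flirr"])
    )
    correlation = correlate_flirr_e(summaries)
    return {
        "summaries": summaries,
        "assignments": assignments,
        "merged": merged,
        "correlation": correlation,
    }
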