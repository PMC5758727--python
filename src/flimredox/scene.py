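"""Synthetic three-channel FLIM fields of view with known ground truth.

Scenes emulate a monolayer of cells imaged in the Trp / NAD(P)H / FAD
autofluorescence channels: elliptical cells with a concentric nuclear
ellipse, granular mitochondrial blobs in the cytosol, Poisson photon
statistics, and piecewise-constant bi-exponential decay truth per
compartment and channel.  Channel physiology is built in: FAD signal is
(nearly) mitochondria-only, NAD(P)H comes from both mitochondria
(OXPHOS) and cytosol (glycolysis), and the nucleus emits a low NAD(P)H
signal so that mask-based exclusion — not thresholding — must remove it.

A treatment shifts the enzyme-bound fractions per cell (bound NAD(P)H
up, bound FAD down, quenched Trp up, all tied to one per-cell response
multiplier), which makes the true per-cell FLIRR change — and hence the
responder category — known in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from skimage.morphology import dilation, disk

from .decay import BiExpParams, IRFModel, TimeAxis, model_decay
from .roi import SegmentationMasks

logger = logging.getLogger("flimredox")

__all__ = [
    "DecayTruth",
    "CellGeometry",
    "SceneSpec",
    "TreatmentEffect",
    "Scene",
    "make_fov",
    "apply_treatment",
    "response_multiplier_for_change",
]

CHANNELS = ("trp", "nadh", "fad")
COMPARTMENTS = ("nucleus", "cytosol", "mito")

# compartment codes in Scene.compartments
BACKGROUND, NUCLEUS, CYTOSOL, MITO = 0, 1, 2, 3
_COMP_CODE = {"nucleus": NUCLEUS, "cytosol": CYTOSOL, "mito": MITO}

FRACTION_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class DecayTruth:
    """Ground-truth bi-exponential mix for one compartment and channel.

    ``bound`` names which amplitude fraction carries the enzyme-bound
    (or, for Trp, quenched) species: "a2" for NAD(P)H (bound = long
    lifetime), "a1" for FAD and Trp (bound/quenched = short lifetime).
    """

    tau1: float
    tau2: float
    a1_pct: float
    bound: str = "a2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a1_pct <= 1.0:
            raise ValueError("a1_pct must lie in [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0 or self.tau1 > self.tau2:
            raise ValueError("require 0 < tau1 <= tau2")

    @property
    def a2_pct(self) -> float:
        return 1.0 - self.a1_pct

    @property
    def bound_fraction(self) -> float:
        return self.a1_pct if self.bound == "a1" else self.a2_pct

    def with_bound_fraction(self, value: float) -> "DecayTruth":
        clipped = float(np.clip(value, *FRACTION_CLIP))
        if clipped != value:
            logger.info("bound fraction %.3f clipped to %.3f", value, clipped)
        a1 = clipped if self.bound == "a1" else 1.0 - clipped
        return replace(self, a1_pct=a1)

    @property
    def tau_m(self) -> float:
        return self.tau1 * self.a1_pct + self.tau2 * self.a2_pct


# synthetic lifetime conventions (ns), order-of-magnitude literature values:
# NAD(P)H free 0.4 / bound 2.5; FAD bound-short 0.3 / 2.8; Trp quenched 1.0 /
# unquenched 3.1.  Bound fractions are the metabolically meaningful dials.
DEFAULT_TRUTHS: dict[str, dict[str, DecayTruth]] = {
    "mito": {
        "nadh": DecayTruth(tau1=0.4, tau2=2.5, a1_pct=0.70, bound="a2"),
        "fad": DecayTruth(tau1=0.3, tau2=2.8, a1_pct=0.60, bound="a1"),
        "trp": DecayTruth(tau1=1.0, tau2=3.1, a1_pct=0.30, bound="a1"),
    },
    "cytosol": {
        "nadh": DecayTruth(tau1=0.4, tau2=2.5, a1_pct=0.80, bound="a2"),
        "fad": DecayTruth(tau1=0.3, tau2=2.8, a1_pct=0.60, bound="a1"),
        "trp": DecayTruth(tau1=1.0, tau2=3.1, a1_pct=0.30, bound="a1"),
    },
    "nucleus": {
        "nadh": DecayTruth(tau1=0.4, tau2=2.5, a1_pct=0.75, bound="a2"),
        "fad": DecayTruth(tau1=0.3, tau2=2.8, a1_pct=0.60, bound="a1"),
        "trp": DecayTruth(tau1=1.0, tau2=3.1, a1_pct=0.30, bound="a1"),
    },
}

# expected photons per pixel; FAD outside mitochondria is ~0 (a tenth of the
# mitochondrial signal) so the channel remains effectively mitochondrial
DEFAULT_BRIGHTNESS: dict[str, dict[str, float]] = {
    "mito": {"nadh": 400.0, "fad": 300.0, "trp": 150.0},
    "cytosol": {"nadh": 80.0, "fad": 30.0, "trp": 100.0},
    "nucleus": {"nadh": 20.0, "fad": 15.0, "trp": 50.0},
}


@dataclass(frozen=True)
class CellGeometry:
    """One elliptical cell with a concentric elliptical nucleus."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (row, col) in pixels
    orientation: float  # radians
    nucleus_scale: float = 0.4


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to generate one reproducible field of view."""

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 5
    cell_axis_range: tuple[float, float] = (18.0, 30.0)
    nucleus_scale: float = 0.4
    # blob texture must be resolvable at the 2x2-pixel ROI scale, mirroring
    # perinuclear mitochondrial aggregates rather than sub-pixel granularity
    mito_density: float = 0.02  # fraction of cytosol pixels seeding blobs
    mito_dilation: int = 2  # disk radius for blob growth
    brightness: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_BRIGHTNESS
    )
    truths: Mapping[str, Mapping[str, DecayTruth]] = field(
        default_factory=lambda: DEFAULT_TRUTHS
    )
    background_brightness: float = 0.5
    #: acquisition-depth multiplier on every compartment brightness; raise it
    #: to emulate longer dwell / higher excitation at fixed thresholds-per-unit
    exposure: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class TreatmentEffect:
    """Bound-fraction shifts applied per cell, scaled by a response multiplier.

    Each cell draws multiplier m_i ~ Normal(1, spread) (or is handed one
    explicitly); its deltas are m_i times the base deltas.  Post-effect
    fractions are clipped to [0.01, 0.99] with clipping logged.  The
    optional brightness factors emulate the intensity changes of the
    classical redox response (NAD(P)H photons down, FAD photons up under
    increased OXPHOS); they default to no change.
    """

    d_nadh_bound_mito: float = 0.10
    d_nadh_bound_cyto: float = 0.10
    d_fad_bound_mito: float = -0.08
    d_trp_quench: float = 0.12
    spread: float = 0.10
    nadh_brightness_factor: float = 1.0
    fad_brightness_factor: float = 1.0


@dataclass
class Scene:
    """A generated field of view plus its full ground truth."""

    spec: SceneSpec
    cells: dict[int, CellGeometry]
    masks: SegmentationMasks
    compartments: np.ndarray  # per-pixel code: 0 bg, 1 nucleus, 2 cytosol, 3 mito
    truths: dict[int, dict[str, dict[str, DecayTruth]]]  # cell -> compartment -> channel
    brightness: dict[int, dict[str, dict[str, float]]]
    photons: dict[str, np.ndarray]
    cell_multipliers: dict[int, float] = field(default_factory=dict)

    @property
    def mito_mask(self) -> np.ndarray:
        return self.compartments == MITO

    def true_flirr(self, cell_id: int, compartment: str) -> float:
        """Closed-form compartment FLIRR: NAD(P)H a2% over FAD a1%."""
        t = self.truths[cell_id][compartment]
        return t["nadh"].a2_pct / t["fad"].a1_pct

    def true_trp_e_pct(self, cell_id: int, compartment: str, tau_d: float = 3.1) -> float:
        return (1.0 - self.truths[cell_id][compartment]["trp"].tau_m / tau_d) * 100.0

    def true_parameter_maps(self, channel: str) -> dict[str, np.ndarray]:
        """Per-pixel ground-truth maps in the fitted-map layout (NaN outside cells)."""
        shape = self.compartments.shape
        maps = {
            name: np.full(shape, np.nan)
            for name in ("a1_pct", "a2_pct", "tau1", "tau2", "tau_m", "chi2")
        }
        maps["photons"] = self.photons[channel].astype(float)
        maps["converged"] = np.zeros(shape)
        labels = self.masks.cell_labels
        for cell_id in self.cells:
            for comp, code in _COMP_CODE.items():
                sel = (labels == cell_id) & (self.compartments == code)
                if not sel.any():
                    continue
                t = self.truths[cell_id][comp][channel]
                maps["a1_pct"][sel] = t.a1_pct
                maps["a2_pct"][sel] = t.a2_pct
                maps["tau1"][sel] = t.tau1
                maps["tau2"][sel] = t.tau2
                maps["tau_m"][sel] = t.tau_m
                maps["chi2"][sel] = 1.0
                maps["converged"][sel] = 1.0
        return maps

    def cubes(
        self, irf: IRFModel, axis: TimeAxis, seed: int | np.random.Generator
    ) -> dict[str, np.ndarray]:
        """Poisson TCSPC cubes (time, y, x) consistent with the scene truth.

        Each pixel's mean decay is the compartment truth scaled to the
        compartment brightness; background pixels carry a flat mean.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        h, w = self.compartments.shape
        labels = self.masks.cell_labels
        cubes: dict[str, np.ndarray] = {}
        for channel in CHANNELS:
            mean = np.empty((axis.n_bins, h, w))
            mean[:] = self.spec.exposure * self.spec.background_brightness / axis.n_bins
            for cell_id in self.cells:
                for comp, code in _COMP_CODE.items():
                    sel = (labels == cell_id) & (self.compartments == code)
                    if not sel.any():
                        continue
                    t = self.truths[cell_id][comp][channel]
                    shape_vec = model_decay(
                        BiExpParams(a1=t.a1_pct, a2=t.a2_pct, tau1=t.tau1, tau2=t.tau2),
                        irf,
                        axis,
                    )
                    bright = self.spec.exposure * self.brightness[cell_id][comp][channel]
                    mean[:, sel] = (shape_vec * (bright / shape_vec.sum()))[:, None]
            cubes[channel] = rng.poisson(mean).astype(np.int32)
        return cubes


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _ellipse_mask(shape: tuple[int, int], geom: CellGeometry, scale: float = 1.0) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - geom.center[0]
    dx = xx - geom.center[1]
    c, s = np.cos(geom.orientation), np.sin(geom.orientation)
    u = c * dy + s * dx
    v = -s * dy + c * dx
    ry, rx = geom.axes[0] * scale, geom.axes[1] * scale
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _place_cells(spec: SceneSpec, rng: np.random.Generator, max_tries: int = 2000) -> dict[int, CellGeometry]:
    h, w = spec.shape
    lo, hi = spec.cell_axis_range
    cells: dict[int, CellGeometry] = {}
    occupied = np.zeros(spec.shape, dtype=bool)
    tries = 0
    while len(cells) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in {spec.shape} "
                f"after {max_tries} attempts"
            )
        axes = tuple(rng.uniform(lo, hi, size=2))
        margin = max(axes) + 2
        if 2 * margin >= min(h, w):
            raise RuntimeError("cell axes too large for the field of view")
        center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        geom = CellGeometry(
            center=center,
            axes=axes,  # type: ignore[arg-type]
            orientation=rng.uniform(0, np.pi),
            nucleus_scale=spec.nucleus_scale,
        )
        mask = _ellipse_mask(spec.shape, geom, scale=1.1)  # keep a small gap between cells
        if (mask & occupied).any():
            continue
        occupied |= mask
        cells[len(cells) + 1] = geom
    return cells


def _mito_mask(cyto: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    seeds = np.zeros_like(cyto)
    idx = np.flatnonzero(cyto)
    if len(idx) == 0 or spec.mito_density <= 0:
        return seeds
    n_seeds = max(int(spec.mito_density * len(idx)), 1)
    chosen = rng.choice(idx, size=n_seeds, replace=False)
    seeds.flat[chosen] = True
    blobs = dilation(seeds, disk(spec.mito_dilation))
    return blobs & cyto


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def make_fov(spec: SceneSpec) -> Scene:
    """Generate one field of view; bit-reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)

    labels = np.zeros(spec.shape, dtype=np.int64)
    compartments = np.zeros(spec.shape, dtype=np.int8)
    nucleus = np.zeros(spec.shape, dtype=bool)
    for cell_id, geom in cells.items():
        body = _ellipse_mask(spec.shape, geom)
        nuc = _ellipse_mask(spec.shape, geom, scale=geom.nucleus_scale)
        labels[body] = cell_id
        nucleus |= nuc
        cyto = body & ~nuc
        mito = _mito_mask(cyto, spec, rng)
        compartments[nuc] = NUCLEUS
        compartments[cyto & ~mito] = CYTOSOL
        compartments[mito] = MITO

    truths = {
        cell_id: {comp: dict(spec.truths[comp]) for comp in COMPARTMENTS}
        for cell_id in cells
    }
    brightness = {
        cell_id: {comp: dict(spec.brightness[comp]) for comp in COMPARTMENTS}
        for cell_id in cells
    }

    scene = Scene(
        spec=spec,
        cells=cells,
        masks=SegmentationMasks(cell_labels=labels, nucleus=nucleus),
        compartments=compartments,
        truths=truths,
        brightness=brightness,
        photons={},
    )
    scene.photons = _draw_photons(scene, rng)
    return scene


def _draw_photons(scene: Scene, rng: np.random.Generator) -> dict[str, np.ndarray]:
    h, w = scene.compartments.shape
    labels = scene.masks.cell_labels
    photons: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        mean = np.full((h, w), scene.spec.background_brightness)
        for cell_id in scene.cells:
            for comp, code in _COMP_CODE.items():
                sel = (labels == cell_id) & (scene.compartments == code)
                mean[sel] = scene.brightness[cell_id][comp][channel]
        photons[channel] = rng.poisson(scene.spec.exposure * mean).astype(np.int64)
    return photons


# ---------------------------------------------------------------------------
# treatment
# ---------------------------------------------------------------------------


def response_multiplier_for_change(
    truth: Mapping[str, Mapping[str, DecayTruth]],
    effect: TreatmentEffect,
    target_change_pct: float,
) -> float:
    """Per-cell multiplier m giving an exact true mitochondrial FLIRR change.

    With bound-fraction deltas linear in m, the FLIRR change is a Möbius
    function of m and the required multiplier has the closed form
    m = c·a2·af / (dn·af − (1+c)·a2·df) where c is the fractional change,
    a2/af the control bound fractions and dn/df the NAD(P)H/FAD deltas.
    """
    c = target_change_pct / 100.0
    a2 = truth["mito"]["nadh"].a2_pct
    af = truth["mito"]["fad"].a1_pct
    dn = effect.d_nadh_bound_mito
    df = effect.d_fad_bound_mito
    denom = dn * af - (1.0 + c) * a2 * df
    if denom <= 0:
        raise ValueError("effect deltas cannot reach the requested change")
    return c * a2 * af / denom


def apply_treatment(
    scene: Scene,
    effect: TreatmentEffect,
    seed: int,
    multipliers: Mapping[int, float] | None = None,
) -> Scene:
    """Return the treated re-imaging of the same field of view.

    Geometry and masks are shared with the control scene (identical FoV);
    each cell realises its own response multiplier — drawn from
    Normal(1, effect.spread) unless supplied — and new Poisson photon
    images are drawn.  The realised multipliers are recorded on the
    returned scene; true per-cell FLIRR changes follow from them exactly.
    """
    rng = np.random.default_rng(seed)
    realized: dict[int, float] = {}
    new_truths: dict[int, dict[str, dict[str, DecayTruth]]] = {}
    new_brightness: dict[int, dict[str, dict[str, float]]] = {}
    for cell_id in scene.cells:
        m = (
            float(multipliers[cell_id])
            if multipliers is not None
            else float(rng.normal(1.0, effect.spread))
        )
        realized[cell_id] = m
        t = scene.truths[cell_id]
        nt = {comp: dict(t[comp]) for comp in COMPARTMENTS}
        nt["mito"]["nadh"] = t["mito"]["nadh"].with_bound_fraction(
            t["mito"]["nadh"].bound_fraction + m * effect.d_nadh_bound_mito
        )
        nt["cytosol"]["nadh"] = t["cytosol"]["nadh"].with_bound_fraction(
            t["cytosol"]["nadh"].bound_fraction + m * effect.d_nadh_bound_cyto
        )
        nt["mito"]["fad"] = t["mito"]["fad"].with_bound_fraction(
            t["mito"]["fad"].bound_fraction + m * effect.d_fad_bound_mito
        )
        for comp in COMPARTMENTS:
            nt[comp]["trp"] = t[comp]["trp"].with_bound_fraction(
                t[comp]["trp"].bound_fraction + m * effect.d_trp_quench
            )
        new_truths[cell_id] = nt
        nb = {comp: dict(scene.brightness[cell_id][comp]) for comp in COMPARTMENTS}
        for comp in COMPARTMENTS:
            nb[comp]["nadh"] *= effect.nadh_brightness_factor
            nb[comp]["fad"] *= effect.fad_brightness_factor
        new_brightness[cell_id] = nb

    treated = Scene(
        spec=scene.spec,
        cells=scene.cells,
        masks=scene.masks,
        compartments=scene.compartments,
        truths=new_truths,
        brightness=new_brightness,
        photons={},
        cell_multipliers=realized,
    )
    treated.photons = _draw_photons(treated, rng)
    return treated
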