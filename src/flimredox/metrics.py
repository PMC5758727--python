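"""Metabolic readouts per ROI: FLIRR, intensity redox ratio, Trp FRET efficiency.

FLIRR (fluorescence lifetime redox ratio) is the enzyme-bound NAD(P)H
fraction over the enzyme-bound FAD fraction, NAD(P)H-a2% / FAD-a1%.  It
rises with oxidative-phosphorylation activity and, being built from
intensity-normalised fractions, is insensitive to photon-throughput
artefacts (scattering, attenuation, illumination drift) that confound
the classical Chance-style intensity ratio FAD / NAD(P)H.

Tryptophan acts as a FRET donor quenched by enzyme-bound NAD(P)H; the
transfer efficiency follows from the amplitude-weighted donor lifetime,
E% = (1 - tau_m / tau_D) * 100 with tau_D = 3.1 ns for free Trp in
solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("flimredox")

__all__ = [
    "DonorReference",
    "flirr",
    "intensity_redox_ratio",
    "fret_efficiency",
    "flirr_map",
    "build_redox_table",
]

TRP_DONOR_LIFETIME_NS = 3.1  # unquenched tryptophan in solution


@dataclass(frozen=True)
class DonorReference:
    """Unquenched donor lifetime used for FRET efficiency (ns)."""

    tau_d: float = TRP_DONOR_LIFETIME_NS

    def __post_init__(self) -> None:
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")


def flirr(nadh_a2_pct: float, fad_a1_pct: float) -> float:
    """Lifetime redox ratio NAD(P)H-a2% / FAD-a1%.

    Strictly increasing in the bound NAD(P)H fraction and strictly
    decreasing in the bound FAD fraction — the two shifts that OXPHOS
    activity drives in opposite directions.
    """
    if not (0 <= nadh_a2_pct <= 1) or not (0 <= fad_a1_pct <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if fad_a1_pct == 0:
        raise ZeroDivisionError("FAD a1% is zero; FLIRR undefined")
    return nadh_a2_pct / fad_a1_pct


def intensity_redox_ratio(fad_photons: float, nadh_photons: float) -> float:
    """Classical intensity redox ratio FAD / NAD(P)H on one ROI footprint."""
    if nadh_photons <= 0:
        raise ZeroDivisionError("no NAD(P)H photons; intensity ratio undefined")
    if fad_photons < 0:
        raise ValueError("photon counts must be non-negative")
    return fad_photons / nadh_photons


def fret_efficiency(trp_tau_m: float, ref: DonorReference = DonorReference()) -> float:
    """FRET efficiency in percent from donor lifetime quenching.

    E% = (1 - tau_m / tau_D) * 100.  Values are returned as computed;
    a negative E% (tau_m exceeding the donor reference) signals
    miscalibration and is flagged downstream, never clipped.
    """
    if trp_tau_m <= 0:
        raise ValueError("trp tau_m must be positive")
    return (1.0 - trp_tau_m / ref.tau_d) * 100.0


def flirr_map(nadh_a2_pct_map: np.ndarray, fad_a1_pct_map: np.ndarray) -> np.ndarray:
    """Per-pixel FLIRR image; pixels lacking either fit are NaN."""
    nadh = np.asarray(nadh_a2_pct_map, dtype=float)
    fad = np.asarray(fad_a1_pct_map, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError("map shapes differ")
    out = np.full(nadh.shape, np.nan)
    ok = np.isfinite(nadh) & np.isfinite(fad) & (fad > 0)
    out[ok] = nadh[ok] / fad[ok]
    return out


def build_redox_table(
    roi_df: pd.DataFrame, donor: DonorReference = DonorReference()
) -> pd.DataFrame:
    """Attach FLIRR, intensity ratio, Trp tau_m and E% to an ROI table.

    Adds one validity flag per metric: a zero FAD bound fraction or zero
    NAD(P)H photons marks the corresponding ratio invalid (NaN in the
    value column) instead of emitting infinities; a negative E% keeps its
    value but clears ``e_pct_valid``.
    """
    df = roi_df.copy()

    fad_a1 = df["fad_a1_pct"].to_numpy(dtype=float)
    nadh_a2 = df["nadh_a2_pct"].to_numpy(dtype=float)
    flirr_valid = np.isfinite(fad_a1) & np.isfinite(nadh_a2) & (fad_a1 > 0)
    df["flirr"] = np.where(flirr_valid, nadh_a2 / np.where(fad_a1 > 0, fad_a1, 1.0), np.nan)
    df["flirr_valid"] = flirr_valid

    nadh_ph = df["photons_nadh"].to_numpy(dtype=float)
    fad_ph = df["photons_fad"].to_numpy(dtype=float)
    ratio_valid = np.isfinite(nadh_ph) & (nadh_ph > 0) & np.isfinite(fad_ph)
    df["intensity_ratio"] = np.where(
        ratio_valid, fad_ph / np.where(nadh_ph > 0, nadh_ph, 1.0), np.nan
    )
    df["intensity_ratio_valid"] = ratio_valid

    trp_tau_m = df["trp_tau_m"].to_numpy(dtype=float)
    tau_valid = np.isfinite(trp_tau_m) & (trp_tau_m > 0)
    e_pct = np.where(tau_valid, (1.0 - trp_tau_m / donor.tau_d) * 100.0, np.nan)
    df["trp_e_pct"] = e_pct
    df["e_pct_valid"] = tau_valid & (e_pct >= 0)
    n_neg = int(np.sum(tau_valid & (e_pct < 0)))
    if n_neg:
        logger.warning("%d ROIs with negative E%% (tau_m > donor reference); flagged", n_neg)
    return df
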