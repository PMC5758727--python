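"""Cell-level aggregation, responder categorization and cohort statistics.

ROI-level redox records are reduced to per-cell medians (the median, not
the mean, is the cell statistic throughout — it is robust to the skewed
per-cell ROI distributions the 2x2 assay produces).  Each cell's percent
median change of FLIRR from control to treatment assigns it to a
responder category (low / medium / high by default); categories pool ROI
values across fields of view for frequency distributions, per-cell FLIRR
vs E% correlation, and the mitochondrial-vs-whole-cell comparison that
attributes the whole-cell excess response to cytosolic glycolysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("flimredox")

__all__ = [
    "CategoryScheme",
    "ResponderAssignment",
    "percent_median_change",
    "categorize",
    "cell_summaries",
    "responder_assignments",
    "merge_categories",
    "frequency_distribution",
    "correlate_flirr_e",
    "glycolysis_attribution",
]

UNCATEGORIZED = "uncategorized"

#: example three-category scheme (percent median FLIRR change boundaries)
EXAMPLE_CATEGORY_RANGES = (
    ("Category1", 25.0, 55.0),
    ("Category2", 55.0, 85.0),
    ("Category3", 85.0, 125.0),
)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered responder categories over percent-change intervals.

    Intervals are half-open [lower, upper); the last interval is closed
    at its upper bound so shared endpoints resolve deterministically.
    Values outside every interval map to ``uncategorized``.
    """

    intervals: tuple[tuple[str, float, float], ...] = EXAMPLE_CATEGORY_RANGES

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.intervals]
        if len(set(labels)) != len(labels):
            raise ValueError("category labels must be unique")
        prev_hi = -np.inf
        for label, lo, hi in self.intervals:
            if lo >= hi:
                raise ValueError(f"{label}: lower bound must be below upper bound")
            if lo < prev_hi:
                raise ValueError(f"{label}: intervals overlap or are out of order")
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.intervals)

    def assign(self, change_pct: float) -> str:
        for i, (label, lo, hi) in enumerate(self.intervals):
            last = i == len(self.intervals) - 1
            if lo <= change_pct < hi or (last and change_pct == hi):
                return label
        return UNCATEGORIZED

    @classmethod
    def tertiles(cls, changes: Sequence[float], labels: Sequence[str] | None = None) -> "CategoryScheme":
        """Equal-count scheme derived from the observed changes."""
        changes = np.asarray(changes, dtype=float)
        if len(changes) < 3:
            raise ValueError("need at least 3 cells for tertile boundaries")
        labels = tuple(labels) if labels else ("Category1", "Category2", "Category3")
        qs = np.quantile(changes, [0.0, 1 / 3, 2 / 3, 1.0])
        # widen the outer edges a hair so min/max cells stay categorized
        qs[0] -= 1e-9
        qs[-1] += 1e-9
        intervals = tuple(
            (labels[i], float(qs[i]), float(qs[i + 1])) for i in range(3)
        )
        return cls(intervals=intervals)


@dataclass(frozen=True)
class ResponderAssignment:
    """A cell's percent median change and the category it falls in."""

    fov_id: str
    cell_id: int
    change_pct: float
    category: str


def percent_median_change(ctrl_median: float, rx_median: float) -> float:
    """Percent change of the per-cell median from control to treatment."""
    if ctrl_median <= 0:
        raise ValueError("control median must be positive")
    return 100.0 * (rx_median - ctrl_median) / ctrl_median


def categorize(change_pct: float, scheme: CategoryScheme) -> str:
    """Category label for a percent change (``uncategorized`` outside all bands)."""
    return scheme.assign(change_pct)


def cell_summaries(
    redox_df: pd.DataFrame,
    min_rois: int = 5,
) -> pd.DataFrame:
    """Per-cell medians (and means) of FLIRR and E% by condition and morphology.

    Cells contributing fewer than ``min_rois`` valid ROIs are excluded
    and logged.  Input is a redox table with one row per ROI carrying
    fov, cell_id, condition, morphology, flirr and trp_e_pct columns.
    """
    df = redox_df
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df[df["flirr_valid"] & np.isfinite(df["flirr"])]
    keys = ["fov", "cell_id", "condition", "morphology"]
    grouped = df.groupby(keys, sort=True)
    out = grouped.agg(
        median_flirr=("flirr", "median"),
        mean_flirr=("flirr", "mean"),
        median_e_pct=("trp_e_pct", "median"),
        mean_e_pct=("trp_e_pct", "mean"),
        median_intensity_ratio=("intensity_ratio", "median"),
        n_rois=("flirr", "size"),
    ).reset_index()
    small = out["n_rois"] < min_rois
    for _, row in out[small].iterrows():
        logger.info(
            "cell %s/%s (%s, %s) excluded: %d ROIs < minimum %d",
            row["fov"], row["cell_id"], row["condition"], row["morphology"],
            row["n_rois"], min_rois,
        )
    return out[~small].reset_index(drop=True)


def responder_assignments(
    summaries: pd.DataFrame,
    scheme: CategoryScheme,
    control: str,
    treatment: str,
    morphology: str = "mito",
) -> pd.DataFrame:
    """Assign each cell a responder category from its FLIRR median change.

    Control and treatment rows join on (fov, cell_id) — the assay re-images
    the same field of view, so each cell is its own control.  The change is
    computed on the stated morphology (mitochondrial data is the paper-style
    basis for categorization).
    """
    sub = summaries[summaries["morphology"] == morphology]
    ctrl = sub[sub["condition"] == control].set_index(["fov", "cell_id"])
    rx = sub[sub["condition"] == treatment].set_index(["fov", "cell_id"])
    rows = []
    for key in ctrl.index.intersection(rx.index):
        ctrl_median = ctrl.loc[key, "median_flirr"]
        if ctrl_median <= 0:
            logger.info("cell %s excluded: non-positive control median", key)
            continue
        change = percent_median_change(ctrl_median, rx.loc[key, "median_flirr"])
        rows.append(
            {
                "fov": key[0],
                "cell_id": key[1],
                "change_pct": change,
                "category": scheme.assign(change),
            }
        )
    return pd.DataFrame(rows, columns=["fov", "cell_id", "change_pct", "category"])


def merge_categories(
    assignments: pd.DataFrame,
    redox_df: pd.DataFrame,
    value: str = "flirr",
) -> pd.DataFrame:
    """Pool ROI values across fields of view within each responder category.

    Returns one row per ROI of a categorized cell, keyed by (category,
    condition, morphology); total pooled ROI counts equal the ROI count
    of all categorized cells, and no ROI lands in two categories.
    """
    cat = assignments[assignments["category"] != UNCATEGORIZED]
    merged = redox_df.merge(cat[["fov", "cell_id", "category"]], on=["fov", "cell_id"])
    cols = ["category", "condition", "morphology", "fov", "cell_id", value]
    return merged[cols].sort_values(["category", "condition", "morphology"]).reset_index(drop=True)


def frequency_distribution(values: Sequence[float], bin_edges: Sequence[float]) -> pd.DataFrame:
    """Histogram table over half-open bins [e_i, e_{i+1}), last bin closed.

    A value on an interior edge counts toward the right-hand bin; the
    ``frequency`` column normalises counts by the number of in-range
    values (zero-safe for empty input).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    vals = np.asarray(list(values), dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / total if total else np.zeros_like(counts, dtype=float),
        }
    )


def correlate_flirr_e(
    summaries: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    morphology: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of per-cell median FLIRR vs median E%.

    Pairs are per-cell (median FLIRR, median E%) pooled across the stated
    conditions, computed separately per morphology.  Degenerate inputs
    (fewer than 3 pairs or zero variance) yield a flagged NaN row rather
    than an exception.
    """
    df = summaries
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    if morphology is not None:
        df = df[df["morphology"] == morphology]
    rows = []
    for morph, sub in df.groupby("morphology"):
        x = sub["median_flirr"].to_numpy(dtype=float)
        y = sub["median_e_pct"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"morphology": morph, "n": len(x), "pearson_r": np.nan, "valid": False})
            continue
        r, _ = stats.pearsonr(x, y)
        rows.append({"morphology": morph, "n": len(x), "pearson_r": float(r), "valid": True})
    return pd.DataFrame(rows)


def glycolysis_attribution(
    mito_change_pct: float,
    wholecell_change_pct: float,
    margin: float = 5.0,
) -> tuple[float, str]:
    """Attribute the whole-cell excess over the mitochondrial response to glycolysis.

    FAD is exclusively mitochondrial and NAD(P)H reports both OXPHOS and
    cytosolic glycolysis, so when the whole-cell percent median change
    exceeds the mitochondrial one, the increment reflects glycolytic
    NAD(P)H binding.  Returns the increment in percentage points and a
    qualitative call: ``glycolysis-responsive`` beyond ``margin`` points,
    ``OXPHOS-driven`` within it.
    """
    increment = wholecell_change_pct - mito_change_pct
    call = "glycolysis-responsive" if increment > margin else "OXPHOS-driven"
    return increment, call
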