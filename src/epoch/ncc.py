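"""Quantification of nucleocytoplasmic compartmentalization (NCC).

Per-cell readouts from a two-channel reporter field (nuclear mCherry,
cytoplasmic eGFP): segmentation into nucleus and cytoplasm, Pearson
colocalization of the channels over each cell, cross-sectional intensity
profiles, cytoplasmic mean intensities, cytoplasmic puncta counts, the
Z-factor screening-window statistic, and condition-level comparisons
(pairwise Welch t-tests or one-way ANOVA with Bonferroni-corrected
pairwise follow-ups).

Colocalization convention: Pearson r is computed per cell over the union
of its nucleus and cytoplasm pixels on raw intensities, and aggregated
as mean +/- SD per condition.  Healthy cells (separated channels) score
negative; cells whose mCherry has relocated into eGFP-rich cytoplasmic
puncta score higher — the statistic that separates senescent from
quiescent populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, remove_small_objects, white_tophat
from skimage.segmentation import watershed

__all__ = [
    "SegmentationResult",
    "ColocalizationTable",
    "ScreenResult",
    "segment_field",
    "pearson_colocalization",
    "line_profile",
    "cytoplasmic_intensity",
    "count_puncta",
    "z_factor",
    "compare_conditions",
]


@dataclass
class SegmentationResult:
    """Per-cell nucleus and cytoplasm label maps (label 0 = background)."""

    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    cell_ids: list[int]

    def cell_mask(self, cell_id: int, compartment: str = "both") -> np.ndarray:
        if cell_id not in self.cell_ids:
            raise KeyError(f"unknown cell id {cell_id}")
        nuc = self.nucleus_labels == cell_id
        cyt = self.cytoplasm_labels == cell_id
        if compartment == "nucleus":
            return nuc
        if compartment == "cytoplasm":
            return cyt
        if compartment == "both":
            return nuc | cyt
        raise ValueError(f"unknown compartment {compartment!r}")


@dataclass
class ColocalizationTable:
    """Per-cell colocalization readouts for one condition.

    ``cells`` has columns cell_id, pearson_r, n_pixels,
    cytoplasmic_egfp_mean, cytoplasmic_mcherry_puncta, valid.  Cells with
    zero channel variance are flagged invalid (r = NaN) and excluded from
    aggregates.
    """

    cells: pd.DataFrame
    condition: str = ""

    @property
    def valid_r(self) -> np.ndarray:
        ok = self.cells["valid"].to_numpy(dtype=bool)
        return self.cells.loc[ok, "pearson_r"].to_numpy(dtype=float)


@dataclass
class ScreenResult:
    """Condition-level summary of a colocalization screen."""

    summary: pd.DataFrame
    pairwise: pd.DataFrame
    method: str
    anova_F: float | None = None
    anova_p: float | None = None
    z_factor: float | None = field(default=None)


def segment_field(
    mcherry: np.ndarray,
    egfp: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    min_nucleus_area: int = 20,
    peak_min_distance: int = 7,
) -> SegmentationResult:
    """Segment cells from the two channels without ground truth.

    Nuclei are detected on the smoothed mCherry channel (nuclear by
    construction in non-senescent cells) by Otsu thresholding and a
    distance-transform watershed to split touching nuclei; whole cells
    come from a watershed of the combined-channel foreground seeded by
    the nuclei; the cytoplasm is the cell region minus its nucleus.
    An all-background image yields zero cells.  Deterministic.
    """
    mcherry = np.asarray(mcherry, dtype=float)
    egfp = np.asarray(egfp, dtype=float)
    if mcherry.shape != egfp.shape:
        raise ValueError("channel shapes differ")
    if mcherry.size == 0:
        raise ValueError("empty image")

    empty = SegmentationResult(
        nucleus_labels=np.zeros(mcherry.shape, dtype=np.int32),
        cytoplasm_labels=np.zeros(mcherry.shape, dtype=np.int32),
        cell_ids=[],
    )

    sm_nuc = gaussian(mcherry, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(sm_nuc) == 0:
        return empty
    nuc_mask = sm_nuc > threshold_otsu(sm_nuc)
    nuc_mask = remove_small_objects(nuc_mask, max_size=min_nucleus_area - 1)
    if not nuc_mask.any():
        return empty

    # split touching nuclei on the distance transform
    dist = ndi.distance_transform_edt(nuc_mask)
    peaks = peak_local_max(
        dist, min_distance=peak_min_distance, labels=nuc_mask, exclude_border=False
    )
    markers = np.zeros(nuc_mask.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        markers, _ = ndi.label(nuc_mask)
    nuc_labels = watershed(-dist, markers, mask=nuc_mask).astype(np.int32)

    sm_sum = gaussian(mcherry + egfp, sigma=smooth_sigma, preserve_range=True)
    fg = sm_sum > threshold_otsu(sm_sum)
    fg |= nuc_mask
    cells = watershed(-sm_sum, nuc_labels, mask=fg).astype(np.int32)
    cyt_labels = np.where(nuc_labels > 0, 0, cells).astype(np.int32)

    ids = sorted(set(np.unique(nuc_labels)) & set(np.unique(cyt_labels)) - {0})
    keep = np.isin(nuc_labels, ids)
    nuc_labels = np.where(keep, nuc_labels, 0)
    keep = np.isin(cyt_labels, ids)
    cyt_labels = np.where(keep, cyt_labels, 0)
    return SegmentationResult(nuc_labels, cyt_labels, [int(i) for i in ids])


def pearson_colocalization(
    mcherry: np.ndarray,
    egfp: np.ndarray,
    segmentation: SegmentationResult,
    *,
    condition: str = "",
    spot_threshold: float | None = None,
    min_spot_area: int = 2,
) -> ColocalizationTable:
    """Per-cell Pearson correlation of the two channels.

    r is computed over the union of each cell's nucleus and cytoplasm
    pixels.  Cells whose region has fewer than two pixels or zero
    variance in either channel are flagged invalid.  When
    ``spot_threshold`` is given, cytoplasmic mCherry puncta are counted
    per cell as well.
    """
    mcherry = np.asarray(mcherry, dtype=float)
    egfp = np.asarray(egfp, dtype=float)
    if mcherry.shape != segmentation.nucleus_labels.shape:
        raise ValueError("segmentation does not match channel shape")
    rows = []
    for cid in segmentation.cell_ids:
        mask = segmentation.cell_mask(cid, "both")
        a = mcherry[mask]
        b = egfp[mask]
        valid = a.size >= 2 and a.std() > 0 and b.std() > 0
        r = float(np.corrcoef(a, b)[0, 1]) if valid else np.nan
        cyt = segmentation.cell_mask(cid, "cytoplasm")
        cyt_egfp = float(egfp[cyt].mean()) if cyt.any() else np.nan
        n_puncta = (
            count_puncta(
                mcherry, segmentation, cid, spot_threshold, min_area=min_spot_area
            )
            if spot_threshold is not None
            else np.nan
        )
        rows.append(
            {
                "cell_id": cid,
                "pearson_r": r,
                "n_pixels": int(a.size),
                "cytoplasmic_egfp_mean": cyt_egfp,
                "cytoplasmic_mcherry_puncta": n_puncta,
                "valid": valid,
            }
        )
    cols = [
        "cell_id",
        "pearson_r",
        "n_pixels",
        "cytoplasmic_egfp_mean",
        "cytoplasmic_mcherry_puncta",
        "valid",
    ]
    return ColocalizationTable(pd.DataFrame(rows, columns=cols), condition=condition)


def line_profile(
    channel: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    n_points: int = 100,
) -> pd.DataFrame:
    """Bilinear intensity profile along the segment start -> end.

    Coordinates are 0-based (row, column).  Returns per-point position
    (pixels along the segment) and intensity.
    """
    channel = np.asarray(channel, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    h, w = channel.shape
    for (y, x) in (start, end):
        if not (0 <= y <= h - 1 and 0 <= x <= w - 1):
            raise ValueError(f"endpoint ({y}, {x}) outside image")
    t = np.linspace(0.0, 1.0, n_points)
    ys = start[0] + t * (end[0] - start[0])
    xs = start[1] + t * (end[1] - start[1])
    vals = ndi.map_coordinates(channel, np.vstack([ys, xs]), order=1, mode="nearest")
    length = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    return pd.DataFrame({"position": t * length, "intensity": vals})


def cytoplasmic_intensity(
    channel: np.ndarray, segmentation: SegmentationResult, cell_id: int
) -> float:
    """Mean channel intensity over one cell's cytoplasm pixels."""
    mask = segmentation.cell_mask(cell_id, "cytoplasm")
    if not mask.any():
        raise ValueError(f"cell {cell_id} has an empty cytoplasm mask")
    return float(np.asarray(channel, dtype=float)[mask].mean())


def count_puncta(
    channel: np.ndarray,
    segmentation: SegmentationResult,
    cell_id: int,
    spot_threshold: float,
    min_area: int = 2,
    tophat_radius: int = 5,
) -> int:
    """Count cytoplasmic puncta in one cell.

    A white top-hat (disk footprint) flattens smooth background, pixels
    above ``spot_threshold`` inside the cell's cytoplasm are grouped into
    connected components, and components of area >= ``min_area`` count.
    """
    if spot_threshold <= 0 or min_area <= 0:
        raise ValueError("spot_threshold and min_area must be positive")
    channel = np.asarray(channel, dtype=float)
    flat = white_tophat(channel, footprint=disk(tophat_radius))
    mask = (flat > spot_threshold) & segmentation.cell_mask(cell_id, "cytoplasm")
    labels, n = ndi.label(mask)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())


def z_factor(positive_control, negative_control) -> float:
    """Screening-window statistic 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.

    Sample standard deviations (ddof=1).  Equals 1 for noise-free,
    separated controls; values near or above 0.5 indicate an assay robust
    enough for large-scale screening.  Raises if the control means are
    equal (window undefined).
    """
    pos = np.asarray(positive_control, dtype=float)
    neg = np.asarray(negative_control, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each control group needs >= 2 values")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise ValueError("control means are equal; Z-factor undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def compare_conditions(
    tables: list[ColocalizationTable],
    method: str = "ttest",
    *,
    equal_var: bool = False,
    pos_control: str | None = None,
    neg_control: str | None = None,
) -> ScreenResult:
    """Condition-level statistics over per-cell colocalization tables.

    ``method='ttest'``: two-sided two-sample t-test (Welch by default)
    for every unordered condition pair, uncorrected.
    ``method='anova_bonferroni'``: one-way ANOVA F-test across all
    conditions, then the same pairwise t-tests with Bonferroni-corrected
    p = min(1, m * p_raw) over the m pairs performed.

    If ``pos_control``/``neg_control`` name two conditions, the Z-factor
    of their per-cell r distributions is reported.
    """
    if method not in ("ttest", "anova_bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    if len(tables) < 2:
        raise ValueError("need >= 2 conditions")
    groups: dict[str, np.ndarray] = {}
    for t in tables:
        vals = t.valid_r
        if vals.size < 2:
            raise ValueError(f"condition {t.condition!r} has < 2 usable cells")
        groups[t.condition] = vals

    summary = pd.DataFrame(
        [
            {
                "condition": c,
                "mean_r": float(v.mean()),
                "sd_r": float(v.std(ddof=1)),
                "n_cells": int(v.size),
            }
            for c, v in groups.items()
        ]
    )

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t_stat, p = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        p = float(p) if np.isfinite(p) else 1.0
        t_stat = float(t_stat) if np.isfinite(t_stat) else 0.0
        row = {"comparison": f"{a} vs {b}", "statistic": t_stat, "p": p}
        if method == "anova_bonferroni":
            row["p_corrected"] = min(1.0, m * p)
        rows.append(row)
    pairwise = pd.DataFrame(rows)

    anova_F = anova_p = None
    if method == "anova_bonferroni":
        F, ap = stats.f_oneway(*groups.values())
        anova_F, anova_p = float(F), float(ap)

    zf = None
    if pos_control is not None and neg_control is not None:
        zf = z_factor(groups[pos_control], groups[neg_control])

    return ScreenResult(
        summary=summary,
        pairwise=pairwise,
        method=method,
        anova_F=anova_F,
        anova_p=anova_p,
        z_factor=zf,
    )
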