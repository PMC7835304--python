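"""Histology arm: fluorescence intensity normalization, pixelwise
TSPO/microglia co-localization, and perivascular co-expression counts.

Fluorescence intensities are expressed as percent of the control-group
mean for the same region. Co-localization thresholds each channel (Otsu by
default), then reports 100 * |A+ ∩ B+| / |B+| — the extent of TSPO signal
within marker-positive (Iba1) pixels; the denominator is an exposed option.
Perivascular co-expression restricts a cell table to cells within a
distance of the vessel border (60 um by default, computed from a vessel
mask via the Euclidean distance transform) and reports the percent of
iron-positive cells also expressing the marker, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateDataError

__all__ = [
    "normalize_to_control",
    "coloc_percent",
    "perivascular_coexpression",
    "vessel_distance_um",
    "ColocResult",
    "CoexpressionResult",
]


@dataclass
class ColocResult:
    percent: float  # NaN when undefined (empty denominator)
    defined: bool
    mask_a: np.ndarray
    mask_b: np.ndarray
    threshold_a: float
    threshold_b: float


@dataclass
class CoexpressionResult:
    pct_iron_with_marker: float
    pct_marker_with_iron: float
    n_iron: int
    n_marker: int
    n_in_range: int
    defined: bool


def normalize_to_control(eae_values, ctr_values) -> list[float]:
    """Each value as percent of the control-group mean (controls normalized
    against themselves average exactly 100)."""
    ctr = np.asarray(list(ctr_values), dtype=float)
    if ctr.size == 0 or ctr.mean() == 0:
        raise DegenerateDataError("control mean is zero or control group empty")
    return [100.0 * float(v) / float(ctr.mean()) for v in eae_values]


def _threshold(channel: np.ndarray, method: str, fixed: float | None) -> float:
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed thresholding requires a threshold value")
        return float(fixed)
    if method != "otsu":
        raise ValueError("threshold_method must be 'otsu' or 'fixed'")
    if np.ptp(channel) == 0:
        raise DegenerateDataError("constant channel; Otsu threshold undefined")
    return float(threshold_otsu(channel))


def coloc_percent(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    threshold_method: str = "otsu",
    fixed_a: float | None = None,
    fixed_b: float | None = None,
    denominator: str = "b",
) -> ColocResult:
    """Percent of co-localized positive pixels.

    ``denominator='b'`` (default) reports |A+ ∩ B+| / |B+|; alternatives:
    ``'a'`` and ``'union'``. An empty denominator yields a flagged,
    undefined result (NaN), never a silent 0.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share shape")
    ta = _threshold(a, threshold_method, fixed_a)
    tb = _threshold(b, threshold_method, fixed_b)
    mask_a, mask_b = a > ta, b > tb
    inter = int(np.count_nonzero(mask_a & mask_b))
    denom = {
        "a": int(np.count_nonzero(mask_a)),
        "b": int(np.count_nonzero(mask_b)),
        "union": int(np.count_nonzero(mask_a | mask_b)),
    }[denominator]
    if denom == 0:
        return ColocResult(float("nan"), False, mask_a, mask_b, ta, tb)
    return ColocResult(100.0 * inter / denom, True, mask_a, mask_b, ta, tb)


def vessel_distance_um(vessel_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Distance (um) from the vessel border; 0 inside the vessel."""
    return ndimage.distance_transform_edt(~np.asarray(vessel_mask, bool)) * float(
        pixel_size_um
    )


def perivascular_coexpression(
    cells: pd.DataFrame,
    max_dist_um: float = 60.0,
    iron_col: str = "positive_iron",
    marker_col: str = "positive_marker",
    dist_col: str = "distance_to_vessel_um",
) -> CoexpressionResult:
    """Co-expression percentages among perivascular cells.

    Restricts to cells within ``max_dist_um`` of the vessel border and
    reports 100 * |iron+ ∩ marker+| / |iron+| (and the marker-denominated
    counterpart). No iron-positive cell in range yields a flagged undefined
    result.
    """
    sel = cells[cells[dist_col] <= max_dist_um]
    iron = sel[iron_col].astype(bool)
    marker = sel[marker_col].astype(bool)
    n_iron, n_marker = int(iron.sum()), int(marker.sum())
    both = int((iron & marker).sum())
    if n_iron == 0:
        return CoexpressionResult(
            float("nan"), float("nan"), 0, n_marker, len(sel), False
        )
    pct_iron = 100.0 * both / n_iron
    pct_marker = 100.0 * both / n_marker if n_marker else float("nan")
    return CoexpressionResult(pct_iron, pct_marker, n_iron, n_marker, len(sel), True)
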