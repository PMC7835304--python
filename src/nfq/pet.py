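"""TSPO-PET quantification: SUV conversion, analysis-window summation, and
atlas-VOI SUV / SUVR tables referenced to (unaffected) neocortex.

SUV = tissue activity (MBq/cm^3) / (injected dose (MBq) / body weight (g)).
The dynamic acquisition (six 5-min frames starting 20 min post-injection)
is collapsed to a single volume by a duration-weighted mean over the 20–50
min window — identical to plain frame summation up to a constant factor for
equal-length frames, and SUVR is invariant to that factor. Regional values
are arithmetic means over atlas VOI voxels; SUVR divides each regional SUV
by the neocortex SUV, optionally computed over neocortex voxels outside a
lesion-exclusion mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .phantom import AtlasPhantom, REGIONS
from .volume import DynamicPET, Volume3D

__all__ = [
    "compute_suv",
    "sum_window",
    "voi_mean",
    "suv_table",
    "compute_suvr",
    "reference_suv",
]


def compute_suv(activity: Volume3D, dose_MBq: float, weight_g: float) -> Volume3D:
    """Voxelwise activity / (dose / weight). Linear in activity."""
    if dose_MBq <= 0 or weight_g <= 0:
        raise ValueError("dose_MBq and weight_g must be positive")
    out = activity.copy(data=np.asarray(activity.data, dtype=float) / (dose_MBq / weight_g))
    out.units = "SUV"
    return out


def sum_window(pet: DynamicPET, t0_min: float = 20.0, t1_min: float = 50.0) -> Volume3D:
    """Duration-weighted mean of the frames whose interval lies in [t0, t1).

    Equals the plain frame mean for equal-length frames; robust to unequal
    frame durations otherwise.
    """
    acq0, acq1 = pet.acquisition_window_min
    picked = [
        (f, e - s)
        for f, (s, e) in zip(pet.frames, pet.frame_times)
        if s >= t0_min - 1e-9 and e <= t1_min + 1e-9
    ]
    if not picked:
        raise ValueError(
            f"window [{t0_min}, {t1_min}) min not covered; acquisition spans "
            f"[{acq0}, {acq1}] min"
        )
    total = sum(d for _, d in picked)
    data = sum(f.data * (d / total) for f, d in picked)
    return Volume3D(data=np.asarray(data, dtype=float), affine=pet.affine.copy(),
                    units=pet.frames[0].units)


def voi_mean(volume: Volume3D, atlas: AtlasPhantom, region: str) -> float:
    """Arithmetic mean over the region's voxels (never a silent NaN)."""
    mask = atlas.region_mask(region)
    if not np.any(mask):
        raise DegenerateDataError(f"region {region!r} has no voxels")
    return float(np.mean(volume.data[mask]))


def reference_suv(
    suv: Volume3D,
    atlas: AtlasPhantom,
    reference: str = "neocortex",
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Mean reference-region SUV, optionally over voxels outside an
    exclusion mask (the 'unaffected' part of a lesioned reference)."""
    mask = atlas.region_mask(reference)
    if exclude_mask is not None:
        mask = mask & ~np.asarray(exclude_mask, dtype=bool)
    if not np.any(mask):
        raise DegenerateDataError("reference region empty after exclusion")
    ref = float(np.mean(suv.data[mask]))
    if ref <= 0:
        raise DegenerateDataError(f"reference SUV must be positive, got {ref}")
    return ref


def suv_table(
    suv: Volume3D, atlas: AtlasPhantom, animal_id: str, regions=REGIONS
) -> pd.DataFrame:
    """Tidy per-region SUV table: (animal_id, region, metric, value)."""
    rows = [
        {"animal_id": animal_id, "region": r, "metric": "SUV",
         "value": voi_mean(suv, atlas, r)}
        for r in regions
    ]
    return pd.DataFrame(rows)


def compute_suvr(
    suv_tbl: pd.DataFrame,
    reference: str = "neocortex",
    *,
    suv_volume: Volume3D | None = None,
    atlas: AtlasPhantom | None = None,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Append SUVR rows to a tidy SUV table.

    The reference value is the table's own reference-region SUV unless an
    ``exclude_mask`` is given, in which case it is recomputed voxelwise over
    the unaffected reference voxels (requires ``suv_volume`` and ``atlas``).
    """
    suv_rows = suv_tbl[suv_tbl["metric"] == "SUV"]
    out = [suv_tbl]
    for animal_id, grp in suv_rows.groupby("animal_id", sort=False):
        if exclude_mask is not None:
            if suv_volume is None or atlas is None:
                raise ValueError("exclude_mask requires suv_volume and atlas")
            ref = reference_suv(suv_volume, atlas, reference, exclude_mask)
        else:
            sel = grp.loc[grp["region"] == reference, "value"]
            if sel.empty:
                raise DegenerateDataError(f"no {reference!r} SUV row for {animal_id}")
            ref = float(sel.iloc[0])
        if ref <= 0:
            raise DegenerateDataError(f"reference SUV must be positive, got {ref}")
        suvr = grp.assign(metric="SUVR", value=grp["value"] / ref)
        out.append(suvr)
    return pd.concat(out, ignore_index=True)
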