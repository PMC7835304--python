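"""In-silico cohort generator with exact ground truth.

Generates everything the analysis pipeline consumes — a labelled schematic
mouse-brain atlas with six analysed regions plus skull fiducials, dynamic
TSPO-PET frames with a configurable regional uptake-ratio profile, T2*-like
SPIO-MRI volumes with punctate hypointense lesion clusters, a smooth
multiplicative receiver-coil bias field and a rigid inter-modality
misalignment, per-animal metadata with a clinical score monotonically
linked to lesion burden, and two-channel fluorescence fields — together
with the exact ground truth (uptake ratios, lesion masks and fractions,
bias field, misalignment) needed to validate every downstream stage.

Geometry is schematic (ellipsoids sized to realistic mouse regional
volumes), not anatomical: the pipeline needs labels and contrasts, not
anatomy. All randomness flows from a single integer seed through a local
``numpy.random.Generator``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, SizingError
from .registration import LANDMARK_NAMES, LandmarkSet, resample
from .transforms import RigidTransform, random_rigid
from .volume import DynamicPET, Volume3D

__all__ = [
    "REGIONS",
    "REGIONS_TESTED",
    "REGION_CODES",
    "AtlasPhantom",
    "GroundTruth",
    "RegionEffect",
    "default_effect_profile",
    "null_effect_profile",
    "generate_atlas",
    "generate_pet",
    "generate_spio_mri",
    "generate_cohort",
    "generate_fluorescence",
    "draw_cohort_truth",
    "draw_region_measurements",
    "default_cs_link",
    "AnimalBundle",
    "Cohort",
]

#: The six analysed CNS regions. Neocortex is the SUVR reference.
REGIONS = (
    "neocortex",
    "caudate_putamen",
    "hippocampus",
    "thalamus",
    "cerebellum",
    "brainstem",
)
#: Regions entering group statistics (the reference itself is excluded,
#: its SUVR is 1 by construction).
REGIONS_TESTED = REGIONS[1:]
REGION_CODES = {name: code for code, name in enumerate(REGIONS, start=1)}

# Schematic anatomy as fractions of the grid half-FOV: (center, semi-axes)
# of each ellipsoid. The scene scales with the grid — at the reference
# 64^3 / 0.2 mm grid (12.8 mm FOV) the regions have mouse-like proportions
# (hippocampus ~19 mm^3, thalamus ~18, caudate/putamen ~17, cerebellum
# ~54, brainstem ~31, neocortex shell ~150 mm^3).
_CEREBRUM = (np.array([0.0, 0.234, 0.078]), np.array([0.656, 0.625, 0.469]))
_STRUCTURES = {
    "caudate_putamen": (np.array([0.0, 0.500, -0.031]), np.array([0.375, 0.219, 0.188])),
    "hippocampus": (np.array([0.0, 0.094, 0.188]), np.array([0.438, 0.234, 0.172])),
    "thalamus": (np.array([0.0, 0.188, -0.125]), np.array([0.344, 0.234, 0.203])),
    "cerebellum": (np.array([0.0, -0.672, 0.125]), np.array([0.500, 0.313, 0.313])),
    "brainstem": (np.array([0.0, -0.531, -0.250]), np.array([0.281, 0.422, 0.234])),
}
_LANDMARKS_FRAC = {
    "eye_L": np.array([-0.438, 0.906, 0.125]),
    "eye_R": np.array([0.438, 0.906, 0.125]),
    "condyle_L": np.array([-0.750, 0.313, -0.406]),
    "condyle_R": np.array([0.750, 0.313, -0.406]),
    "cochlea_L": np.array([-0.531, -0.500, -0.344]),
    "cochlea_R": np.array([0.531, -0.500, -0.344]),
}


@dataclass
class AtlasPhantom:
    """Label volume (integer region codes, 0 = background), the code->name
    map, and the six skull fiducials in world mm."""

    labels: Volume3D
    region_names: dict[int, str]
    landmarks: LandmarkSet

    def region_code(self, name: str) -> int:
        for code, n in self.region_names.items():
            if n == name:
                return code
        raise KeyError(f"unknown region {name!r}")

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels.data == self.region_code(name)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels.data > 0


@dataclass
class GroundTruth:
    """Exact per-animal truth recorded by the generators."""

    true_suvr: dict[str, float] = field(default_factory=dict)
    true_lesion_fraction: dict[str, float] = field(default_factory=dict)
    true_lesion_mask: Volume3D | None = None
    true_bias_field: Volume3D | None = None
    rigid_misalignment: RigidTransform | None = None
    cs: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "true_suvr": self.true_suvr,
            "true_lesion_fraction": self.true_lesion_fraction,
            "cs": self.cs,
            "rigid_misalignment": None
            if self.rigid_misalignment is None
            else self.rigid_misalignment.as_matrix().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _default_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    """Scanner-style affine: isotropic-ish voxels, world origin at grid center."""
    vox = np.asarray(voxel_size_mm, dtype=float)
    shape = np.asarray(grid_shape)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vox)
    aff[:3, 3] = -vox * (shape - 1) / 2.0
    return aff


def generate_atlas(
    grid_shape=(64, 64, 64),
    voxel_size_mm=(0.2, 0.2, 0.2),
    seed: int = 0,
) -> AtlasPhantom:
    """Build the schematic labelled atlas and its six fiducials.

    The anatomy occupies fixed fractions of the grid field of view, so the
    scene scales with the grid: 64^3 at 0.2 mm gives a mouse-sized brain.
    The seed jitters the fiducial positions slightly (manual-identification
    variability across atlas builds); the label volume itself is
    deterministic.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size_mm = tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,)))
    if min(grid_shape) < 32:
        raise SizingError(
            f"grid {grid_shape} too small to resolve all regions "
            "(needs >= 32 voxels per axis; >= 48^3 recommended)"
        )
    rng = np.random.default_rng(seed)
    affine = _default_affine(grid_shape, voxel_size_mm)
    half_fov = np.asarray(grid_shape) * np.asarray(voxel_size_mm) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    xyz = (
        np.stack([ii, jj, kk], axis=-1) @ affine[:3, :3].T + affine[:3, 3]
    )  # (X,Y,Z,3) world mm

    def inside(center, semi):
        return np.sum(((xyz - center * half_fov) / (semi * half_fov)) ** 2, axis=-1) <= 1.0

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[inside(*_CEREBRUM)] = REGION_CODES["neocortex"]
    for name in ("caudate_putamen", "hippocampus", "thalamus", "cerebellum"):
        labels[inside(*_STRUCTURES[name])] = REGION_CODES[name]
    bs = inside(*_STRUCTURES["brainstem"]) & (labels != REGION_CODES["cerebellum"])
    labels[bs] = REGION_CODES["brainstem"]

    for name, code in REGION_CODES.items():
        if not np.any(labels == code):
            raise SizingError(f"region {name!r} has no voxels on this grid")

    pts = {}
    for name in LANDMARK_NAMES:
        p = _LANDMARKS_FRAC[name] * half_fov + rng.uniform(-0.15, 0.15, size=3)
        vox = np.round((p - affine[:3, 3]) / np.diag(affine[:3, :3])).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.asarray(grid_shape)):
            raise SizingError(f"landmark {name!r} falls outside the grid FOV")
        if labels[tuple(vox)] != 0:
            raise SizingError(f"landmark {name!r} falls inside the brain label")
        pts[name] = p

    vol = Volume3D(data=labels, affine=affine, units="label")
    region_names = {0: "background", **{c: n for n, c in REGION_CODES.items()}}
    return AtlasPhantom(labels=vol, region_names=region_names, landmarks=LandmarkSet(pts))


def generate_pet(
    atlas: AtlasPhantom,
    suvr_profile: dict[str, float],
    reference_suv: float = 0.21,
    dose_MBq: float = 6.0,
    weight_g: float = 19.0,
    psf_fwhm_mm: float = 0.9,
    noise_sd: float = 0.05,
    n_frames: int = 6,
    frame_len_min: float = 5.0,
    t_start_min: float = 20.0,
    background_ratio: float = 0.6,
    seed: int = 0,
) -> tuple[DynamicPET, GroundTruth]:
    """Render dynamic PET frames realizing a regional uptake-ratio profile.

    Activity in region r is ``reference_activity * suvr_profile[r]`` where
    ``reference_activity = reference_suv * dose / weight`` (so the neocortex
    SUV equals ``reference_suv``, on the scale of real cortical TSPO-tracer
    uptake ~0.21). The scene is blurred by an isotropic Gaussian PSF of the
    given FWHM and each frame receives additive Gaussian noise with standard
    deviation ``noise_sd * reference_activity``. Extracerebral soft tissue
    sits at ``background_ratio`` times the reference.
    """
    missing = [r for r in REGIONS if r not in suvr_profile]
    if missing:
        raise ConfigurationError(f"suvr_profile missing regions: {missing}")
    if abs(suvr_profile["neocortex"] - 1.0) > 1e-9:
        raise ConfigurationError("reference region (neocortex) must have ratio 1.0")
    if dose_MBq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    rng = np.random.default_rng(seed)

    a_ref = reference_suv * dose_MBq / weight_g  # MBq/cm^3
    truth = np.full(atlas.labels.shape, background_ratio * a_ref, dtype=float)
    for name in REGIONS:
        truth[atlas.region_mask(name)] = suvr_profile[name] * a_ref
    if psf_fwhm_mm > 0:
        sigma_vox = (psf_fwhm_mm / 2.354820045) / atlas.labels.voxel_size_mm
        truth = ndimage.gaussian_filter(truth, sigma=sigma_vox)

    frames, times = [], []
    for i in range(n_frames):
        data = truth if noise_sd == 0 else truth + rng.normal(
            0.0, noise_sd * a_ref, size=truth.shape
        )
        frames.append(
            Volume3D(data=data.copy(), affine=atlas.labels.affine.copy(), units="MBq/cm3")
        )
        t0 = t_start_min + i * frame_len_min
        times.append((t0, t0 + frame_len_min))

    pet = DynamicPET(frames=frames, frame_times=times, dose_MBq=dose_MBq, weight_g=weight_g)
    return pet, GroundTruth(true_suvr=dict(suvr_profile))


# ---------------------------------------------------------------------------
# SPIO-MRI phantom


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = ii**2 + jj**2 + kk**2 <= r**2
    return np.stack([ii[keep], jj[keep], kk[keep]], axis=1)


_BALLS = {r: _ball_offsets(r) for r in (1, 2, 3)}


def _place_punctate_lesions(
    region_mask: np.ndarray,
    target_voxels: int,
    occupied: np.ndarray,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
) -> np.ndarray:
    """Drop non-overlapping spherical clusters (radius 1–3 voxels) wholly
    inside ``region_mask`` (and ``allowed``, when given) until the voxel
    count is as close as possible to ``target_voxels``. Returns the added
    lesion mask."""
    lesion = np.zeros_like(region_mask, dtype=bool)
    placeable = region_mask if allowed is None else (region_mask & allowed)
    coords = np.argwhere(placeable)
    if len(coords) == 0 or target_voxels <= 0:
        return lesion
    shape = np.asarray(region_mask.shape)
    placed = 0
    radius = 3
    fails = 0
    while True:
        deficit = target_voxels - placed
        if deficit <= 3:  # a radius-1 ball (7 vox) would overshoot more
            break
        while radius > 1 and len(_BALLS[radius]) > max(deficit, 2 * deficit - 1):
            radius -= 1
        ball = _BALLS[radius]
        center = coords[rng.integers(len(coords))]
        vox = center + ball
        if np.any(vox < 0) or np.any(vox >= shape):
            fails += 1
        else:
            idx = tuple(vox.T)
            if np.all(placeable[idx]) and not np.any(occupied[idx]) and not np.any(
                lesion[idx]
            ):
                lesion[idx] = True
                placed += len(ball)
                fails = 0
            else:
                fails += 1
        if fails >= 400:
            if radius > 1:
                radius -= 1
                fails = 0
            else:  # region too crowded: nearest achievable, recorded exactly
                break
    return lesion


def generate_spio_mri(
    atlas: AtlasPhantom,
    lesion_fraction: dict[str, float],
    lesion_contrast: float = 0.7,
    bias_amplitude: float = 0.2,
    noise_sd: float = 5.0,
    misalignment: RigidTransform | None = None,
    mu_tissue: float = 100.0,
    seed: int = 0,
) -> tuple[Volume3D, LandmarkSet, GroundTruth]:
    """Render a T2*-like volume with punctate hypointense SPIO lesions.

    The volume lives on its own (misaligned) native grid: ``misalignment``
    maps atlas world coordinates into the MRI world frame, the atlas labels
    are nearest-resampled into that frame, and lesions are painted there —
    so lesion edges stay crisp and the realized per-region fraction is
    recorded exactly from the native-frame mask (never silently different
    from the request without being recorded). Tissue is N(mu_tissue,
    noise_sd), lesions sit at ``mu_tissue * (1 - lesion_contrast)``, and the
    whole image is multiplied by a smooth strictly-positive bias field
    (exponential of a random second-order polynomial, mean 1 over the brain,
    peak deviation ``bias_amplitude``).

    Returns the MRI volume, the fiducials in the MRI frame, and the truth.
    """
    if not 0.0 < lesion_contrast < 1.0:
        raise ConfigurationError("lesion_contrast must be in (0, 1)")
    unknown = [r for r in lesion_fraction if r not in REGIONS]
    if unknown:
        raise ConfigurationError(f"lesion_fraction has unknown regions: {unknown}")
    misalignment = misalignment or RigidTransform.identity()
    rng = np.random.default_rng(seed)

    # native grid: same geometry as the atlas grid, but its own world frame
    ref_native = Volume3D(
        data=np.zeros(atlas.labels.shape, dtype=np.int16),
        affine=atlas.labels.affine.copy(),
    )
    labels_native = resample(atlas.labels, misalignment, ref_native, "nearest").data
    brain = labels_native > 0
    # punctate sites are intraparenchymal: keep clusters >= 1 voxel below the
    # pial surface so they are enclosed by tissue
    interior = ndimage.binary_erosion(brain)

    lesion = np.zeros(labels_native.shape, dtype=bool)
    realized: dict[str, float] = {}
    for name in REGIONS:
        req = float(lesion_fraction.get(name, 0.0))
        rmask = labels_native == REGION_CODES[name]
        n_region = int(rmask.sum())
        if n_region == 0:
            realized[name] = 0.0
            continue
        target = int(round(req / 100.0 * n_region))
        added = _place_punctate_lesions(rmask, target, lesion, rng, allowed=interior)
        lesion |= added
        realized[name] = 100.0 * float((lesion & rmask).sum()) / n_region

    data = np.where(
        brain,
        mu_tissue + rng.normal(0.0, noise_sd, size=brain.shape),
        np.abs(rng.normal(mu_tissue * 0.04, max(noise_sd * 0.3, 0.5), size=brain.shape)),
    )
    data[lesion] = mu_tissue * (1.0 - lesion_contrast) + rng.normal(
        0.0, noise_sd, size=int(lesion.sum())
    )
    data = np.clip(data, 0.5, None)  # keep log-intensity defined everywhere

    field = np.ones_like(data)
    if bias_amplitude > 0:
        grids = np.meshgrid(
            *[np.linspace(-1.0, 1.0, s) for s in data.shape], indexing="ij"
        )
        x, y, z = grids
        basis = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
        p = sum(c * b for c, b in zip(rng.normal(size=9), basis))
        p -= p[brain].mean()
        peak = np.abs(p[brain]).max()
        if peak > 0:
            p *= np.log1p(bias_amplitude) / peak
        field = np.exp(p)
        field /= field[brain].mean()
        data = data * field

    mri = Volume3D(data=data, affine=ref_native.affine.copy(), units="a.u.")
    truth = GroundTruth(
        true_lesion_fraction=realized,
        true_lesion_mask=Volume3D(lesion, ref_native.affine.copy(), units="mask"),
        true_bias_field=Volume3D(field, ref_native.affine.copy(), units="ratio"),
        rigid_misalignment=misalignment,
    )
    return mri, atlas.landmarks.transformed(misalignment), truth


# ---------------------------------------------------------------------------
# Cohort model


@dataclass
class RegionEffect:
    """Group-level measurement scale for one region (EAE vs CTR)."""

    suvr_eae: float
    suvr_eae_sd: float
    suvr_ctr: float
    suvr_ctr_sd: float
    spio_eae: float
    spio_eae_sd: float
    spio_ctr: float
    spio_ctr_sd: float


def default_effect_profile() -> dict[str, RegionEffect]:
    """Region effects on the scale of the reported PLP-EAE group summaries
    (SUVR and SPIO fractional volume, mean +/- SD per group)."""
    return {
        "neocortex": RegionEffect(1.0, 0.0, 1.0, 0.0, 0.5, 0.5, 0.3, 0.3),
        "caudate_putamen": RegionEffect(1.2, 0.1, 1.0, 0.1, 5.4, 4.5, 0.6, 1.1),
        "hippocampus": RegionEffect(1.6, 0.1, 1.3, 0.1, 5.7, 2.6, 1.7, 1.5),
        "thalamus": RegionEffect(1.5, 0.2, 1.1, 0.1, 7.3, 5.5, 1.6, 1.7),
        "cerebellum": RegionEffect(2.4, 0.2, 1.9, 0.3, 14.5, 7.5, 3.9, 2.8),
        "brainstem": RegionEffect(2.0, 0.3, 1.4, 0.1, 9.0, 8.1, 0.5, 0.5),
    }


def null_effect_profile() -> dict[str, RegionEffect]:
    """EAE distributions identical to CTR (exchangeable group labels)."""
    out = {}
    for name, e in default_effect_profile().items():
        out[name] = RegionEffect(
            e.suvr_ctr, e.suvr_ctr_sd, e.suvr_ctr, e.suvr_ctr_sd,
            e.spio_ctr, e.spio_ctr_sd, e.spio_ctr, e.spio_ctr_sd,
        )
    return out


def _gamma_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantile of the moment-matched gamma; fractional volumes are
    nonnegative and right-skewed (reported SDs are on the order of the
    means)."""
    if mean <= 0 or sd <= 0:
        return np.full(np.shape(u), max(mean, 0.0))
    from scipy import stats as sps

    return sps.gamma.ppf(u, (mean / sd) ** 2, scale=sd**2 / mean)


#: Loading of the shared per-animal severity factor in the truth copula.
SEVERITY_COUPLING = 0.8


@dataclass
class AnimalTruthDraw:
    group: str
    severity: float  # latent per-animal factor (standard normal)
    suvr: dict[str, float]
    spio: dict[str, float]


def draw_cohort_truth(
    profile: dict[str, RegionEffect],
    n_eae: int,
    n_ctr: int,
    rng: np.random.Generator,
    coupling: float = SEVERITY_COUPLING,
) -> list[AnimalTruthDraw]:
    """Per-animal true regional values of the cohort model.

    Each animal carries a latent severity factor z ~ N(0, 1); each
    (region, metric) value is drawn through a Gaussian copula with loading
    ``coupling`` on z, so disease burden co-varies across regions within an
    animal. Marginals are moment-matched to the effect profile: SUVR is
    normal, SPIO fractional volume is gamma (nonnegative, right-skewed).
    EAE and CTR use the same construction with their own group moments, so
    a null profile (EAE moments = CTR moments) makes the groups
    exchangeable. The SUVR reference (neocortex) is pinned at 1.
    """
    from scipy import stats as sps

    lam = float(np.clip(coupling, 0.0, 1.0))
    resid = np.sqrt(1.0 - lam**2)
    out: list[AnimalTruthDraw] = []
    for group in ["EAE"] * n_eae + ["CTR"] * n_ctr:
        z = float(rng.standard_normal())
        suvr, spio = {}, {}
        for name in REGIONS:
            e = profile[name]
            z_s = lam * z + resid * rng.standard_normal()
            z_p = lam * z + resid * rng.standard_normal()
            if group == "EAE":
                suvr[name] = e.suvr_eae + e.suvr_eae_sd * z_s
                spio[name] = float(
                    _gamma_ppf(sps.norm.cdf(z_p), e.spio_eae, e.spio_eae_sd)
                )
            else:
                suvr[name] = e.suvr_ctr + e.suvr_ctr_sd * z_s
                spio[name] = float(
                    _gamma_ppf(sps.norm.cdf(z_p), e.spio_ctr, e.spio_ctr_sd)
                )
            suvr[name] = max(0.1, suvr[name])
        suvr["neocortex"] = 1.0
        out.append(AnimalTruthDraw(group=group, severity=z, suvr=suvr, spio=spio))
    return out


def draw_region_measurements(
    profile: dict[str, RegionEffect],
    n_eae: int,
    n_ctr: int,
    rng: np.random.Generator,
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-region (EAE array, CTR array) views of :func:`draw_cohort_truth`
    — the distributional layer of the cohort model, used for calibration
    studies without rendering image volumes."""
    draws = draw_cohort_truth(profile, n_eae, n_ctr, rng)
    eae = [d for d in draws if d.group == "EAE"]
    ctr = [d for d in draws if d.group == "CTR"]
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for name in profile:
        out[name] = {
            "suvr": (
                np.array([d.suvr[name] for d in eae]),
                np.array([d.suvr[name] for d in ctr]),
            ),
            "spio": (
                np.array([d.spio[name] for d in eae]),
                np.array([d.spio[name] for d in ctr]),
            ),
        }
    return out


def default_cs_link(total_burden_pct: float) -> float:
    """Monotone map from total lesion burden (sum of per-region fractional
    volumes, %) to the 0–4 clinical score in 0.5 steps."""
    raw = 0.5 + 3.0 * total_burden_pct / 45.0
    return float(np.clip(np.round(2.0 * raw) / 2.0, 0.5, 4.0))


@dataclass
class CohortRecord:
    animal_id: str
    group: str  # "EAE" | "CTR"
    cs: float
    day_post_immunization: int
    dose_MBq: float
    weight_g: float

    def __post_init__(self) -> None:
        if self.group not in ("EAE", "CTR"):
            raise ValueError("group must be 'EAE' or 'CTR'")
        if not 0.0 <= self.cs <= 4.0:
            raise ValueError("clinical score must lie on the 0–4 scale")


@dataclass
class AnimalBundle:
    record: CohortRecord
    pet: DynamicPET
    mri: Volume3D
    mri_landmarks: LandmarkSet
    observed_landmarks: LandmarkSet  # with manual-identification jitter
    truth: GroundTruth


@dataclass
class Cohort:
    atlas: AtlasPhantom
    animals: list[AnimalBundle]


def generate_cohort(
    n_eae: int = 7,
    n_ctr: int = 5,
    effect_profile: dict[str, RegionEffect] | None = None,
    cs_link: Callable[[float], float] = default_cs_link,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    voxel_size_mm=(0.3, 0.3, 0.3),
    psf_fwhm_mm: float = 0.9,
    pet_noise_sd: float = 0.05,
    lesion_contrast: float = 0.7,
    bias_amplitude: float = 0.2,
    mri_noise_sd: float = 5.0,
    max_rotation_deg: float = 5.0,
    max_translation_mm: float = 1.5,
    landmark_jitter_sd_mm: float = 0.05,
) -> Cohort:
    """Generate a complete in-silico cohort with recoverable structure.

    Per-animal true regional values come from :func:`draw_cohort_truth`: a
    latent severity factor couples uptake ratios and lesion burden across
    regions within each animal, and the clinical score follows the lesion
    burden through the monotone ``cs_link`` — so group contrasts and pooled
    clinical-score correlations are built in. CTR animals sit at the
    control moments of the effect profile with CS 0.
    """
    if n_eae < 2 or n_ctr < 2:
        raise ConfigurationError("n_eae and n_ctr must both be >= 2")
    profile = effect_profile if effect_profile is not None else default_effect_profile()
    missing = [r for r in REGIONS if r not in profile]
    if missing:
        raise ConfigurationError(f"effect_profile missing regions: {missing}")
    rng = np.random.default_rng(seed)
    atlas = generate_atlas(grid_shape, voxel_size_mm, seed=int(rng.integers(2**31)))
    truth_draws = draw_cohort_truth(profile, n_eae, n_ctr, rng)

    animals: list[AnimalBundle] = []
    for i, draw in enumerate(truth_draws):
        group = draw.group
        aid = f"{group.lower()}{i + 1:02d}" if group == "EAE" else f"ctr{i - n_eae + 1:02d}"
        suvr_profile = dict(draw.suvr)
        lesion_req = dict(draw.spio)

        dose = rng.uniform(5.55, 7.0)
        weight = rng.normal(17.1, 1.7) if group == "EAE" else rng.normal(19.6, 0.8)
        pet, pet_truth = generate_pet(
            atlas,
            suvr_profile,
            dose_MBq=dose,
            weight_g=max(weight, 12.0),
            psf_fwhm_mm=psf_fwhm_mm,
            noise_sd=pet_noise_sd,
            seed=int(rng.integers(2**31)),
        )
        misalignment = random_rigid(rng, max_rotation_deg, max_translation_mm)
        mri, mri_lms, mri_truth = generate_spio_mri(
            atlas,
            lesion_req,
            lesion_contrast=lesion_contrast,
            bias_amplitude=bias_amplitude,
            noise_sd=mri_noise_sd,
            misalignment=misalignment,
            seed=int(rng.integers(2**31)),
        )
        burden = sum(mri_truth.true_lesion_fraction.values())
        cs = cs_link(burden) if group == "EAE" else 0.0
        record = CohortRecord(
            animal_id=aid,
            group=group,
            cs=cs,
            day_post_immunization=int(rng.integers(11, 15)),
            dose_MBq=dose,
            weight_g=max(weight, 12.0),
        )
        truth = GroundTruth(
            true_suvr=pet_truth.true_suvr,
            true_lesion_fraction=mri_truth.true_lesion_fraction,
            true_lesion_mask=mri_truth.true_lesion_mask,
            true_bias_field=mri_truth.true_bias_field,
            rigid_misalignment=misalignment,
            cs=cs,
        )
        observed = mri_lms.jittered(rng, landmark_jitter_sd_mm)
        animals.append(
            AnimalBundle(
                record=record,
                pet=pet,
                mri=mri,
                mri_landmarks=mri_lms,
                observed_landmarks=observed,
                truth=truth,
            )
        )
    return Cohort(atlas=atlas, animals=animals)


def cohort_metadata(cohort: Cohort) -> pd.DataFrame:
    rows = [
        {
            "animal_id": a.record.animal_id,
            "group": a.record.group,
            "cs": a.record.cs,
            "day_post_immunization": a.record.day_post_immunization,
            "dose_MBq": a.record.dose_MBq,
            "weight_g": a.record.weight_g,
        }
        for a in cohort.animals
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fluorescence phantom


def generate_fluorescence(
    field_size=(192, 192),
    n_cells: int = 60,
    frac_double: float = 0.4,
    vessel: dict | None = None,
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Two-channel fluorescence field of round cell blobs.

    Channel B is a pan myeloid marker (every cell is positive); a fraction
    ``frac_double`` of cells additionally express channel A, so the expected
    pixel co-localization |A+ ∩ B+| / |B+| equals ``frac_double``. The cell
    table records, per cell, the centroid, channel memberships, and the
    Euclidean distance (um) from the vessel border (distance 0 inside).

    Returns ``(channel_a, channel_b, cell_table)``.
    """
    if not 0.0 <= frac_double <= 1.0:
        raise ConfigurationError("frac_double must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = (int(s) for s in field_size)
    vessel = vessel or {"center": (h // 2, w // 5), "radius": max(min(h, w) // 12, 4)}

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    vr, vc = vessel["center"]
    vessel_mask = (rr - vr) ** 2 + (cc - vc) ** 2 <= vessel["radius"] ** 2
    dist_um = ndimage.distance_transform_edt(~vessel_mask) * pixel_size_um

    margin, min_sep = 6, 7.0
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells and tries < 20000:
        tries += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if vessel_mask[r, c]:
            continue
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < n_cells:
        raise ConfigurationError("field too small to place the requested cells")

    n_double = int(round(frac_double * n_cells))
    double = np.zeros(n_cells, dtype=bool)
    double[rng.permutation(n_cells)[:n_double]] = True

    chan_a = np.abs(rng.normal(6.0, 2.0, size=(h, w)))
    chan_b = np.abs(rng.normal(6.0, 2.0, size=(h, w)))
    sigma = 2.2
    rows = []
    for cid, ((r, c), dbl) in enumerate(zip(centers, double)):
        blob = np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)))
        amp = rng.uniform(160.0, 240.0)
        chan_b = chan_b + amp * blob
        if dbl:
            chan_a = chan_a + rng.uniform(160.0, 240.0) * blob
        rows.append(
            {
                "cell_id": cid,
                "row": r,
                "col": c,
                "positive_a": bool(dbl),
                "positive_b": True,
                "distance_to_vessel_um": float(dist_um[r, c]),
            }
        )
    return chan_a, chan_b, pd.DataFrame(rows)
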