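"""Synthetic head-CT phantoms with known hemorrhage ground truth.

A phantom is an ellipsoidal soft-tissue "brain" (~30 HU) inside a
high-density skull shell (1000 HU) surrounded by air (-1000 HU), with a
hemorrhagic lesion of configurable intensity statistics:

* ``PH-like`` — one confluent high-contrast blob, emulating parenchymal
  hematoma (larger, denser, well demarcated);
* ``HI2-like`` — several scattered small low-contrast blobs, emulating
  confluent petechial hemorrhagic infarction (smaller volume, lower
  contrast to background, more varied shape).

Lesion voxel intensities are drawn iid Normal(mean, sd^2) *before* any
blurring, so the region statistics driving the adaptive thresholding
rules are analytically known; in-plane Gaussian blur (partial-volume
mimicry) and global additive noise then degrade the image.  The ground
truth is the pre-blur lesion support.  Lesion masks are built by taking
exactly the required number of nearest voxels under a random ellipsoidal
metric, so the achieved volume matches the target to within one voxel.

All randomness flows from the spec's ``seed``; identical specs produce
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .adaptive_segmentation import ROIBox
from .preprocessing import BrainMask
from .volume_io import BinaryMask, CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "make_head_phantom",
    "make_cohort",
    "write_dicom_series",
    "PH_VOLUME_ML",
    "HI2_VOLUME_ML",
]

AIR_HU = -1000.0
SKULL_HU = 1000.0
HU_CLIP = (-80.0, 200.0)  # physiologic soft-tissue/blood range for lesion draws

# Cohort volume statistics (mL) the lognormal volume sampler reproduces:
# mean and SD of hemorrhage volume for parenchymal-hematoma and
# HI2-type cases respectively.
PH_VOLUME_ML = (17.28, 12.44)
HI2_VOLUME_ML = (6.81, 9.59)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case; ``seed`` fixes everything."""

    shape: tuple[int, int, int] = (24, 128, 128)
    spacing: tuple[float, float, float] = (5.0, 0.5, 0.5)
    lesion_kind: str = "PH"  # "PH" | "HI2"
    lesion_mean: float = 65.0
    lesion_sd: float = 8.0
    lesion_target_ml: float = 17.28
    background_mean: float = 30.0
    noise_sd: float = 2.0
    blur_sigma: float = 1.0
    seed: int = 0
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.lesion_kind not in ("PH", "HI2"):
            raise ValueError(f"lesion_kind must be 'PH' or 'HI2', got {self.lesion_kind!r}")
        if self.lesion_target_ml <= 0:
            raise ValueError("lesion_target_ml must be > 0")
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.lesion_sd < 0:
            raise ValueError("noise_sd, blur_sigma and lesion_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhantomCase:
    spec: PhantomSpec
    volume: CTVolume
    gt: BinaryMask
    brain: BrainMask
    roi: ROIBox


def _ellipsoid_metric(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    """Normalised ellipsoid distance (<=1 inside) on the voxel grid."""
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0],
        np.arange(shape[1]) * spacing[1],
        np.arange(shape[2]) * spacing[2],
        indexing="ij",
    )
    return np.sqrt(
        ((zz - center_mm[0]) / semi_mm[0]) ** 2
        + ((yy - center_mm[1]) / semi_mm[1]) ** 2
        + ((xx - center_mm[2]) / semi_mm[2]) ** 2
    )


def _head_geometry(spec: PhantomSpec):
    shape, spacing = spec.shape, spec.spacing
    extent = tuple(shape[i] * spacing[i] for i in range(3))
    center = tuple(e / 2 for e in extent)
    # brain fills ~75% of each half-extent; skull shell sits just outside
    semi = tuple(0.75 * e / 2 for e in extent)
    d = _ellipsoid_metric(shape, spacing, center, semi)
    brain = d <= 1.0
    skull = (d > 1.0) & (d <= 1.18)
    return brain, skull, d, center, semi


def _take_nearest(metric: np.ndarray, allowed: np.ndarray, n: int) -> np.ndarray:
    """Mask of the n allowed voxels with the smallest metric values."""
    flat = np.where(allowed.ravel(), metric.ravel(), np.inf)
    if np.isfinite(flat).sum() < n:
        raise ValueError("lesion does not fit inside the brain")
    idx = np.argpartition(flat, n - 1)[:n]
    out = np.zeros(metric.size, dtype=bool)
    out[idx] = True
    return out.reshape(metric.shape)


def _lesion_mask(spec: PhantomSpec, brain: np.ndarray, d_brain: np.ndarray, rng) -> np.ndarray:
    vox_ml = spec.spacing[0] * spec.spacing[1] * spec.spacing[2] / 1000.0
    n_total = max(1, int(round(spec.lesion_target_ml / vox_ml)))
    interior = brain & (d_brain <= 0.8)  # keep lesions clear of the skull

    n_blobs = 1 if spec.lesion_kind == "PH" else int(rng.integers(3, 11))
    props = rng.dirichlet(np.full(n_blobs, 4.0)) if n_blobs > 1 else np.array([1.0])
    counts = np.maximum(1, np.round(props * n_total).astype(int))
    counts[-1] = max(1, n_total - int(counts[:-1].sum()))

    cand = np.argwhere(interior & (d_brain <= 0.6))
    lesion = np.zeros(spec.shape, dtype=bool)
    available = interior.copy()
    for n_i in counts:
        center_vox = cand[rng.integers(len(cand))]
        center_mm = tuple(center_vox[i] * spec.spacing[i] for i in range(3))
        # random ellipsoidal shape; absolute scale is irrelevant (nearest-n)
        ratios = rng.uniform(0.5, 1.0, size=3)
        semi = (
            max(ratios[0] * 10.0, spec.spacing[0]),  # allow single-slice blobs
            ratios[1] * 10.0,
            ratios[2] * 10.0,
        )
        metric = _ellipsoid_metric(spec.shape, spec.spacing, center_mm, semi)
        blob = _take_nearest(metric, available, int(n_i))
        lesion |= blob
        available &= ~blob
    return lesion


def make_head_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom: volume, ground truth, brain mask and ROI."""
    rng = np.random.default_rng(spec.seed)
    brain, skull, d_brain, _, _ = _head_geometry(spec)
    lesion = _lesion_mask(spec, brain, d_brain, rng)

    vox = np.full(spec.shape, AIR_HU, dtype=np.float64)
    vox[brain] = spec.background_mean
    vox[skull] = SKULL_HU
    draws = rng.normal(spec.lesion_mean, spec.lesion_sd, size=int(lesion.sum()))
    vox[lesion] = np.clip(draws, *HU_CLIP)

    if spec.blur_sigma > 0:
        vox = ndimage.gaussian_filter(
            vox, sigma=(0.0, spec.blur_sigma, spec.blur_sigma), mode="nearest"
        )
    if spec.noise_sd > 0:
        vox = vox + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = CTVolume(
        voxels=vox.astype(np.float32),
        spacing=spec.spacing,
        case_id=spec.case_id or f"phantom-{spec.lesion_kind}-{spec.seed}",
    )
    gt = BinaryMask(voxels=lesion, spacing=spec.spacing)
    brain_mask = BrainMask(mask=BinaryMask(voxels=brain, spacing=spec.spacing), provenance="phantom")

    zs, ys, xs = np.nonzero(lesion)
    pad = 5  # in-plane margin around the lesion bounding box
    roi = ROIBox(
        z0=int(zs.min()),
        z1=int(zs.max()) + 1,
        y0=max(0, int(ys.min()) - pad),
        y1=min(spec.shape[1], int(ys.max()) + 1 + pad),
        x0=max(0, int(xs.min()) - pad),
        x1=min(spec.shape[2], int(xs.max()) + 1 + pad),
    )
    return PhantomCase(spec=spec, volume=volume, gt=gt, brain=brain_mask, roi=roi)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a lognormal to the given mean and SD
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def make_cohort(
    n: int,
    ph_fraction: float = 23.0 / 51.0,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Specs for a cohort mixing PH-like and HI2-like cases.

    Per-case volumes are drawn from lognormal distributions moment-matched
    to the cohort summaries (PH: mean 17.28 mL, SD 12.44; HI2: mean
    6.81 mL, SD 9.59); the right skew matches the printed min-max ranges.
    Lesion mean/SD get mild per-case jitter.  HI2 cases default to a
    10 HU lower lesion mean (lower contrast to background).  The returned
    specs are lightweight; call :func:`make_head_phantom` to realise one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    n_ph = int(round(n * ph_fraction))
    rng = np.random.default_rng(seed)
    kinds = ["PH"] * n_ph + ["HI2"] * (n - n_ph)

    specs = []
    for i, kind in enumerate(kinds):
        mean_ml, sd_ml = PH_VOLUME_ML if kind == "PH" else HI2_VOLUME_ML
        mu, sig = _lognormal_params(mean_ml, sd_ml)
        vol_ml = float(rng.lognormal(mu, sig))
        vox_ml = base.spacing[0] * base.spacing[1] * base.spacing[2] / 1000.0
        vol_ml = max(vol_ml, 10 * vox_ml)  # at least a resolvable speck
        kind_mean = base.lesion_mean if kind == "PH" else base.lesion_mean - 10.0
        specs.append(
            replace(
                base,
                lesion_kind=kind,
                lesion_target_ml=vol_ml,
                lesion_mean=float(kind_mean + rng.normal(0.0, 3.0)),
                lesion_sd=float(np.clip(base.lesion_sd + rng.normal(0.0, 1.0), 2.0, 15.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
                case_id=f"cohort-{seed}-{i:03d}-{kind}",
            )
        )
    return specs


def write_dicom_series(vol: CTVolume, directory: str | Path) -> None:
    """Export a volume as a synthetic single-frame CT DICOM series.

    Stored pixels are int16 with slope 1 / intercept -1024, one file per
    axial slice, for exercising the series reader; not a clinically
    complete DICOM object.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[vol.case_id or "htseg-phantom"])
    study_uid = generate_uid(entropy_srcs=[(vol.case_id or "htseg-phantom") + "-study"])
    dz, dy, dx = vol.spacing

    for z in range(vol.shape[0]):
        stored = np.round(vol.voxels[z] + 1024.0).astype(np.int16)
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=[series_uid, str(z)])
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientID = vol.case_id or "phantom"
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [vol.origin[2], vol.origin[1], vol.origin[0] + z * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = stored.tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(directory / f"slice_{z:03d}.dcm", enforce_file_format=True)
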