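"""Synthetic 4D short-axis image phantom with AHA-16 segments and AIF tube.

Renders the simulated experiment at the image level: a three-slice
myocardial annulus divided into the 16 AHA segments (6 basal, 6 mid, 4
apical, equal angular sectors), the aorta-surrogate inflow tube as a disk
beside it, and a constant background.  Every voxel of a region carries
that region's contrast curve (plus optional Gaussian HU noise), so
ROI-extracting the stack inverts the rendering exactly at zero noise.

The stack and integer labelmap export to NIfTI (time as the 4th axis,
voxel units HU); extracted curves are ordinary :class:`ContrastCurve`
objects and serialize to CSV like any other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import ContrastCurve
from .errors import InvalidInputError
from .kinetics import AHA16_SEGMENTS

__all__ = [
    "ImagePhantomSpec",
    "TUBE_LABEL",
    "BACKGROUND_LABEL",
    "build_labelmap",
    "render_phantom",
    "extract_segment_tacs",
    "save_phantom_nifti",
]

BACKGROUND_LABEL = 0
TUBE_LABEL = 17

#: segments per slice: basal ring (6), mid ring (6), apical ring (4)
_SLICE_SEGMENTS = ((1, 2, 3, 4, 5, 6), (7, 8, 9, 10, 11, 12), (13, 14, 15, 16))


@dataclass(frozen=True)
class ImagePhantomSpec:
    """Geometry of the synthetic short-axis stack.

    In-plane coordinates are millimetres with the annulus centred at the
    origin; the default 64x64 grid at 2 mm spans ±64 mm.  Angular sectors
    start at the anterior insertion (12 o'clock) and run clockwise, per the
    AHA numbering convention.
    """

    grid_size: int = 64
    n_slices: int = 3
    voxel_size_mm: float = 2.0
    inner_radius_mm: float = 20.0
    outer_radius_mm: float = 32.0
    tube_center_mm: tuple[float, float] = (40.0, 40.0)
    tube_radius_mm: float = 8.0
    background_hu: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise InvalidInputError("need 0 < inner radius < outer radius")
        if self.tube_radius_mm <= 0 or self.voxel_size_mm <= 0:
            raise InvalidInputError("tube_radius_mm and voxel_size_mm must be positive")
        cx, cy = self.tube_center_mm
        if np.hypot(cx, cy) < self.outer_radius_mm + self.tube_radius_mm:
            raise InvalidInputError("tube must be disjoint from the myocardial annulus")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")
        if self.n_slices != 3:
            raise InvalidInputError("the 16-segment layout uses exactly 3 slices")

    @property
    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.grid_size / 2 - 0.5
        axis = (np.arange(self.grid_size) - half) * self.voxel_size_mm
        return np.meshgrid(axis, axis, indexing="ij")


def build_labelmap(spec: ImagePhantomSpec) -> np.ndarray:
    """Integer labelmap (x, y, slice): 0 background, 1..16 segments, 17 tube."""
    x, y = spec.coords_mm
    r = np.hypot(x, y)
    annulus = (r >= spec.inner_radius_mm) & (r <= spec.outer_radius_mm)
    # angle from 12 o'clock (+y), clockwise
    theta = np.mod(np.arctan2(x, y), 2 * np.pi)
    cx, cy = spec.tube_center_mm
    tube = np.hypot(x - cx, y - cy) <= spec.tube_radius_mm
    labelmap = np.zeros((spec.grid_size, spec.grid_size, spec.n_slices), dtype=np.int16)
    for z, segments in enumerate(_SLICE_SEGMENTS):
        plane = np.zeros((spec.grid_size, spec.grid_size), dtype=np.int16)
        n_sectors = len(segments)
        sector = np.minimum((theta / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
        for i, seg in enumerate(segments):
            plane[annulus & (sector == i)] = seg
        plane[tube] = TUBE_LABEL
        labelmap[:, :, z] = plane
    return labelmap


def render_phantom(
    spec: ImagePhantomSpec,
    segment_curves: dict[int, ContrastCurve],
    aif_curve: ContrastCurve,
    frame_times: np.ndarray,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the 4D stack (x, y, slice, frame) and its 3D labelmap.

    Each voxel of segment ``s`` carries ``segment_curves[s]`` evaluated at
    ``frame_times`` (plus optional noise), tube voxels carry the AIF, and
    background voxels the constant ``background_hu``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    missing = [s for s in AHA16_SEGMENTS if s not in segment_curves]
    if missing:
        raise InvalidInputError(f"missing contrast curves for segments {missing}")
    labelmap = build_labelmap(spec)
    nt = frame_times.size
    stack = np.full(labelmap.shape + (nt,), spec.background_hu, dtype=float)
    for seg in AHA16_SEGMENTS:
        stack[labelmap == seg] = segment_curves[seg].at(frame_times)
    stack[labelmap == TUBE_LABEL] = aif_curve.at(frame_times)
    if spec.noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        stack += rng.normal(0.0, spec.noise_sigma, stack.shape)
    return stack, labelmap


def extract_segment_tacs(
    stack: np.ndarray,
    labelmap: np.ndarray,
    frame_times: np.ndarray,
    injection_start: float = 5.0,
    labels=None,
) -> dict[int, ContrastCurve]:
    """Spatial-mean curve per label; the tube label yields the AIF.

    By default all non-background labels present in the labelmap are
    extracted; requesting an absent label is an error.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if stack.shape[:3] != labelmap.shape:
        raise InvalidInputError("stack and labelmap disagree on spatial shape")
    if stack.shape[3] != frame_times.size:
        raise InvalidInputError("frame_times length must match the stack's time axis")
    present = set(np.unique(labelmap)) - {BACKGROUND_LABEL}
    if labels is None:
        labels = sorted(present)
    missing = [l for l in labels if l not in present]
    if missing:
        raise InvalidInputError(f"labels {missing} absent from labelmap")
    out = {}
    for label in labels:
        mask = labelmap == label
        out[int(label)] = ContrastCurve(
            times=frame_times,
            values=stack[mask].mean(axis=0),
            injection_start=injection_start,
        )
    return out


def label_voxel_counts(spec: ImagePhantomSpec) -> dict[int, int]:
    """Voxels per non-background label; sets the ROI noise-averaging factor."""
    labelmap = build_labelmap(spec)
    labels, counts = np.unique(labelmap, return_counts=True)
    return {int(l): int(c) for l, c in zip(labels, counts) if l != BACKGROUND_LABEL}


def save_phantom_nifti(
    stack: np.ndarray,
    labelmap: np.ndarray,
    out_dir: str | Path,
    spec: ImagePhantomSpec,
    frame_interval: float = 1.0,
    prefix: str = "phantom",
) -> tuple[Path, Path]:
    """Write the 4D stack and labelmap as NIfTI files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spec.voxel_size_mm, spec.voxel_size_mm, 8.0, 1.0])
    img = nib.Nifti1Image(stack.astype(np.float32), affine)
    img.header.set_zooms((spec.voxel_size_mm, spec.voxel_size_mm, 8.0, frame_interval))
    stack_path = out_dir / f"{prefix}_4d.nii"
    nib.save(img, stack_path)
    lab = nib.Nifti1Image(labelmap.astype(np.int16), affine)
    label_path = out_dir / f"{prefix}_labels.nii"
    nib.save(lab, label_path)
    return stack_path, label_path
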