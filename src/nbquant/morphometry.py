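"""Quantitative parameters of segmented bodies (pipeline stage 3).

Two metrics are reported per body, chosen for robustness to confocal
anisotropy: the *diameter*, defined as the mean of the X- and Y-axis
bounding-box lengths in micrometres (the Z extent never enters, so the
poorer axial resolution cannot inflate sizes), and the *maximum gray
value*, the brightest raw voxel of the object in 8-bit a.u.  Bounding-box
lengths use inclusive voxel extents, ``(max - min + 1) * pitch``, so a
single-voxel object has the size of one voxel rather than zero.

Per-nucleus summaries are the body count plus, for nuclei that contain at
least one body, the arithmetic means of the per-body diameter and maximum
gray value.  For empty nuclei the means are *absent*, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConsistencyError, InputError

__all__ = [
    "BodyRecord",
    "NucleusMetrics",
    "measure_body",
    "measure_bodies",
    "summarize_nucleus",
    "rayleigh_limit",
]


@dataclass(frozen=True)
class BodyRecord:
    """One segmented body: voxel count, bounding-box extents (x, y, z) in
    micrometres, diameter = (x_len + y_len)/2, and the maximum raw
    intensity over its voxels."""

    body_id: int
    nucleus_id: int
    voxel_count: int
    bbox_extent: tuple[float, float, float]
    diameter_um: float
    max_gray: float


@dataclass(frozen=True)
class NucleusMetrics:
    """Per-nucleus summary; mean fields are ``None`` iff the nucleus has
    no bodies."""

    nucleus_id: int
    group: str
    n_bodies: int
    mean_diameter_um: Optional[float]
    mean_max_gray: Optional[float]
    cytoplasmic_flag: Optional[bool]


def measure_body(
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray],
    raw: np.ndarray,
    voxel_size: tuple[float, float, float],
    body_id: int = 1,
    nucleus_id: int = 0,
) -> BodyRecord:
    """Measure one body given its voxel index arrays (z, y, x).

    ``max_gray`` is read from the *raw* image, so it is not bounded below
    by the segmentation threshold (which may act on the blurred image).
    """
    zs, ys, xs = (np.asarray(a) for a in voxel_indices)
    if zs.size == 0:
        raise ConsistencyError("cannot measure an empty voxel set")
    dz, dy, dx = voxel_size
    z_len = float((zs.max() - zs.min() + 1) * dz)
    y_len = float((ys.max() - ys.min() + 1) * dy)
    x_len = float((xs.max() - xs.min() + 1) * dx)
    return BodyRecord(
        body_id=body_id,
        nucleus_id=nucleus_id,
        voxel_count=int(zs.size),
        bbox_extent=(x_len, y_len, z_len),
        diameter_um=(x_len + y_len) / 2.0,
        max_gray=float(np.asarray(raw)[zs, ys, xs].max()),
    )


def measure_bodies(
    label_grid: np.ndarray,
    raw: np.ndarray,
    voxel_size: tuple[float, float, float],
    nucleus_id: int = 0,
) -> list[BodyRecord]:
    """Measure every labelled object in a body label grid."""
    labels = np.unique(label_grid)
    labels = labels[labels > 0]
    return [
        measure_body(np.nonzero(label_grid == k), raw, voxel_size,
                     body_id=int(k), nucleus_id=nucleus_id)
        for k in labels
    ]


def summarize_nucleus(
    bodies: Sequence[BodyRecord],
    group: str,
    cytoplasmic_flag: Optional[bool] = None,
) -> NucleusMetrics:
    """Aggregate per-body records into one per-nucleus row."""
    ids = {b.nucleus_id for b in bodies}
    if len(ids) > 1:
        raise ConsistencyError(f"bodies from multiple nuclei: {sorted(ids)}")
    n = len(bodies)
    return NucleusMetrics(
        nucleus_id=ids.pop() if ids else 0,
        group=group,
        n_bodies=n,
        mean_diameter_um=float(np.mean([b.diameter_um for b in bodies])) if n else None,
        mean_max_gray=float(np.mean([b.max_gray for b in bodies])) if n else None,
        cytoplasmic_flag=cytoplasmic_flag,
    )


def rayleigh_limit(emission_wavelength_nm: float = 530.0,
                   numerical_aperture: float = 1.25) -> float:
    """Lateral Rayleigh resolution limit, 0.61 * lambda / NA, in um.

    Defaults describe Alexa 488 emission (~530 nm) through a 40x/1.25 NA
    objective, giving ~0.26 um — sizes below this are not optically
    meaningful even if the segmentation reports them.
    """
    if not 300 < emission_wavelength_nm < 800:
        raise InputError("emission wavelength must lie in (300, 800) nm")
    if numerical_aperture <= 0:
        raise InputError("numerical aperture must be positive")
    return 0.61 * (emission_wavelength_nm / 1000.0) / numerical_aperture
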