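"""Core in-memory containers: labeled volumes and 2-D slice samples.

A :class:`LabeledVolume` is the unit of I/O and evaluation — a single-channel
3-D image with voxel spacing, a modality tag (CT or T1-weighted MR) and a
slice-thickness domain tag.  Following common clinical convention, a scan is
"thick" when its slice spacing exceeds 3 mm and "thin" otherwise; the domain
tag is always derived from the spacing, never set independently.

A :class:`SliceSample` is the unit of training: one 2-D slice replicated to
three identical channels, with an optional per-pixel integer label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Slice spacing (mm) above which a scan counts as thick-slice.
THICK_THRESHOLD_MM = 3.0


class Modality(str, Enum):
    CT = "CT"
    MR_T1 = "MR_T1"


class Domain(str, Enum):
    THICK = "thick"
    THIN = "thin"


def domain_from_spacing(slice_spacing_mm: float) -> Domain:
    """Thick iff slice spacing > 3 mm."""
    return Domain.THICK if slice_spacing_mm > THICK_THRESHOLD_MM else Domain.THIN


@dataclass
class LabeledVolume:
    """3-D intensity array (slices, H, W) with spacing and tags.

    ``spacing`` is (slice, row, col) in mm, matching the array axes.  ``mask``
    is an optional binary ventricle mask of identical shape.  ``meta`` carries
    provenance (normalization statistics, slice truncation records, ...).
    """

    intensity: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    volume_id: str
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError(
                f"volume {self.volume_id!r}: intensity must be 3-D, "
                f"got shape {self.intensity.shape}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensity.shape:
                raise ValueError(
                    f"volume {self.volume_id!r}: mask shape {self.mask.shape} "
                    f"!= intensity shape {self.intensity.shape}"
                )

    @property
    def domain(self) -> Domain:
        return domain_from_spacing(self.spacing[0])

    @property
    def n_slices(self) -> int:
        return self.intensity.shape[0]

    def mask_volume_mm3(self) -> float:
        """Ventricle volume in mm^3 (voxel count times voxel volume)."""
        if self.mask is None:
            raise ValueError(f"volume {self.volume_id!r} has no mask")
        return float(self.mask.sum()) * float(np.prod(self.spacing))


@dataclass
class SliceSample:
    """One 2-D training sample: H x W x 3 image, optional H x W label map."""

    image: np.ndarray
    domain: Domain
    modality: Modality
    volume_id: str
    slice_index: int
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
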