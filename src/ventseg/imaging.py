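"""Volume I/O, intensity normalization and slice decomposition.

Volumes are stored as NIfTI (.nii.gz) with the array laid out
(slice, row, col) and the matching spacings in the header zooms.  The
thick/thin domain tag is never stored explicitly — it is re-derived from the
slice spacing on every read, so a file can never carry an inconsistent tag.

Normalization is a z-score over the head region.  The head region is found by
comparing against the background reference value taken from the volume border
(air surrounds the head in every phantom and any sane acquisition), which
makes the transform exactly invariant under positive affine intensity maps
a*x + b: the border reference shifts with the histogram, so the same voxels
are selected and the z-score removes the affine map entirely.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import Domain, LabeledVolume, Modality, SliceSample


class VolumeFormatError(ValueError):
    """Raised for files that are not 3-D single-channel volumes."""


# ---------------------------------------------------------------------------
# NIfTI read/write


def write_volume(vol: LabeledVolume, path: str | Path,
                 mask_path: str | Path | None = None) -> None:
    """Write intensities (and optionally the mask) as .nii/.nii.gz files.

    Gzip members are written with mtime=0 so identical volumes produce
    byte-identical files regardless of wall-clock time.
    """
    _write_array(np.asarray(vol.intensity, dtype=np.float32), vol.spacing, path)
    if mask_path is not None:
        if vol.mask is None:
            raise ValueError(f"volume {vol.volume_id!r} has no mask to write")
        _write_array(np.asarray(vol.mask, dtype=np.uint8), vol.spacing, mask_path)


def _write_array(arr: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    path = Path(path)
    if path.name.endswith(".nii.gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))


def read_volume(path: str | Path, modality: Modality | str = Modality.CT,
                volume_id: str | None = None,
                mask_path: str | Path | None = None) -> LabeledVolume:
    """Read a 3-D NIfTI volume; domain derives from the slice spacing."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj).astype(np.uint8)
    return LabeledVolume(
        intensity=data.astype(np.float64),
        spacing=tuple(float(z) for z in zooms),
        modality=Modality(modality),
        volume_id=volume_id or path.name.split(".")[0],
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Normalization


def _head_region(x: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Boolean head mask: voxels differing from the border background value."""
    border = np.concatenate([
        x[0].ravel(), x[-1].ravel(),
        x[:, 0].ravel(), x[:, -1].ravel(),
        x[:, :, 0].ravel(), x[:, :, -1].ravel(),
    ])
    bg = float(np.median(border))
    scale = max(float(np.max(np.abs(x - bg))), 1.0)
    return np.abs(x - bg) > rtol * scale


#: Default normalization policy: head-region z-scoring for both modalities.
#: (CT windowing is not emulated; phantom intensities are abstract units.)
DEFAULT_NORMALIZATION_POLICY = {Modality.CT: "zscore", Modality.MR_T1: "zscore"}


def normalize(vol: LabeledVolume,
              policy: dict | None = None) -> LabeledVolume:
    """Normalize per the modality's policy (currently head-region z-scoring).

    The affine (x - mu) / sd is applied to every voxel; mu and sd are the
    head-region mean and standard deviation.  The statistics are stored under
    ``meta['norm']`` so the transform is invertible (:func:`denormalize`).
    Applying :func:`normalize` twice is the identity up to float precision.
    """
    policy = DEFAULT_NORMALIZATION_POLICY if policy is None else policy
    method = policy.get(Modality(vol.modality))
    if method is None:
        raise ValueError(
            f"no normalization policy defined for modality {vol.modality}")
    if method != "zscore":
        raise ValueError(f"unknown normalization method {method!r}")
    x = np.asarray(vol.intensity, dtype=np.float64)
    region = _head_region(x)
    if not region.any():
        raise ValueError(
            f"volume {vol.volume_id!r}: degenerate constant intensity, "
            "cannot normalize"
        )
    mu = float(x[region].mean())
    sd = float(x[region].std())
    if sd == 0.0:
        raise ValueError(
            f"volume {vol.volume_id!r}: zero intensity variance over the head "
            "region, cannot normalize"
        )
    out = (x - mu) / sd
    meta = dict(vol.meta)
    meta["norm"] = {"mean": mu, "sd": sd}
    return LabeledVolume(
        intensity=out, spacing=vol.spacing, modality=vol.modality,
        volume_id=vol.volume_id, mask=vol.mask, meta=meta,
    )


def denormalize(vol: LabeledVolume) -> LabeledVolume:
    stats = vol.meta.get("norm")
    if stats is None:
        raise ValueError(f"volume {vol.volume_id!r} carries no normalization stats")
    out = vol.intensity * stats["sd"] + stats["mean"]
    meta = {k: v for k, v in vol.meta.items() if k != "norm"}
    return LabeledVolume(
        intensity=out, spacing=vol.spacing, modality=vol.modality,
        volume_id=vol.volume_id, mask=vol.mask, meta=meta,
    )


# ---------------------------------------------------------------------------
# Slice decomposition


def volume_to_samples(vol: LabeledVolume) -> list[SliceSample]:
    """Split a (normalized) volume into per-slice 3-channel samples.

    Labels are attached iff the volume carries a mask.  Slice order and
    0-based indices are preserved so predictions can be restacked.
    """
    samples = []
    for i in range(vol.n_slices):
        sl = np.asarray(vol.intensity[i], dtype=np.float32)
        img = np.repeat(sl[:, :, None], 3, axis=2)
        label = None if vol.mask is None else vol.mask[i].astype(np.int64)
        samples.append(SliceSample(
            image=img, domain=vol.domain, modality=vol.modality,
            volume_id=vol.volume_id, slice_index=i, label=label,
        ))
    return samples
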