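"""Synthetic head/ventricle phantoms with a thick-slice partial-volume model.

The generator emulates the statistical structure of a clinical thick/thin
cohort: a head-shaped ellipsoid of brain tissue containing a bilateral,
branched ventricle-like cavity whose size sweeps from normal to markedly
enlarged (hydrocephalus-like), imaged at a thin slice spacing and again at a
thick spacing obtained by averaging blocks of consecutive thin slices — the
partial-volume effect that creates the thick-vs-thin domain gap.

Intensities are abstract units; only the contrast ordering is contractual
(CSF-filled ventricles darker than brain on both CT and T1-weighted MR).
Noise is additive Gaussian inside the head.  The thick volume is built from
the *noiseless* thin volume and receives its own independent noise draw with
standard deviation reduced by sqrt(thick_factor), as slab averaging of k
acquisitions would give — so thick images are cleaner as well as blurrier
through-plane, and neither volume is a deterministic function of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import read_volume, write_volume
from .volume import Domain, LabeledVolume, Modality, THICK_THRESHOLD_MM

#: In-plane voxel size (mm); 64 voxels at 3 mm span 192 mm, enough for a head.
IN_PLANE_MM = 3.0

#: Default tissue means (background, brain, ventricle) per modality.  CSF is
#: hypodense on CT and dark on T1, hence ventricle < brain in both.
DEFAULT_INTENSITY_MEANS = {
    Modality.CT: (0.0, 1.0, 0.35),
    Modality.MR_T1: (0.0, 1.0, 0.20),
}

#: Severity mix spanning normal -> atrophy -> NPH -> acquired hydrocephalus.
DEFAULT_SEVERITY_MIX = {1.0: 0.25, 1.4: 0.25, 1.8: 0.25, 2.3: 0.25}
DEFAULT_MODALITY_MIX = {Modality.CT: 0.5, Modality.MR_T1: 0.5}

#: Default cohort layout: labeled thick / unlabeled thin training volumes and
#: held-out phantom pairs (each pair contributes one thick + one thin volume).
DEFAULT_COHORT = {"n_train_labeled_thick": 40, "n_train_unlabeled_thin": 40,
                  "n_test": 10}


@dataclass
class PhantomSpec:
    """Parameters of one thin/thick phantom pair.

    ``thin_spacing * thick_factor`` must exceed 3 mm so the derived thick
    volume really is thick-slice; ``thin_spacing`` itself must not.
    """

    head_radii: tuple[float, float, float] = (60.0, 85.0, 75.0)
    ventricle_scale: float = 1.0
    modality: Modality = Modality.CT
    thin_spacing: float = 0.6
    thick_factor: int = 6
    intensity_means: tuple[float, float, float] | None = None
    noise_sd: float = 0.22
    noise_correlation_mm: float = 5.0
    in_plane_psf_mm: float = 0.0
    in_plane_size: tuple[int, int] = (64, 64)
    n_slices: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.intensity_means is None:
            self.intensity_means = DEFAULT_INTENSITY_MEANS[self.modality]
        if not (0 < self.thin_spacing <= THICK_THRESHOLD_MM):
            raise ValueError(f"thin_spacing must be in (0, 3] mm, got {self.thin_spacing}")
        if self.thick_factor < 2:
            raise ValueError(f"thick_factor must be >= 2, got {self.thick_factor}")
        if self.thin_spacing * self.thick_factor <= THICK_THRESHOLD_MM:
            raise ValueError(
                "thin_spacing * thick_factor must exceed 3 mm so the averaged "
                f"volume is thick-slice; got {self.thin_spacing * self.thick_factor}"
            )
        if self.ventricle_scale < 0.5:
            raise ValueError(f"ventricle_scale must be >= 0.5, got {self.ventricle_scale}")
        bg, brain, vent = self.intensity_means
        if not (vent < brain):
            raise ValueError(
                f"ventricle mean {vent} must be below brain mean {brain} "
                f"(CSF is dark on {self.modality.value})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# Geometry

# Lateral-ventricle skeleton in mm, right hemisphere; (z, y, x) control points
# and tube radii at each point.  Mirrored over the midline (x -> -x) for the
# left side.  Anterior horn -> body -> atrium -> posterior horn, plus an
# inferior-horn branch from the atrium: the bilateral branched topology of the
# ventricular system.
_LATERAL_PATH = np.array([
    (5.0, 38.0, 10.0),    # anterior horn tip
    (9.0, 12.0, 16.0),    # body
    (3.0, -22.0, 20.0),   # atrium
    (-3.0, -44.0, 13.0),  # posterior horn tip
])
_LATERAL_RADII = np.array([3.0, 4.5, 4.5, 2.6])
_INFERIOR_BRANCH = np.array([
    (3.0, -22.0, 20.0),   # atrium (branch point)
    (-9.0, -2.0, 30.0),   # inferior horn tip
])
_INFERIOR_RADII = np.array([4.0, 2.2])
# Third ventricle: midline slab bridging the two bodies.
_THIRD_PATH = np.array([(7.0, 14.0, 0.0), (-6.0, -6.0, 0.0)])
_THIRD_RADII = np.array([2.6, 2.2])


def _tube_mask(zz, yy, xx, path, radii, scale):
    """Union of capsules along a polyline; radii multiplied by scale."""
    mask = np.zeros(zz.shape, dtype=bool)
    pts = np.stack([zz, yy, xx], axis=-1)
    for a, b, ra, rb in zip(path[:-1], path[1:], radii[:-1], radii[1:]):
        d = b - a
        dd = float(d @ d)
        t = np.clip(((pts - a) @ d) / dd, 0.0, 1.0)
        proj = a + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
        mask |= dist <= (ra + (rb - ra) * t) * scale
    return mask


def _build_thin(spec: PhantomSpec, rng: np.random.Generator):
    """Noiseless thin-grid head/ventricle masks and the mm coordinate grid."""
    ns, (h, w) = spec.n_slices, spec.in_plane_size
    z = (np.arange(ns) - (ns - 1) / 2.0) * spec.thin_spacing
    y = (np.arange(h) - (h - 1) / 2.0) * IN_PLANE_MM
    x = (np.arange(w) - (w - 1) / 2.0) * IN_PLANE_MM
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")

    # Seeded anatomical variability: head radii +-5 %, head centre shift,
    # mirrored control-point jitter with a small left/right asymmetry.
    radii = np.asarray(spec.head_radii) * rng.uniform(0.95, 1.05, size=3)
    centre = np.array([rng.uniform(-4, 4), rng.uniform(-3, 3), rng.uniform(-3, 3)])
    head = (((zz - centre[0]) / radii[0]) ** 2
            + ((yy - centre[1]) / radii[1]) ** 2
            + ((xx - centre[2]) / radii[2]) ** 2) <= 1.0

    jit = rng.normal(0.0, 1.2, size=_LATERAL_PATH.shape)
    jit_b = rng.normal(0.0, 1.2, size=_INFERIOR_BRANCH.shape)
    asym = rng.normal(0.0, 0.6, size=(2,) + _LATERAL_PATH.shape)
    asym_b = rng.normal(0.0, 0.6, size=(2,) + _INFERIOR_BRANCH.shape)
    s = spec.ventricle_scale
    vent = np.zeros_like(head)
    for side, flip in ((0, 1.0), (1, -1.0)):
        lat = (_LATERAL_PATH + jit + asym[side]) * np.array([1.0, 1.0, flip])
        inf = (_INFERIOR_BRANCH + jit_b + asym_b[side]) * np.array([1.0, 1.0, flip])
        vent |= _tube_mask(zz, yy, xx, lat, _LATERAL_RADII, s)
        vent |= _tube_mask(zz, yy, xx, inf, _INFERIOR_RADII, s)
    third = _THIRD_PATH + rng.normal(0.0, 0.8, size=_THIRD_PATH.shape)
    vent |= _tube_mask(zz, yy, xx, third, _THIRD_RADII, s)

    # Cap the cavity inside the brain so ventricle remains a strict subset of
    # the head no matter how enlarged it is.
    inner = (((zz - centre[0]) / (radii[0] * 0.80)) ** 2
             + ((yy - centre[1]) / (radii[1] * 0.80)) ** 2
             + ((xx - centre[2]) / (radii[2] * 0.80)) ** 2) <= 1.0
    vent &= inner & head
    return head, vent


# ---------------------------------------------------------------------------
# Generation


def _noise_field(rng: np.random.Generator, shape, sd: float,
                 correlation_mm: float) -> np.ndarray:
    """Additive Gaussian acquisition noise, optionally with in-plane spatial
    correlation (reconstruction-kernel mottle), normalized to variance sd^2."""
    noise = rng.normal(0.0, 1.0, size=shape)
    if correlation_mm > 0:
        sigma_vox = correlation_mm / IN_PLANE_MM
        noise = gaussian_filter(noise, sigma=(0.0, sigma_vox, sigma_vox))
        noise /= noise.std()
    return sd * noise


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, LabeledVolume]:
    """Generate a paired (thin, thick) labeled phantom.

    The thick volume is the noiseless thin volume block-averaged over
    ``thick_factor`` consecutive slices (majority-vote mask, ties counting as
    foreground), with its own independent noise draw.  Trailing slices that do
    not fill a block are dropped and recorded in the metadata.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E3779B9]))
    head, vent = _build_thin(spec, rng)
    bg, brain, ventricle = spec.intensity_means
    clean = np.full(head.shape, bg, dtype=np.float64)
    clean[head] = brain
    clean[vent] = ventricle
    if spec.in_plane_psf_mm > 0:
        # In-plane point-spread blur of the acquisition; applied before slab
        # averaging so thick remains an exact block mean of thin.
        sigma_vox = spec.in_plane_psf_mm / IN_PLANE_MM
        clean = gaussian_filter(clean, sigma=(0.0, sigma_vox, sigma_vox))

    k = spec.thick_factor
    n_blocks = spec.n_slices // k
    n_used = n_blocks * k
    truncated = spec.n_slices - n_used

    thick_clean = clean[:n_used].reshape(n_blocks, k, *clean.shape[1:]).mean(axis=1)
    vote = vent[:n_used].reshape(n_blocks, k, *vent.shape[1:]).sum(axis=1)
    thick_mask = (vote * 2 >= k).astype(np.uint8)  # ties -> foreground
    thick_head = head[:n_used].reshape(n_blocks, k, *head.shape[1:]).mean(axis=1) > 0

    thin = clean.copy()
    thick = thick_clean.copy()
    if spec.noise_sd > 0:
        thin_noise = _noise_field(rng, clean.shape, spec.noise_sd,
                                  spec.noise_correlation_mm)
        thick_noise = _noise_field(rng, thick_clean.shape,
                                   spec.noise_sd / np.sqrt(k),
                                   spec.noise_correlation_mm)
        thin[head] += thin_noise[head]
        thick[thick_head] += thick_noise[thick_head]

    tag = f"{spec.modality.value.lower()}_s{spec.seed}"
    meta = {"ventricle_scale": spec.ventricle_scale, "truncated_slices": truncated}
    thin_vol = LabeledVolume(
        intensity=thin, mask=vent.astype(np.uint8),
        spacing=(spec.thin_spacing, IN_PLANE_MM, IN_PLANE_MM),
        modality=spec.modality, volume_id=f"{tag}_thin", meta=dict(meta),
    )
    thick_vol = LabeledVolume(
        intensity=thick, mask=thick_mask,
        spacing=(spec.thin_spacing * k, IN_PLANE_MM, IN_PLANE_MM),
        modality=spec.modality, volume_id=f"{tag}_thick", meta=dict(meta),
    )
    assert thin_vol.domain == Domain.THIN and thick_vol.domain == Domain.THICK
    return thin_vol, thick_vol


# ---------------------------------------------------------------------------
# Cohort


def _draw(rng: np.random.Generator, mix: dict):
    keys = list(mix.keys())
    p = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def make_cohort(n_train_labeled_thick: int, n_train_unlabeled_thin: int,
                n_test: int, out_dir: str | Path,
                severity_mix: dict | None = None,
                modality_mix: dict | None = None,
                seed: int = 0,
                spec_template: PhantomSpec | None = None) -> Path:
    """Write a synthetic cohort to ``out_dir`` and return the manifest path.

    Splits: ``train`` thick volumes with masks listed in the manifest;
    ``train`` thin volumes whose masks are withheld (written to disk but
    referenced only from ``ground_truth.csv``); ``test`` pairs contributing
    one thick and one thin volume each, masks likewise withheld.  Paths in the
    manifest are relative to its directory; generation is fully reproducible
    given the seed.
    """
    severity_mix = severity_mix or dict(DEFAULT_SEVERITY_MIX)
    modality_mix = modality_mix or dict(DEFAULT_MODALITY_MIX)
    if min(n_train_labeled_thick, n_train_unlabeled_thin, n_test) < 0:
        raise ValueError("cohort counts must be nonnegative")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort output directory not writable: {out_dir}") from exc

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FF_EE]))
    rows, truth_rows = [], []
    counter = 0

    def new_spec():
        nonlocal counter
        counter += 1
        base = spec_template or PhantomSpec()
        return replace(
            base,
            ventricle_scale=float(_draw(rng, severity_mix)),
            modality=Modality(_draw(rng, modality_mix)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    def emit(vol: LabeledVolume, vid: str, split: str, public_mask: bool):
        path = f"{vid}.nii.gz"
        mask_file = f"{vid}_mask.nii.gz"
        write_volume(vol, out_dir / path, out_dir / mask_file)
        rows.append({
            "volume_id": vid, "path": path,
            "mask_path": mask_file if public_mask else "",
            "modality": vol.modality.value, "domain": vol.domain.value,
            "split": split,
        })
        if not public_mask:
            truth_rows.append({"volume_id": vid, "mask_path": mask_file})

    for i in range(n_train_labeled_thick):
        _, thick = generate_phantom(new_spec())
        emit(thick, f"train_thick_{i:03d}", "train", public_mask=True)
    for i in range(n_train_unlabeled_thin):
        thin, _ = generate_phantom(new_spec())
        emit(thin, f"train_thin_{i:03d}", "train", public_mask=False)
    for i in range(n_test):
        thin, thick = generate_phantom(new_spec())
        emit(thick, f"test_thick_{i:03d}", "test", public_mask=False)
        emit(thin, f"test_thin_{i:03d}", "test", public_mask=False)

    manifest = out_dir / "manifest.csv"
    cols = ["volume_id", "path", "mask_path", "modality", "domain", "split"]
    pd.DataFrame(rows, columns=cols).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows, columns=["volume_id", "mask_path"]).to_csv(
        out_dir / "ground_truth.csv", index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, keep_default_na=False)
    df.attrs["root"] = Path(manifest_path).parent
    return df


def load_volume_row(row, root: Path, with_truth: bool = False,
                    truth: dict | None = None) -> LabeledVolume:
    """Materialize one manifest row; optionally attach withheld ground truth."""
    mask_path = row["mask_path"] or None
    if mask_path is None and with_truth:
        if truth is None or row["volume_id"] not in truth:
            raise KeyError(f"no ground truth available for volume {row['volume_id']!r}")
        mask_path = truth[row["volume_id"]]
    return read_volume(
        root / row["path"], modality=row["modality"], volume_id=row["volume_id"],
        mask_path=None if mask_path is None else root / mask_path,
    )


def load_ground_truth(manifest_path: str | Path) -> dict:
    gt = Path(manifest_path).parent / "ground_truth.csv"
    if not gt.exists():
        return {}
    df = pd.read_csv(gt, keep_default_na=False)
    return dict(zip(df["volume_id"], df["mask_path"]))
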