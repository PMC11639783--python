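"""Synthetic radiograph phantoms with identity-stable anatomy.

A phantom models the statistical structure the embedding method relies on:
per-identity skeletal/anatomical geometry (thorax outline, rib pattern,
spine, cardiac silhouette, clavicles) that is constant across a patient's
images, plus per-acquisition variation (small rotation/translation,
brightness/contrast jitter, additive Gaussian noise).  Rendering is purely
parametric geometry - it makes no attempt at photorealism, disease findings
or DICOM semantics.

``generate_dataset`` writes 8-bit PNGs plus an NIH-dialect metadata CSV
(``Image Index``, ``Patient ID``) so the whole pipeline runs with no
external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

_MAX_ROTATION = 10.0       # degrees
_MAX_TRANSLATION = 0.05    # fraction of the frame
_MAX_AXIS = 0.49           # semi-axis as fraction of the frame


@dataclass
class IdentityPhantom:
    """Per-identity anatomy parameters (fractions of the image frame)."""

    thorax_axes: tuple[float, float] = (0.33, 0.38)
    rib_count: int = 8
    rib_spacing: float = 0.065
    rib_curvature: float = 0.25
    cardiac_width_fraction: float = 0.32
    clavicle_angle: float = 12.0
    spine_offset: float = 0.0
    identity_seed: int = 0

    def __post_init__(self):
        a, b = self.thorax_axes
        if not (0.0 <= a <= _MAX_AXIS and 0.0 <= b <= _MAX_AXIS):
            raise ValueError(f"thorax semi-axes {self.thorax_axes} out of [0, {_MAX_AXIS}]")
        if self.rib_count < 0:
            raise ValueError("rib_count must be >= 0")
        if abs(self.spine_offset) > 0.1:
            raise ValueError("spine_offset out of renderable bounds")

    @classmethod
    def sample(cls, identity_seed: int) -> "IdentityPhantom":
        """Draw one identity from the population geometry distribution."""
        rng = np.random.default_rng(identity_seed)
        return cls(
            thorax_axes=(rng.uniform(0.27, 0.38), rng.uniform(0.31, 0.42)),
            rib_count=int(rng.integers(7, 11)),
            rib_spacing=rng.uniform(0.055, 0.080),
            rib_curvature=rng.uniform(0.10, 0.40),
            cardiac_width_fraction=rng.uniform(0.22, 0.42),
            clavicle_angle=rng.uniform(5.0, 22.0),
            spine_offset=rng.uniform(-0.03, 0.03),
            identity_seed=identity_seed,
        )


@dataclass
class AcquisitionParams:
    """Per-image acquisition variation.

    Bounds: |rotation| <= 10 deg, |translation| <= 5% of the frame; jitters
    default to zero so a bare phantom renders without degradation.
    """

    noise_sd: float = 0.0
    brightness: float = 0.0
    contrast: float = 0.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    acquisition_seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.rotation) > _MAX_ROTATION:
            raise ValueError(f"|rotation| must be <= {_MAX_ROTATION} deg")
        if any(abs(t) > _MAX_TRANSLATION for t in self.translation):
            raise ValueError(f"|translation| must be <= {_MAX_TRANSLATION} of frame")

    @classmethod
    def sample(cls, acquisition_seed: int, noise_sd: float = 0.03) -> "AcquisitionParams":
        """Default acquisition-variation distribution (see methods note)."""
        rng = np.random.default_rng(acquisition_seed)
        return cls(
            noise_sd=noise_sd,
            brightness=rng.uniform(-0.08, 0.08),
            contrast=rng.uniform(-0.10, 0.10),
            rotation=rng.uniform(-3.0, 3.0),
            translation=(rng.uniform(-0.02, 0.02), rng.uniform(-0.02, 0.02)),
            acquisition_seed=acquisition_seed,
        )


def _band(value, center, half_width):
    return np.abs(value - center) < half_width


def render_radiograph(phantom: IdentityPhantom, acq: AcquisitionParams,
                      size: int = 200) -> np.ndarray:
    """Render one size x size grayscale image in [0, 1], deterministic."""
    y, x = np.mgrid[0:size, 0:size]
    # normalized frame coordinates in [-0.5, 0.5]
    xn = (x + 0.5) / size - 0.5
    yn = (y + 0.5) / size - 0.5
    img = np.full((size, size), 0.12)
    a, b = phantom.thorax_axes
    if a > 0 and b > 0:
        thorax = (xn / a) ** 2 + (yn / b) ** 2 <= 1.0
        img[thorax] += 0.33
        # lung fields: darker inner half-ellipses either side of the spine
        for side in (-1, 1):
            lung = ((xn - side * 0.5 * a) / (0.42 * a)) ** 2 + (yn / (0.80 * b)) ** 2 <= 1.0
            img[lung & thorax] -= 0.16
        # spine: bright vertical band
        img[thorax & _band(xn, phantom.spine_offset, 0.035)] += 0.22
        # ribs: curved bright bands following y = y_r + curvature * (x/a)^2
        for r in range(phantom.rib_count):
            y_r = -0.78 * b + r * phantom.rib_spacing
            rib = _band(yn - phantom.rib_curvature * (xn / max(a, 1e-9)) ** 2 * a,
                        y_r, 0.011)
            img[rib & thorax] += 0.18
        # cardiac silhouette: bright ellipse, lower-left of center
        cw = phantom.cardiac_width_fraction
        if cw > 0:
            heart = ((xn - 0.06) / (cw * a)) ** 2 + ((yn - 0.16 * b * 2) / (0.38 * b)) ** 2 <= 1.0
            img[heart & thorax] += 0.14
        # clavicles: angled bright bands across the apices
        ang = np.deg2rad(phantom.clavicle_angle)
        for side in (-1, 1):
            clav = (
                _band(yn + 0.80 * b - np.tan(ang) * side * (xn - side * 0.06), 0.0, 0.010)
                & (side * xn > 0.04)
                & (side * xn < a)
            )
            img[clav] += 0.18
    img = np.clip(img, 0.0, 1.0)
    # acquisition degradation
    if acq.contrast:
        img = 0.5 + (1.0 + acq.contrast) * (img - 0.5)
    if acq.brightness:
        img = img + acq.brightness
    if acq.rotation:
        img = ndimage.rotate(img, acq.rotation, reshape=False, order=1, mode="nearest")
    if any(acq.translation):
        shift = (acq.translation[1] * size, acq.translation[0] * size)
        img = ndimage.shift(img, shift, order=1, mode="nearest")
    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.acquisition_seed)
        img = img + rng.normal(0.0, acq.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(n_identities: int, images_per_identity: int,
                     size: int = 200, seed: int = 0, out_dir=None,
                     noise_sd: float = 0.03):
    """Render a phantom cohort; returns (metadata DataFrame, phantom list).

    With ``out_dir`` set, writes one 8-bit PNG per image plus
    ``metadata.csv`` in the NIH dialect; the DataFrame's ``Image Index``
    column then matches the filenames on disk.  Without ``out_dir`` the
    DataFrame gains an ``array`` column holding the rendered images.
    """
    if n_identities < 2:
        raise ValueError("need at least two identities")
    if images_per_identity < 1:
        raise ValueError("images_per_identity must be >= 1")
    master = np.random.default_rng(seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows, phantoms, arrays = [], [], []
    for pid in range(1, n_identities + 1):
        identity_seed = int(master.integers(2 ** 31))
        phantom = IdentityPhantom.sample(identity_seed)
        phantoms.append(phantom)
        age = int(master.integers(18, 90))
        gender = "M" if master.integers(2) else "F"
        for k in range(images_per_identity):
            acq_seed = int(master.integers(2 ** 31))
            acq = AcquisitionParams.sample(acq_seed, noise_sd=noise_sd)
            img = render_radiograph(phantom, acq, size=size)
            name = f"{pid:08d}_{k:03d}.png"
            if out_dir is not None:
                as_u8 = np.round(img * 255.0).astype(np.uint8)
                Image.fromarray(as_u8, mode="L").save(out_dir / name)
            else:
                arrays.append(img)
            rows.append({
                "Image Index": name,
                "Patient ID": pid,
                "Follow-up #": k,
                "Patient Age": age,
                "Patient Gender": gender,
            })
    metadata = pd.DataFrame(rows)
    if out_dir is not None:
        metadata.to_csv(out_dir / "metadata.csv", index=False)
    else:
        metadata["array"] = arrays
    return metadata, phantoms
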