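"""Seeded synthetic fixtures: two-class texture images and feature-space blobs.

The texture generator emulates the one property the texture pipeline needs
from histopathology-style images — two classes with distinguishable texture
*scale* — without attempting tissue realism.  Class "benign" images are
Gaussian noise fields blurred with a wide kernel (smooth, coherent texture:
low contrast, high homogeneity); class "malignant" images use a narrow (or
no) kernel and stay rough (high contrast).  Every image is contrast-
stretched to the full 8-bit range before saving so the classes differ in
texture scale only, not in brightness or amplitude, and so that heavily
blurred fields do not quantize to constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import EmptyDatasetError, InvalidInputError


@dataclass(frozen=True)
class TextureGenSpec:
    """Generator settings for the two-class texture fixture.

    ``smooth_kernel``/``rough_kernel`` are Gaussian blur sigmas in pixels for
    the benign/malignant class; ``rough_kernel < smooth_kernel`` guarantees
    the malignant class has the higher expected contrast.  ``noise_sd`` is
    the pre-blur noise amplitude in 8-bit intensity units.
    """

    n_per_class: int = 50
    resolution: int = 40
    smooth_kernel: float = 8.0
    rough_kernel: float = 0.0
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.smooth_kernel < 0 or self.rough_kernel < 0:
            raise InvalidInputError("blur kernels must be >= 0")
        if self.rough_kernel >= self.smooth_kernel:
            raise InvalidInputError("rough_kernel must be < smooth_kernel")
        if self.resolution < 8:
            raise InvalidInputError("resolution must be >= 8")
        if self.noise_sd <= 0:
            raise InvalidInputError("noise_sd must be > 0")


@dataclass(frozen=True)
class BlobGenSpec:
    """Two isotropic Gaussian point clouds in feature space."""

    n_per_class: int = 100
    dim: int = 4
    center_a: tuple[float, ...] | None = None
    center_b: tuple[float, ...] | None = None
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidInputError("sd must be > 0")
        if self.n_per_class < 1:
            raise InvalidInputError("n_per_class must be >= 1")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Resolved centers; defaults place them 10*sd apart."""
        if self.center_a is not None and self.center_b is not None:
            a = np.asarray(self.center_a, dtype=float)
            b = np.asarray(self.center_b, dtype=float)
        else:
            a = np.zeros(self.dim)
            # offset along the all-ones diagonal, total separation 10*sd
            b = np.full(self.dim, 10.0 * self.sd / np.sqrt(self.dim))
        if a.shape != (self.dim,) or b.shape != (self.dim,):
            raise InvalidInputError("centers must match dim")
        return a, b

    @property
    def separation(self) -> float:
        a, b = self.centers()
        return float(np.linalg.norm(a - b))


def _texture_field(rng: np.random.Generator, spec: TextureGenSpec, sigma: float) -> np.ndarray:
    field = rng.normal(128.0, spec.noise_sd, size=(spec.resolution, spec.resolution))
    if sigma > 0:
        field = gaussian_filter(field, sigma=sigma, mode="reflect")
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        stretched = np.full_like(field, 128.0)
    else:
        stretched = (field - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(stretched), 0, 255).astype(np.uint8)


def make_texture_dataset(spec: TextureGenSpec, out_dir: str | Path) -> Path:
    """Write the two-class PNG fixture in benign/ and malignant/ subfolders.

    Byte-identical for a fixed spec (seeded noise, deterministic PNG
    encoding); the spec itself is stored as ``generator.json`` alongside the
    images for provenance.  Returns the fixture root.
    """
    if spec.n_per_class < 1:
        raise EmptyDatasetError("n_per_class must be >= 1")
    root = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    for label, sigma in ((("benign"), spec.smooth_kernel), (("malignant"), spec.rough_kernel)):
        cls_dir = root / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        for idx in range(spec.n_per_class):
            arr = _texture_field(rng, spec, sigma)
            Image.fromarray(arr, mode="L").save(cls_dir / f"{label}_{idx:03d}.png")
    (root / "generator.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return root


def make_feature_blobs(spec: BlobGenSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the blob fixture.

    Returns ``(points, labels, true_centers)`` where labels are 0 for the
    first blob and 1 for the second, and ``true_centers`` has shape (2, D)
    for recovery assertions.
    """
    a, b = spec.centers()
    rng = np.random.default_rng(spec.seed)
    pts_a = rng.normal(a, spec.sd, size=(spec.n_per_class, spec.dim))
    pts_b = rng.normal(b, spec.sd, size=(spec.n_per_class, spec.dim))
    points = np.vstack([pts_a, pts_b])
    labels = np.repeat([0, 1], spec.n_per_class)
    return points, labels, np.stack([a, b])
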