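"""Gray-level co-occurrence matrix (GLCM) texture features.

This module turns a quantized grayscale image into the four-component
texture feature vector

    E = [ASM, CON, IDM, COR]

where, for a normalized co-occurrence table ``P`` over gray levels
``i, j = 0 .. N_g - 1``,

* ASM (angular second moment / energy) = sum P(i,j)^2 — concentration of
  the pair distribution; high for uniform, fine textures;
* CON (contrast) = sum (i-j)^2 P(i,j) — depth/clarity of texture grooves;
* IDM (inverse difference moment / homogeneity) = sum P(i,j)/(1+(i-j)^2);
* COR (correlation) = sum (i-mu1)(j-mu2) P(i,j) / (d1 d2), the normalized
  covariance of the row/column marginals.

Shannon entropy (ENT, in bits) and Tamura coarseness are available as
optional extras.  All statistics are computed on the *normalized* table so
that values are comparable across image sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateCorrelationError,
    GLCMContractError,
    InvalidInputError,
    NoPairsError,
)

CANONICAL_ANGLES = (0, 45, 90, 135)

#: (row, col) pixel offset per canonical angle, unit distance.  Angles are
#: measured counter-clockwise with image rows increasing downward, so 45°
#: pairs a pixel with its upper-right neighbor.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_NORM_TOL = 1e-8


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer gray levels in ``[0, n_levels - 1]``."""

    pixels: np.ndarray
    n_levels: int

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("GrayImage requires a non-empty 2-D pixel grid")
        if self.n_levels < 2:
            raise InvalidInputError("n_levels must be >= 2")
        if not np.issubdtype(px.dtype, np.integer):
            raise InvalidInputError("pixel values must be integers")
        if px.min() < 0 or px.max() >= self.n_levels:
            raise InvalidInputError("pixel values must lie in [0, n_levels - 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GLCMParams:
    """Displacement and counting conventions for the co-occurrence table.

    Defaults follow common Haralick practice: unit distance, symmetric
    counting, features averaged over the four canonical directions.
    """

    distance: int = 1
    angles: tuple[int, ...] = CANONICAL_ANGLES
    n_levels: int = 8
    symmetric: bool = True
    average_angles: bool = True

    def __post_init__(self):
        if self.distance < 1:
            raise InvalidInputError("distance must be >= 1")
        angles = tuple(self.angles)
        if not angles:
            raise InvalidInputError("at least one angle is required")
        for a in angles:
            if a not in _ANGLE_OFFSETS:
                raise InvalidInputError(
                    f"angle {a} not in canonical set {CANONICAL_ANGLES}"
                )
        if self.n_levels < 2:
            raise InvalidInputError("n_levels must be >= 2")
        object.__setattr__(self, "angles", angles)

    def effective_angles(self) -> tuple[int, ...]:
        """Angles actually used: all of them when averaging, else the first."""
        return self.angles if self.average_angles else self.angles[:1]


@dataclass(frozen=True)
class GLCM:
    """An ``N_g x N_g`` co-occurrence table: raw counts plus normalized probs.

    When several angles are averaged, ``counts`` is the sum over angles while
    ``probs`` is the mean of the per-angle normalized tables.
    """

    counts: np.ndarray
    probs: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class TextureVector:
    """The texture feature vector, mandatory components in fixed order."""

    asm: float
    con: float
    idm: float
    cor: float
    ent: float | None = None
    coarseness: float | None = None

    FIELDS = ("asm", "con", "idm", "cor", "ent", "coarseness")

    def as_array(self) -> np.ndarray:
        """Feature values as a 1-D array: [ASM, CON, IDM, COR] plus any
        optional components that are present, in declaration order."""
        vals = [self.asm, self.con, self.idm, self.cor]
        for name in ("ent", "coarseness"):
            v = getattr(self, name)
            if v is not None:
                vals.append(v)
        return np.asarray(vals, dtype=float)


def quantize_image(raw: np.ndarray, n_levels: int) -> GrayImage:
    """Uniformly bin 8-bit intensities ``[0, 255]`` into ``n_levels`` levels.

    The binning is monotone: a brighter pixel never maps to a lower level.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.size == 0:
        raise InvalidInputError("expected a non-empty 2-D intensity grid")
    if n_levels < 2:
        raise InvalidInputError("n_levels must be >= 2")
    arr = np.clip(raw, 0, 255).astype(np.int64)
    levels = (arr * n_levels) // 256
    return GrayImage(pixels=levels.astype(np.int64), n_levels=n_levels)


def _directional_counts(pixels: np.ndarray, n_levels: int, distance: int, angle: int) -> np.ndarray:
    """Count ordered pixel pairs at the (distance, angle) displacement."""
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    M, N = pixels.shape
    r0, r1 = max(0, -dr), min(M, M - dr)
    c0, c1 = max(0, -dc), min(N, N - dc)
    if r0 >= r1 or c0 >= c1:
        raise NoPairsError(
            f"no pixel pair fits offset (d={distance}, theta={angle}) in a {M}x{N} image"
        )
    src = pixels[r0:r1, c0:c1]
    dst = pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    flat = src.ravel() * n_levels + dst.ravel()
    return np.bincount(flat, minlength=n_levels * n_levels).reshape(n_levels, n_levels)


def compute_glcm(img: GrayImage, params: GLCMParams) -> GLCM:
    """Build the co-occurrence table of Haralick's construction.

    ``counts[i, j]`` is the number of ordered in-bounds pixel pairs whose
    gray levels are ``(i, j)`` at the requested displacement; with symmetric
    counting the transpose is added.  ``probs`` is counts normalized to sum
    to one, averaged over angles when ``params.average_angles`` is set.
    """
    if params.n_levels < img.n_levels:
        raise InvalidInputError(
            f"params.n_levels={params.n_levels} cannot hold image levels up to {img.n_levels - 1}"
        )
    total_counts = np.zeros((params.n_levels, params.n_levels), dtype=np.int64)
    prob_tables = []
    for angle in params.effective_angles():
        counts = _directional_counts(img.pixels, params.n_levels, params.distance, angle)
        if params.symmetric:
            counts = counts + counts.T
        total_counts += counts
        prob_tables.append(counts / counts.sum())
    probs = np.mean(prob_tables, axis=0)
    return GLCM(counts=total_counts, probs=probs)


def _checked_probs(glcm: GLCM) -> np.ndarray:
    p = np.asarray(glcm.probs, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise GLCMContractError("probs must be a square table")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _NORM_TOL:
        raise GLCMContractError("GLCM probabilities must be non-negative and sum to 1")
    return p


def asm(glcm: GLCM) -> float:
    """Angular second moment (energy): sum of squared probabilities, in (0, 1]."""
    p = _checked_probs(glcm)
    return float(np.sum(p * p))


def con(glcm: GLCM) -> float:
    """Contrast: squared-level-difference weighted sum, >= 0."""
    p = _checked_probs(glcm)
    i, j = np.indices(p.shape)
    return float(np.sum((i - j) ** 2 * p))


def idm(glcm: GLCM) -> float:
    """Inverse difference moment (local homogeneity), in (0, 1]."""
    p = _checked_probs(glcm)
    i, j = np.indices(p.shape)
    return float(np.sum(p / (1.0 + (i - j) ** 2)))


def cor(glcm: GLCM) -> float:
    """Correlation of the row and column marginals, in [-1, 1].

    Raises :class:`DegenerateCorrelationError` when either marginal has zero
    standard deviation (e.g. the GLCM of a constant image).
    """
    p = _checked_probs(glcm)
    levels = np.arange(p.shape[0], dtype=float)
    px, py = p.sum(axis=1), p.sum(axis=0)
    mu1, mu2 = float(levels @ px), float(levels @ py)
    var1 = float(((levels - mu1) ** 2) @ px)
    var2 = float(((levels - mu2) ** 2) @ py)
    if var1 <= 0.0 or var2 <= 0.0:
        raise DegenerateCorrelationError(
            "GLCM correlation undefined: a marginal standard deviation is zero"
        )
    i, j = np.indices(p.shape)
    cov = float(np.sum((i - mu1) * (j - mu2) * p))
    return cov / np.sqrt(var1 * var2)


def ent(glcm: GLCM) -> float:
    """Shannon entropy of the pair distribution, in bits (>= 0)."""
    p = _checked_probs(glcm)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def tamura_coarseness(img: GrayImage, max_k: int = 4) -> float:
    """Tamura coarseness: mean over pixels of the best averaging window size.

    For window exponents ``k = 0 .. max_k`` (window side ``2^k``, capped by
    the image size) the image is mean-filtered, horizontal/vertical absolute
    differences of the filtered image are taken at offset ``max(1, 2^(k-1))``
    with edge-clamped indexing, and each pixel selects the ``k`` with the
    largest difference (ties broken toward the smallest ``k``).  The result
    is the mean of ``2^k_best`` and is therefore >= 1.
    """
    from scipy.ndimage import uniform_filter

    a = img.pixels.astype(float)
    M, N = a.shape
    ks = [k for k in range(max_k + 1) if 2**k <= min(M, N)]
    if not ks:
        raise InvalidInputError("image smaller than the minimum averaging window")

    def _shift(arr: np.ndarray, off: int, axis: int) -> np.ndarray:
        idx = np.clip(np.arange(arr.shape[axis]) + off, 0, arr.shape[axis] - 1)
        return np.take(arr, idx, axis=axis)

    best_e = np.zeros_like(a)
    best_k = np.zeros(a.shape, dtype=int)
    for k in ks:
        avg = uniform_filter(a, size=2**k, mode="nearest")
        off = max(1, 2 ** (k - 1))
        eh = np.abs(_shift(avg, off, axis=1) - _shift(avg, -off, axis=1))
        ev = np.abs(_shift(avg, off, axis=0) - _shift(avg, -off, axis=0))
        e = np.maximum(eh, ev)
        better = e > best_e  # strict: ties keep the smaller k
        best_k[better] = k
        best_e[better] = e[better]
    return float(np.mean(2.0 ** best_k))


def extract_feature_vector(
    img: GrayImage,
    params: GLCMParams | None = None,
    include_optional: bool = False,
) -> TextureVector:
    """Compute the texture feature vector [ASM, CON, IDM, COR] of an image.

    On a degenerate image whose GLCM correlation is undefined (constant
    gray level), COR is reported as 0.0 and a warning is issued so that
    batch runs are not aborted.  With ``include_optional`` the vector also
    carries ENT (bits) and Tamura coarseness.
    """
    params = params or GLCMParams(n_levels=img.n_levels)
    glcm = compute_glcm(img, params)
    try:
        cor_value = cor(glcm)
    except DegenerateCorrelationError:
        warnings.warn(
            "degenerate GLCM correlation (constant image?); substituting COR=0",
            RuntimeWarning,
            stacklevel=2,
        )
        cor_value = 0.0
    return TextureVector(
        asm=asm(glcm),
        con=con(glcm),
        idm=idm(glcm),
        cor=cor_value,
        ent=ent(glcm) if include_optional else None,
        coarseness=tamura_coarseness(img) if include_optional else None,
    )
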