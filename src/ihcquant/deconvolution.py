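"""Colour deconvolution of H-DAB brightfield images.

Brightfield immunohistochemistry slides carry two absorbing stains:
haematoxylin (blue nuclear counterstain) and DAB (brown chromogen marking
antibody binding).  Under the Beer–Lambert law the optical density
``OD_c = -log10(I_c / I0_c)`` of each RGB channel is additive across
co-localised stains, so a pixel's OD vector is a non-negative linear
combination of per-stain unit colour vectors.  Inverting that linear system
("colour deconvolution", Ruifrok–Johnston) yields per-stain concentration
maps in OD units, from which the DAB signal can be quantified free of the
counterstain.

The module covers the image-side plumbing: RGB -> OD conversion, the
standard H-DAB stain basis, the per-pixel unmixing, re-encoding a stain
concentration map as the 8-bit grey image downstream scoring thresholds,
and 8-bit TIFF/PNG input/output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ShapeError, SingularBasisError, ValidationError

#: Default incident (white-reference) intensity per channel.
DEFAULT_WHITE = 255.0

#: Maximum representable OD for 8-bit data with intensities clamped to >= 1.
MAX_OD_8BIT = float(-np.log10(1.0 / 255.0))  # ~2.4065

#: Published H-DAB absorption colour vectors (per RGB channel, pre-normalisation).
HAEMATOXYLIN_RGB_OD = (0.650, 0.704, 0.286)
DAB_RGB_OD = (0.269, 0.570, 0.776)

STAIN_NAMES = ("haematoxylin", "dab", "residual")


@dataclass(frozen=True)
class StainMatrix:
    """Unmixing basis: three unit OD colour vectors (rows).

    Rows are (haematoxylin, DAB, residual).  The residual row completes the
    basis orthogonally to the two real stains so the matrix is invertible;
    it carries whatever part of a pixel's OD the two stains cannot explain.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = STAIN_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError(f"stain rows must have unit length, norms={norms}")
        if np.any(m[:2] < 0):
            raise ValidationError("real stain vectors must be non-negative")
        if not np.isfinite(np.linalg.cond(m)) or abs(np.linalg.det(m)) < 1e-12:
            raise SingularBasisError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def from_rows(cls, rows) -> "StainMatrix":
        """Build from three (possibly unnormalised) row vectors."""
        m = np.asarray(rows, dtype=float).reshape(3, 3)
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValidationError("stain rows must be non-zero")
        return cls(m / norms)


def default_hdab_matrix() -> StainMatrix:
    """The standard published H-DAB unmixing basis.

    Haematoxylin and DAB rows are the Ruifrok–Johnston vectors, unit
    normalised; the residual row is their normalised cross product, which
    makes the basis invertible and leaves pure two-stain mixtures with zero
    residual concentration.
    """
    h = np.asarray(HAEMATOXYLIN_RGB_OD, dtype=float)
    d = np.asarray(DAB_RGB_OD, dtype=float)
    h = h / np.linalg.norm(h)
    d = d / np.linalg.norm(d)
    r = np.cross(h, d)
    r = r / np.linalg.norm(r)
    return StainMatrix(np.vstack([h, d, r]))


def _check_rgb(pixels: np.ndarray) -> np.ndarray:
    a = np.asarray(pixels)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ShapeError(f"expected H x W x 3 RGB array, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ShapeError("image must have at least one pixel")
    if a.min() < 0 or a.max() > 255:
        raise ValidationError("RGB intensities must lie in [0, 255]")
    return a


def rgb_to_od(pixels: np.ndarray, white: float | np.ndarray = DEFAULT_WHITE) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density per channel.

    ``OD_c = -log10(max(I_c, 1) / I0_c)``.  Zero intensities are clamped to 1
    before the log so the OD stays finite (bounded by ~2.4065 at I0=255).
    Intensities above the white reference are clamped to OD 0.

    Parameters
    ----------
    pixels : (H, W, 3) array of intensities in [0, 255]
    white : scalar or length-3 incident intensity I0 per channel (default 255)
    """
    a = _check_rgb(pixels).astype(float)
    i0 = np.broadcast_to(np.asarray(white, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ValidationError("white reference must be positive")
    od = -np.log10(np.maximum(a, 1.0) / i0)
    return np.maximum(od, 0.0)


def deconvolve(od: np.ndarray, basis: StainMatrix, clamp: bool = False) -> np.ndarray:
    """Unmix an OD image into per-stain concentration maps.

    Solves, per pixel, ``od_vector = c @ basis.matrix`` via the basis
    inverse; concentrations are in OD units along each stain vector.

    Parameters
    ----------
    od : (H, W, 3) or (N, 3) optical densities
    basis : the stain matrix
    clamp : if True, negative concentrations (noise below the white point)
        are clamped to 0 — use this for scoring.  Raw values keep the exact
        linear round trip and are the default.
    """
    a = np.asarray(od, dtype=float)
    if a.shape[-1] != 3:
        raise ShapeError(f"OD array must have 3 channels, got shape {a.shape}")
    conc = a @ basis.inverse
    if clamp:
        conc = np.maximum(conc, 0.0)
    return conc


def concentration_to_grey(conc: np.ndarray, stain: str, basis: StainMatrix | None = None) -> np.ndarray:
    """Encode one stain's concentration map as an 8-bit grey image.

    ``grey = round(255 * 10**(-c))`` clamped to [0, 255]: no stain is white
    (255), denser stain is darker.  The step-tablet calibration is the exact
    inverse of this encoding, so grey -> OD -> grey round-trips to within
    8-bit quantisation.

    ``conc`` may be the full (H, W, 3) concentration stack, from which the
    requested stain's plane is taken, or a single (H, W) plane (then
    ``stain`` is only validated).
    """
    names = basis.names if basis is not None else STAIN_NAMES
    if stain not in ("haematoxylin", "dab"):
        raise ValidationError(f"unknown stain {stain!r}; expected 'haematoxylin' or 'dab'")
    a = np.asarray(conc, dtype=float)
    if a.ndim == 3 and a.shape[2] == 3:
        a = a[..., names.index(stain)]
    grey = np.round(255.0 * np.power(10.0, -np.maximum(a, 0.0)))
    return np.clip(grey, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Image input / output (8-bit RGB TIFF and PNG)
# ---------------------------------------------------------------------------

def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB TIFF or PNG; reject anything else with a clear error."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        with Image.open(path) as im:
            if im.mode == "RGBA":
                im = im.convert("RGB")
            arr = np.asarray(im)
    if arr.dtype != np.uint8:
        raise ValidationError(
            f"{path.name}: only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return _check_rgb(arr)


def write_grey_image(path: str | Path, grey: np.ndarray) -> None:
    """Write an 8-bit greyscale image as TIFF or PNG by file extension."""
    path = Path(path)
    a = np.asarray(grey)
    if a.dtype != np.uint8 or a.ndim != 2:
        raise ValidationError("grey image must be a 2-D uint8 array")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, a)
    else:
        from PIL import Image

        Image.fromarray(a, mode="L").save(path)


def write_rgb_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit RGB image as TIFF or PNG by file extension."""
    path = Path(path)
    a = _check_rgb(pixels)
    if a.dtype != np.uint8:
        raise ValidationError("RGB image must be uint8")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, a)
    else:
        from PIL import Image

        Image.fromarray(a, mode="RGB").save(path)
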