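"""Grey-value to optical-density calibration via a step tablet.

An OD step tablet is a calibrated grey wedge: a monotone table of
(8-bit grey, optical density) pairs.  Scoring converts the DAB-deconvolved
grey image back to OD through this table by piecewise-linear interpolation,
mirroring the ImageJ calibration workflow.  The packaged default tablet is
synthetic-but-exact for this package's grey encoding
``grey = round(255 * 10**(-od))``, so calibration inverts the encoding to
within 8-bit quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import EmptyROIError, ValidationError


@dataclass(frozen=True)
class StepTablet:
    """Ordered (grey, od) calibration knots: grey strictly increasing,
    od strictly decreasing (darker = denser)."""

    grey: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grey, dtype=float)
        d = np.asarray(self.od, dtype=float)
        if g.ndim != 1 or g.shape != d.shape or g.size < 2:
            raise ValidationError("step tablet needs >= 2 (grey, od) pairs")
        if g.min() < 0 or g.max() > 255:
            raise ValidationError("grey values must lie in [0, 255]")
        if not np.all(np.diff(g) > 0):
            raise ValidationError("grey values must be strictly increasing")
        if not np.all(np.diff(d) < 0):
            raise ValidationError("od values must be strictly decreasing")
        if not np.all(np.isfinite(d)) or d.min() < 0:
            raise ValidationError("od values must be finite and >= 0")
        object.__setattr__(self, "grey", g)
        object.__setattr__(self, "od", d)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StepTablet":
        """Load a 2-column CSV (grey, od); a header row is accepted."""
        import pandas as pd

        df = pd.read_csv(path, header=None)
        if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
            df = pd.read_csv(path)
        if df.shape[1] != 2:
            raise ValidationError("step tablet CSV must have exactly 2 columns")
        arr = df.to_numpy(dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"grey": self.grey.astype(int), "od": self.od}).to_csv(
            path, index=False
        )


def default_step_tablet(max_od: float = 2.0, step: float = 0.1) -> StepTablet:
    """Default tablet: knots at grey = round(255 * 10**(-od)) for od on a
    regular grid from 0 to ``max_od``.

    A stand-in for a physical (e.g. Kodak) wedge, constructed to be the
    exact inverse of this package's grey encoding.  At the dark end the
    8-bit grid collapses neighbouring od steps onto one grey level
    (od 1.9 and 2.0 both map to grey 3); duplicates keep the denser od, so
    the default covers od 0–2 in 20 strictly monotone knots.
    """
    ods = np.round(np.arange(0.0, max_od + step / 2, step), 10)
    greys = np.round(255.0 * np.power(10.0, -ods)).astype(int)
    # dedup greys, keeping the largest od (the densest step) per grey level
    keep: dict[int, float] = {}
    for g, od in zip(greys, ods):
        keep[g] = max(keep.get(g, -1.0), od)
    g_sorted = np.array(sorted(keep), dtype=float)
    d_sorted = np.array([keep[int(g)] for g in g_sorted])
    return StepTablet(g_sorted, d_sorted)


def grey_to_od(grey, tablet: StepTablet):
    """Map grey values to OD by piecewise-linear interpolation between the
    tablet knots; greys outside the knot range clamp to the boundary od.

    Accepts a scalar or an array; returns the same shape as a float.
    """
    g = np.asarray(grey, dtype=float)
    # np.interp needs increasing x; tablet grey is increasing, od decreasing,
    # and it clamps at both ends, which is exactly the boundary policy.
    out = np.interp(g, tablet.grey, tablet.od)
    return float(out) if np.isscalar(grey) or g.ndim == 0 else out


def mean_od(grey_img: np.ndarray, mask: np.ndarray, tablet: StepTablet) -> float:
    """Arithmetic mean of per-pixel calibrated OD over the masked region."""
    img = np.asarray(grey_img)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValidationError(f"mask shape {m.shape} != image shape {img.shape}")
    if not m.any():
        raise EmptyROIError("ROI mask selects no pixels")
    return float(np.mean(grey_to_od(img[m], tablet)))
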