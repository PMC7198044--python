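"""ROI rasterisation, percent-positive thresholding and composite scoring.

Tumour regions are delineated by hand-drawn polygons (areas of fibrosis,
necrosis and lumen are excluded by drawing around them).  Inside the union
mask, staining is summarised by two intensive metrics computed on the
DAB-deconvolved 8-bit grey image:

* mean optical density (via the step-tablet calibration), and
* percent positive area — the share of masked pixels whose grey value
  falls inside the positivity window [t_min, t_max] (defaults 67–206,
  bounds inclusive: brighter than 206 is unstained background, darker
  than 67 is over-saturated artefact).

The per-sample biomarker value is their product, score = mean OD x %Pos.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import StepTablet, mean_od
from .deconvolution import (
    StainMatrix,
    concentration_to_grey,
    deconvolve,
    rgb_to_od,
)
from .exceptions import EmptyROIError, ValidationError

TISSUE_CLASSES = ("HCC", "CCA", "MET", "CONTROL")
MARKERS = ("ACSL3", "ACSL4")


@dataclass(frozen=True)
class ROIPolygon:
    """A hand-drawn region outline in 0-based pixel coordinates
    (x rightward, y downward); must be simple (non-self-intersecting)."""

    label: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError(f"polygon {self.label!r} needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"polygon {self.label!r} has non-finite vertices")
        if _self_intersects(v):
            raise ValidationError(f"polygon {self.label!r} is self-intersecting")
        object.__setattr__(self, "vertices", v)


def _self_intersects(v: np.ndarray) -> bool:
    # shapely's simplicity test; collinear/degenerate rings are tolerated
    try:
        from shapely.geometry import LineString
    except ImportError:  # pragma: no cover - shapely is a soft dependency
        return False
    ring = np.vstack([v, v[:1]])
    return not LineString(ring).is_simple


@dataclass(frozen=True)
class PositivityThreshold:
    """Grey-value window for 'positively stained' pixels, bounds inclusive."""

    t_min: int = 67
    t_max: int = 206

    def __post_init__(self) -> None:
        if not (0 <= self.t_min <= self.t_max <= 255):
            raise ValidationError(
                f"need 0 <= t_min <= t_max <= 255, got ({self.t_min}, {self.t_max})"
            )


@dataclass(frozen=True)
class StainingMeasurement:
    """One sample's quantification; score = mean_od * pct_pos by construction."""

    sample_id: str
    tissue_class: str
    marker: str
    mean_od: float
    pct_pos: float

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(f"unknown tissue class {self.tissue_class!r}")
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if not 0.0 <= self.pct_pos <= 100.0:
            raise ValidationError("pct_pos must lie in [0, 100]")
        if self.mean_od < 0:
            raise ValidationError("mean_od must be >= 0")

    @property
    def score(self) -> float:
        return self.mean_od * self.pct_pos


def rasterise(polygons, image_shape) -> np.ndarray:
    """Union boolean mask of the polygons on an image grid.

    A pixel (x, y) is selected iff its centre (x + 0.5, y + 0.5) lies inside
    any polygon (even-odd rule for simple polygons).  Polygons lying fully
    outside the image raise a warning and contribute nothing; if every
    polygon is outside, the ROI is empty and an error is raised.
    """
    from matplotlib.path import Path as MplPath

    if not polygons:
        raise ValidationError("need at least one polygon")
    h, w = int(image_shape[0]), int(image_shape[1])
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    mask = np.zeros(h * w, dtype=bool)
    for poly in polygons:
        ring = np.vstack([poly.vertices, poly.vertices[:1]])
        inside = MplPath(ring, closed=True).contains_points(centres)
        if not inside.any():
            warnings.warn(
                f"polygon {poly.label!r} selects no pixels on a {h}x{w} image",
                stacklevel=2,
            )
        mask |= inside
    if not mask.any():
        raise EmptyROIError("no polygon selects any pixel")
    return mask.reshape(h, w)


def percent_positive(
    grey_img: np.ndarray, mask: np.ndarray, thr: PositivityThreshold
) -> float:
    """Percent of masked pixels with grey in [t_min, t_max] (inclusive)."""
    img = np.asarray(grey_img)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValidationError(f"mask shape {m.shape} != image shape {img.shape}")
    if not m.any():
        raise EmptyROIError("ROI mask selects no pixels")
    vals = img[m]
    pos = (vals >= thr.t_min) & (vals <= thr.t_max)
    return 100.0 * float(pos.sum()) / float(vals.size)


def score_sample(
    image: np.ndarray,
    rois,
    basis: StainMatrix,
    tablet: StepTablet,
    thr: PositivityThreshold,
    sample_id: str,
    tissue_class: str,
    marker: str,
    white: float = 255.0,
) -> StainingMeasurement:
    """Full image-to-score pipeline for one sample.

    RGB -> OD -> deconvolve (negative concentrations clamped) -> DAB 8-bit
    grey -> mean calibrated OD and percent positive area over the ROI union
    mask -> composite score.  Deterministic for fixed inputs.
    """
    od = rgb_to_od(image, white=white)
    conc = deconvolve(od, basis, clamp=True)
    dab_grey = concentration_to_grey(conc, "dab", basis)
    mask = rasterise(rois, dab_grey.shape)
    return StainingMeasurement(
        sample_id=sample_id,
        tissue_class=tissue_class,
        marker=marker,
        mean_od=mean_od(dab_grey, mask, tablet),
        pct_pos=percent_positive(dab_grey, mask, thr),
    )


# ---------------------------------------------------------------------------
# ROI JSON and score CSV interchange
# ---------------------------------------------------------------------------
# ROI schema: {"image": name, "rois": [{"label": str, "vertices": [[x, y], ...]}]}
# ImageJ's binary .roi format is NOT supported; export ROIs to this JSON form.

def load_rois(path: str | Path) -> list[ROIPolygon]:
    with open(path) as fh:
        doc = json.load(fh)
    if "rois" not in doc or not isinstance(doc["rois"], list):
        raise ValidationError(f"{path}: expected a top-level 'rois' list")
    return [ROIPolygon(r["label"], np.asarray(r["vertices"], float)) for r in doc["rois"]]


def save_rois(path: str | Path, image_name: str, polygons) -> None:
    doc = {
        "image": image_name,
        "rois": [
            {"label": p.label, "vertices": np.asarray(p.vertices).tolist()}
            for p in polygons
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def measurements_to_frame(measurements):
    """Per-sample score table (one row per StainingMeasurement)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "tissue_class": m.tissue_class,
                "marker": m.marker,
                "mean_od": m.mean_od,
                "pct_pos": m.pct_pos,
                "score": m.score,
            }
            for m in measurements
        ]
    )
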