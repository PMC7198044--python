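"""Synthetic stained-tissue phantoms and group score tables.

Every pipeline stage is testable without any slide: the phantom generator
forward-renders H-DAB images through the same Beer–Lambert model and stain
basis the deconvolution inverts, keeping per-pixel ground-truth OD maps and
region labels; the score simulator draws per-class composite scores from
log-normal distributions with controllable separation.

What the phantoms emulate: DAB-stained tumour regions of varying intensity
on a haematoxylin-counterstained background, plus unstained "excluded"
areas standing in for necrosis/fibrosis/lumen that an analyst would draw
ROIs around.  What they deliberately do not emulate: real histology
texture, stain co-localisation gradients, scanner optics beyond additive
Gaussian grey noise.

The default scanner noise (sigma = 1 grey level) matters quantitatively:
besides realism it dithers the 8-bit quantisation, so region-mean OD
recovery stays accurate well into the dense-stain range where a noiseless
single pixel would be limited by the grey-level grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import StainMatrix, default_hdab_matrix
from .exceptions import ValidationError
from .scoring import ROIPolygon

LABEL_BACKGROUND, LABEL_TUMOUR, LABEL_NUCLEUS, LABEL_EXCLUDED = 0, 1, 2, 3


@dataclass(frozen=True)
class StainedRegion:
    """Axis-aligned rectangle (x0, y0, x1, y1), exclusive upper bounds,
    with a uniform DAB optical density."""

    rect: tuple[int, int, int, int]
    dab_od: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"degenerate rectangle {self.rect}")
        if self.dab_od < 0:
            raise ValidationError("DAB OD must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic slide image.

    Nuclei are random non-overlapping discs of haematoxylin; stained and
    excluded regions are rectangles so ground-truth pixel counts are exact.
    Overlaps resolve by precedence excluded > nucleus > stained.
    """

    size: tuple[int, int] = (256, 256)
    background: int = 255
    n_nuclei: int = 30
    nucleus_radius: tuple[float, float] = (3.0, 6.0)
    nucleus_od: tuple[float, float] = (0.4, 0.8)
    stained_regions: tuple[StainedRegion, ...] = ()
    excluded_regions: tuple[tuple[int, int, int, int], ...] = ()
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 1 or w < 1:
            raise ValidationError("image size must be >= 1x1")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if not 0 <= self.background <= 255:
            raise ValidationError("background intensity must lie in [0, 255]")
        for reg in self.stained_regions:
            x0, y0, x1, y1 = reg.rect
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise ValidationError(f"stained region {reg.rect} outside {w}x{h} image")
        for rect in self.excluded_regions:
            x0, y0, x1, y1 = rect
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise ValidationError(f"excluded region {rect} outside {w}x{h} image")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Rendered image plus the per-pixel truth it was rendered from."""

    image: np.ndarray          # (H, W, 3) uint8, noise applied
    haematoxylin_od: np.ndarray  # (H, W) true H concentration
    dab_od: np.ndarray           # (H, W) true DAB concentration
    labels: np.ndarray           # (H, W) int, LABEL_* partition
    spec: PhantomSpec
    basis: StainMatrix

    def region_roi(self, index: int = 0) -> ROIPolygon:
        """ROI polygon outlining stained region ``index`` (pixel-centre
        rasterisation of this rectangle recovers its exact pixel count)."""
        x0, y0, x1, y1 = self.spec.stained_regions[index].rect
        return ROIPolygon(
            f"stained-{index}",
            np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float),
        )


def render_phantom(spec: PhantomSpec, basis: StainMatrix | None = None) -> PhantomGroundTruth:
    """Forward Beer–Lambert rendering of a phantom, deterministic per seed.

    Per pixel the RGB OD vector is ``c_H * H_row + c_DAB * DAB_row``; the
    noiseless intensity is ``round(background * 10**(-OD))`` and Gaussian
    noise (sigma in grey levels) is added in intensity space, then clamped
    to [0, 255].
    """
    if basis is None:
        basis = default_hdab_matrix()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    h_map = np.zeros((h, w))
    d_map = np.zeros((h, w))
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.int8)

    for reg in spec.stained_regions:
        x0, y0, x1, y1 = reg.rect
        d_map[y0:y1, x0:x1] = reg.dab_od
        labels[y0:y1, x0:x1] = LABEL_TUMOUR

    # rejection-sample non-overlapping nucleus discs (best effort)
    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < spec.n_nuclei and attempts < 50 * max(1, spec.n_nuclei):
        attempts += 1
        r = rng.uniform(*spec.nucleus_radius)
        cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
        cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
        if any((cx - px) ** 2 + (cy - py) ** 2 < (r + pr) ** 2 for px, py, pr in placed):
            continue
        od = rng.uniform(*spec.nucleus_od)
        disc = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
        h_map[disc] = od
        labels[disc] = LABEL_NUCLEUS
        placed.append((cx, cy, r))

    for rect in spec.excluded_regions:  # precedence: excluded wins
        x0, y0, x1, y1 = rect
        h_map[y0:y1, x0:x1] = 0.0
        d_map[y0:y1, x0:x1] = 0.0
        labels[y0:y1, x0:x1] = LABEL_EXCLUDED

    m = basis.matrix
    od_rgb = h_map[..., None] * m[0] + d_map[..., None] * m[1]
    # noise enters before the 8-bit quantisation (sensor noise precedes the
    # ADC); a noiseless render is exactly round(I0 * 10**-OD)
    signal = spec.background * np.power(10.0, -od_rgb)
    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
    image = np.clip(np.round(signal), 0, 255).astype(np.uint8)
    return PhantomGroundTruth(image, h_map, d_map, labels, spec, basis)


# ---------------------------------------------------------------------------
# Group score simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Log-normal score distribution of one tissue class: score =
    exp(N(log_mean, log_sd))."""

    n: int
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group size must be >= 1")
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be > 0")


def lognormal_shift_for_auc(auc: float, sd0: float, sd1: float) -> float:
    """Latent-normal location shift giving a target binormal AUC.

    For log-normal scores the AUC depends only on the latent normals:
    AUC = Phi(delta / sqrt(sd0^2 + sd1^2)), so
    delta = Phi^{-1}(auc) * sqrt(sd0^2 + sd1^2).
    """
    from scipy.stats import norm

    if not 0 < auc < 1:
        raise ValidationError("target AUC must lie in (0, 1)")
    return float(norm.ppf(auc) * np.hypot(sd0, sd1))


#: Default per-class score distributions.  Qualitative shape: HCC scores
#: stochastically largest; control and CCA low and similar; metastases
#: intermediate and overlapping HCC.  The HCC-control latent shift is set
#: by lognormal_shift_for_auc(0.95, 0.6, 0.6) ~ 1.396, matching the strong
#: single-marker discrimination the study design anticipates.  Group sizes
#: follow a ~10:1 skew of tumour over control material at cohort scale.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "CONTROL": GroupParams(16, np.log(5.0), 0.6),
    "HCC": GroupParams(48, np.log(5.0) + 1.3957, 0.6),
    "CCA": GroupParams(8, np.log(5.0) + 0.1, 0.6),
    "MET": GroupParams(24, np.log(5.0) + 1.0, 0.7),
}


@dataclass(frozen=True)
class GroupSimSpec:
    """Per-class sampling recipe for one marker's score table."""

    groups: dict[str, GroupParams] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    marker: str = "ACSL4"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("need at least one group")


def simulate_scores(spec: GroupSimSpec) -> pd.DataFrame:
    """Seeded log-normal score draws per class, as a diagnostics-ready
    score table (sample_id, tissue_class, marker, score)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cls in sorted(spec.groups):
        gp = spec.groups[cls]
        draws = np.exp(rng.normal(gp.log_mean, gp.log_sd, gp.n))
        for i, s in enumerate(draws):
            rows.append(
                {
                    "sample_id": f"{cls}-{i:03d}",
                    "tissue_class": cls,
                    "marker": spec.marker,
                    "score": float(s),
                }
            )
    return pd.DataFrame(rows)
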