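"""End-to-end orchestration: batch scoring and the study report.

`run_scoring` walks a metadata table of (sample, marker, image, ROI) rows,
scores each sample and writes the per-sample score CSV; unreadable images
and empty ROIs are logged and counted, never silently dropped.
`run_diagnostics` turns a score table into a machine-readable study
report: per-marker omnibus and pairwise blocks plus one diagnostic block
(AUC, 95% CI, optimal threshold, sensitivity %, specificity %) per
comparison and marker, including the logistic two-marker combination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .calibration import StepTablet, default_step_tablet
from .deconvolution import StainMatrix, default_hdab_matrix, read_rgb_image
from .exceptions import IHCQuantError, ValidationError
from .scoring import (
    PositivityThreshold,
    load_rois,
    measurements_to_frame,
    score_sample,
)

logger = logging.getLogger("ihcquant")

#: The study's default contrasts: positive class first, negative class second.
DEFAULT_COMPARISONS: dict[str, tuple[str, str]] = {
    "hcc-vs-control": ("HCC", "CONTROL"),
    "hcc-vs-cca": ("HCC", "CCA"),
    "hcc-vs-met": ("HCC", "MET"),
}


@dataclass
class RunConfig:
    """Everything one run needs; loadable from a JSON file."""

    image_dir: Path = Path(".")
    roi_dir: Path = Path(".")
    metadata_csv: Path | None = None
    tablet_csv: Path | None = None
    output_dir: Path = Path("out")
    stain_rows: list | None = None          # 9 floats row-major, pre-normalisation
    t_min: int = 67
    t_max: int = 206
    adjust: str = "bh"                       # bh | bonferroni
    ci: str = "delong"                       # delong | bootstrap
    comparisons: dict = field(default_factory=lambda: dict(DEFAULT_COMPARISONS))
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        cfg = cls()
        for key, val in doc.items():
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown config key {key!r}")
            if key.endswith(("_dir", "_csv")) and val is not None:
                val = Path(val)
            setattr(cfg, key, val)
        return cfg

    def basis(self) -> StainMatrix:
        if self.stain_rows is None:
            return default_hdab_matrix()
        return StainMatrix.from_rows(np.asarray(self.stain_rows, float).reshape(3, 3))

    def tablet(self) -> StepTablet:
        if self.tablet_csv is None:
            return default_step_tablet()
        return StepTablet.from_csv(self.tablet_csv)

    def threshold(self) -> PositivityThreshold:
        return PositivityThreshold(self.t_min, self.t_max)


def run_scoring(config: RunConfig) -> pd.DataFrame:
    """Score every sample listed in the metadata CSV.

    The metadata CSV needs columns sample_id, tissue_class, marker, image,
    roi (file names relative to image_dir / roi_dir).  Failures (missing or
    unreadable image, empty ROI) are logged with reasons and counted; if no
    sample is scorable the run errors out.  Writes scores.csv and an
    exclusion log to the output directory.
    """
    logging.basicConfig(level=config.log_level)
    if config.metadata_csv is None:
        raise ValidationError("config.metadata_csv is required for scoring")
    meta = pd.read_csv(config.metadata_csv)
    required = {"sample_id", "tissue_class", "marker", "image", "roi"}
    if not required.issubset(meta.columns):
        raise ValidationError(f"metadata CSV needs columns {sorted(required)}")
    if meta.empty:
        raise IHCQuantError("metadata CSV lists no samples")

    basis, tablet, thr = config.basis(), config.tablet(), config.threshold()
    measurements, exclusions = [], []
    for row in meta.itertuples(index=False):
        try:
            image = read_rgb_image(Path(config.image_dir) / row.image)
            rois = load_rois(Path(config.roi_dir) / row.roi)
            measurements.append(
                score_sample(
                    image, rois, basis, tablet, thr,
                    sample_id=str(row.sample_id),
                    tissue_class=str(row.tissue_class),
                    marker=str(row.marker),
                )
            )
        except (IHCQuantError, OSError, KeyError) as exc:
            reason = f"{type(exc).__name__}: {exc}"
            logger.warning("excluding sample %s (%s): %s", row.sample_id, row.marker, reason)
            exclusions.append({"sample_id": row.sample_id, "marker": row.marker, "reason": reason})
    if not measurements:
        raise IHCQuantError("no scorable samples (all excluded)")
    logger.info("scored %d samples, excluded %d", len(measurements), len(exclusions))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = measurements_to_frame(measurements)
    frame.to_csv(out / "scores.csv", index=False)
    pd.DataFrame(exclusions, columns=["sample_id", "marker", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    return frame


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------

def _diagnostic_block(scores, labels, config: RunConfig) -> dict:
    r = dx.roc(scores, labels, ci=config.ci, seed=config.seed)
    y = dx.youden(r)
    return {
        "auc": r.auc,
        "auc_ci_95": [r.auc_ci[0], r.auc_ci[1]],
        "ci_method": r.ci_method,
        "optimal_threshold": y.optimal_threshold,
        "sensitivity_pct": 100.0 * y.sensitivity,
        "specificity_pct": 100.0 * y.specificity,
        "youden_j": y.J,
    }


def run_diagnostics(score_table: pd.DataFrame, config: RunConfig) -> dict:
    """Build the full study report from a per-sample score table.

    Blocks: per marker, Kruskal–Wallis across all classes and the pairwise
    rank-sum matrix; per configured comparison and marker (plus the
    logistic combination where both markers cover the samples), the
    ROC/Youden diagnostic block.  A comparison whose classes are absent is
    marked unavailable and the run continues.  Reruns with identical config
    and seed produce identical reports.
    """
    table = dx.validate_score_table(score_table)
    markers = sorted(table["marker"].unique())
    report: dict = {
        "seed": config.seed,
        "options": {"adjust": config.adjust, "ci": config.ci},
        "markers": {},
        "comparisons": {},
    }
    for marker in markers:
        sub = table[table["marker"] == marker]
        block: dict = {}
        if sub["tissue_class"].nunique() >= 2:
            kw = dx.kruskal_wallis(table, marker)
            pw = dx.pairwise_wilcoxon(table, marker, adjust=config.adjust)
            block["kruskal_wallis"] = {
                "H": kw.H, "df": kw.df, "p_value": kw.p_value, "mean_ranks": kw.mean_ranks,
            }
            block["pairwise"] = pw.table.to_dict(orient="records")
        else:
            block["kruskal_wallis"] = None
            block["pairwise"] = None
        report["markers"][marker] = block

    for name, (pos_cls, neg_cls) in config.comparisons.items():
        comp: dict = {}
        for marker in markers:
            sub = table[table["marker"] == marker]
            sel = sub[sub["tissue_class"].isin([pos_cls, neg_cls])]
            if sel["tissue_class"].nunique() < 2:
                comp[marker] = {"available": False}
                continue
            labels = (sel["tissue_class"] == pos_cls).astype(int).to_numpy()
            block = _diagnostic_block(sel["score"].to_numpy(float), labels, config)
            block["available"] = True
            comp[marker] = block
        comp["combined"] = _combined_block(table, markers, pos_cls, neg_cls, config)
        report["comparisons"][name] = comp
    validate_report(report)
    return report


def _combined_block(table, markers, pos_cls, neg_cls, config) -> dict:
    if len(markers) < 2:
        return {"available": False}
    a, b = markers[0], markers[1]
    wide = table[table["tissue_class"].isin([pos_cls, neg_cls])].pivot_table(
        index=["sample_id", "tissue_class"], columns="marker", values="score"
    ).reset_index()
    wide = wide.dropna(subset=[a, b])
    if wide.empty or wide["tissue_class"].nunique() < 2:
        return {"available": False}
    labels = (wide["tissue_class"] == pos_cls).astype(int).to_numpy()
    model = dx.combine_markers(
        wide[a].to_numpy(float), wide[b].to_numpy(float), labels, names=(a, b)
    )
    block: dict = {
        "available": True,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "converged": model.converged,
        "separation": model.separation,
    }
    if np.all(np.isfinite(model.probabilities)):
        block.update(_diagnostic_block(model.probabilities, labels, config))
    return block


# ---------------------------------------------------------------------------
# Report structure validation (lightweight, no external schema library)
# ---------------------------------------------------------------------------

_DIAG_KEYS = {"auc", "auc_ci_95", "optimal_threshold", "sensitivity_pct", "specificity_pct"}


def validate_report(report: dict) -> None:
    """Structural check of the report; raises ValidationError on violation."""
    for key in ("seed", "options", "markers", "comparisons"):
        if key not in report:
            raise ValidationError(f"report missing {key!r}")
    for name, comp in report["comparisons"].items():
        for marker, block in comp.items():
            if not isinstance(block, dict) or "available" not in block:
                raise ValidationError(f"malformed block {name}/{marker}")
            if block["available"] and "auc" in block:
                if not _DIAG_KEYS.issubset(block):
                    raise ValidationError(f"incomplete diagnostic block {name}/{marker}")
                lo, hi = block["auc_ci_95"]
                if not (0 <= lo <= block["auc"] <= hi <= 1):
                    raise ValidationError(f"inconsistent AUC CI in {name}/{marker}")
                for k in ("sensitivity_pct", "specificity_pct"):
                    if not 0 <= block[k] <= 100:
                        raise ValidationError(f"{k} out of range in {name}/{marker}")


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
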