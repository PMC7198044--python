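"""Diagnostic statistics for composite staining scores.

The battery mirrors standard biomarker practice on a per-sample score table:

* Kruskal–Wallis H across tissue classes (with tie correction and
  per-class mean midranks),
* pairwise two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg
  (or Bonferroni) multiplicity adjustment,
* ROC curves with trapezoidal AUC (= the Mann–Whitney pair statistic,
  ties counted 1/2) and a 95% DeLong or bootstrap confidence interval,
* Youden-index optimal cut-offs with their sensitivity/specificity,
* an unpenalised maximum-likelihood logistic combination of two markers,
  whose in-sample predicted probabilities feed a combined-marker ROC,
* the two-proportion unequal-allocation sample-size formula (Rosner form)
  used for study power planning.

Rank tests are delegated to scipy and multiplicity adjustment to
statsmodels; the ROC/Youden/DeLong, logistic IRLS and sample-size
machinery is implemented here with the exact conventions the reporting
needs (midpoint thresholds, low-threshold tie-break, flagged separation,
nearest-integer rounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

# ---------------------------------------------------------------------------
# Score-table validation
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("sample_id", "tissue_class", "marker", "score")


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample score table invariants and return it."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    scores = table["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)) or scores.min() < 0:
        raise ValidationError("scores must be finite and >= 0")
    if table.duplicated(subset=["sample_id", "marker"]).any():
        raise ValidationError("duplicate (sample_id, marker) rows")
    return table


def _marker_groups(table: pd.DataFrame, marker: str) -> dict[str, np.ndarray]:
    sub = table[table["marker"] == marker]
    if sub.empty:
        raise ValidationError(f"no rows for marker {marker!r}")
    return {
        cls: grp["score"].to_numpy(dtype=float)
        for cls, grp in sub.groupby("tissue_class", sort=True)
    }


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    H: float
    df: int
    p_value: float
    mean_ranks: dict[str, float]


def kruskal_wallis(table: pd.DataFrame, marker: str) -> GroupComparisonResult:
    """Kruskal–Wallis H test across tissue classes for one marker.

    H is computed on midranks with the usual tie correction
    ``H' = H / (1 - sum(t^3 - t) / (N^3 - N))``; the p-value comes from the
    chi-square distribution with k-1 degrees of freedom.  Per-class mean
    midranks are reported alongside.  If every observation is identical the
    tie-correction denominator vanishes; H is then defined as 0 with p = 1.
    """
    groups = _marker_groups(table, marker)
    if len(groups) < 2:
        raise ValidationError("need >= 2 tissue classes")
    values = [groups[k] for k in groups]
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    mean_ranks, i = {}, 0
    for cls, v in groups.items():
        mean_ranks[cls] = float(ranks[i : i + v.size].mean())
        i += v.size
    df = len(groups) - 1
    if np.ptp(pooled) == 0:  # all identical: scipy raises, define H = 0
        return GroupComparisonResult(0.0, df, 1.0, mean_ranks)
    h, p = stats.kruskal(*values)
    return GroupComparisonResult(float(h), df, float(p), mean_ranks)


# ---------------------------------------------------------------------------
# Pairwise Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    """Per class-pair rank-sum results; `table` has one row per pair with
    columns (class_a, class_b, W, p_raw, p_adj)."""

    table: pd.DataFrame
    adjust: str


def _ranksum_pair(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(min(ranks[: x.size].sum(), ranks[x.size :].sum()))
    if np.ptp(pooled) == 0:  # fully degenerate: no evidence either way
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        # mirror R wilcox.test: exact when untied and both samples small
        method = "exact" if (not has_ties and x.size < 50 and y.size < 50) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def pairwise_wilcoxon(
    table: pd.DataFrame, marker: str, adjust: str = "bh", method: str = "auto"
) -> PairwiseResult:
    """Two-sided Wilcoxon rank-sum tests for every pair of tissue classes.

    The reported W is the smaller of the two rank sums.  p-values are exact
    when the samples are untied and small (both n < 50), otherwise from the
    normal approximation with tie-corrected variance and continuity
    correction; ``method`` forces 'exact' or 'asymptotic'.  Adjustment across
    all pairs is Benjamini–Hochberg step-up ('bh', controls the false
    discovery rate) or 'bonferroni'.
    """
    from statsmodels.stats.multitest import multipletests

    if adjust not in ("bh", "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    groups = _marker_groups(table, marker)
    classes = sorted(groups)
    if len(classes) < 2:
        raise ValidationError("need >= 2 tissue classes")
    rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            w, p = _ranksum_pair(groups[a], groups[b], method)
            rows.append({"class_a": a, "class_b": b, "W": w, "p_raw": p})
    df = pd.DataFrame(rows)
    sm_method = "fdr_bh" if adjust == "bh" else "bonferroni"
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method=sm_method)[1]
    return PairwiseResult(df, adjust)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw, <= 1)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong or bootstrap CI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """Operating points (threshold, sensitivity, specificity) at every
    midpoint between distinct scores plus -inf/+inf; a score strictly above
    the threshold predicts the positive class."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str = "delong"


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # pair statistic with ties counted 1/2; O(n log n) via midranks
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float) -> tuple[float, float]:
    """DeLong variance of the AUC via structural components."""
    m, n = pos.size, neg.size
    # V10[i] = P(pos_i beats a random neg), V01[j] = P(a random pos beats neg_j)
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc(
    scores,
    labels,
    ci: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ROCResult:
    """ROC analysis of a score against binary labels (1 = diseased).

    Higher scores indicate the positive class (the direction is fixed, not
    auto-detected).  The AUC equals both the trapezoidal area and the
    Mann–Whitney pair statistic with ties counted 1/2.  The 95% CI is
    DeLong's (default) or a seeded percentile bootstrap, truncated to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])

    auc = _mann_whitney_auc(pos, neg)
    if ci == "delong":
        lo, hi = _delong_ci(pos, neg, auc, level)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            draws[b] = _mann_whitney_auc(
                rng.choice(pos, pos.size, replace=True),
                rng.choice(neg, neg.size, replace=True),
            )
        alpha = 1 - level
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        lo, hi = max(0.0, float(lo)), min(1.0, float(hi))
    else:
        raise ValidationError(f"unknown CI method {ci!r}")
    lo, hi = min(lo, auc), max(hi, auc)  # CI always contains the point estimate
    return ROCResult(thresholds, sens, spec, auc, (lo, hi), ci)


@dataclass(frozen=True)
class YoudenResult:
    optimal_threshold: float
    sensitivity: float
    specificity: float
    J: float


def youden(roc_result: ROCResult) -> YoudenResult:
    """Operating point maximising J = sensitivity + specificity - 1.

    Ties in J are broken toward the lowest threshold so a single cut-off
    can be reported.
    """
    j = roc_result.sensitivity + roc_result.specificity - 1.0
    best = int(np.argmax(j > j.max() - 1e-12))  # first (lowest-threshold) maximiser
    return YoudenResult(
        optimal_threshold=float(roc_result.thresholds[best]),
        sensitivity=float(roc_result.sensitivity[best]),
        specificity=float(roc_result.specificity[best]),
        J=float(j[best]),
    )


# ---------------------------------------------------------------------------
# Logistic combination of two markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    separation: bool
    probabilities: np.ndarray


def combine_markers(
    scores_a, scores_b, labels, names: tuple[str, str] = ("ACSL3", "ACSL4")
) -> LogisticModel:
    """Unpenalised ML logistic regression of two marker scores on a binary
    outcome; the in-sample predicted probabilities feed a combined ROC.

    Fitting is Newton/IRLS (tolerance 1e-10, <= 100 iterations) on the
    exact log-likelihood; at convergence the score equations are satisfied
    to 1e-8 in max norm.  Complete separation is detected and flagged: the
    coefficients diverge, iteration stops at the cap, and the returned fit
    is not an ML solution (its predicted probabilities still order the
    samples and saturate toward 0/1).  A constant (zero-variance) marker is
    dropped from the design with coefficient 0, so the combined model
    reduces to the informative marker.
    """
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (xa.shape == xb.shape == y.shape) or xa.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if y.min() == y.max():
        raise ValidationError("both outcome classes must be present")

    cols, used = [], []
    for name, x in zip(names, (xa, xb)):
        if np.ptp(x) > 0:
            cols.append(x)
            used.append(name)
    X = np.column_stack([np.ones_like(y, dtype=float)] + cols)

    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(100):
        eta = np.clip(X @ beta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = np.maximum(p * (1 - p), 1e-12)  # keeps the step defined as p -> 0/1
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:  # rank-deficient (e.g. collinear markers)
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(grad).max() <= 1e-8 and np.abs(step).max() <= 1e-10:
            converged = True
            break

    probs = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -700, 700)))
    # complete/quasi-complete separation: perfect in-sample prediction with
    # diverging coefficients, no finite ML optimum
    separation = bool(
        not converged and np.abs(beta).max() > 30 and np.all((probs > 0.5) == (y == 1))
    )
    if separation:
        warnings.warn("complete separation: logistic coefficients diverge", stacklevel=2)

    coeffs = {name: 0.0 for name in names}
    for k, name in enumerate(used):
        coeffs[name] = float(beta[k + 1])
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients=coeffs,
        converged=converged,
        separation=separation,
        probabilities=probs,
    )


# ---------------------------------------------------------------------------
# Two-proportion sample size (unequal allocation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    """Design of a two-proportion comparison: expected marker-positive
    frequency p1 in the larger group and p2 in the smaller group, two-sided
    alpha, power 1-beta, and allocation ratio kappa = n_large / n_small."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80
    ratio: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2)):
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.p1 == self.p2:
            raise ValidationError("p1 == p2 gives an infinite sample size")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.ratio < 1:
            raise ValidationError("ratio must be >= 1 (n_large / n_small)")


def sample_size(spec: SampleSizeSpec, rounding: str = "nearest") -> tuple[int, int]:
    """Required (n_large, n_small) for a two-proportion comparison with
    unequal allocation (normal approximation, Rosner form).

    With kappa = ratio and pooled p̄ = (p2 + kappa*p1) / (1 + kappa):

        n_small = [ z_{1-a/2} sqrt(p̄q̄ (1 + 1/kappa))
                    + z_{1-b} sqrt(p2 q2 + p1 q1 / kappa) ]^2 / (p1 - p2)^2
        n_large = kappa * n_small

    Both are rounded to the nearest integer by default ('ceil' rounds up),
    with a floor of 1.
    """
    if rounding not in ("nearest", "ceil"):
        raise ValidationError(f"unknown rounding {rounding!r}")
    k = spec.ratio
    p1, p2 = spec.p1, spec.p2  # p1: larger group, p2: smaller group
    q1, q2 = 1 - p1, 1 - p2
    pbar = (p2 + k * p1) / (1 + k)
    qbar = 1 - pbar
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n_small = (
        z_a * np.sqrt(pbar * qbar * (1 + 1 / k)) + z_b * np.sqrt(p2 * q2 + p1 * q1 / k)
    ) ** 2 / (p1 - p2) ** 2
    n_large = k * n_small
    rnd = np.ceil if rounding == "ceil" else np.round
    return int(max(1, rnd(n_large))), int(max(1, rnd(n_small)))
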