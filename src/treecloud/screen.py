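"""Feature-vs-species association screening.

Each candidate feature (spectral index or texture parameter) is scored
against the binary species label.  The default score is the point-biserial
correlation, i.e. the Pearson correlation between the feature and a 0/1
coding of the label; an alternative ``logistic`` method fits a univariate
logistic regression and reports sign(beta) * sqrt(McFadden pseudo-R^2),
a bounded signed analogue of the same association.  Missing feature values
are handled pairwise-complete.

Correlation strength categories follow the conventional |r| bands:
[0, 0.30) micro, [0.30, 0.50) real, [0.50, 0.80) significant,
[0.80, 1] high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORY_EDGES = (0.30, 0.50, 0.80)
CATEGORY_NAMES = ("micro", "real", "significant", "high")


def categorize(r: float) -> str:
    a = abs(r)
    if a < CATEGORY_EDGES[0]:
        return "micro"
    if a < CATEGORY_EDGES[1]:
        return "real"
    if a < CATEGORY_EDGES[2]:
        return "significant"
    return "high"


@dataclass(frozen=True)
class CorrelationReport:
    feature_id: str
    r: float
    category: str
    n_used: int
    zero_variance: bool = False


def _binary_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"screening requires exactly two classes, got {classes.size}"
        )
    # code the lexicographically larger class as 1 so the sign of r is
    # reproducible regardless of input order
    return (labels == classes[-1]).astype(float)


def _logistic_r(x: np.ndarray, y: np.ndarray) -> float:
    """sign(beta) * sqrt(McFadden pseudo-R^2) from a univariate logit."""
    import statsmodels.api as sm

    xs = (x - x.mean()) / x.std()  # standardize for a stable fit
    X = sm.add_constant(xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            pseudo_r2 = float(fit.prsquared)
            beta = float(fit.params[1])
        except Exception:
            # perfect separation: association is as strong as it gets
            beta = float(np.sign(np.corrcoef(xs, y)[0, 1]))
            pseudo_r2 = 1.0
    pseudo_r2 = min(max(pseudo_r2, 0.0), 1.0)
    return float(np.sign(beta) * np.sqrt(pseudo_r2))


def correlate_feature(
    column, labels, feature_id: str = "", method: str = "pointbiserial"
) -> CorrelationReport:
    """Score one feature column against the binary species label.

    Rows where the feature is NaN are dropped (pairwise-complete).  A
    zero-variance feature scores r = 0 and is flagged.
    """
    x = np.asarray(column, dtype=float)
    y = _binary_codes(labels)
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present among complete rows")
    if np.ptp(x) == 0:
        warnings.warn(
            f"feature {feature_id or '<unnamed>'} has zero variance; r set to 0",
            stacklevel=2,
        )
        return CorrelationReport(feature_id, 0.0, categorize(0.0), x.size, True)
    if method == "pointbiserial":
        r = float(stats.pointbiserialr(y, x).statistic)
    elif method == "logistic":
        r = _logistic_r(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationReport(feature_id, r, categorize(r), int(x.size))


def screen_features(
    features: pd.DataFrame, labels, method: str = "pointbiserial"
) -> list[CorrelationReport]:
    """Correlate every feature column with the label."""
    return [
        correlate_feature(features[c], labels, feature_id=str(c), method=method)
        for c in features.columns
    ]


def rank_select(
    reports: list[CorrelationReport], k: int = 10
) -> list[CorrelationReport]:
    """Top-k reports by |r| (descending); ties break lexicographically on
    feature_id so repeated runs select the same sensitive set."""
    if k > len(reports):
        raise ValueError("k exceeds the number of reports")
    ordered = sorted(reports, key=lambda rep: (-abs(rep.r), rep.feature_id))
    return ordered[:k]


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in reports],
            "r": [r.r for r in reports],
            "category": [r.category for r in reports],
            "n_used": [r.n_used for r in reports],
        }
    )
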