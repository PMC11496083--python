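"""Sequencing-depth saturation analysis.

Detection of isoform features degrades with sequencing depth.  To quantify
this, the alignment is subsampled on a grid of fractions (default 5%..100% in
steps of 5), the full quantification is re-run per fraction, and one of two
estimators is computed against the mean uniquely-mapped reads per cell X:

* ``fraction_positive`` — fraction of cells with a nonzero count for the
  feature (raw counts; fractional weights count as positive);
* ``mean_log_count`` — mean log2-normalized count over all cells, zeros
  included.

The estimator Y is then fitted with the two-parameter rational saturation
model ``Y = a * X / (b + X)``: ``a`` is the asymptotic plateau of the
estimator and ``b`` the depth at which Y reaches a/2.  For a, b > 0 the curve
passes through the origin and rises monotonically and concavely to ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bam_reads import ReadRecord, reads_per_cell, subsample
from .quantifier import (
    CountMatrix,
    FeatureIndex,
    classify_records,
    log_normalize,
    quantify,
)

__all__ = [
    "SaturationPoint",
    "RationalFit",
    "DEFAULT_FRACTIONS",
    "rational",
    "fraction_positive",
    "mean_log_count",
    "saturation_curve",
    "fit_rational",
    "points_frame",
]

#: 5% .. 100% in increments of 5 — the standard subsampling grid (20 points).
DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 21))


@dataclass(frozen=True)
class SaturationPoint:
    fraction: float
    x: float  # mean uniquely-mapped reads per cell at this fraction
    y: float  # estimator value


@dataclass(frozen=True)
class RationalFit:
    """Least-squares estimate of the saturation model parameters."""

    a: float
    b: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return rational(np.asarray(x, dtype=float), self.a, self.b)


def rational(x, a: float, b: float):
    """The saturation model Y = a*X / (b + X)."""
    x = np.asarray(x, dtype=float)
    return a * x / (b + x)


def fraction_positive(m: CountMatrix, feature: str) -> float:
    """Fraction of cells with a raw count above zero for ``feature``."""
    counts = m.feature_vector(feature)
    if counts.size == 0:
        return 0.0
    return float(np.count_nonzero(counts > 0) / counts.size)


def mean_log_count(m: CountMatrix, feature: str, scale: float = 10_000.0) -> float:
    """Mean log2-normalized count of ``feature`` over all cells (zeros included)."""
    try:
        i = m.feature_names.index(feature)
    except ValueError:
        raise KeyError(f"unknown feature {feature!r}") from None
    if len(m.barcodes) == 0:
        return 0.0
    return float(log_normalize(m, scale)[i].mean())


_ESTIMATORS: dict[str, Callable[[CountMatrix, str], float]] = {
    "fraction_positive": fraction_positive,
    "mean_log_count": mean_log_count,
}


def saturation_curve(
    records: Sequence[ReadRecord],
    index: FeatureIndex,
    whitelist: Sequence[str],
    feature: str,
    estimator: str = "fraction_positive",
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 42,
    min_kmer_frac: float = 0.7,
) -> list[SaturationPoint]:
    """Subsample, re-quantify and evaluate the estimator per fraction.

    X is recomputed from each subsample (not scaled from the full run), and
    the same seed keeps subsets nested across fractions.  Points are returned
    sorted by X.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; use one of {sorted(_ESTIMATORS)}")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    estimate = _ESTIMATORS[estimator]
    feature_names = index.refset.feature_names
    points = []
    for fraction in fractions:
        sub = subsample(records, fraction, seed)
        x = reads_per_cell(sub, whitelist)
        assignments = classify_records(sub, index, min_kmer_frac)
        m = quantify(assignments, feature_names, whitelist=whitelist)
        points.append(SaturationPoint(fraction=fraction, x=x, y=estimate(m, feature)))
    return sorted(points, key=lambda p: p.x)


def fit_rational(points: Sequence[SaturationPoint] | tuple) -> RationalFit:
    """Nonlinear least squares for (a, b) with an analytic Jacobian.

    Initialization: a0 = max(Y); b0 = the X whose Y lies closest to a0/2.
    Parameters are constrained non-negative; success requires convergence and
    strictly positive estimates.  On failure the fit is still returned with
    ``converged=False``.
    """
    if points and isinstance(points[0], SaturationPoint):
        x = np.array([p.x for p in points], dtype=float)
        y = np.array([p.y for p in points], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in points)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 points with distinct X")
    if not np.any(y != 0):
        raise ValueError("all-zero estimator values cannot be fitted")

    a0 = float(y.max())
    b0 = float(x[np.argmin(np.abs(y - a0 / 2.0))])
    b0 = max(b0, 1e-9)

    def residuals(theta):
        a, b = theta
        return a * x / (b + x) - y

    def jacobian(theta):
        a, b = theta
        return np.column_stack([x / (b + x), -a * x / (b + x) ** 2])

    result = least_squares(
        residuals,
        x0=[a0, b0],
        jac=jacobian,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, b = result.x
    return RationalFit(
        a=float(a),
        b=float(b),
        rss=float(np.sum(result.fun**2)),
        converged=bool(result.success and a > 0 and b > 0),
    )


def points_frame(points: Sequence[SaturationPoint]) -> pd.DataFrame:
    """Tidy (fraction, x, y) table for CSV export."""
    return pd.DataFrame(
        {
            "fraction": [p.fraction for p in points],
            "reads_per_cell": [p.x for p in points],
            "estimator": [p.y for p in points],
        }
    )
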