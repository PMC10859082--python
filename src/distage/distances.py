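"""Distances between two expression distributions.

Hellinger distance (the primary metric) and Jensen-Shannon distance operate
on the pairwise pooled-grid PMFs; the Kolmogorov-Smirnov distance operates
directly on the two raw value vectors, matching its usual two-sample
definition. All three are symmetric, zero for identical inputs, and bounded
by 1 (JS with base-2 logarithms).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import ks_2samp

from distage.density import (
    GridMismatchError,
    ProbabilityMassFunction,
    estimate_pair_pmfs,
)

#: metric name -> operates on PMFs (True) or raw sample vectors (False)
METRICS: dict[str, bool] = {"hellinger": True, "js": True, "ks": False}


def _check_grids(p: ProbabilityMassFunction, q: ProbabilityMassFunction) -> None:
    if not p.same_grid(q):
        raise GridMismatchError("PMFs must share the same grid")


def hellinger(p: ProbabilityMassFunction, q: ProbabilityMassFunction) -> float:
    """Hellinger distance ``(1/sqrt(2)) * ||sqrt(P) - sqrt(Q)||_2`` in [0, 1]."""
    _check_grids(p, q)
    s = float(np.sum((np.sqrt(p.masses) - np.sqrt(q.masses)) ** 2))
    return min(1.0, np.sqrt(max(0.0, 0.5 * s)))


def js_distance(
    p: ProbabilityMassFunction, q: ProbabilityMassFunction, log_base: float = 2.0
) -> float:
    """Jensen-Shannon distance: sqrt of the JS divergence vs M = (P+Q)/2.

    With base-2 logarithms (the default) the value lies in [0, 1].
    """
    _check_grids(p, q)
    d = float(jensenshannon(p.masses, q.masses, base=log_base))
    if np.isnan(d):  # identical degenerate inputs
        return 0.0
    return min(1.0, max(0.0, d))


def ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance: sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(ks_2samp(x, y, method="asymp").statistic)


def pair_distance(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "hellinger",
    k: int = 1000,
    bandwidth_rule: str = "nrd0",
) -> float:
    """Distance between two raw expression vectors under the chosen metric.

    PMF-based metrics (hellinger, js) first run the pooled-grid density
    pipeline; ks is evaluated on the raw vectors.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if metric == "ks":
        return ks_distance(x, y)
    p, q = estimate_pair_pmfs(x, y, k=k, bandwidth_rule=bandwidth_rule)
    return hellinger(p, q) if metric == "hellinger" else js_distance(p, q)
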