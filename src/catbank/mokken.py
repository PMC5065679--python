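"""Nonparametric scalability screening (Mokken analysis).

Loevinger's H coefficients compare observed inter-item covariances with the
maximum covariance attainable given the items' marginal distributions (the
comonotone coupling).  H = 1 for a perfect Guttman scale, ~0 when items are
independent; items whose aggregate H_i falls below a threshold (0.3 by
convention) are deemed unscalable and screened out before parametric
calibration.  A rest-score monotonicity check verifies that mean item scores
increase with the total score on the remaining items, as any monotone latent
trait model requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcm import InvalidInputError, ResponseMatrix

__all__ = [
    "ConstantItemError",
    "ScalabilityResult",
    "MonotonicityResult",
    "loevinger_coefficients",
    "check_monotonicity",
]


class ConstantItemError(ValueError):
    def __init__(self, item_id):
        self.item_id = item_id
        super().__init__(f"item {item_id!r} has zero variance; H undefined")


@dataclass
class ScalabilityResult:
    pairwise_h: pd.DataFrame
    item_h: pd.Series
    scale_h: float
    flagged_items: list
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Hi": self.item_h,
                "flagged": [i in set(self.flagged_items) for i in self.item_h.index],
            }
        )


@dataclass
class MonotonicityResult:
    """Per-item rest-score monotonicity violations.

    ``violations[item]`` lists tuples ``(group_lo, group_hi, drop, zstat)``
    for each adjacent pair of rest-score groups whose mean item score
    decreases; ``zstat`` scales the drop by the two group-mean standard
    errors so callers can ignore sampling noise.
    """

    violations: dict
    group_edges: list = field(default_factory=list)
    warning: str | None = None

    def n_violations(self, min_z: float = 0.0) -> int:
        return sum(
            1
            for v in self.violations.values()
            for (_, _, _, z) in v
            if z >= min_z
        )


def _complete_cases(responses: ResponseMatrix) -> np.ndarray:
    X = responses.values()
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} person(s) with missing responses "
            "for Mokken analysis"
        )
    return X[keep]


def loevinger_coefficients(
    responses: ResponseMatrix, threshold: float = 0.3
) -> ScalabilityResult:
    """Pairwise, per-item and scale Loevinger H for polytomous items.

    H_ij = cov(X_i, X_j) / covmax(X_i, X_j), where covmax is attained by the
    comonotone joint distribution with the observed marginals (equivalently
    1 minus the ratio of weighted Guttman errors to their expectation under
    independence).  H_i aggregates item i's covariances against all others.
    """
    if responses.n_items < 3:
        raise InvalidInputError("Mokken analysis needs >= 3 items")
    X = _complete_cases(responses)
    if X.shape[0] < 2:
        raise InvalidInputError("Mokken analysis needs >= 2 complete persons")
    items = responses.item_ids
    P = X.shape[0]
    means = X.mean(axis=0)
    var = X.var(axis=0)
    for j, v in enumerate(var):
        if v <= 1e-12:
            raise ConstantItemError(items[j])
    cov = np.cov(X.T, ddof=0)
    Xs = np.sort(X, axis=0)
    covmax = Xs.T @ Xs / P - np.outer(means, means)
    off = ~np.eye(len(items), dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        hij = np.where(off, cov / covmax, 1.0)
    item_h = np.array(
        [
            cov[i, off[i]].sum() / covmax[i, off[i]].sum()
            for i in range(len(items))
        ]
    )
    iu = np.triu_indices(len(items), 1)
    scale_h = float(cov[iu].sum() / covmax[iu].sum())

    pairwise = pd.DataFrame(hij, index=items, columns=items)
    series = pd.Series(item_h, index=items, name="Hi")
    flagged = [i for i, h in zip(items, item_h) if h < threshold]
    return ScalabilityResult(
        pairwise_h=pairwise,
        item_h=series,
        scale_h=scale_h,
        flagged_items=flagged,
        threshold=threshold,
    )


def check_monotonicity(
    responses: ResponseMatrix, min_group_size: int | None = None
) -> MonotonicityResult:
    """Rest-score monotonicity check.

    Persons are grouped by their rest score (total minus the item under
    scrutiny); adjacent rest-score values are merged until every group holds
    at least ``min_group_size`` persons (default n/10, at least 10).  Any
    decrease in mean item score between successive groups is recorded with
    its magnitude and a z statistic.
    """
    if responses.n_items < 3:
        raise InvalidInputError("monotonicity check needs >= 3 items")
    X = _complete_cases(responses)
    P = X.shape[0]
    if min_group_size is None:
        min_group_size = max(10, P // 10)
    items = responses.item_ids
    violations: dict = {i: [] for i in items}

    total = X.sum(axis=1)
    degenerate = True
    for j, item in enumerate(items):
        rest = total - X[:, j]
        order = np.argsort(rest, kind="stable")
        rs, xs = rest[order], X[order, j]
        # merge consecutive rest-score values into groups of >= min size
        groups = []
        start = 0
        while start < P:
            end = start + min_group_size
            if end >= P:
                end = P
            else:
                # extend to include ties on the boundary rest score
                while end < P and rs[end] == rs[end - 1]:
                    end += 1
            if end - start < min_group_size and groups:
                lo, _ = groups.pop()
                groups.append((lo, end))
            else:
                groups.append((start, end))
            start = end
        if len(groups) < 2:
            continue
        degenerate = False
        stats = []
        for lo, hi in groups:
            seg = xs[lo:hi]
            stats.append((seg.mean(), seg.var(ddof=1) / len(seg) if len(seg) > 1 else 0.0))
        for g in range(len(stats) - 1):
            m0, v0 = stats[g]
            m1, v1 = stats[g + 1]
            if m1 < m0:
                drop = m0 - m1
                z = drop / np.sqrt(v0 + v1) if (v0 + v1) > 0 else np.inf
                violations[item].append((g, g + 1, float(drop), float(z)))

    warning = None
    if degenerate:
        warning = "too few persons to form 2 rest-score groups"
        warnings.warn(warning)
        violations = {i: [] for i in items}
    return MonotonicityResult(violations=violations, warning=warning)
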