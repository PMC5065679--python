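"""Partial Credit Model core: probabilities, information, calibration, scoring.

The Partial Credit Model (PCM) is the polytomous Rasch model.  A person at
latent location ``theta`` (logits) answering item *i* with ``m_i + 1`` ordered
categories scores ``k`` with probability

    P(X = k | theta) ∝ exp( D * sum_{j<=k} (theta - delta_i - tau_ij) )

where ``delta_i`` is the item location, ``tau_ij`` are the category thresholds
(centred to sum to zero within an item), and ``D`` is the logistic scaling
constant (1.0 on the logit metric, 1.7 to approximate the normal-ogive
metric inside the adaptive-testing engine).

Item parameters are estimated by marginal maximum likelihood with a
standard-normal latent distribution (Bock–Aitkin EM over Gauss–Hermite
quadrature).  Person locations are scored by maximum likelihood or Warm's
weighted likelihood; the latter stays finite at extreme (all-minimum or
all-maximum) response patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, roots_hermitenorm

__all__ = [
    "InvalidInputError",
    "NullCategoryError",
    "UndefinedPSIError",
    "ItemParameters",
    "ItemBank",
    "ResponseMatrix",
    "PersonAbility",
    "EstimationConfig",
    "ConvergenceReport",
    "category_probabilities",
    "item_information",
    "test_information",
    "expected_score",
    "fit_pcm",
    "estimate_person_locations",
    "person_separation_index",
]


class InvalidInputError(ValueError):
    """Raised when inputs violate a documented precondition."""


class NullCategoryError(ValueError):
    """An item has a response category that was never observed."""

    def __init__(self, item_id: str, category):
        self.item_id = item_id
        self.category = category
        super().__init__(
            f"item {item_id!r}: category {category!r} has no observations; "
            "collapse or recode before fitting"
        )


class UndefinedPSIError(ValueError):
    """Person Separation Index undefined (zero person variance)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemParameters:
    """PCM parameters for one polytomous item.

    ``thresholds`` are the within-item centred category thresholds tau_k
    (one fewer than the number of categories, summing to zero).  The
    ``scoring_map`` sends raw category codes (as collected, e.g. 1..5) to
    analysis scores 0..m and may be many-to-one after category collapsing.
    """

    item_id: str
    n_categories: int
    location: float
    thresholds: tuple
    scoring_map: dict | None = None

    def __post_init__(self):
        if self.n_categories < 2:
            raise InvalidInputError(
                f"item {self.item_id!r}: n_categories must be >= 2"
            )
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) != self.n_categories - 1:
            raise InvalidInputError(
                f"item {self.item_id!r}: expected {self.n_categories - 1} "
                f"thresholds, got {len(thr)}"
            )
        if abs(sum(thr)) > 1e-8:
            raise InvalidInputError(
                f"item {self.item_id!r}: thresholds must sum to 0 "
                f"(got {sum(thr):.3g}); centre them first"
            )
        if self.scoring_map is not None:
            m = {int(k): int(v) for k, v in self.scoring_map.items()}
            object.__setattr__(self, "scoring_map", m)
            scores = [m[k] for k in sorted(m)]
            if any(b < a for a, b in zip(scores, scores[1:])):
                raise InvalidInputError(
                    f"item {self.item_id!r}: scoring_map must be weakly "
                    "monotone in the raw category order"
                )
            if sorted(set(scores)) != list(range(self.max_score + 1)):
                raise InvalidInputError(
                    f"item {self.item_id!r}: scoring_map must cover scores "
                    f"0..{self.max_score}"
                )

    @property
    def max_score(self) -> int:
        return self.n_categories - 1

    @property
    def step_difficulties(self) -> np.ndarray:
        """Uncentred step difficulties beta_k = delta + tau_k."""
        return self.location + np.asarray(self.thresholds)

    def map_raw(self, value):
        """Apply the scoring map to one raw code (identity if no map)."""
        if self.scoring_map is None:
            return int(value)
        try:
            return self.scoring_map[int(value)]
        except KeyError:
            raise InvalidInputError(
                f"item {self.item_id!r}: raw code {value!r} not in scoring map"
            ) from None


@dataclass
class ItemBank:
    """A calibrated set of items plus the scaling constant D."""

    items: list
    D: float = 1.0
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.D <= 0:
            raise InvalidInputError("D must be > 0")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate item ids: {dup}")

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids) -> "ItemBank":
        keep = [self[i] for i in item_ids]
        return ItemBank(items=keep, D=self.D, name=self.name,
                        metadata=dict(self.metadata))


class ResponseMatrix:
    """Persons x items integer category responses with missing support.

    Backed by a pandas DataFrame (index: person ids, columns: item ids,
    float values with NaN for missing).  An optional ``factors`` frame keyed
    by person id carries categorical covariates for DIF screening.
    """

    def __init__(self, data: pd.DataFrame, factors: pd.DataFrame | None = None):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        self.data = data.astype(float)
        if factors is not None:
            factors = factors.copy()
            factors.index = factors.index.astype(str)
            factors = factors.reindex(self.data.index)
        self.factors = factors

    @classmethod
    def from_array(cls, values, person_ids=None, item_ids=None, factors=None):
        values = np.asarray(values, dtype=float)
        p, i = values.shape
        persons = person_ids or [f"P{v + 1:04d}" for v in range(p)]
        items = item_ids or [f"item{j + 1:02d}" for j in range(i)]
        df = pd.DataFrame(values, index=persons, columns=items)
        return cls(df, factors=factors)

    @property
    def person_ids(self) -> list:
        return list(self.data.index)

    @property
    def item_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_items(self, item_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.data[list(item_ids)], factors=self.factors)

    def drop_items(self, item_ids) -> "ResponseMatrix":
        keep = [c for c in self.data.columns if c not in set(item_ids)]
        return ResponseMatrix(self.data[keep], factors=self.factors)

    def rescore_item(self, item_id: str, mapping: dict) -> "ResponseMatrix":
        """Return a copy with one column recoded through ``mapping``."""
        df = self.data.copy()
        col = df[item_id]
        m = {int(k): int(v) for k, v in mapping.items()}
        df[item_id] = col.map(lambda x: float(m[int(x)]) if np.isfinite(x) else np.nan)
        return ResponseMatrix(df, factors=self.factors)

    def scored(self, bank: ItemBank) -> np.ndarray:
        """Analysis-score matrix (int, -1 = missing) via the bank's maps."""
        out = np.full(self.data.shape, -1, dtype=int)
        for j, item_id in enumerate(self.item_ids):
            item = bank[item_id]
            col = self.data[item_id].to_numpy()
            for v, x in enumerate(col):
                if np.isfinite(x):
                    s = item.map_raw(x)
                    if not 0 <= s <= item.max_score:
                        raise InvalidInputError(
                            f"item {item_id!r}: score {s} outside 0..{item.max_score}"
                        )
                    out[v, j] = s
        return out


@dataclass
class PersonAbility:
    """Latent-location estimate for one person."""

    person_id: str
    theta: float
    se: float
    estimator_tag: str  # ML | WL | EAP
    extreme_flag: bool = False

    def __post_init__(self):
        if self.se < 0:
            raise InvalidInputError("se must be >= 0")
        if self.extreme_flag and self.estimator_tag == "ML":
            raise InvalidInputError("ML diverges at extreme scores; use WL/EAP")


def abilities_frame(abilities) -> pd.DataFrame:
    """Tabulate a list of :class:`PersonAbility` as a DataFrame."""
    return pd.DataFrame(
        {
            "person_id": [a.person_id for a in abilities],
            "theta": [a.theta for a in abilities],
            "se": [a.se for a in abilities],
            "estimator": [a.estimator_tag for a in abilities],
            "extreme": [a.extreme_flag for a in abilities],
        }
    ).set_index("person_id")


# ---------------------------------------------------------------------------
# probabilities and information
# ---------------------------------------------------------------------------


def _cumulative_steps(item: ItemParameters) -> np.ndarray:
    """Cumulative step difficulties: [0, b1, b1+b2, ...]."""
    return np.concatenate([[0.0], np.cumsum(item.step_difficulties)])


def category_probabilities(theta, item: ItemParameters, D: float = 1.0):
    """PCM category probabilities at ``theta``.

    Returns an array over categories 0..m; with array ``theta`` the category
    axis is last.  Entries are non-negative and sum to one.
    """
    if D <= 0:
        raise InvalidInputError("D must be > 0")
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise InvalidInputError("theta must be finite")
    cum = _cumulative_steps(item)
    k = np.arange(item.n_categories)
    logits = D * (np.multiply.outer(theta, k) - cum)
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def expected_score(theta, item: ItemParameters, D: float = 1.0):
    """E[X | theta] under the PCM."""
    p = category_probabilities(theta, item, D)
    k = np.arange(item.n_categories)
    return (p * k).sum(axis=-1)


def item_information(theta, item: ItemParameters, D: float = 1.0):
    """Fisher information of one item at ``theta``: D^2 * Var(X | theta)."""
    p = category_probabilities(theta, item, D)
    k = np.arange(item.n_categories)
    mean = (p * k).sum(axis=-1)
    var = (p * k ** 2).sum(axis=-1) - mean ** 2
    return D ** 2 * var


def test_information(theta, bank: ItemBank, D: float | None = None):
    """Total information of a bank at ``theta`` (additive over items)."""
    D = bank.D if D is None else D
    theta = np.asarray(theta, dtype=float)
    total = np.zeros(theta.shape)
    for item in bank:
        total = total + item_information(theta, item, D)
    return total


def _bank_tables(items, theta_grid, D):
    """Probabilities/moments for a list of items over a theta grid.

    Returns ``(probs, kmax)`` where ``probs`` has shape (Q, I, Kmax) with
    zero probability on categories an item does not have.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    kmax = np.array([it.max_score for it in items])
    K = int(kmax.max()) + 1
    cum = np.zeros((len(items), K))
    valid = np.zeros((len(items), K), dtype=bool)
    for i, it in enumerate(items):
        c = _cumulative_steps(it)
        cum[i, : len(c)] = c
        valid[i, : len(c)] = True
    k = np.arange(K)
    logits = D * (theta_grid[:, None, None] * k[None, None, :] - cum[None, :, :])
    logits = np.where(valid[None, :, :], logits, -np.inf)
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    return p, kmax


# ---------------------------------------------------------------------------
# marginal maximum likelihood calibration
# ---------------------------------------------------------------------------


@dataclass
class EstimationConfig:
    """Controls for :func:`fit_pcm`.

    ``n_quadrature`` Gauss–Hermite nodes approximate the standard-normal
    latent density; convergence is declared when the relative change in the
    marginal log-likelihood drops below ``tol``.
    """

    max_iter: int = 500
    tol: float = 1e-6
    n_quadrature: int = 49
    D: float = 1.0


@dataclass
class ConvergenceReport:
    converged: bool
    n_iterations: int
    log_likelihood: float
    ll_trace: list
    latent_shift: float
    standard_errors: dict


def _infer_scoring(col: np.ndarray, item_id: str) -> dict:
    """Map observed raw codes to contiguous analysis scores 0..m.

    A gap in the observed integer codes (an unobserved middle category)
    raises :class:`NullCategoryError` rather than silently compressing.
    """
    obs = col[np.isfinite(col)]
    vals = np.unique(obs.astype(int))
    if len(vals) < 2:
        raise InvalidInputError(
            f"item {item_id!r}: needs observations in >= 2 categories"
        )
    full = np.arange(vals.min(), vals.max() + 1)
    missing = sorted(set(full) - set(vals))
    if missing:
        raise NullCategoryError(item_id, missing[0])
    return {int(v): i for i, v in enumerate(vals)}


def _mstep_item(r_qk, grid, D, beta0):
    """Maximise sum_qk r_qk log P_k(theta_q) over step difficulties beta."""
    m = len(beta0)
    k = np.arange(m + 1)
    n_q = r_qk.sum(axis=1)
    # expected counts of X >= j, j = 1..m, per node
    rge = np.cumsum(r_qk[:, ::-1], axis=1)[:, ::-1][:, 1:]

    def loglik(beta):
        cum = np.concatenate([[0.0], np.cumsum(beta)])
        logits = D * (grid[:, None] * k[None, :] - cum[None, :])
        logp = logits - logsumexp(logits, axis=1, keepdims=True)
        return float((r_qk * logp).sum())

    beta = beta0.copy()
    ll = loglik(beta)
    for _ in range(60):
        cum = np.concatenate([[0.0], np.cumsum(beta)])
        logits = D * (grid[:, None] * k[None, :] - cum[None, :])
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (Q, m)
        grad = D * (n_q[:, None] * pge - rge).sum(axis=0)
        jj = np.maximum(np.arange(m)[:, None], np.arange(m)[None, :])
        pge_max = pge[:, jj]  # (Q, m, m)
        hess = -D ** 2 * np.einsum(
            "q,qjl->jl", n_q, pge_max - pge[:, :, None] * pge[:, None, :]
        )
        if np.max(np.abs(grad)) < 1e-9 * max(1.0, n_q.sum()):
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.trace(hess) / m - 1e-8)
        new = beta - step
        new_ll = loglik(new)
        halved = 0
        while new_ll < ll and halved < 25:
            step *= 0.5
            new = beta - step
            new_ll = loglik(new)
            halved += 1
        if new_ll < ll:
            break
        beta, ll = new, new_ll
    return beta


def fit_pcm(responses: ResponseMatrix, config: EstimationConfig | None = None):
    """Calibrate a PCM item bank by marginal maximum likelihood (EM).

    Returns ``(bank, report)``.  Item locations are centred to mean zero
    after convergence (the identification shift is recorded in the report);
    thresholds are centred within each item.
    """
    config = config or EstimationConfig()
    if responses.n_items < 2 or responses.n_persons < 2:
        raise InvalidInputError("need at least 2 items and 2 persons")

    item_ids = responses.item_ids
    raw = responses.values()
    maps = [_infer_scoring(raw[:, j], item_ids[j]) for j in range(len(item_ids))]
    X = np.full(raw.shape, -1, dtype=int)
    for j, m in enumerate(maps):
        col = raw[:, j]
        ok = np.isfinite(col)
        X[ok, j] = [m[int(v)] for v in col[ok]]
    kmax = X.max(axis=0)
    P, I = X.shape

    all_missing = (X < 0).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} person(s) with no responses"
        )
        X = X[~all_missing]
        P = X.shape[0]

    nodes, wts = roots_hermitenorm(config.n_quadrature)
    wts = wts / wts.sum()
    D = config.D

    betas = []
    for j in range(I):
        col = X[:, j]
        counts = np.bincount(col[col >= 0], minlength=kmax[j] + 1).astype(float)
        counts = np.maximum(counts, 0.5)
        betas.append(np.log(counts[:-1] / counts[1:]))  # adjacent-logit start

    obs = X >= 0
    ll_trace = []
    converged = False
    post = None
    for iteration in range(1, config.max_iter + 1):
        # E-step: person x node log-likelihood
        logL = np.zeros((P, len(nodes)))
        plists = []
        for j in range(I):
            k = np.arange(kmax[j] + 1)
            cum = np.concatenate([[0.0], np.cumsum(betas[j])])
            logits = D * (nodes[:, None] * k[None, :] - cum[None, :])
            logp = logits - logsumexp(logits, axis=1, keepdims=True)
            plists.append(logp)
            col = X[:, j]
            mask = obs[:, j]
            logL[mask] += logp[:, col[mask]].T
        joint = logL + np.log(wts)[None, :]
        ll = float(logsumexp(joint, axis=1).sum())
        ll_trace.append(ll)
        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        if len(ll_trace) > 1:
            rel = abs(ll_trace[-1] - ll_trace[-2]) / (abs(ll_trace[-2]) + 1e-12)
            if rel < config.tol:
                converged = True
                break
        # M-step
        for j in range(I):
            col = X[:, j]
            mask = obs[:, j]
            onehot = np.zeros((int(mask.sum()), kmax[j] + 1))
            onehot[np.arange(onehot.shape[0]), col[mask]] = 1.0
            r_qk = post[mask].T @ onehot
            betas[j] = _mstep_item(r_qk, nodes, D, betas[j])

    if not converged:
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(last rel. change above {config.tol:g})"
        )

    locations = np.array([b.mean() for b in betas])
    shift = float(locations.mean())
    locations -= shift
    items = []
    for j in range(I):
        tau = betas[j] - betas[j].mean()
        tau -= tau.mean()  # exact re-centring against rounding
        items.append(
            ItemParameters(
                item_id=item_ids[j],
                n_categories=int(kmax[j]) + 1,
                location=float(locations[j]),
                thresholds=tuple(tau),
                scoring_map=maps[j],
            )
        )
    bank = ItemBank(items=items, D=1.0, name="fitted",
                    metadata={"estimator": "MML-EM", "n_persons": int(P)})

    ses = _parameter_standard_errors(X, obs, betas, kmax, nodes, post, D, item_ids)
    report = ConvergenceReport(
        converged=converged,
        n_iterations=len(ll_trace),
        log_likelihood=ll_trace[-1],
        ll_trace=ll_trace,
        latent_shift=shift,
        standard_errors=ses,
    )
    return bank, report


def _parameter_standard_errors(X, obs, betas, kmax, nodes, post, D, item_ids):
    """Empirical (cross-product) information SEs for locations/thresholds."""
    P = X.shape[0]
    blocks = []
    sizes = [len(b) for b in betas]
    for j, b in enumerate(betas):
        m = len(b)
        k = np.arange(kmax[j] + 1)
        cum = np.concatenate([[0.0], np.cumsum(b)])
        logits = D * (nodes[:, None] * k[None, :] - cum[None, :])
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (Q, m)
        e_pge = post @ pge  # (P, m) posterior-expected P(X>=j)
        ind = (X[:, j][:, None] >= np.arange(1, m + 1)[None, :]).astype(float)
        g = D * (e_pge - ind)
        g[~obs[:, j]] = 0.0
        blocks.append(g)
    G = np.concatenate(blocks, axis=1)
    info = G.T @ G
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        return {}
    out = {}
    start = 0
    for j, m in enumerate(sizes):
        block = cov[start : start + m, start : start + m]
        a = np.full(m, 1.0 / m)
        loc_var = float(a @ block @ a)
        thr_var = np.array(
            [block[t, t] - 2 * (block[t] @ a) + loc_var for t in range(m)]
        )
        out[item_ids[j]] = {
            "location_se": float(np.sqrt(max(loc_var, 0.0))),
            "threshold_se": list(np.sqrt(np.maximum(thr_var, 0.0))),
        }
        start += m
    return out


# ---------------------------------------------------------------------------
# person scoring
# ---------------------------------------------------------------------------


def _solve_theta(X, items, D, estimator):
    """Vectorised Newton solve of the (weighted) likelihood equations.

    ``X`` is an int matrix with -1 for missing.  ML solves
    sum_i D (x_i - E_i) = 0; WL adds Warm's bias correction J/(2 I) with
    J = D^3 sum_i mu3_i (the derivative of the test information).
    """
    obs = X >= 0
    Xf = np.where(obs, X, 0).astype(float)
    theta = np.zeros(X.shape[0])
    for _ in range(200):
        E, V, M3 = _moments_scaled(theta, items, D)
        score = (D * (Xf - E) * obs).sum(axis=1)
        info = (D ** 2 * V * obs).sum(axis=1)
        info = np.maximum(info, 1e-10)
        if estimator == "WL":
            J = (D ** 3 * M3 * obs).sum(axis=1)
            score = score + J / (2.0 * info)
        step = np.clip(score / info, -1.0, 1.0)
        theta = np.clip(theta + step, -10.0, 10.0)
        if np.max(np.abs(step)) < 1e-11:
            break
    _, V, _ = _moments_scaled(theta, items, D)
    info = np.maximum((D ** 2 * V * obs).sum(axis=1), 1e-10)
    se = 1.0 / np.sqrt(info)
    return theta, se


def _moments_scaled(theta, items, D):
    P = len(theta)
    E = np.zeros((P, len(items)))
    V = np.zeros((P, len(items)))
    M3 = np.zeros((P, len(items)))
    for j, it in enumerate(items):
        p = category_probabilities(theta, it, D)
        k = np.arange(it.n_categories)
        mu = (p * k).sum(axis=-1)
        E[:, j] = mu
        V[:, j] = (p * k ** 2).sum(axis=-1) - mu ** 2
        M3[:, j] = (p * (k - mu[:, None]) ** 3).sum(axis=-1)
    return E, V, M3


def estimate_person_locations(
    responses: ResponseMatrix, bank: ItemBank, estimator: str = "WL",
    D: float | None = None,
):
    """Score persons on a calibrated bank by ML or Warm's weighted likelihood.

    Persons with all responses missing are excluded with a warning.  Extreme
    raw-score patterns (all observed responses at floor or ceiling) are
    flagged; under ML they are scored by WL instead, since ML diverges there.
    """
    if estimator not in ("ML", "WL"):
        raise InvalidInputError("estimator must be 'ML' or 'WL'")
    D = bank.D if D is None else D
    items = [bank[i] for i in responses.item_ids]
    X = responses.scored(bank)
    obs = X >= 0

    keep = obs.any(axis=1)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} person(s) with no responses"
        )
    X = X[keep]
    obs = obs[keep]
    person_ids = [p for p, k in zip(responses.person_ids, keep) if k]

    kmax = np.array([it.max_score for it in items])
    raw = np.where(obs, X, 0).sum(axis=1)
    top = (obs * kmax[None, :]).sum(axis=1)
    extreme = (raw == 0) | (raw == top)

    theta = np.zeros(len(person_ids))
    se = np.ones(len(person_ids))
    tags = np.array(["WL"] * len(person_ids), dtype=object)

    if estimator == "WL":
        theta, se = _solve_theta(X, items, D, "WL")
    else:
        # ML for interior patterns, WL fallback at extremes
        t_ml, s_ml = _solve_theta(X, items, D, "ML")
        t_wl, s_wl = _solve_theta(X, items, D, "WL")
        theta = np.where(extreme, t_wl, t_ml)
        se = np.where(extreme, s_wl, s_ml)
        tags = np.where(extreme, "WL", "ML").astype(object)

    return [
        PersonAbility(
            person_id=pid,
            theta=float(t),
            se=float(s),
            estimator_tag=str(tag),
            extreme_flag=bool(ex),
        )
        for pid, t, s, tag, ex in zip(person_ids, theta, se, tags, extreme)
    ]


def person_separation_index(abilities) -> float:
    """Rasch reliability: (theta variance - mean SE^2) / theta variance.

    Extreme persons are excluded (their locations are extrapolations).
    """
    kept = [a for a in abilities if not a.extreme_flag]
    if len(kept) < 2:
        raise InvalidInputError("need >= 2 non-extreme persons for PSI")
    thetas = np.array([a.theta for a in kept])
    ses = np.array([a.se for a in kept])
    var = float(np.var(thetas, ddof=1))
    if var <= 0:
        raise UndefinedPSIError("person variance is zero; PSI undefined")
    return (var - float(np.mean(ses ** 2))) / var
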