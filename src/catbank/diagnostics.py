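"""Screening statistics for PCM item banks.

Implements the battery applied during iterative bank calibration:
standardized response residuals, class-interval chi-square and fit-residual
item fit, detection and repair (category collapsing) of disordered
thresholds, local dependency via residual correlations, differential item
functioning (DIF) by two-way ANOVA of residuals, a principal-component
unidimensionality t-test, and floor/ceiling targeting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import (
    InvalidInputError,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    abilities_frame,
    category_probabilities,
    estimate_person_locations,
)

__all__ = [
    "ResidualMatrix",
    "ItemFitReport",
    "DependencyReport",
    "DifReport",
    "DimensionalityReport",
    "CollapseResult",
    "SemanticMergeError",
    "standardized_residuals",
    "item_fit",
    "fit_residual_transform",
    "detect_disordered_thresholds",
    "collapse_categories",
    "local_dependency",
    "dif_anova",
    "unidimensionality_test",
    "percent_extreme",
]


class SemanticMergeError(ValueError):
    """A proposed category merge crosses a semantic boundary."""


@dataclass
class ResidualMatrix:
    """Standardized residuals z = (x - E[X|theta]) / sqrt(Var[X|theta]).

    Extreme persons (floor/ceiling raw scores) are excluded; ``theta``
    carries the ability estimates used, for class-interval grouping
    downstream.  ``leverage`` holds h_vi = item information / test
    information at theta_v: because theta is estimated from the same
    responses, E[z^2] is deflated by roughly (1 - h), and fit statistics
    divide the squared residuals by (1 - h) to restore calibration.
    """

    values: pd.DataFrame
    theta: pd.Series
    leverage: pd.DataFrame | None = None

    def adjusted_squares(self) -> pd.DataFrame:
        """Squared residuals corrected for estimation leverage."""
        z2 = self.values ** 2
        if self.leverage is None:
            return z2
        return z2 / (1.0 - self.leverage)

    @property
    def person_ids(self):
        return list(self.values.index)

    @property
    def item_ids(self):
        return list(self.values.columns)


@dataclass
class ItemFitReport:
    table: pd.DataFrame  # item_id, fit_residual, chi_square, df, p_value, flagged_reason
    n_class_intervals: int
    fit_residual_bound: float
    alpha: float

    @property
    def flagged_items(self):
        t = self.table
        return list(t.index[t["flagged_reason"] != "none"])

    @property
    def total_chi_square(self):
        return float(self.table["chi_square"].sum())

    @property
    def total_df(self):
        return int(self.table["df"].sum())


@dataclass
class DependencyReport:
    correlations: pd.DataFrame
    flagged_pairs: list  # (item_a, item_b, r)
    cutoff: float
    excluded_items: list = field(default_factory=list)


@dataclass
class DifReport:
    table: pd.DataFrame
    alpha: float
    n_items: int

    @property
    def flagged(self) -> pd.DataFrame:
        t = self.table
        return t[t["flag_uniform"] | t["flag_nonuniform"]]


@dataclass
class DimensionalityReport:
    loadings: pd.Series
    subset_positive: list
    subset_negative: list
    t_stats: pd.Series
    percent_significant: float
    ci: tuple
    computable: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def standardized_residuals(
    responses: ResponseMatrix, bank: ItemBank, abilities
) -> ResidualMatrix:
    """Cell-wise standardized residuals at the estimated person locations."""
    ab = abilities_frame(abilities)
    missing = [p for p in ab.index if p not in set(responses.person_ids)]
    if missing:
        raise InvalidInputError(f"abilities include unknown persons: {missing[:3]}")
    ab = ab[~ab["extreme"]]
    X = responses.scored(bank)
    idx = {p: i for i, p in enumerate(responses.person_ids)}
    rows = [idx[p] for p in ab.index]
    X = X[rows]
    theta = ab["theta"].to_numpy()

    Z = np.full(X.shape, np.nan)
    info = np.zeros(X.shape)
    for j, item_id in enumerate(responses.item_ids):
        item = bank[item_id]
        p = category_probabilities(theta, item, bank.D)
        k = np.arange(item.n_categories)
        mu = (p * k).sum(axis=-1)
        var = np.maximum((p * k ** 2).sum(axis=-1) - mu ** 2, 1e-12)
        obs = X[:, j] >= 0
        Z[obs, j] = (X[obs, j] - mu[obs]) / np.sqrt(var[obs])
        info[obs, j] = bank.D ** 2 * var[obs]
    total = info.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(info > 0, info / total, np.nan)
    lev = np.clip(lev, 0.0, 0.9)
    values = pd.DataFrame(Z, index=list(ab.index), columns=responses.item_ids)
    leverage = pd.DataFrame(lev, index=list(ab.index), columns=responses.item_ids)
    return ResidualMatrix(values=values, theta=ab["theta"], leverage=leverage)


def fit_residual_transform(sq_residuals: np.ndarray) -> float:
    """Normalize a mean squared residual to an approximate z score.

    Wilson–Hilferty cube-root transform of the chi-square-like sum of
    squared standardized residuals: mean 0, SD 1 under model fit, negative
    when responses are more deterministic than the model predicts
    (over-discrimination), positive under misfit.
    """
    s = sq_residuals[np.isfinite(sq_residuals)]
    n = len(s)
    if n == 0:
        return np.nan
    u = s.sum() / n
    c = 2.0 / (9.0 * n)
    return float((np.cbrt(u) - (1.0 - c)) / np.sqrt(c))


def _class_intervals(theta: np.ndarray, n_intervals: int, min_size: int = 20):
    """Equal-count theta groups, merged until each holds >= min_size."""
    n = len(theta)
    n_intervals = max(2, min(n_intervals, n // 2))
    while n_intervals > 2 and n // n_intervals < min_size:
        n_intervals -= 1
    order = np.argsort(theta, kind="stable")
    groups = np.zeros(n, dtype=int)
    edges = np.array_split(order, n_intervals)
    for g, members in enumerate(edges):
        groups[members] = g
    return groups, n_intervals


def item_fit(
    responses: ResponseMatrix,
    bank: ItemBank,
    abilities,
    n_class_intervals: int = 5,
    fit_residual_bound: float = 2.5,
    alpha: float = 0.01,
    min_interval_size: int = 20,
) -> ItemFitReport:
    """Chi-square and fit-residual item fit.

    Persons are grouped into ``n_class_intervals`` equal-count class
    intervals by estimated theta (intervals are merged when any would fall
    under ``min_interval_size``, with a warning).  The chi-square compares
    observed and expected mean scores per interval; df = intervals - 1.
    The fit residual is the normalized mean squared standardized residual.
    """
    resid = standardized_residuals(responses, bank, abilities)
    theta = resid.theta.to_numpy()
    if len(theta) < 2 * 2:
        raise InvalidInputError("too few non-extreme persons for item fit")
    groups, n_used = _class_intervals(theta, n_class_intervals, min_interval_size)
    if n_used < n_class_intervals:
        warnings.warn(
            f"class intervals reduced from {n_class_intervals} to {n_used} "
            "to keep groups filled"
        )

    X = responses.scored(bank)
    idx = {p: i for i, p in enumerate(responses.person_ids)}
    X = X[[idx[p] for p in resid.person_ids]]

    rows = []
    for j, item_id in enumerate(responses.item_ids):
        item = bank[item_id]
        p = category_probabilities(theta, item, bank.D)
        k = np.arange(item.n_categories)
        mu = (p * k).sum(axis=-1)
        var = np.maximum((p * k ** 2).sum(axis=-1) - mu ** 2, 1e-12)
        obs = X[:, j] >= 0
        chi2 = 0.0
        for g in range(n_used):
            sel = obs & (groups == g)
            if sel.sum() == 0:
                continue
            o = X[sel, j].sum()
            e = mu[sel].sum()
            v = var[sel].sum()
            chi2 += (o - e) ** 2 / v
        df = n_used - 1
        pval = float(stats.chi2.sf(chi2, df))
        s2 = resid.adjusted_squares()[item_id].to_numpy()
        fr = fit_residual_transform(s2[np.isfinite(s2)])
        if pval < alpha:
            reason = "misfit"
        elif abs(fr) > fit_residual_bound:
            reason = "fit_residual"
        else:
            reason = "none"
        rows.append((item_id, fr, float(chi2), df, pval, reason))

    table = pd.DataFrame(
        rows,
        columns=["item_id", "fit_residual", "chi_square", "df", "p_value",
                 "flagged_reason"],
    ).set_index("item_id")
    return ItemFitReport(
        table=table,
        n_class_intervals=n_used,
        fit_residual_bound=fit_residual_bound,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# category thresholds
# ---------------------------------------------------------------------------


def detect_disordered_thresholds(item: ItemParameters):
    """Return ``(status, pair)``: 'disordered' with the first adjacent pair
    (1-based threshold indices) where tau_{k+1} < tau_k, else ('ordered', None).
    """
    tau = np.asarray(item.thresholds)
    for k in range(len(tau) - 1):
        if tau[k + 1] < tau[k]:
            return "disordered", (k + 1, k + 2)
    return "ordered", None


@dataclass
class CollapseResult:
    item_id: str
    merge_map: dict  # analysis score -> analysis score
    new_scoring_map: dict  # raw code -> new analysis score
    responses: ResponseMatrix
    refit_required: bool
    message: str = ""


def collapse_categories(
    item: ItemParameters,
    responses: ResponseMatrix,
    semantic_groups: list | None = None,
) -> CollapseResult:
    """Merge the squeezed category at the first disordered threshold pair.

    With thresholds tau_k > tau_{k+1}, analysis score k (the category the
    disordered pair brackets) is merged downward into score k-1, e.g. a
    five-category item disordered between thresholds 3 and 4 rescores
    1-2-3-4-5 to 1-2-3-3-4.  ``semantic_groups``, when given, partitions the
    analysis scores into blocks of semantically mergeable response anchors;
    a merge crossing a block boundary (such as an agreement category into a
    neutral one) raises :class:`SemanticMergeError`.
    """
    status, pair = detect_disordered_thresholds(item)
    if status == "ordered":
        warnings.warn(f"item {item.item_id!r} already ordered; no-op")
        return CollapseResult(
            item_id=item.item_id,
            merge_map={s: s for s in range(item.n_categories)},
            new_scoring_map=dict(item.scoring_map or
                                 {s: s for s in range(item.n_categories)}),
            responses=responses,
            refit_required=False,
            message="already ordered",
        )
    k = pair[0]  # squeezed analysis score
    if semantic_groups is not None:
        block_of = {}
        for b, block in enumerate(semantic_groups):
            for s in block:
                block_of[int(s)] = b
        if block_of.get(k) != block_of.get(k - 1):
            raise SemanticMergeError(
                f"item {item.item_id!r}: merging category {k} into {k - 1} "
                "crosses a semantic boundary"
            )
    merge = {s: (s if s < k else s - 1) for s in range(item.n_categories)}
    base = item.scoring_map or {s: s for s in range(item.n_categories)}
    new_map = {raw: merge[score] for raw, score in base.items()}
    # the response column is recoded from raw codes into the merged score space
    rescored = (
        responses.rescore_item(item.item_id, new_map)
        if item.item_id in responses.item_ids
        else responses
    )
    return CollapseResult(
        item_id=item.item_id,
        merge_map=merge,
        new_scoring_map=new_map,
        responses=rescored,
        refit_required=True,
        message=f"merged analysis category {k} into {k - 1}",
    )


# ---------------------------------------------------------------------------
# local dependency
# ---------------------------------------------------------------------------


def local_dependency(residuals: ResidualMatrix, cutoff: float = 0.20) -> DependencyReport:
    """Pearson correlations of residual columns; pairs above cutoff flagged."""
    df = residuals.values
    if df.shape[1] < 3:
        raise InvalidInputError("local dependency needs >= 3 items")
    sd = df.std()
    excluded = list(sd.index[(sd == 0) | sd.isna()])
    if excluded:
        warnings.warn(f"zero-variance residual column(s) excluded: {excluded}")
    use = df.drop(columns=excluded)
    corr = use.corr()
    np.fill_diagonal(corr.values, 1.0)
    flagged = []
    cols = list(corr.columns)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = corr.iloc[a, b]
            if np.isfinite(r) and r > cutoff:
                flagged.append((cols[a], cols[b], float(r)))
    flagged.sort(key=lambda t: -t[2])
    return DependencyReport(
        correlations=corr, flagged_pairs=flagged, cutoff=cutoff,
        excluded_items=excluded,
    )


# ---------------------------------------------------------------------------
# differential item functioning
# ---------------------------------------------------------------------------


def dif_anova(
    residuals: ResidualMatrix,
    person_factors: pd.DataFrame,
    n_class_intervals: int = 5,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> DifReport:
    """Two-way ANOVA of residuals on person factor and class interval.

    The factor main effect screens uniform DIF, the factor-by-interval
    interaction non-uniform DIF.  P values are Bonferroni-adjusted over
    items within each factor when ``bonferroni`` is set.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    theta = residuals.theta.to_numpy()
    groups, n_used = _class_intervals(theta, n_class_intervals)
    factors = person_factors.reindex(residuals.person_ids)

    items = residuals.item_ids
    n_items = len(items)
    rows = []
    for fac in factors.columns:
        fvals = factors[fac]
        levels = fvals.dropna().unique()
        if len(levels) < 2:
            warnings.warn(f"factor {fac!r} has one level; skipped")
            continue
        for item in items:
            d = pd.DataFrame(
                {
                    "resid": residuals.values[item].to_numpy(),
                    "factor": fvals.to_numpy(),
                    "interval": groups,
                }
            ).dropna()
            try:
                fit = smf.ols("resid ~ C(factor) * C(interval)", data=d).fit()
                a = anova_lm(fit, typ=2)
                f_main = float(a.loc["C(factor)", "F"])
                p_main = float(a.loc["C(factor)", "PR(>F)"])
                f_int = float(a.loc["C(factor):C(interval)", "F"])
                p_int = float(a.loc["C(factor):C(interval)", "PR(>F)"])
            except Exception as exc:  # degenerate design
                warnings.warn(f"DIF ANOVA failed for {item!r}/{fac!r}: {exc}")
                f_main = p_main = f_int = p_int = np.nan
            rows.append((item, fac, f_main, p_main, f_int, p_int))

    table = pd.DataFrame(
        rows,
        columns=["item_id", "factor", "f_uniform", "p_uniform",
                 "f_nonuniform", "p_nonuniform"],
    )
    mult = n_items if bonferroni else 1
    table["p_uniform_adj"] = np.minimum(table["p_uniform"] * mult, 1.0)
    table["p_nonuniform_adj"] = np.minimum(table["p_nonuniform"] * mult, 1.0)
    table["flag_uniform"] = table["p_uniform_adj"] < alpha
    table["flag_nonuniform"] = table["p_nonuniform_adj"] < alpha
    return DifReport(table=table, alpha=alpha, n_items=n_items)


# ---------------------------------------------------------------------------
# unidimensionality
# ---------------------------------------------------------------------------


def unidimensionality_test(
    responses: ResponseMatrix,
    bank: ItemBank,
    abilities,
    alpha_z: float = 1.96,
    subsets: tuple | None = None,
) -> DimensionalityReport:
    """Principal-component residual t-test for unidimensionality.

    Items are split by the sign of their loading on the first principal
    component of the residual correlation matrix; each person's location is
    estimated separately from the two subsets and compared with
    t = (theta_A - theta_B) / sqrt(SE_A^2 + SE_B^2).  Reports the percent of
    |t| > ``alpha_z`` with a binomial (Wald) 95% CI.  ``subsets`` overrides
    the PCA split (for forced comparisons).
    """
    if responses.n_items < 4:
        raise InvalidInputError("unidimensionality test needs >= 4 items")
    resid = standardized_residuals(responses, bank, abilities)
    corr = resid.values.corr()
    good = [c for c in corr.columns if np.isfinite(corr[c]).all()]
    corr = corr.loc[good, good]
    vals, vecs = np.linalg.eigh(corr.to_numpy())
    first = vecs[:, -1]
    if first[np.argmax(np.abs(first))] < 0:
        first = -first
    loadings = pd.Series(first, index=good, name="pc1_loading")
    if subsets is None:
        pos = [i for i, l in loadings.items() if l >= 0]
        neg = [i for i, l in loadings.items() if l < 0]
    else:
        pos, neg = [list(s) for s in subsets]
    if len(pos) < 2 or len(neg) < 2:
        return DimensionalityReport(
            loadings=loadings, subset_positive=pos, subset_negative=neg,
            t_stats=pd.Series(dtype=float), percent_significant=np.nan,
            ci=(np.nan, np.nan), computable=False,
            message="a loading subset has fewer than 2 items",
        )

    keep_persons = resid.person_ids
    sub = ResponseMatrix(responses.data.loc[keep_persons], factors=None)
    ab_a = estimate_person_locations(sub.subset_items(pos), bank.subset(pos), "WL")
    ab_b = estimate_person_locations(sub.subset_items(neg), bank.subset(neg), "WL")
    fa, fb = abilities_frame(ab_a), abilities_frame(ab_b)
    common = fa.index.intersection(fb.index)
    t = (fa.loc[common, "theta"] - fb.loc[common, "theta"]) / np.sqrt(
        fa.loc[common, "se"] ** 2 + fb.loc[common, "se"] ** 2
    )
    sig = (t.abs() > alpha_z)
    pct = 100.0 * float(sig.mean())
    n = len(sig)
    half = 196.0 * np.sqrt(max(sig.mean() * (1 - sig.mean()), 0.0) / n)
    ci = (max(0.0, pct - half), min(100.0, pct + half))
    return DimensionalityReport(
        loadings=loadings, subset_positive=pos, subset_negative=neg,
        t_stats=t, percent_significant=pct, ci=ci,
    )


# ---------------------------------------------------------------------------
# targeting
# ---------------------------------------------------------------------------


def percent_extreme(responses: ResponseMatrix, bank: ItemBank) -> float:
    """Percent of persons at the floor or ceiling of their observed items."""
    X = responses.scored(bank)
    kmax = np.array([bank[i].max_score for i in responses.item_ids])
    obs = X >= 0
    any_obs = obs.any(axis=1)
    raw = np.where(obs, X, 0).sum(axis=1)
    top = (obs * kmax[None, :]).sum(axis=1)
    extreme = any_obs & ((raw == 0) | (raw == top))
    if responses.n_persons == 0:
        return 0.0
    return 100.0 * float(extreme.sum()) / responses.n_persons
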