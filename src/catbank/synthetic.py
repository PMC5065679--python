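"""Synthetic PCM fixtures: item banks, response matrices, pathologies.

The generator emulates a quality-of-life questionnaire study: around 320
respondents answering four domains of five-category Likert items (28
physical, 24 psychological, 12 social, 32 environmental by default), with
standard-normal person locations and item locations spread uniformly over
[-2, 2].  Pathological fixtures (differential item functioning, local
dependency, disordered categories, a second latent dimension, perfect
Guttman patterns) come with ground-truth labels so detection power can be
benchmarked.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcm import (
    InvalidInputError,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    category_probabilities,
)

__all__ = [
    "GeneratorSpec",
    "generate_item_bank",
    "generate_domain_banks",
    "simulate_responses",
    "make_guttman",
    "inject_pathology",
]

DEFAULT_DOMAINS = (
    ("physical", 28),
    ("psychological", 24),
    ("social", 12),
    ("environmental", 32),
)


@dataclass
class GeneratorSpec:
    """Study-design parameters for the synthetic fixtures.

    ``threshold_spread`` is the half-range of the evenly spaced base
    thresholds (logits); per-item jitter scales with it so a spread of zero
    yields the rating-scale degenerate case of all-zero thresholds.
    """

    n_persons: int = 320
    domains: tuple = DEFAULT_DOMAINS
    n_categories: int = 5
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    location_range: tuple = (-2.0, 2.0)
    threshold_spread: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1 or self.n_categories < 2:
            raise InvalidInputError("counts must be positive")
        for _, n in self.domains:
            if n < 1:
                raise InvalidInputError("domain item counts must be positive")


def _draw_thresholds(rng, m, spread):
    if m == 1:
        return np.zeros(1)
    base = np.linspace(-spread, spread, m)
    jitter = rng.normal(0.0, 0.2 * spread, size=m) if spread > 0 else np.zeros(m)
    tau = np.sort(base + jitter)
    return tau - tau.mean()


def generate_item_bank(
    spec: GeneratorSpec, n_items: int | None = None,
    name: str = "synthetic", prefix: str = "item",
) -> ItemBank:
    """Draw a bank of ``n_items`` (default: the spec's total across domains).

    Locations are uniform over ``spec.location_range``; thresholds are
    evenly spaced with jitter, sorted (ordered) and centred within item.
    """
    rng = np.random.default_rng(spec.seed)
    if n_items is None:
        n_items = sum(n for _, n in spec.domains)
    lo, hi = spec.location_range
    m = spec.n_categories - 1
    items = []
    for j in range(n_items):
        loc = float(rng.uniform(lo, hi))
        tau = _draw_thresholds(rng, m, spec.threshold_spread)
        items.append(
            ItemParameters(
                item_id=f"{prefix}{j + 1:03d}",
                n_categories=spec.n_categories,
                location=loc,
                thresholds=tuple(tau),
                scoring_map={k: k for k in range(spec.n_categories)},
            )
        )
    return ItemBank(items=items, D=1.0, name=name,
                    metadata={"generator_seed": spec.seed})


def generate_domain_banks(spec: GeneratorSpec) -> dict:
    """One bank per domain, with domain-specific seeds derived from the spec."""
    out = {}
    for d, (domain, n) in enumerate(spec.domains):
        sub = GeneratorSpec(
            n_persons=spec.n_persons, domains=spec.domains,
            n_categories=spec.n_categories, theta_mean=spec.theta_mean,
            theta_sd=spec.theta_sd, location_range=spec.location_range,
            threshold_spread=spec.threshold_spread,
            seed=(spec.seed * 1000 + d) % (2 ** 31),
        )
        out[domain] = generate_item_bank(
            sub, n_items=n, name=domain, prefix=f"{domain[:3]}_",
        )
    return out


def simulate_responses(
    bank: ItemBank, thetas, seed: int = 0, D: float = 1.0,
    person_prefix: str = "P",
) -> ResponseMatrix:
    """Draw a full response matrix from the PCM at the given person locations."""
    rng = np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    P = len(thetas)
    data = np.empty((P, bank.n_items))
    for j, item in enumerate(bank):
        p = category_probabilities(thetas, item, D)  # (P, K)
        u = rng.random(P)
        data[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    df = pd.DataFrame(
        data,
        index=[f"{person_prefix}{v + 1:04d}" for v in range(P)],
        columns=bank.item_ids,
    )
    return ResponseMatrix(df)


def make_guttman(n_persons: int, n_items: int, n_categories: int = 2) -> ResponseMatrix:
    """Deterministic double-monotone (perfect Guttman) response pattern.

    Person v holds cumulative level l_v on a ladder of n_items * m steps;
    item i (in difficulty order) receives score clip(l_v - i*m, 0, m), so
    scores are non-increasing in item rank and non-decreasing in person
    rank, with no Guttman errors (Loevinger H = 1).
    """
    if n_persons < 1 or n_items < 1 or n_categories < 2:
        raise InvalidInputError("counts must be positive")
    m = n_categories - 1
    levels = np.round(
        np.linspace(0, n_items * m, n_persons)
    ).astype(int)
    data = np.empty((n_persons, n_items))
    for i in range(n_items):
        data[:, i] = np.clip(levels - i * m, 0, m)
    df = pd.DataFrame(
        data,
        index=[f"P{v + 1:04d}" for v in range(n_persons)],
        columns=[f"item{i + 1:02d}" for i in range(n_items)],
    )
    return ResponseMatrix(df)


def inject_pathology(fixture, kind: str, params: dict | None = None, seed: int = 0):
    """Create a labelled psychometric violation; returns (fixture, truth).

    kinds:
      - ``"dependency"``: fixture is a ResponseMatrix; appends a noisy copy
        of one item's column (noise = probability of replacing a response
        with a uniform category draw).
      - ``"disorder"``: fixture is an ItemBank; swaps two adjacent
        thresholds of one item so the generating item is disordered.
      - ``"dif"``: fixture is ``(bank, thetas)``; generates responses where
        one item's location is shifted by ``delta`` for factor level "B".
      - ``"multidim"``: fixture is ``(bank, thetas)``; a second orthogonal
        trait drives a stated subset of items.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "dependency":
        responses: ResponseMatrix = fixture
        source = params.get("item_id", responses.item_ids[-1])
        noise = float(params.get("noise", 0.0))
        n_cat = int(params.get("n_categories",
                               int(np.nanmax(responses.data[source])) + 1))
        col = responses.data[source].to_numpy().copy()
        flip = rng.random(len(col)) < noise
        col[flip] = rng.integers(0, n_cat, size=int(flip.sum()))
        new_id = f"{source}_dup"
        df = responses.data.copy()
        df[new_id] = col
        truth = {"kind": kind, "source_item": source, "new_item": new_id,
                 "noise": noise}
        return ResponseMatrix(df, factors=responses.factors), truth

    if kind == "disorder":
        bank: ItemBank = fixture
        item_id = params.get("item_id", bank.item_ids[0])
        item = bank[item_id]
        if item.n_categories < 3:
            raise InvalidInputError("need >= 3 categories to disorder")
        tau = list(item.thresholds)
        k = int(params.get("pair", len(tau) // 2))
        k = min(max(k, 1), len(tau) - 1)
        # swapping preserves the zero sum; widen the gap so the reversal is
        # material, not cosmetic
        gap = float(params.get("gap", 0.75))
        lo, hi = tau[k - 1], tau[k]
        mid = 0.5 * (lo + hi)
        tau[k - 1], tau[k] = mid + gap / 2, mid - gap / 2
        from dataclasses import replace

        items = [replace(it, thresholds=tuple(tau)) if it.item_id == item_id
                 else it for it in bank]
        truth = {"kind": kind, "item": item_id, "pair": (k, k + 1)}
        return ItemBank(items=items, D=bank.D, name=bank.name,
                        metadata=dict(bank.metadata)), truth

    if kind == "dif":
        bank, thetas = fixture
        thetas = np.asarray(thetas, dtype=float)
        delta = float(params.get("delta", 0.5))
        item_id = params.get("item_id", bank.item_ids[0])
        group = params.get(
            "group", np.where(rng.random(len(thetas)) < 0.5, "A", "B")
        )
        group = np.asarray(group)
        from dataclasses import replace

        shifted_items = [
            replace(it, location=it.location + delta) if it.item_id == item_id
            else it for it in bank
        ]
        bank_b = ItemBank(items=shifted_items, D=bank.D, name=bank.name)
        resp_a = simulate_responses(bank, thetas, seed=seed + 1)
        resp_b = simulate_responses(bank_b, thetas, seed=seed + 2)
        data = resp_a.data.copy()
        mask_b = group == "B"
        data.loc[mask_b, :] = resp_b.data.loc[mask_b, :].to_numpy()
        factors = pd.DataFrame({"group": group}, index=data.index)
        truth = {"kind": kind, "item": item_id, "delta": delta,
                 "factor": "group", "shifted_level": "B"}
        return ResponseMatrix(data, factors=factors), truth

    if kind == "multidim":
        bank, thetas = fixture
        thetas = np.asarray(thetas, dtype=float)
        second_items = params.get("items", bank.item_ids[bank.n_items // 2:])
        theta2 = rng.standard_normal(len(thetas))
        resp1 = simulate_responses(bank, thetas, seed=seed + 1)
        resp2 = simulate_responses(bank, theta2, seed=seed + 2)
        data = resp1.data.copy()
        for item in second_items:
            data[item] = resp2.data[item]
        truth = {"kind": kind, "second_dimension_items": list(second_items)}
        return ResponseMatrix(data), truth

    raise InvalidInputError(f"unknown pathology kind {kind!r}")
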