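"""Text-format plumbing: item banks as JSON, responses as CSV, configs as YAML.

All artifacts are plain text for inspectability.  Bank parameters are
written at 12 significant digits, which makes write -> read -> write
byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationConfig
from .cat import CatConfig
from .pcm import InvalidInputError, ItemBank, ItemParameters, ResponseMatrix
from .synthetic import GeneratorSpec

__all__ = [
    "FormatError",
    "write_bank",
    "read_bank",
    "write_responses",
    "read_responses",
    "read_factors",
    "load_config",
    "dump_config",
    "file_digest",
]


class FormatError(ValueError):
    """Malformed artifact file; message names the offending path/field."""


def _round12(x: float) -> float:
    return float(f"{float(x):.12g}")


def bank_to_dict(bank: ItemBank) -> dict:
    return {
        "name": bank.name,
        "D": _round12(bank.D),
        "metadata": bank.metadata,
        "items": [
            {
                "item_id": it.item_id,
                "n_categories": it.n_categories,
                "location": _round12(it.location),
                "thresholds": [_round12(t) for t in it.thresholds],
                "scoring_map": (
                    {str(k): v for k, v in it.scoring_map.items()}
                    if it.scoring_map is not None else None
                ),
            }
            for it in bank
        ],
    }


def bank_from_dict(d: dict) -> ItemBank:
    items = []
    for i, raw in enumerate(d.get("items", [])):
        path = f"items[{i}]"
        try:
            n_cat = int(raw["n_categories"])
        except (KeyError, TypeError, ValueError):
            raise FormatError(f"{path}.n_categories: missing or not an integer")
        if n_cat < 2:
            raise FormatError(f"{path}.n_categories: must be >= 2, got {n_cat}")
        thr = raw.get("thresholds")
        if not isinstance(thr, list) or len(thr) != n_cat - 1:
            raise FormatError(
                f"{path}.thresholds: expected list of {n_cat - 1} numbers"
            )
        sm = raw.get("scoring_map")
        if sm is not None:
            try:
                sm = {int(k): int(v) for k, v in sm.items()}
            except (TypeError, ValueError):
                raise FormatError(f"{path}.scoring_map: keys/values must be integers")
        try:
            # re-centre only if rounding drifted past the identification
            # tolerance, so write->read->write is byte-stable
            arr = np.asarray([float(t) for t in thr])
            if abs(arr.sum()) > 1e-9:
                arr = arr - arr.mean()
            items.append(
                ItemParameters(
                    item_id=str(raw.get("item_id", f"item{i}")),
                    n_categories=n_cat,
                    location=float(raw.get("location", 0.0)),
                    thresholds=tuple(arr),
                    scoring_map=sm,
                )
            )
        except InvalidInputError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    try:
        return ItemBank(
            items=items,
            D=float(d.get("D", 1.0)),
            name=str(d.get("name", "")),
            metadata=d.get("metadata") or {},
        )
    except InvalidInputError as exc:
        raise FormatError(str(exc)) from exc


def write_bank(bank: ItemBank, path) -> None:
    with open(path, "w") as fh:
        json.dump(bank_to_dict(bank), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_bank(path) -> ItemBank:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return bank_from_dict(d)


def write_responses(responses: ResponseMatrix, path, factors_path=None) -> None:
    df = responses.data.copy()
    df.index.name = "person_id"
    # integer categories written without a decimal point; missing as empty
    out = df.map(lambda x: "" if not np.isfinite(x) else str(int(x))
                 if float(x).is_integer() else repr(x))
    out.to_csv(path)
    if factors_path is not None and responses.factors is not None:
        f = responses.factors.copy()
        f.index.name = "person_id"
        f.to_csv(factors_path)


def read_responses(path, factors_path=None) -> ResponseMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate person_id {dup!r}")
    for col in df.columns:
        bad = df[col].dropna().map(
            lambda x: not float(x).is_integer() if np.isreal(x) else True
        )
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{path}: column {col!r}, person {row!r}: "
                "responses must be integer category codes"
            )
    factors = None
    if factors_path is not None:
        factors = read_factors(factors_path)
    return ResponseMatrix(df.astype(float), factors=factors)


def read_factors(path) -> pd.DataFrame:
    try:
        f = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    f.index = f.index.astype(str)
    return f


_CONFIG_TYPES = {
    "calibration": CalibrationConfig,
    "cat": CatConfig,
    "generator": GeneratorSpec,
}


def load_config(path, kind: str):
    """Read a YAML config of the given kind, ignoring unknown keys loudly."""
    cls = _CONFIG_TYPES[kind]
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - fields)
    if unknown:
        raise FormatError(f"{path}: unknown {kind} config keys: {unknown}")
    converted = {}
    for k, v in raw.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        converted[k] = v
    try:
        return cls(**converted)
    except (TypeError, InvalidInputError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def dump_config(config, path) -> None:
    d = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
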