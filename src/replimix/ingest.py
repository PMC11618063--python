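"""Reading, validating, filtering and weighting meta-analytic effect-size tables.

A table of observed effects (estimate, standard error / sampling variance,
study and meta-analysis membership) is turned into the z statistics
``z = es/se`` and per-effect cluster weights ``w_ij = 1/n_j`` that the mixture
fit and the confidence-band construction consume.  Each study contributes a
total weight of 1, so the summed weight equals the number of independent
studies J.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptyResultError, SchemaError

__all__ = [
    "EffectTable",
    "FilterLog",
    "load_effects",
    "filter_effects",
    "deduplicate_studies",
    "compute_weights",
]

#: canonical internal column order
_COLUMNS = ["meta_id", "study_id", "effect_id", "effect_type", "label",
            "es", "se", "var", "z", "weight"]

#: cluster key: records from the same study in the same meta-analysis
_STUDY_KEY = ["meta_id", "study_id"]


@dataclass
class FilterLog:
    """Per-rule removal counts from :func:`filter_effects`.

    A record can violate several rules at once; per-rule counts therefore
    may sum to more than ``n_removed``.
    """

    counts: dict[str, int] = field(default_factory=dict)
    n_removed: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "count": v} for k, v in self.counts.items()]
        rows.append({"rule": "total_removed", "count": self.n_removed})
        rows.append({"rule": "retained", "count": self.n_retained})
        return pd.DataFrame(rows)


@dataclass
class EffectTable:
    """An ordered collection of observed effects with cluster weights.

    Wraps a :class:`pandas.DataFrame` with columns ``meta_id, study_id,
    effect_id, effect_type, label, es, se, var, z, weight``.  The cluster
    unit is the (meta_id, study_id) pair; within a cluster every record
    carries weight 1/n_j, so each study contributes total weight 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"EffectTable missing internal columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_per_study(self) -> pd.Series:
        """Record count n_j per (meta_id, study_id) cluster."""
        return self.data.groupby(_STUDY_KEY, sort=False).size()

    @property
    def n_studies(self) -> int:
        return int(self.data.drop_duplicates(_STUDY_KEY).shape[0])

    @property
    def z(self) -> np.ndarray:
        return self.data["z"].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    def copy(self) -> "EffectTable":
        return EffectTable(self.data.copy())

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _as_numeric(s: pd.Series) -> pd.Series:
    # unparseable cells become NaN, never 0
    return pd.to_numeric(s, errors="coerce")


def load_effects(path: str | Path, schema: dict[str, str]) -> EffectTable:
    """Load a delimited effect-size table and derive se, var and z.

    Parameters
    ----------
    path
        CSV or TSV file with a header row (delimiter sniffed).
    schema
        Role → column-name mapping.  Required roles: ``es``, ``study``,
        ``meta`` and at least one of ``var`` / ``se``.  Optional:
        ``effect_type``, ``label``.

    Row order is preserved; unparseable numeric cells become missing values.
    No filtering happens here — see :func:`filter_effects`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                          skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    except csv.Error:
        # delimiter sniffing fails on single-column files; fall back to comma
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.empty:
        raise EmptyInputError(f"{path} contains no records")

    for role in ("es", "study", "meta"):
        if role not in schema:
            raise SchemaError(f"schema missing required role '{role}'")
    if "var" not in schema and "se" not in schema:
        raise SchemaError("schema must map 'var' or 'se' to a column")
    for role, col in schema.items():
        if col not in raw.columns:
            raise SchemaError(f"column '{col}' (role '{role}') not found in {path.name}")

    es = _as_numeric(raw[schema["es"]])
    if "var" in schema:
        # variance wins when both are mapped; SE derived for consistency
        var = _as_numeric(raw[schema["var"]])
        se = pd.Series(np.where(var > 0, np.sqrt(np.abs(var)), np.nan),
                       index=var.index)
    else:
        se = _as_numeric(raw[schema["se"]])
        se = se.where(se > 0)
        var = se**2

    data = pd.DataFrame({
        "meta_id": raw[schema["meta"]].astype(str),
        "study_id": raw[schema["study"]].astype(str),
        "effect_id": [f"E{i}" for i in range(len(raw))],
        "effect_type": (raw[schema["effect_type"]].astype(str)
                        if "effect_type" in schema else "other"),
        "label": (raw[schema["label"]].astype(str)
                  if "label" in schema else raw[schema["study"]].astype(str)),
        "es": es,
        "se": se,
        # raw variance kept as-is (may be 0/negative/missing) for the filter log
        "var": var,
        "z": es / se,
        "weight": np.nan,
    })
    return compute_weights(EffectTable(data))


def filter_effects(table: EffectTable) -> tuple[EffectTable, FilterLog]:
    """Remove records with missing/zero/negative sampling variance or missing estimate.

    Returns the cleaned table (weights recomputed) and a per-rule removal log.
    Raises :class:`EmptyResultError` if nothing survives.
    """
    df = table.data
    var = df["var"]
    es = df["es"]
    rules = {
        "missing_variance": var.isna(),
        "zero_variance": var == 0,
        "negative_variance": var < 0,
        "missing_estimate": es.isna(),
    }
    bad = pd.Series(False, index=df.index)
    log = FilterLog()
    for name, mask in rules.items():
        log.counts[name] = int(mask.sum())
        bad |= mask
    log.n_removed = int(bad.sum())
    log.n_retained = len(df) - log.n_removed
    if log.n_retained == 0:
        raise EmptyResultError("filter_effects removed every record")
    out = df.loc[~bad].copy()
    return compute_weights(EffectTable(out)), log


def _normalize_key(s: pd.Series) -> pd.Series:
    return s.astype(str).str.casefold().map(lambda x: re.sub(r"\s+", " ", x).strip())


def deduplicate_studies(table: EffectTable, key: str = "label") -> EffectTable:
    """Drop repeat occurrences of a study shared across meta-analyses.

    Studies are matched by a normalized (case-folded, whitespace-collapsed)
    value of ``key`` (default: the study label column).  When the same
    normalized key appears under more than one meta_id, the occurrence first
    in input order is kept and all records of the later occurrences are
    dropped.  Weights are recomputed.
    """
    df = table.data
    if key not in df.columns:
        raise SchemaError(f"dedup key column '{key}' not present")
    norm = _normalize_key(df[key])
    first_meta = df.assign(_norm=norm).drop_duplicates("_norm").set_index("_norm")["meta_id"]
    keep = df["meta_id"].to_numpy() == first_meta.reindex(norm).to_numpy()
    out = df.loc[keep].copy()
    if out.empty:
        raise EmptyResultError("deduplicate_studies removed every record")
    return compute_weights(EffectTable(out))


def compute_weights(table: EffectTable) -> EffectTable:
    """Set w_ij = 1/n_j within each (meta_id, study_id) cluster.

    The summed weight then equals the number of distinct studies J exactly.
    """
    df = table.data.copy()
    n = df.groupby(_STUDY_KEY, sort=False)["effect_id"].transform("size")
    df["weight"] = 1.0 / n.to_numpy(dtype=float)
    return EffectTable(df)
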