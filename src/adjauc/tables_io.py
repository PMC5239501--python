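"""Reading and writing the package's normalized tables.

The ingestion contract is a single long-format CSV/TSV screen table, one row
per measurement::

    study,drug,cell_line,concentration_nM,response
    CCLE,CRIZOTINIB,KMS26,2.5,1.8
    ...

``concentration_nM`` must be positive; ``response`` is percent inhibition
(0 = no effect, 100 = complete inhibition).  Rows violating the contract
(non-positive or missing concentration, missing response) are dropped and
counted.  Converters from any specific portal's native download format are
out of scope: normalizing to this schema is the caller's job, and
:func:`viability_to_inhibition` helps with the one common sign flip.

Sensitivity tables (the output of :func:`adjauc.metrics.six_metric_table`
and :func:`adjauc.harmonize.harmonized_table`) round-trip through CSV with
``+inf`` serialized as the literal ``Inf``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dose_response import ConcentrationRange, DoseResponseCurve
from .errors import ConfigError, SchemaError
from .metrics import METRICS, SensitivityRecord

__all__ = [
    "SCREEN_COLUMNS",
    "SENSITIVITY_COLUMNS",
    "DEFAULT_CONFIG",
    "read_screen_table",
    "validate_screen_table",
    "iter_curves",
    "write_screen_table",
    "write_sensitivity_table",
    "read_sensitivity_table",
    "records_to_frame",
    "frame_to_records",
    "read_config",
    "viability_to_inhibition",
]

log = logging.getLogger(__name__)

SCREEN_COLUMNS = ("study", "drug", "cell_line", "concentration_nM", "response")
SENSITIVITY_COLUMNS = (
    "study", "drug", "cell_line", "metric", "value",
    "x_min_nM", "x_max_nM", "extrapolated",
)

#: Run-configuration defaults (YAML keys accepted by :func:`read_config`).
DEFAULT_CONFIG: dict[str, float | int] = {
    "grid_step": 1.0,          # nM, AUC integration grid
    "n_resample": 1000,        # bootstrap/permutation resamples
    "seed": 0,
    "amplitude_threshold": 30.0,  # percent, low-amplitude refit rule
}

_INF_LITERAL = "Inf"


def viability_to_inhibition(viability) -> np.ndarray | float:
    """Convert percent viability to percent inhibition (``100 - viability``).

    Provided for callers whose raw screens report relative viability; the
    package itself works exclusively in percent inhibition.
    """
    return 100.0 - np.asarray(viability, dtype=float) if not np.isscalar(
        viability
    ) else 100.0 - float(viability)


def validate_screen_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the screen-table schema; drop and count invalid rows.

    Returns a clean copy with string identifiers and float measurements.
    The number of dropped rows is stored in ``df.attrs['n_dropped']`` and
    logged.
    """
    for col in SCREEN_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"screen table is missing required column {col!r}")
    out = df.loc[:, list(SCREEN_COLUMNS)].copy()
    for col in ("study", "drug", "cell_line"):
        out[col] = out[col].astype(str)
    for col in ("concentration_nM", "response"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    ok = (
        np.isfinite(out["concentration_nM"])
        & (out["concentration_nM"] > 0)
        & np.isfinite(out["response"])
    )
    n_dropped = int((~ok).sum())
    out = out.loc[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    if n_dropped:
        log.info("screen table: dropped %d invalid row(s)", n_dropped)
    return out


def read_screen_table(path, format: str | None = None) -> pd.DataFrame:
    """Read a long-format screen table from CSV (default) or TSV.

    ``format`` may be ``"csv"`` or ``"tsv"``; if omitted it is inferred from
    the file suffix.  See :func:`validate_screen_table` for the row filter.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    return validate_screen_table(pd.read_csv(path, sep=sep))


def write_screen_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(SCREEN_COLUMNS)].to_csv(path, index=False)


def iter_curves(table: pd.DataFrame) -> list[DoseResponseCurve]:
    """Group a validated screen table into per-(study, drug, cell line) curves.

    Groups with fewer than two distinct concentrations cannot form a curve
    and are skipped with a logged count.  Grouping is order-independent:
    points are sorted by concentration inside each curve.
    """
    curves: list[DoseResponseCurve] = []
    n_skipped = 0
    for (study, drug, cell), grp in table.groupby(
        ["study", "drug", "cell_line"], sort=True
    ):
        try:
            curves.append(
                DoseResponseCurve(
                    str(study), str(drug), str(cell),
                    grp["concentration_nM"].to_numpy(float),
                    grp["response"].to_numpy(float),
                )
            )
        except ValueError:
            n_skipped += 1
    if n_skipped:
        log.info("iter_curves: skipped %d group(s) with < 2 distinct doses", n_skipped)
    return curves


# ---------------------------------------------------------------------------
# Sensitivity tables


def records_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    """Sensitivity records -> DataFrame, stably ordered by (drug, cell line,
    study, metric)."""
    rows = [
        {
            "study": r.study_id,
            "drug": r.drug_id,
            "cell_line": r.cell_line_id,
            "metric": r.metric,
            "value": r.value,
            "x_min_nM": r.range_used.x_min,
            "x_max_nM": r.range_used.x_max,
            "extrapolated": bool(r.extrapolated),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(SENSITIVITY_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["drug", "cell_line", "study", "metric"], kind="stable"
        ).reset_index(drop=True)
    return df


def frame_to_records(df: pd.DataFrame) -> list[SensitivityRecord]:
    return [
        SensitivityRecord(
            str(row.study), str(row.drug), str(row.cell_line), str(row.metric),
            float(row.value),
            ConcentrationRange(float(row.x_min_nM), float(row.x_max_nM)),
            bool(row.extrapolated),
        )
        for row in df.itertuples(index=False)
    ]


def write_sensitivity_table(
    records: Sequence[SensitivityRecord] | pd.DataFrame, path
) -> None:
    """Write a sensitivity table to CSV; ``+inf`` becomes the literal ``Inf``.

    Accepts either a list of records or an already-built frame.  Output rows
    are ordered by (drug, cell line, study, metric) so repeated writes of the
    same records are byte-identical.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    bad = set(df["metric"]) - set(METRICS)
    if bad:
        raise SchemaError(f"unknown metric name(s): {sorted(bad)}")
    out = df.copy()
    out["value"] = [
        _INF_LITERAL if math.isinf(v) else repr(float(v)) for v in out["value"]
    ]
    out.to_csv(path, index=False)


def read_sensitivity_table(path) -> pd.DataFrame:
    """Read a sensitivity table written by :func:`write_sensitivity_table`."""
    df = pd.read_csv(path, dtype={"value": str})
    for col in SENSITIVITY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"sensitivity table is missing column {col!r}")
    df["value"] = [
        math.inf if str(v).strip() == _INF_LITERAL else float(v)
        for v in df["value"]
    ]
    for col in ("study", "drug", "cell_line", "metric"):
        df[col] = df[col].astype(str)
    df["extrapolated"] = df["extrapolated"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Configuration


def read_config(path) -> dict:
    """Read a YAML run configuration, applying defaults for absent keys.

    Unknown keys are rejected (typos should fail loudly, not silently fall
    back to defaults).
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a key/value mapping")
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(raw)
    return cfg
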