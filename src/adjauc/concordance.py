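"""Between-study agreement of sensitivity metrics, with resampling uncertainty.

Two studies' sensitivity tables are joined on (drug, cell line) for a chosen
metric.  For the potency metrics (EC50/IC50) the comparison is restricted to
the subset of finite values: a censored (+inf) value on either side removes
the pair.  Agreement is summarized by the Pearson and Spearman correlations,
a percentile-bootstrap 95% confidence interval on Pearson's r, and a
permutation p-value (fraction of label permutations whose |r| reaches the
observed |r|, lower-bounded by 1/(n_resample + 1)); all resampling is
reproducible from an explicit seed.  A drug's agreement is called *moderate*
when Pearson's r strictly exceeds 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .metrics import METRICS

__all__ = [
    "MODERATE_R",
    "MIN_PAIRS",
    "PairedSensitivity",
    "ConcordanceResult",
    "paired_finite",
    "pearson_r",
    "spearman_rho",
    "resample_uncertainty",
    "concordance_report",
]

log = logging.getLogger(__name__)

#: Strict threshold for "moderate" between-study agreement.
MODERATE_R = 0.5
#: Correlations are not reported on fewer pairs than this.
MIN_PAIRS = 3

_POTENCY_METRICS = ("EC50", "IC50")


@dataclass(frozen=True)
class PairedSensitivity:
    """One (drug, cell line) measured by both studies under one metric."""

    drug_id: str
    cell_line_id: str
    value_a: float
    value_b: float
    metric: str
    study_a: str
    study_b: str


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement summary for one metric, pooled or for a single drug.

    ``scope`` is ``"pooled"`` or a drug identifier.  When fewer than
    :data:`MIN_PAIRS` pairs survive filtering (or variance is zero) the
    numeric fields are NaN and ``reason`` explains why.
    """

    metric: str
    scope: str
    study_a: str
    study_b: str
    n_pairs: int
    pearson_r: float = math.nan
    spearman_rho: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p_value: float = math.nan
    moderate: bool = False
    drug_class: str | None = None
    best_metric: bool = False
    reason: str | None = None


def paired_finite(
    table_a: pd.DataFrame, table_b: pd.DataFrame, metric: str
) -> list[PairedSensitivity]:
    """Inner-join two sensitivity tables on (drug, cell line) for ``metric``.

    For EC50/IC50, pairs with a censored (+inf) value on either side are
    dropped (and the drop is logged); AUC-family pairs are never dropped for
    infinity.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    a = table_a.loc[table_a["metric"] == metric]
    b = table_b.loc[table_b["metric"] == metric]
    merged = a.merge(b, on=["drug", "cell_line"], suffixes=("_a", "_b"))
    n_before = len(merged)
    if metric in _POTENCY_METRICS:
        finite = np.isfinite(merged["value_a"]) & np.isfinite(merged["value_b"])
        merged = merged.loc[finite]
        if n_before - len(merged):
            log.info(
                "paired_finite(%s): dropped %d pair(s) with censored values",
                metric, n_before - len(merged),
            )
    return [
        PairedSensitivity(
            str(row.drug), str(row.cell_line),
            float(row.value_a), float(row.value_b),
            metric, str(row.study_a), str(row.study_b),
        )
        for row in merged.itertuples(index=False)
    ]


def _arrays(pairs: Sequence[PairedSensitivity]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([p.value_a for p in pairs], dtype=float)
    b = np.array([p.value_b for p in pairs], dtype=float)
    if a.size < MIN_PAIRS:
        raise UndefinedCorrelationError(
            f"correlation needs >= {MIN_PAIRS} pairs, got {a.size}"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance on one side")
    return a, b


def pearson_r(pairs: Sequence[PairedSensitivity]) -> float:
    """Product-moment correlation of the paired values."""
    a, b = _arrays(pairs)
    return float(stats.pearsonr(a, b).statistic)


def spearman_rho(pairs: Sequence[PairedSensitivity]) -> float:
    """Rank correlation (average ranks for ties) of the paired values."""
    a, b = _arrays(pairs)
    return float(stats.spearmanr(a, b).statistic)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r of each row of A with the matching row of B; NaN where a row
    is constant."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", A, B)
    den = np.sqrt(np.einsum("ij,ij->i", A, A) * np.einsum("ij,ij->i", B, B))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def resample_uncertainty(
    pairs: Sequence[PairedSensitivity],
    n_resample: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(ci_low, ci_high, p_value) for Pearson's r by bootstrap + permutation.

    The CI is the 2.5/97.5 percentile of r over ``n_resample`` bootstrap
    resamples of the pairs (with replacement; degenerate constant resamples
    are excluded from the percentile).  The p-value is the fraction of
    ``n_resample`` permutations of one side whose |r| is at least the
    observed |r|, floored at ``1/(n_resample + 1)``.
    """
    a, b = _arrays(pairs)
    n = a.size
    r_obs = float(stats.pearsonr(a, b).statistic)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_resample, n))
    r_boot = _rowwise_pearson(a[idx], b[idx])
    ci_low, ci_high = np.nanpercentile(r_boot, [2.5, 97.5])

    b_perm = rng.permuted(np.broadcast_to(b, (n_resample, n)).copy(), axis=1)
    r_perm = _rowwise_pearson(np.broadcast_to(a, (n_resample, n)), b_perm)
    p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    p = max(p, 1.0 / (n_resample + 1))
    return float(ci_low), float(ci_high), p


def _one_result(
    pairs: Sequence[PairedSensitivity],
    metric: str,
    scope: str,
    study_a: str,
    study_b: str,
    n_resample: int,
    seed: int,
    drug_class: str | None = None,
) -> ConcordanceResult:
    try:
        r = pearson_r(pairs)
        rho = spearman_rho(pairs)
        ci_low, ci_high, p = resample_uncertainty(pairs, n_resample, seed)
    except UndefinedCorrelationError as exc:
        return ConcordanceResult(
            metric, scope, study_a, study_b, n_pairs=len(pairs),
            drug_class=drug_class, reason=str(exc),
        )
    return ConcordanceResult(
        metric, scope, study_a, study_b, n_pairs=len(pairs),
        pearson_r=r, spearman_rho=rho, ci_low=ci_low, ci_high=ci_high,
        p_value=p, moderate=(r > MODERATE_R), drug_class=drug_class,
    )


def concordance_report(
    tables: Mapping[str, pd.DataFrame],
    metrics: Sequence[str] = METRICS,
    annotations: Mapping[str, str] | None = None,
    n_resample: int = 1000,
    seed: int = 0,
    per_drug: bool = True,
) -> list[ConcordanceResult]:
    """Pooled and per-drug agreement for every study pair and metric.

    ``tables`` maps study id -> sensitivity table (long format with a
    ``metric`` column).  For each unordered study pair one pooled result per
    metric is produced; with ``per_drug`` each drug also gets one result per
    metric, carrying its class from ``annotations`` (``"unclassified"`` when
    absent) and the strict ``moderate`` flag.  Within each (pair, drug) the
    metric achieving the highest Pearson r is flagged ``best_metric``.
    Resampling seeds are derived deterministically from ``seed``.
    """
    studies = sorted(tables)
    if len(studies) < 2:
        raise ValueError("concordance needs at least 2 studies")
    ss = np.random.SeedSequence(seed)
    results: list[ConcordanceResult] = []
    for study_a, study_b in combinations(studies, 2):
        per_drug_group: list[ConcordanceResult] = []
        for metric in metrics:
            pairs = paired_finite(tables[study_a], tables[study_b], metric)
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            results.append(
                _one_result(pairs, metric, "pooled", study_a, study_b,
                            n_resample, sub)
            )
            if not per_drug:
                continue
            by_drug: dict[str, list[PairedSensitivity]] = {}
            for p in pairs:
                by_drug.setdefault(p.drug_id, []).append(p)
            for drug in sorted(by_drug):
                cls = (annotations or {}).get(drug, "unclassified")
                sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                per_drug_group.append(
                    _one_result(by_drug[drug], metric, drug, study_a, study_b,
                                n_resample, sub, drug_class=cls)
                )
        # flag, per drug, the metric with the highest Pearson r
        best: dict[str, float] = {}
        for res in per_drug_group:
            if not math.isnan(res.pearson_r):
                best[res.scope] = max(best.get(res.scope, -2.0), res.pearson_r)
        for i, res in enumerate(per_drug_group):
            if not math.isnan(res.pearson_r) and res.pearson_r == best.get(res.scope):
                per_drug_group[i] = ConcordanceResult(
                    **{**res.__dict__, "best_metric": True}
                )
        results.extend(per_drug_group)
    return results
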