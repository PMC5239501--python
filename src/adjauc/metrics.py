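"""The six drug-sensitivity metrics.

For every curve two models are fitted (flexible-asymptote EC50 model and
fixed-asymptote IC50 model), and from each model a potency value and a
normalized area under the curve are derived:

* ``EC50`` / ``IC50`` — the fitted half-effect concentration, censored to
  +infinity when it exceeds the maximal tested concentration (an estimate
  beyond the tested range is not supported by the data);
* ``AUC_EC50`` / ``AUC_IC50`` — normalized area under the fitted curve over
  the curve's own tested concentration window, in [0, 1];
* ``ADJ_AUC_EC50`` / ``ADJ_AUC_IC50`` — the same area but evaluated only
  over the concentration window shared by the studies being compared, while
  the fit still uses every measured point (see :mod:`adjauc.harmonize`).

The AUC is a ratio of grid sums over a linear concentration grid
``x = x_min, x_min + step, ..., x_max`` (default step 1 nM, both endpoints
included)::

    AUC = sum(f(x) - A_min) / sum(max(A_max, 100) - A_min)

so an inactive curve scores 0 and a curve saturated at 100% inhibition over
the whole window scores 1.  The linear grid makes wide high-concentration
windows dominate the sum, which is exactly why the unadjusted AUC is not
comparable across studies with different dose ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .dose_response import (
    ConcentrationRange,
    DoseResponseCurve,
    FitResult,
    AMPLITUDE_THRESHOLD,
    fit_ec50_model,
    fit_ic50_model,
    predict_response,
)
from .errors import IncomparableRangesError, InsufficientDataError, NoValueError

__all__ = [
    "METRICS",
    "DEFAULT_GRID_STEP",
    "SensitivityRecord",
    "half_max_concentration",
    "compute_auc",
    "adjusted_auc",
    "intersect_ranges",
    "fit_both_models",
    "six_metric_table",
]

log = logging.getLogger(__name__)

#: Canonical metric names, in reporting order.
METRICS = ("EC50", "IC50", "AUC_EC50", "AUC_IC50", "ADJ_AUC_EC50", "ADJ_AUC_IC50")

DEFAULT_GRID_STEP = 1.0  # nM


@dataclass(frozen=True)
class SensitivityRecord:
    """One (study, drug, cell line, metric) sensitivity value.

    ``value`` may be ``+inf`` for censored EC50/IC50.  ``range_used`` is the
    concentration window the metric refers to (the curve's own tested range,
    or the cross-study shared range for adjusted AUC).  ``extrapolated``
    marks adjusted-AUC records whose shared window reaches beyond the curve's
    own tested range, i.e. the fitted model was evaluated where that curve
    was not measured.
    """

    study_id: str
    drug_id: str
    cell_line_id: str
    metric: str
    value: float
    range_used: ConcentrationRange
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


def half_max_concentration(
    fit: FitResult, tested_range: ConcentrationRange
) -> float:
    """Fitted EC50/IC50 with the out-of-range censoring rule applied.

    Returns the fitted half-effect concentration if it does not exceed the
    maximal tested concentration, else ``+inf``.  Values below the minimal
    tested concentration are kept finite (censoring is one-sided).
    """
    if not fit.converged:
        raise NoValueError("no half-max concentration from a failed fit")
    ec50 = fit.params.ec50
    return ec50 if ec50 <= tested_range.x_max else math.inf


@lru_cache(maxsize=512)
def _grid(x_min: float, x_max: float, step: float) -> np.ndarray:
    """Linear grid from x_min to x_max inclusive; last interval clamped."""
    n = int(math.floor((x_max - x_min) / step + 1e-12))
    xs = x_min + step * np.arange(n + 1)
    if xs[-1] < x_max - 1e-9 * max(1.0, x_max):
        xs = np.append(xs, x_max)
    else:
        xs[-1] = x_max
    return xs


def compute_auc(
    fit: FitResult,
    conc_range: ConcentrationRange,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Normalized area under the fitted curve over ``conc_range``, in [0, 1]."""
    if not fit.converged:
        raise NoValueError("no AUC from a failed fit")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    p = fit.params
    denom_level = max(p.a_max, 100.0) - p.a_min
    if denom_level <= 0:
        raise NoValueError("degenerate fit: non-positive normalization amplitude")
    xs = _grid(conc_range.x_min, conc_range.x_max, grid_step)
    num = float(np.sum(predict_response(p, xs) - p.a_min))
    den = xs.size * denom_level
    return num / den


def adjusted_auc(
    fit: FitResult,
    shared_range: ConcentrationRange,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """AUC over the cross-study shared concentration window.

    The computation is identical to :func:`compute_auc`; the distinction is
    the contract: ``fit`` must have been produced from *all* of the curve's
    measured points, including those outside ``shared_range`` — no data is
    discarded, only the integration window is restricted.
    """
    return compute_auc(fit, shared_range, grid_step)


def intersect_ranges(ranges: Sequence[ConcentrationRange]) -> ConcentrationRange:
    """Intersection of two or more concentration ranges.

    Raises :class:`IncomparableRangesError` if the intersection is empty."""
    if len(ranges) < 2:
        raise ValueError("need at least 2 ranges to intersect")
    lo = max(r.x_min for r in ranges)
    hi = min(r.x_max for r in ranges)
    if lo >= hi:
        raise IncomparableRangesError(
            f"ranges do not overlap: max(x_min)={lo} >= min(x_max)={hi}"
        )
    return ConcentrationRange(lo, hi)


def fit_both_models(
    curve: DoseResponseCurve,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> tuple[FitResult, FitResult]:
    """Convenience: (EC50-model fit, IC50-model fit) for one curve."""
    return (
        fit_ec50_model(curve, amplitude_threshold=amplitude_threshold),
        fit_ic50_model(curve),
    )


def six_metric_table(
    curves: Iterable[DoseResponseCurve],
    grid_step: float = DEFAULT_GRID_STEP,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    fits: dict[tuple[str, str, str], tuple[FitResult, FitResult]] | None = None,
) -> list[SensitivityRecord]:
    """Per-curve EC50, IC50 and both unadjusted AUCs.

    Adjusted AUCs require a cross-study shared range and are produced by
    :func:`adjauc.harmonize.harmonized_table` instead.  Curves for which
    either model fit fails to fit or converge are omitted, with a logged
    count.  Pre-computed fits may be passed via ``fits`` (keyed by
    ``curve.key``) to avoid refitting.
    """
    records: list[SensitivityRecord] = []
    n_skipped = 0
    for curve in curves:
        try:
            if fits is not None and curve.key in fits:
                ec50_fit, ic50_fit = fits[curve.key]
            else:
                ec50_fit, ic50_fit = fit_both_models(curve, amplitude_threshold)
        except InsufficientDataError:
            n_skipped += 1
            continue
        if not (ec50_fit.converged and ic50_fit.converged):
            n_skipped += 1
            continue
        tr = curve.tested_range
        sid, did, cid = curve.key
        records.append(
            SensitivityRecord(sid, did, cid, "EC50",
                              half_max_concentration(ec50_fit, tr), tr)
        )
        records.append(
            SensitivityRecord(sid, did, cid, "IC50",
                              half_max_concentration(ic50_fit, tr), tr)
        )
        records.append(
            SensitivityRecord(sid, did, cid, "AUC_EC50",
                              compute_auc(ec50_fit, tr, grid_step), tr)
        )
        records.append(
            SensitivityRecord(sid, did, cid, "AUC_IC50",
                              compute_auc(ic50_fit, tr, grid_step), tr)
        )
    if n_skipped:
        log.info("six_metric_table: omitted %d unusable curve(s)", n_skipped)
    return records
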