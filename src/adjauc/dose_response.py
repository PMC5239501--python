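"""Constrained log-logistic dose-response modelling.

The sigmoid model used throughout the package is the four-parameter
log-logistic (Hill) curve on percent-inhibition responses

    y(x) = A_max + (A_min - A_max) / (1 + (x / EC50)^Hill)

where ``A_min`` and ``A_max`` are the lower and upper asymptotes (no effect
and maximal effect, in percent inhibition), ``EC50`` is the concentration
producing half of the maximal effect, and ``Hill`` is the slope.  With
``Hill > 0`` the curve increases with concentration: the convention is that
responses are percent inhibition (0 = no effect, 100 = complete inhibition).

Two fit families are provided:

* the *EC50 model*: asymptotes are free within data-driven bounds
  (``R_min <= A_min <= 0`` and ``min(0, R_min) <= A_max <= max(100, R_max)``,
  with ``R_min``/``R_max`` the minimal/maximal measured responses), followed
  by a curve-completeness test and refit rules for incomplete or
  low-amplitude curves;
* the *IC50 model*: asymptotes fixed at 0 and 100, so the half-effect
  concentration is the absolute 50%-inhibition concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, NoValueError

__all__ = [
    "BEND_RATIO",
    "AMPLITUDE_THRESHOLD",
    "ConcentrationRange",
    "DoseResponseCurve",
    "LogisticParams",
    "FitResult",
    "predict_response",
    "concentration_at_response",
    "bend_level",
    "bend_concentration",
    "is_complete",
    "fit_logistic",
    "fit_ec50_model",
    "fit_ic50_model",
    "residual_standard_error",
]

log = logging.getLogger(__name__)

#: Constant defining the upper bend point of the sigmoid: the bend response
#: level is A_max - (A_max - A_min)/(1 + BEND_RATIO), attained at
#: concentration EC50 * BEND_RATIO**(1/Hill).
BEND_RATIO = 4.6805

#: Default amplitude (A_max - A_min, percent) below which a fitted response is
#: treated as noise and the curve refit with A_max pinned to 100.
AMPLITUDE_THRESHOLD = 30.0

_HILL_BOUNDS = (0.1, 10.0)
_LOG10_EC50_PAD = 3.0  # decades beyond the tested range allowed for EC50


@dataclass(frozen=True)
class ConcentrationRange:
    """Closed concentration interval [x_min, x_max] in nM."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.x_min < self.x_max):
            raise ValueError(
                f"invalid concentration range [{self.x_min}, {self.x_max}]: "
                "need 0 < x_min < x_max"
            )

    @property
    def span(self) -> float:
        return self.x_max - self.x_min

    def covers(self, other: "ConcentrationRange") -> bool:
        return self.x_min <= other.x_min and self.x_max >= other.x_max


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the four-parameter log-logistic curve.

    Attributes
    ----------
    a_min, a_max : float
        Lower and upper asymptotes, percent inhibition (``a_min <= a_max``).
    ec50 : float
        Half-maximal-effect concentration, nM (> 0).
    hill : float
        Hill slope (> 0, dimensionless).
    """

    a_min: float
    a_max: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.a_min <= self.a_max):
            raise ValueError(f"a_min={self.a_min} must not exceed a_max={self.a_max}")
        if not (self.ec50 > 0 and math.isfinite(self.ec50)):
            raise ValueError(f"ec50 must be positive and finite, got {self.ec50}")
        if not (self.hill > 0 and math.isfinite(self.hill)):
            raise ValueError(f"hill must be positive and finite, got {self.hill}")

    @property
    def amplitude(self) -> float:
        return self.a_max - self.a_min


@dataclass(frozen=True)
class DoseResponseCurve:
    """One drug/cell-line/study measurement series.

    ``concentrations`` are positive, finite, in nM; ``responses`` are percent
    inhibition.  Replicate measurements at the same concentration are kept as
    separate points.  At least two distinct concentrations are required.
    """

    study_id: str
    drug_id: str
    cell_line_id: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.responses, dtype=float)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if x.size < 2:
            raise ValueError("a dose-response curve needs at least 2 points")
        if not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("concentrations must be finite and > 0")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        order = np.argsort(x, kind="stable")
        object.__setattr__(self, "concentrations", x[order])
        object.__setattr__(self, "responses", y[order])
        if self.n_distinct < 2:
            raise ValueError("need at least 2 distinct concentrations")

    @property
    def n_points(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)

    @property
    def r_min(self) -> float:
        return float(np.min(self.responses))

    @property
    def r_max(self) -> float:
        return float(np.max(self.responses))

    @property
    def tested_range(self) -> ConcentrationRange:
        return ConcentrationRange(
            float(self.concentrations[0]), float(self.concentrations[-1])
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.study_id, self.drug_id, self.cell_line_id)


@dataclass(frozen=True)
class FitResult:
    """A fitted log-logistic model plus its provenance.

    ``model_kind`` is ``"EC50"`` (flexible asymptotes) or ``"IC50"``
    (asymptotes fixed at 0/100).  ``complete`` records the outcome of the
    curve-completeness test on the initial flexible fit; ``amplitude_refit``
    records whether the low-amplitude rule forced ``A_max = 100``.
    ``n_free`` is the number of free parameters of the final fit (4, 3 or 2),
    used for the residual standard error's degrees of freedom.
    """

    params: LogisticParams
    model_kind: str
    converged: bool
    n_points: int
    n_free: int
    residual_se: float = math.nan
    complete: bool = False
    amplitude_refit: bool = False

    def __post_init__(self) -> None:
        if self.model_kind not in ("EC50", "IC50"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "IC50" and not (
            self.params.a_min == 0.0 and self.params.a_max == 100.0
        ):
            raise ValueError("IC50 model requires asymptotes fixed at 0 and 100")


# ---------------------------------------------------------------------------
# Curve evaluation


def predict_response(params: LogisticParams, x):
    """Evaluate the log-logistic curve at concentration(s) ``x`` (nM, > 0).

    Returns percent inhibition; strictly increasing in ``x`` when
    ``a_min < a_max``.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs <= 0) or not np.all(np.isfinite(xs)):
        raise ValueError("concentrations must be finite and > 0")
    y = params.a_max + (params.a_min - params.a_max) / (
        1.0 + (xs / params.ec50) ** params.hill
    )
    return float(y) if np.isscalar(x) else y


def concentration_at_response(params: LogisticParams, y: float) -> float:
    """Invert the curve: concentration (nM) at which the fitted response is ``y``.

    Defined only on the open interval ``(a_min, a_max)``.
    """
    if not (params.a_min < y < params.a_max):
        raise ValueError(
            f"response {y} outside the open asymptote interval "
            f"({params.a_min}, {params.a_max})"
        )
    ratio = (y - params.a_min) / (params.a_max - y)
    return float(params.ec50 * ratio ** (1.0 / params.hill))


def bend_level(params: LogisticParams) -> float:
    """Response level (percent) of the upper bend point of the sigmoid."""
    return (params.a_min - params.a_max) / (1.0 + BEND_RATIO) + params.a_max


def bend_concentration(params: LogisticParams) -> float:
    """Concentration (nM) at which the curve attains its upper bend level.

    Closed form: ``ec50 * BEND_RATIO**(1/hill)``.  Identical (to rounding)
    to ``concentration_at_response(params, bend_level(params))``.
    """
    return float(params.ec50 * BEND_RATIO ** (1.0 / params.hill))


def is_complete(curve: DoseResponseCurve, params: LogisticParams) -> bool:
    """Completeness test: does the tested range resolve the upper plateau?

    True iff at least two measured concentrations lie strictly above the
    concentration at which the fitted curve reaches its upper bend level.
    Degenerate flat fits (``a_min == a_max``) are reported incomplete.
    """
    if params.amplitude <= 0:
        return False
    x_bend = concentration_at_response(params, bend_level(params))
    return int(np.sum(curve.concentrations > x_bend)) >= 2


# ---------------------------------------------------------------------------
# Fitting

_FIX_TOL = 1e-9  # a box narrower than this pins the parameter


def _setup_bounds(
    curve: DoseResponseCurve,
    fixed_a_min: float | None,
    fixed_a_max: float | None,
):
    """Build (names, x0, lb, ub, fixed) in the internal parameterization
    (a_min, a_max, log10 ec50, log hill)."""
    r_min, r_max = curve.r_min, curve.r_max
    tr = curve.tested_range

    # target response for the EC50 initial guess: nearest measured point to
    # the mid-response level
    mid = 0.5 * (r_min + r_max)
    i_mid = int(np.argmin(np.abs(curve.responses - mid)))
    ec50_0 = float(curve.concentrations[i_mid])

    boxes = {
        "a_min": (min(r_min, 0.0), 0.0, min(r_min, 0.0)),
        "a_max": (min(0.0, r_min), max(100.0, r_max), r_max),
        "log10_ec50": (
            math.log10(tr.x_min) - _LOG10_EC50_PAD,
            math.log10(tr.x_max) + _LOG10_EC50_PAD,
            math.log10(ec50_0),
        ),
        "log_hill": (math.log(_HILL_BOUNDS[0]), math.log(_HILL_BOUNDS[1]), 0.0),
    }
    fixed: dict[str, float] = {}
    if fixed_a_min is not None:
        fixed["a_min"] = float(fixed_a_min)
    if fixed_a_max is not None:
        fixed["a_max"] = float(fixed_a_max)
    for name, (lo, hi, _) in list(boxes.items()):
        if name not in fixed and hi - lo < _FIX_TOL:
            fixed[name] = 0.5 * (lo + hi)

    names = [n for n in boxes if n not in fixed]
    lb = np.array([boxes[n][0] for n in names])
    ub = np.array([boxes[n][1] for n in names])
    x0 = np.clip(
        np.array([boxes[n][2] for n in names]),
        lb + 1e-8 * np.maximum(ub - lb, 1.0),
        ub - 1e-8 * np.maximum(ub - lb, 1.0),
    )
    return names, x0, lb, ub, fixed


def _unpack(theta, names, fixed) -> LogisticParams:
    vals = dict(fixed)
    vals.update(zip(names, theta))
    a_min = vals.get("a_min", 0.0)
    a_max = vals.get("a_max", 0.0)
    if a_min > a_max:  # guard against pathological box corners
        a_min = a_max
    return LogisticParams(
        a_min=a_min,
        a_max=a_max,
        ec50=10.0 ** vals["log10_ec50"],
        hill=math.exp(vals["log_hill"]),
    )


def fit_logistic(
    curve: DoseResponseCurve,
    fixed_a_min: float | None = None,
    fixed_a_max: float | None = None,
) -> FitResult:
    """Bounded least-squares fit of the log-logistic model to one curve.

    Free asymptotes are constrained to ``R_min <= A_min <= 0`` and
    ``min(0, R_min) <= A_max <= max(100, R_max)``; fixed asymptotes are
    honored exactly.  The optimizer works on (a_min, a_max, log10 ec50,
    log hill) with the Hill slope confined to (0.1, 10].

    Raises
    ------
    InsufficientDataError
        If the number of distinct concentrations is below the number of free
        parameters.
    """
    names, x0, lb, ub, fixed = _setup_bounds(curve, fixed_a_min, fixed_a_max)
    n_free = len(names)
    if curve.n_distinct < n_free:
        raise InsufficientDataError(
            f"{curve.n_distinct} distinct concentrations < {n_free} free parameters"
        )

    x = curve.concentrations
    y = curve.responses

    def resid(theta):
        p = _unpack(theta, names, fixed)
        return predict_response(p, x) - y

    try:
        res = least_squares(
            resid, x0, bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        params = _unpack(res.x, names, fixed)
        converged = bool(res.success) and np.all(np.isfinite(res.x))
    except Exception:  # optimizer blow-up: report best-effort non-convergence
        params = _unpack(x0, names, fixed)
        converged = False

    model_kind = (
        "IC50" if fixed_a_min == 0.0 and fixed_a_max == 100.0 else "EC50"
    )
    fit = FitResult(
        params=params,
        model_kind=model_kind,
        converged=converged,
        n_points=curve.n_points,
        n_free=n_free,
    )
    if converged and curve.n_points > n_free:
        fit = replace(fit, residual_se=residual_standard_error(fit, curve))
    return fit


def fit_ec50_model(
    curve: DoseResponseCurve,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> FitResult:
    """Full EC50-model pipeline: flexible fit, completeness test, refits.

    1. With >= 5 distinct concentrations, fit all four parameters within the
       asymptote bounds; otherwise skip straight to step 2's constrained fit.
    2. If the completeness test fails (fewer than two points beyond the upper
       bend), refit with ``A_max`` fixed at 100 (the upper asymptote cannot
       be estimated from an incomplete curve).
    3. If the surviving fit's amplitude ``A_max - A_min`` is below
       ``amplitude_threshold`` (default 30), refit with ``A_max = 100`` so
       that assay noise is not mistaken for a genuine low-amplitude response;
       this sets ``amplitude_refit``.
    """
    complete = False
    if curve.n_distinct >= 5:
        fit = fit_logistic(curve)
        complete = fit.converged and is_complete(curve, fit.params)
        if not complete:
            fit = fit_logistic(curve, fixed_a_max=100.0)
    else:
        fit = fit_logistic(curve, fixed_a_max=100.0)

    amplitude_refit = False
    if fit.params.amplitude < amplitude_threshold:
        amplitude_refit = True
        if fit.params.a_max != 100.0:
            fit = fit_logistic(curve, fixed_a_max=100.0)

    return replace(
        fit, model_kind="EC50", complete=complete, amplitude_refit=amplitude_refit
    )


def fit_ic50_model(curve: DoseResponseCurve) -> FitResult:
    """IC50-model fit: asymptotes fixed at 0 and 100, two free parameters."""
    if curve.n_distinct < 3:
        raise InsufficientDataError(
            f"IC50 model needs >= 3 distinct concentrations, got {curve.n_distinct}"
        )
    return fit_logistic(curve, fixed_a_min=0.0, fixed_a_max=100.0)


def residual_standard_error(fit: FitResult, curve: DoseResponseCurve) -> float:
    """sqrt(SSR / (n - p)) of a converged fit on its own curve.

    ``p`` is the number of free parameters of the fit (4, 3 or 2 depending on
    which asymptotes were fixed).
    """
    if not fit.converged:
        raise NoValueError("residual standard error undefined for a failed fit")
    n, p = curve.n_points, fit.n_free
    if n <= p:
        raise NoValueError(f"residual SE undefined: n={n} <= p={p}")
    resid = predict_response(fit.params, curve.concentrations) - curve.responses
    return float(math.sqrt(float(np.sum(resid**2)) / (n - p)))
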