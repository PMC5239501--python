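"""Synthetic multi-study screen generator with known ground truth.

Emulates the situation the package exists for: several screening studies
measure the *same* drug/cell-line sensitivities, each under its own serial
dilution design (number of doses, top concentration, dilution factor) and
with independent assay noise.  Ground-truth sigmoid parameters are drawn per
(drug, cell line) from three activity classes:

* ``cytotoxic``  — full-amplitude response, A_max = 100;
* ``cytostatic`` — plateaued response, A_max uniform in [30, 90], so the
  absolute 50%-inhibition level may never be reached;
* ``inactive``   — A_max below 30, amplitude indistinguishable from noise.

The default designs mirror three common large-screen layouts: an 8-point
half-log series topping at 8 uM, a 9-point two-fold series topping at 2 uM
(bottom 7.8125 nM), and a 16-point two-fold series topping at 66 uM.
Because every study sees the same truths, recovery of the truth and
between-study concordance of every metric can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import LogisticParams, predict_response
from .tables_io import SCREEN_COLUMNS

__all__ = [
    "DoseDesign",
    "TruthRecord",
    "SimConfig",
    "DEFAULT_DESIGNS",
    "sample_truth",
    "simulate_curve",
    "simulate_multistudy",
    "truths_to_frame",
]

ACTIVITY_CLASSES = ("cytotoxic", "cytostatic", "inactive")


@dataclass(frozen=True)
class DoseDesign:
    """Serial dilution design: concentrations top / factor^k, k = 0..n-1."""

    study_id: str
    n_concentrations: int
    top: float  # nM
    dilution_factor: float
    bias: float = 0.0  # additive percent-inhibition offset of this study's assay

    def __post_init__(self) -> None:
        if self.n_concentrations < 2:
            raise ValueError("a design needs at least 2 concentrations")
        if self.top <= 0 or self.dilution_factor <= 1:
            raise ValueError("need top > 0 and dilution_factor > 1")

    @property
    def concentrations(self) -> np.ndarray:
        """Ascending concentrations in nM."""
        k = np.arange(self.n_concentrations)
        return np.sort(self.top / self.dilution_factor**k)


#: Three-study default: half-log 8-point to 8 uM, two-fold 9-point to 2 uM,
#: two-fold 16-point to 66 uM.
DEFAULT_DESIGNS = (
    DoseDesign("STUDY_A", 8, 8000.0, 3.1623),
    DoseDesign("STUDY_B", 9, 2000.0, 2.0),
    DoseDesign("STUDY_C", 16, 66000.0, 2.0),
)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth sigmoid for one (drug, cell line)."""

    drug_id: str
    cell_line_id: str
    params: LogisticParams
    activity_class: str

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.activity_class!r}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; every random draw is reproducible from ``seed``.

    ``class_proportions`` are the (cytotoxic, cytostatic, inactive) weights;
    ``log10_ec50_range`` is the uniform support of log10 EC50 in nM;
    ``hill_log_sd`` the standard deviation of log Hill around 1.
    """

    n_drugs: int = 17
    n_cell_lines: int = 300
    designs: Sequence[DoseDesign] = DEFAULT_DESIGNS
    noise_sd: float = 5.0
    class_proportions: tuple[float, float, float] = (0.30, 0.45, 0.25)
    log10_ec50_range: tuple[float, float] = (0.5, 4.5)
    hill_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.noise_sd < 0 or self.hill_log_sd < 0:
            raise ValueError("noise_sd and hill_log_sd must be >= 0")
        if not self.designs:
            raise ValueError("at least one dose design is required")


def sample_truth(config: SimConfig, rng: np.random.Generator) -> list[TruthRecord]:
    """Draw ground-truth parameters for every (drug, cell line) pair.

    Per pair: activity class from ``class_proportions``; log10 EC50 uniform
    on ``log10_ec50_range``; Hill = exp(Normal(0, hill_log_sd)) clipped to
    (0.1, 10]; A_min = 0; A_max by class (100 / U[30, 90) / U[0, 30)).
    """
    truths: list[TruthRecord] = []
    lo, hi = config.log10_ec50_range
    for d in range(config.n_drugs):
        for c in range(config.n_cell_lines):
            cls = ACTIVITY_CLASSES[
                rng.choice(len(ACTIVITY_CLASSES), p=config.class_proportions)
            ]
            if cls == "cytotoxic":
                a_max = 100.0
            elif cls == "cytostatic":
                a_max = float(rng.uniform(30.0, 90.0))
            else:
                a_max = float(rng.uniform(0.0, 30.0))
            ec50 = float(10.0 ** rng.uniform(lo, hi))
            hill = float(np.clip(np.exp(rng.normal(0.0, config.hill_log_sd)),
                                 0.1 + 1e-12, 10.0))
            truths.append(
                TruthRecord(
                    f"DRUG{d + 1:03d}", f"CL{c + 1:04d}",
                    LogisticParams(0.0, a_max, ec50, hill), cls,
                )
            )
    return truths


def simulate_curve(
    truth: TruthRecord,
    design: DoseDesign,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(concentrations, responses) for one truth under one design.

    Responses are the sigmoid evaluated at the design's concentrations plus
    homoscedastic Gaussian noise (and the design's additive bias); they are
    deliberately NOT clipped to [0, 100] — raw screens under- and overshoot.
    """
    x = design.concentrations
    y = predict_response(truth.params, x) + design.bias
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return x, np.asarray(y, dtype=float)


def truths_to_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Truth table for recovery tests (one row per drug/cell line)."""
    return pd.DataFrame(
        {
            "drug": [t.drug_id for t in truths],
            "cell_line": [t.cell_line_id for t in truths],
            "a_min": [t.params.a_min for t in truths],
            "a_max": [t.params.a_max for t in truths],
            "ec50_nM": [t.params.ec50 for t in truths],
            "hill": [t.params.hill for t in truths],
            "activity_class": [t.activity_class for t in truths],
        }
    )


def simulate_multistudy(
    config: SimConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate every study of ``config`` over one shared set of truths.

    Returns one screen table per design (long format, see
    :mod:`adjauc.tables_io`) plus the truth table.  Every study measures the
    same truths under its own design and independent noise.
    """
    rng = np.random.default_rng(config.seed)
    truths = sample_truth(config, rng)
    tables: list[pd.DataFrame] = []
    for design in config.designs:
        n_pts = design.n_concentrations
        rows = {col: [] for col in SCREEN_COLUMNS}
        for truth in truths:
            x, y = simulate_curve(truth, design, config.noise_sd, rng)
            rows["study"].extend([design.study_id] * n_pts)
            rows["drug"].extend([truth.drug_id] * n_pts)
            rows["cell_line"].extend([truth.cell_line_id] * n_pts)
            rows["concentration_nM"].extend(x.tolist())
            rows["response"].extend(y.tolist())
        tables.append(pd.DataFrame(rows))
    return tables, truths_to_frame(truths)
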