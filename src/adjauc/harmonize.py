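"""Cross-study harmonization: shared dose ranges and pooled adjusted AUC.

Different screening studies test the same drug over different concentration
windows (for example a drug titrated to a top concentration of 2 uM in one
study and 66 uM in another), which makes the plain AUC incomparable across
studies.  Harmonization proceeds per drug:

1. canonicalize drug and cell-line names so the studies' catalogs intersect;
2. determine each study's *modal* tested range for the drug (studies
   occasionally run a drug over more than one dilution series; the most
   frequent per-curve range represents the study);
3. intersect the modal ranges into the drug's shared range;
4. score every curve of that drug — including cell lines screened by only
   one study — with the adjusted AUC over the shared range, the fit still
   using all measured points;
5. average adjusted values per (drug, cell line) across studies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dose_response import ConcentrationRange, FitResult
from .errors import IncomparableRangesError, InsufficientDataError
from .metrics import (
    AMPLITUDE_THRESHOLD,
    DEFAULT_GRID_STEP,
    SensitivityRecord,
    adjusted_auc,
    fit_both_models,
    intersect_ranges,
)
from .tables_io import iter_curves, validate_screen_table

__all__ = [
    "StudyDrugRange",
    "PooledRecord",
    "HarmonizedResult",
    "canonicalize_name",
    "study_drug_ranges",
    "shared_drug_range",
    "harmonized_table",
]

log = logging.getLogger(__name__)

_NON_ALNUM = re.compile(r"[^A-Za-z0-9]+")


@dataclass(frozen=True)
class StudyDrugRange:
    """One distinct per-curve tested range of a drug within a study."""

    study_id: str
    drug_id: str
    range: ConcentrationRange
    n_curves: int
    modal: bool


@dataclass(frozen=True)
class PooledRecord:
    """Cross-study average of an adjusted AUC for one (drug, cell line)."""

    drug_id: str
    cell_line_id: str
    metric: str
    value: float
    n_studies: int
    contributing_studies: tuple[str, ...]


@dataclass(frozen=True)
class HarmonizedResult:
    records: list[SensitivityRecord]
    pooled: list[PooledRecord]
    shared_ranges: dict[str, ConcentrationRange]
    incomparable_drugs: list[str]


def canonicalize_name(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Deterministic identifier normalization: uppercase, strip everything
    non-alphanumeric, then apply an optional synonym table.

    ``"PLX-4720"`` and ``"plx 4720"`` collide to ``"PLX4720"`` by design.
    """
    name = _NON_ALNUM.sub("", str(raw)).upper()
    if not name:
        raise ValueError(f"name {raw!r} is empty after canonicalization")
    if synonyms:
        name = synonyms.get(name, name)
    return name


def study_drug_ranges(table: pd.DataFrame) -> list[StudyDrugRange]:
    """Enumerate distinct per-curve tested ranges per (study, drug).

    The most frequent range is flagged modal; ties break toward the larger
    maximal concentration, then the wider span.
    """
    if not len(table):
        raise ValueError("empty screen table")
    per_curve = (
        table.groupby(["study", "drug", "cell_line"])["concentration_nM"]
        .agg(["min", "max"])
        .reset_index()
    )
    out: list[StudyDrugRange] = []
    for (study, drug), grp in per_curve.groupby(["study", "drug"]):
        counts = grp.groupby(["min", "max"]).size()
        entries = sorted(
            counts.items(),
            key=lambda kv: (kv[1], kv[0][1], kv[0][1] - kv[0][0]),
            reverse=True,
        )
        for i, ((lo, hi), n) in enumerate(entries):
            out.append(
                StudyDrugRange(
                    str(study), str(drug),
                    ConcentrationRange(float(lo), float(hi)),
                    int(n), modal=(i == 0),
                )
            )
    return out


def shared_drug_range(
    ranges: Sequence[StudyDrugRange], drug: str
) -> ConcentrationRange:
    """Intersection of the studies' modal ranges for one drug.

    Raises :class:`IncomparableRangesError` if the drug appears in fewer
    than two studies or the modal ranges do not overlap.
    """
    modal = {r.study_id: r.range for r in ranges if r.drug_id == drug and r.modal}
    if len(modal) < 2:
        raise IncomparableRangesError(
            f"drug {drug!r} has a modal range in {len(modal)} study(ies); "
            "a shared range needs at least 2"
        )
    return intersect_ranges(list(modal.values()))


def harmonized_table(
    tables: Sequence[pd.DataFrame],
    grid_step: float = DEFAULT_GRID_STEP,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    fits: Mapping[tuple[str, str, str], tuple[FitResult, FitResult]] | None = None,
) -> HarmonizedResult:
    """Adjusted AUCs over per-drug shared ranges, plus cross-study pooling.

    ``tables`` are validated screen tables (normally one per study).  Every
    curve of every drug that has a shared range is scored — including cell
    lines unique to one study — and per-(drug, cell line) values are averaged
    across the studies that measured them.  Drugs without a shared range
    (single-study drugs, disjoint ranges) are reported in
    ``incomparable_drugs``, not fatal.  Pre-computed model fits may be passed
    via ``fits`` keyed by ``(study, drug, cell_line)``.
    """
    if len(tables) < 2:
        raise ValueError("harmonization needs at least 2 screen tables")
    combined = validate_screen_table(pd.concat(list(tables), ignore_index=True))
    ranges = study_drug_ranges(combined)

    shared: dict[str, ConcentrationRange] = {}
    incomparable: list[str] = []
    for drug in sorted({r.drug_id for r in ranges}):
        try:
            shared[drug] = shared_drug_range(ranges, drug)
        except IncomparableRangesError:
            incomparable.append(drug)
    if incomparable:
        log.info("harmonize: %d drug(s) without a shared range: %s",
                 len(incomparable), ", ".join(incomparable))

    records: list[SensitivityRecord] = []
    n_skipped = 0
    for curve in iter_curves(combined):
        rng = shared.get(curve.drug_id)
        if rng is None:
            continue
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
        extrap = not curve.tested_range.covers(rng)
        sid, did, cid = curve.key
        records.append(
            SensitivityRecord(
                sid, did, cid, "ADJ_AUC_EC50",
                adjusted_auc(ec50_fit, rng, grid_step), rng, extrapolated=extrap,
            )
        )
        records.append(
            SensitivityRecord(
                sid, did, cid, "ADJ_AUC_IC50",
                adjusted_auc(ic50_fit, rng, grid_step), rng, extrapolated=extrap,
            )
        )
    if n_skipped:
        log.info("harmonize: omitted %d unusable curve(s)", n_skipped)

    pooled: list[PooledRecord] = []
    by_key: dict[tuple[str, str, str], list[SensitivityRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.drug_id, rec.cell_line_id, rec.metric), []).append(rec)
    for (drug, cell, metric), recs in sorted(by_key.items()):
        studies = tuple(sorted({r.study_id for r in recs}))
        pooled.append(
            PooledRecord(
                drug, cell, metric,
                value=sum(r.value for r in recs) / len(recs),
                n_studies=len(studies),
                contributing_studies=studies,
            )
        )
    return HarmonizedResult(records, pooled, shared, incomparable)
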