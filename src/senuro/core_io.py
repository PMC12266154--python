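"""Shared data model, table I/O and clinical derived quantities.

The pipeline operates on four kinds of tabular inputs: per-cell biopsy
classification tables, urinary proteomics matrices, spatial point clouds and
longitudinal clinical cohort tables.  This module holds the record types the
other stages share, the CSV/TSV readers and writers for the cell tables, and
the small clinical calculators (CKD-EPI eGFR, analyte-to-creatinine ratios)
everything downstream depends on.

Units and conventions
---------------------
* serum creatinine: mg/dL internally (``umol_l_to_mg_dl`` converts from SI),
* times: days from recruitment, day 0 = baseline,
* eGFR: mL/min per 1.73 m^2,
* booleans in tables: 0/1; ``NA`` permitted only for the optional
  cytoplasmic-clusterin column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger("senuro")

UMOL_PER_MGDL = 88.42


class InputError(ValueError):
    """Invalid value passed to a clinical calculator."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


@dataclass
class EgfrCoefficients:
    """Constants of the 2009 CKD-EPI creatinine equation.

    ``race_factor`` defaults to 1.0 (coefficient disabled); set it to 1.159
    to reproduce the original equation's Black-race multiplier.
    """

    kappa_f: float = 0.7
    kappa_m: float = 0.9
    alpha_f: float = -0.329
    alpha_m: float = -0.411
    slope: float = -1.209
    age_factor: float = 0.993
    sex_factor_f: float = 1.018
    race_factor: float = 1.0
    scale: float = 141.0


#: module-wide default coefficient set
CKD_EPI_2009 = EgfrCoefficients()


@dataclass
class Participant:
    """One cohort participant with baseline data and follow-up events.

    ``serum_creatinine`` is a time-sorted list of ``(day, mg/dL)`` pairs with
    the day-0 entry giving the baseline.  ``rrt_start`` / ``death`` are days
    from recruitment, ``None`` if the event did not occur.
    """

    id: str
    age: float
    sex: str
    sbp: float
    dbp: float
    serum_creatinine: list = field(default_factory=list)
    uacr: float = 0.0
    uccr: float = 0.0
    rrt_start: Optional[float] = None
    death: Optional[float] = None
    last_followup: float = 0.0

    def __post_init__(self):
        if self.age <= 0:
            raise InputError(f"participant {self.id}: age must be positive")
        if self.sex not in ("F", "M"):
            raise InputError(f"participant {self.id}: sex must be 'F' or 'M'")
        if self.uacr < 0 or self.uccr < 0:
            raise InputError(f"participant {self.id}: ratios must be >= 0")
        days = [t for t, _ in self.serum_creatinine]
        if any(t < 0 for t in days) or any(
            b < a for a, b in zip(days, days[1:])
        ):
            raise InputError(
                f"participant {self.id}: creatinine series must be "
                "time-sorted with nonnegative days"
            )

    @property
    def baseline_creatinine(self) -> Optional[float]:
        return self.serum_creatinine[0][1] if self.serum_creatinine else None


@dataclass
class CellRecord:
    """One classified cell from a biopsy section.

    ``clusterin_cytoplasmic`` is only populated for the P21/clusterin panel;
    it stays ``None`` for P21/KI67 tables.  ``extra`` carries any columns the
    reader did not recognise so writes round-trip losslessly.
    """

    participant_id: str
    section_id: str
    cell_id: str
    epithelial: bool
    p21_nuclear: bool
    ki67_nuclear: bool
    clusterin_cytoplasmic: Optional[bool] = None
    extra: dict = field(default_factory=dict)


def ckd_epi_2009(
    creatinine: float,
    age: float,
    sex: str,
    coeffs: EgfrCoefficients = CKD_EPI_2009,
) -> float:
    """Estimated GFR (mL/min/1.73m^2) from serum creatinine (mg/dL).

    141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
        * 0.993^age * (1.018 if female) * race_factor
    """
    if creatinine <= 0:
        raise InputError("serum creatinine must be positive")
    if age <= 0:
        raise InputError("age must be positive")
    if sex == "F":
        kappa, alpha, sex_factor = coeffs.kappa_f, coeffs.alpha_f, coeffs.sex_factor_f
    elif sex == "M":
        kappa, alpha, sex_factor = coeffs.kappa_m, coeffs.alpha_m, 1.0
    else:
        raise InputError("sex must be 'F' or 'M'")
    ratio = creatinine / kappa
    return (
        coeffs.scale
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** coeffs.slope
        * coeffs.age_factor**age
        * sex_factor
        * coeffs.race_factor
    )


def egfr_to_creatinine(
    egfr: float,
    age: float,
    sex: str,
    coeffs: EgfrCoefficients = CKD_EPI_2009,
) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr``.

    Exact piecewise inversion of :func:`ckd_epi_2009`; used by the synthetic
    generators to emit creatinine series consistent with target trajectories.
    """
    if egfr <= 0:
        raise InputError("eGFR must be positive")
    if age <= 0:
        raise InputError("age must be positive")
    if sex == "F":
        kappa, alpha, sex_factor = coeffs.kappa_f, coeffs.alpha_f, coeffs.sex_factor_f
    else:
        kappa, alpha, sex_factor = coeffs.kappa_m, coeffs.alpha_m, 1.0
    g = egfr / (
        coeffs.scale * coeffs.age_factor**age * sex_factor * coeffs.race_factor
    )
    # g > 1 on the sub-kappa branch (alpha < 0), g <= 1 on the steep branch
    if g > 1.0:
        return kappa * g ** (1.0 / alpha)
    return kappa * g ** (1.0 / coeffs.slope)


def umol_l_to_mg_dl(creatinine_umol_l: float) -> float:
    """Convert serum creatinine from µmol/L to the internal mg/dL."""
    return creatinine_umol_l / UMOL_PER_MGDL


def ratio_to_creatinine(analyte: float, creatinine: float) -> float:
    """Analyte (µg/L) over urinary creatinine (mmol/L) -> µg/mmol."""
    if creatinine <= 0:
        raise InputError("urinary creatinine must be positive")
    return analyte / creatinine


def cohort_flow(total: int, exclusions: Sequence[int]) -> int:
    """Size of the analysis set after sequentially applying exclusion counts."""
    n = total - sum(exclusions)
    if n < 0:
        raise InputError("exclusions exceed the recruited total")
    return n


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Proportion as a percentage rounded to ``ndigits`` decimal places."""
    if denominator <= 0:
        raise InputError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


_CELL_COLUMNS = [
    "participant_id",
    "section_id",
    "cell_id",
    "epithelial",
    "p21_nuclear",
    "ki67_nuclear",
]
_OPTIONAL_CELL_COLUMNS = ["clusterin_cytoplasmic"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cell_table(path) -> list[CellRecord]:
    """Read a per-cell classification CSV/TSV into :class:`CellRecord` rows.

    Mandatory columns: participant_id, section_id, cell_id, epithelial,
    p21_nuclear, ki67_nuclear (booleans as 0/1).  The clusterin column is
    optional and may contain NA.  Unknown columns are preserved in ``extra``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"participant_id": str,
                                                      "section_id": str,
                                                      "cell_id": str})
    for col in _CELL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table {path} is missing column '{col}'")
    has_clu = "clusterin_cytoplasmic" in df.columns
    extra_cols = [
        c for c in df.columns if c not in _CELL_COLUMNS + _OPTIONAL_CELL_COLUMNS
    ]
    records = []
    for row in df.itertuples(index=False):
        clu = None
        if has_clu:
            v = getattr(row, "clusterin_cytoplasmic")
            clu = None if pd.isna(v) else bool(int(v))
        records.append(
            CellRecord(
                participant_id=str(row.participant_id),
                section_id=str(row.section_id),
                cell_id=str(row.cell_id),
                epithelial=bool(int(row.epithelial)),
                p21_nuclear=bool(int(row.p21_nuclear)),
                ki67_nuclear=bool(int(row.ki67_nuclear)),
                clusterin_cytoplasmic=clu,
                extra={c: getattr(row, c) for c in extra_cols},
            )
        )
    return records


def write_cell_table(records: Sequence[CellRecord], path) -> None:
    """Write cell records to CSV/TSV; inverse of :func:`read_cell_table`."""
    path = Path(path)
    rows = []
    any_clu = any(r.clusterin_cytoplasmic is not None for r in records)
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "section_id": r.section_id,
            "cell_id": r.cell_id,
            "epithelial": int(r.epithelial),
            "p21_nuclear": int(r.p21_nuclear),
            "ki67_nuclear": int(r.ki67_nuclear),
        }
        if any_clu:
            row["clusterin_cytoplasmic"] = (
                "" if r.clusterin_cytoplasmic is None
                else int(r.clusterin_cytoplasmic)
            )
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def configure_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
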