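"""Quantification of senescent epithelia from per-cell classification tables.

A cell is called senescent when its nucleus is P21+ and KI67- (cell-cycle
inhibitor present, proliferation marker absent).  The senescent fraction of a
biopsy is the number of such epithelial cells over all epithelial cells, with
counts pooled across sections before division — pooling by counts, not by
averaging per-section percentages, so large sections carry their weight.

The module also tests P21/clusterin co-expression on the second staining
panel: a 2x2 contingency table of nuclear P21 against cytoplasmic clusterin,
summarised by an odds ratio with a Woolf log-method confidence interval and a
two-sided Fisher exact p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellRecord, InputError, logger


class CellClass(Enum):
    SEN = "p21+ki67-"          # profile consistent with senescence
    PROLIF = "p21-ki67+"
    DOUBLE_POS = "p21+ki67+"
    DOUBLE_NEG = "p21-ki67-"


@dataclass
class SenescenceResult:
    participant_id: str
    n_epithelial: int
    n_p21pos_ki67neg: int

    @property
    def pct_senescent(self) -> float:
        return 100.0 * self.n_p21pos_ki67neg / self.n_epithelial


@dataclass
class ContingencyTable2x2:
    """Counts a..d = (P21+Clu+, P21+Clu-, P21-Clu+, P21-Clu-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be >= 0")


def classify_cell(p21: bool, ki67: bool) -> CellClass:
    """Four-way nuclear classification; SEN iff P21+ and KI67-."""
    if p21 and not ki67:
        return CellClass.SEN
    if p21 and ki67:
        return CellClass.DOUBLE_POS
    if ki67:
        return CellClass.PROLIF
    return CellClass.DOUBLE_NEG


def senescent_fraction(cells: Sequence[CellRecord]) -> list[SenescenceResult]:
    """Per-participant senescent-epithelium percentage, sections pooled.

    Only epithelial cells enter numerator and denominator.  Participants
    with zero epithelial cells are excluded with a warning.  Results are
    returned in sorted participant order (input row and section order are
    irrelevant).
    """
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    seen: set[str] = set()
    for cell in cells:
        seen.add(cell.participant_id)
        if not cell.epithelial:
            continue
        den[cell.participant_id] = den.get(cell.participant_id, 0) + 1
        if classify_cell(cell.p21_nuclear, cell.ki67_nuclear) is CellClass.SEN:
            num[cell.participant_id] = num.get(cell.participant_id, 0) + 1
    results = []
    for pid in sorted(seen):
        if den.get(pid, 0) == 0:
            logger.warning(
                "participant %s has no epithelial cells; excluded", pid
            )
            continue
        results.append(
            SenescenceResult(
                participant_id=pid,
                n_epithelial=den[pid],
                n_p21pos_ki67neg=num.get(pid, 0),
            )
        )
    return results


def contingency_from_cells(cells: Sequence[CellRecord]) -> ContingencyTable2x2:
    """2x2 P21 x clusterin table over epithelial cells.

    Cells missing a clusterin call are excluded (counted and logged).
    """
    a = b = c = d = 0
    n_missing = 0
    for cell in cells:
        if not cell.epithelial:
            continue
        if cell.clusterin_cytoplasmic is None:
            n_missing += 1
            continue
        if cell.p21_nuclear:
            if cell.clusterin_cytoplasmic:
                a += 1
            else:
                b += 1
        elif cell.clusterin_cytoplasmic:
            c += 1
        else:
            d += 1
    if n_missing:
        logger.info("%d epithelial cells lacked a clusterin call; excluded",
                    n_missing)
    return ContingencyTable2x2(a, b, c, d)


def coexpression_or(table: ContingencyTable2x2) -> dict:
    """Odds ratio ad/bc with Woolf 95% CI and two-sided Fisher exact p.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction for the OR
    and CI (flagged in the result); the Fisher p always uses the raw counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = a, b, c, d
    odds = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci_low = math.exp(math.log(odds) - 1.96 * se)
    ci_high = math.exp(math.log(odds) + 1.96 * se)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "or": odds,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "fisher_p": float(p),
        "haldane_corrected": corrected,
    }


def top_tertile_labels(values: Sequence[float]) -> np.ndarray:
    """Boolean labels for membership in the highest tertile.

    The cut point is the 2/3 quantile with linear interpolation; ties at the
    cut go to the upper tertile (inclusive >=).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("no values to split into tertiles")
    cut = np.quantile(v, 2.0 / 3.0, method="linear")
    return v >= cut
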