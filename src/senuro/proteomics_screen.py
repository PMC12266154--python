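"""Urinary proteomics normalisation and senescence-correlation screen.

Label-free urinary proteomics intensities are confounded by two nuisance
scales: the instrument response of each run and the concentration of the
urine itself.  The screen removes them in sequence — division by the alcohol
dehydrogenase (ADH) spike-in standard, then by urinary creatinine — before
correlating every retained protein against the histologic senescent-epithelium
percentage with Spearman's rank test and Benjamini-Hochberg FDR control.
Candidates are shortlisted by adjusted significance and a strict rho cut,
then flagged against a packaged SASP (senescence-associated secretory
phenotype) protein list.

The module also carries the 2^-ddCt relative-expression calculator used for
the in-vitro qPCR arm (dual reference genes, averaged).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import InputError, logger


class NormalizationError(ValueError):
    """A sample cannot be normalised (non-positive ADH or creatinine)."""


@dataclass
class ProteomicsSample:
    """Per-sample protein intensities with normalisation anchors.

    ``intensities`` maps protein -> arbitrary units; proteins missing from a
    sample are simply absent from the map.  ``adh_intensity`` is the measured
    spike-in signal and ``urinary_creatinine`` is in mmol/L.
    """

    sample_id: str
    intensities: dict
    adh_intensity: float
    urinary_creatinine: float
    unique_peptides: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.intensities.values()):
            raise InputError(f"sample {self.sample_id}: intensities must be >= 0")


def normalize(samples: Sequence[ProteomicsSample]) -> pd.DataFrame:
    """Spike-in then creatinine correction: value / ADH / creatinine.

    Returns a samples x proteins matrix (NaN where a protein was not
    detected in a sample).  Samples with non-positive ADH or creatinine are
    rejected outright — silently rescaling them would corrupt the screen.
    """
    for s in samples:
        if s.adh_intensity <= 0:
            raise NormalizationError(
                f"sample {s.sample_id}: non-positive ADH spike-in intensity"
            )
        if s.urinary_creatinine <= 0:
            raise NormalizationError(
                f"sample {s.sample_id}: non-positive urinary creatinine"
            )
    rows = [
        {
            p: v / s.adh_intensity / s.urinary_creatinine
            for p, v in s.intensities.items()
        }
        for s in samples
    ]
    # built row-wise so the sample order is preserved exactly
    return pd.DataFrame(rows, index=[s.sample_id for s in samples])


def peptide_filter(
    samples: Sequence[ProteomicsSample], min_unique: int = 2
) -> set:
    """Proteins whose unique-peptide count reaches ``min_unique`` (inclusive)
    in at least one sample."""
    best: dict = {}
    for s in samples:
        for p, k in s.unique_peptides.items():
            if k > best.get(p, -1):
                best[p] = k
    return {p for p, k in best.items() if k >= min_unique}


def _spearman_t_approx(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho (average ranks on ties) with two-sided t-approximation p."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return math.nan, math.nan, n
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan, math.nan, n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0, n
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho (small n only).

    Enumerates all n! rank assignments; intended for n <= 10.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > 10:
        raise InputError("exact permutation test limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += abs(r) >= abs(obs) - 1e-12
        total += 1
    return obs, count / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over one family."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def correlation_screen(
    matrix: pd.DataFrame,
    senescence_pct: pd.Series | Sequence[float],
    min_completeness: float = 0.8,
    sasp_list: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Spearman screen of every protein column against senescence.

    Proteins observed in fewer than ``min_completeness`` of samples, or with
    constant values (rho undefined), are emitted with NaN statistics and
    excluded from the BH family; adjusted p-values are computed across the
    remaining tested proteins only.
    """
    y = np.asarray(senescence_pct, dtype=float)
    if len(y) != len(matrix):
        raise InputError("senescence vector must match the matrix rows")
    sasp = set(sasp_list) if sasp_list is not None else set()
    rows = []
    for protein in matrix.columns:
        x = matrix[protein].to_numpy(dtype=float)
        n_obs = int(np.isfinite(x).sum())
        if n_obs < max(3, int(np.ceil(min_completeness * len(y)))):
            rho, p = math.nan, math.nan
            n_used = n_obs
        else:
            rho, p, n_used = _spearman_t_approx(x, y)
        rows.append(
            {"protein": protein, "rho": rho, "p": p, "n": n_used,
             "sasp_flag": protein in sasp}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"])
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.info("correlation screen: %d proteins untestable, excluded "
                    "from the BH family", n_dropped)
    return out.sort_values("rho", ascending=False).reset_index(drop=True)


def shortlist(
    candidates: pd.DataFrame,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    sasp_list: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Adjusted-significant candidates with rho strictly above ``rho_min``.

    A protein at rho == rho_min is excluded.  If a SASP list is given the
    ``sasp_flag`` column is (re)computed against it.
    """
    out = candidates[
        (candidates["p_adj"] < alpha) & (candidates["rho"] > rho_min)
    ].copy()
    if sasp_list is not None:
        sasp = set(sasp_list)
        out["sasp_flag"] = out["protein"].isin(sasp)
    return out.reset_index(drop=True)


def load_sasp_list() -> list[str]:
    """Packaged SASP protein list (synthetic stand-in, user-replaceable).

    One protein symbol per line; lines starting with '#' are comments.
    """
    text = (
        resources.files("senuro.data")
        .joinpath("sasp_list_synthetic.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def delta_ct(target_ct: float, ref_cts: Sequence[float]) -> float:
    """dCt = target Ct minus the mean of the reference-gene Cts."""
    ref = np.asarray(ref_cts, float)
    if ref.size == 0 or not np.all(np.isfinite(ref)) or not math.isfinite(target_ct):
        raise InputError("Ct values must be finite and references nonempty")
    return float(target_ct - ref.mean())


def ddct(
    target_ct: float,
    ref_cts: Sequence[float],
    control_delta_cts: Sequence[float],
) -> float:
    """Relative expression 2^-(ddCt) against a control group.

    ddCt = dCt(sample) - mean dCt(controls); the sign convention makes the
    control-group mean map to 1.0 and upregulation to values above 1.
    """
    controls = np.asarray(control_delta_cts, float)
    if controls.size == 0:
        raise InputError("control group must be nonempty")
    dd = delta_ct(target_ct, ref_cts) - controls.mean()
    return float(2.0 ** (-dd))
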