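"""Synthetic matched biopsy / urine-proteome / spatial / outcome datasets.

Real studies of renal epithelial senescence pair four data streams per
participant: a biopsy cell-classification table, a urinary proteome, a
spatial-transcriptomics section and longitudinal renal function.  None of
those clinical data are shareable, so this module generates datasets with the
same statistical structure the analysis assumes, at tunable effect sizes:

* a cohort whose latent senescent-epithelium fraction rises with age and
  falls with eGFR, coupled to a urinary clusterin-to-creatinine ratio (uCCR)
  through a Gaussian copula with a targetable Spearman correlation;
* per-cell biopsy tables whose expected P21+KI67- epithelial fraction equals
  the latent senescence;
* a urine proteome in which a small set of marker proteins (one designated
  clusterin analogue flagged in the packaged SASP list) depend monotonically
  on senescence, wrapped in multiplicative urine-concentration and
  instrument-response effects that spike-in/creatinine normalisation must
  remove;
* 2-D fields of typed cells with per-cell CDKN1A counts and a CLU transcript
  point cloud whose intensity is elevated within a disc around CDKN1A+
  proximal-tubule centroids;
* proportional-hazards progression outcomes with declining eGFR trajectories
  and independent censoring.

Every generator is a pure function of (config, seed); a single global seed is
split into fixed per-generator substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import Participant, egfr_to_creatinine
from .spatial_enrichment import SpatialField
from .proteomics_screen import ProteomicsSample

# fixed substream offsets so generators are independently reproducible
_STREAM = {"cohort": 11, "biopsy": 23, "proteome": 37, "spatial": 53, "outcome": 71}

#: reference measurement-noise SD (log scale) at which marker_rhos are attained
_REF_NOISE_SD = 1.0

#: uCCR threshold (µg/mmol) used for the binary high/low outcome covariate
DEFAULT_UCCR_THRESHOLD = 124.5


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], int(seed)])


def _copula_r(rho_spearman: float) -> float:
    """Pearson correlation of a bivariate normal with given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based normal scores: exactly Gaussian margins for copulas."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


@dataclass
class SpatialConfig:
    """Geometry and intensities for one synthetic tissue field.

    Units: µm and transcripts/µm².  Cell density (n_cells / field_size^2) and
    the CLU background rate are set to plausible subcellular-resolution
    spatial-transcriptomics values (~0.012 cells/µm², ~0.02 transcripts/µm²).
    """

    field_size: float = 500.0
    n_cells: int = 3000
    celltype_props: dict = dc_field(
        default_factory=lambda: {"PT": 0.5, "LOH_DCT": 0.3, "other": 0.2}
    )
    cdkn1a_pos_frac: float = 0.15
    clu_rate_background: float = 0.02
    clu_rate_near_pos: float = 0.1
    enrichment_radius: float = 20.0
    cell_radius: float = 7.0

    def validate(self) -> None:
        total = sum(self.celltype_props.values())
        if any(p < 0 or p > 1 for p in self.celltype_props.values()) or not math.isclose(
            total, 1.0, abs_tol=1e-9
        ):
            raise ValueError("celltype_props must lie in [0,1] and sum to 1")
        if not 0 <= self.cdkn1a_pos_frac <= 1:
            raise ValueError("cdkn1a_pos_frac must lie in [0,1]")
        if min(self.clu_rate_background, self.clu_rate_near_pos) < 0:
            raise ValueError("transcript rates must be >= 0")
        if self.field_size <= 0 or self.n_cells <= 0 or self.enrichment_radius <= 0:
            raise ValueError("field geometry must be positive")


@dataclass
class OutcomeConfig:
    """Progression-hazard model for the outcome cohort.

    ``baseline_hazard`` is the daily hazard at the covariate reference point;
    1e-4/day gives a ~10% three-year progression risk in the low-uCCR group.
    ``log_hr_uccr_high`` defaults to ln(2.2).  Adjustment covariates carry
    small fixed log-hazard slopes so that multivariable models are exercised.
    """

    baseline_hazard: float = 1.0e-4
    log_hr_uccr_high: float = math.log(2.2)
    censor_rate: float = 1.0e-4
    death_rate: float = 4.0e-5
    log_hr_egfr: float = math.log(0.979)      # per mL/min
    log_hr_lnacr: float = math.log(1.254)     # per ln(mg/mmol)
    log_hr_age: float = math.log(0.976)       # per year
    log_hr_sbp: float = math.log(1.018)       # per mm Hg
    followup_days: float = 1095.0
    visit_interval: float = 120.0
    uccr_threshold: float = DEFAULT_UCCR_THRESHOLD

    def validate(self) -> None:
        if min(self.baseline_hazard, self.censor_rate, self.death_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.followup_days <= 0 or self.visit_interval <= 0:
            raise ValueError("follow-up schedule must be positive")


@dataclass
class SimConfig:
    """Study-level parameters for all four synthetic data streams.

    The defaults target the observed study conditions: a biopsy cohort of 51,
    a median senescent-epithelium fraction near 5%, a ~0.6 rank correlation
    between uCCR and senescence, 331 detected urinary proteins of which 8 are
    true senescence markers.
    """

    n_participants: int = 51
    senescence_beta_age: float = 0.02      # per year, logit scale
    senescence_beta_egfr: float = -0.012   # per mL/min, logit scale (negative)
    senescence_sd: float = 0.45            # residual logit SD
    clusterin_rho_target: float = 0.6      # Spearman(uCCR, senescence)
    n_proteins: int = 331
    n_true_markers: int = 8
    proteome_noise_sd: float = 1.0         # log-scale measurement noise
    # generated Spearman targets of the markers at the reference noise level;
    # the first entry is the clusterin analogue
    marker_rhos: tuple = (0.65, 0.50, 0.55, 0.55, 0.60, 0.60, 0.70, 0.75)
    spatial: SpatialConfig = dc_field(default_factory=SpatialConfig)
    outcome: OutcomeConfig = dc_field(default_factory=OutcomeConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.n_true_markers <= self.n_proteins:
            raise ValueError("need 0 <= n_true_markers <= n_proteins")
        if self.proteome_noise_sd < 0:
            raise ValueError("proteome_noise_sd must be >= 0")
        if self.n_true_markers and len(self.marker_rhos) < self.n_true_markers:
            raise ValueError("marker_rhos must cover n_true_markers entries")
        if not -1 < self.clusterin_rho_target < 1:
            raise ValueError("clusterin_rho_target must lie in (-1, 1)")
        self.spatial.validate()
        self.outcome.validate()


def gen_cohort(
    cfg: SimConfig, n: Optional[int] = None
) -> tuple[list[Participant], pd.DataFrame]:
    """Generate participants with latent senescence and urinary biomarkers.

    Latent senescence is modelled on the logit scale (keeping the percentage
    in [0, 100]) as an additive function of age and baseline eGFR plus
    residual noise; uCCR and uACR are coupled to it through Gaussian copulas,
    with the uCCR rank correlation targeting ``clusterin_rho_target``.

    Returns the participant list and a truth table with one row per
    participant (age, sex, baseline eGFR, senescence %, uCCR, uACR).
    """
    cfg.validate()
    n = int(n if n is not None else cfg.n_participants)
    rng = _rng(cfg.seed, "cohort")

    age = np.clip(rng.normal(56.0, 14.0, n), 19.0, 81.0)
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    sbp = rng.normal(137.0, 21.0, n)
    dbp = rng.normal(80.0, 13.0, n)
    egfr = np.clip(np.exp(rng.normal(math.log(45.0), 0.79, n)), 8.0, 133.0)

    logit_s = (
        special.logit(0.052)
        + cfg.senescence_beta_age * (age - 56.0)
        + cfg.senescence_beta_egfr * (egfr - 45.0)
        + cfg.senescence_sd * rng.standard_normal(n)
    )
    senescence_pct = 100.0 * special.expit(logit_s)

    z_sen = _normal_scores(senescence_pct)
    r = _copula_r(cfg.clusterin_rho_target)
    z_uccr = r * z_sen + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    uccr = np.exp(3.98 + 1.2 * z_uccr)

    r_acr = _copula_r(0.35)
    z_acr = r_acr * z_sen + math.sqrt(1.0 - r_acr**2) * rng.standard_normal(n)
    uacr = np.exp(4.45 + 2.0 * z_acr)

    participants = []
    for i in range(n):
        scr = egfr_to_creatinine(float(egfr[i]), float(age[i]), str(sex[i]))
        participants.append(
            Participant(
                id=f"P{i:04d}",
                age=float(age[i]),
                sex=str(sex[i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                serum_creatinine=[(0.0, scr)],
                uacr=float(uacr[i]),
                uccr=float(uccr[i]),
                last_followup=cfg.outcome.followup_days,
            )
        )
    truth = pd.DataFrame(
        {
            "participant_id": [p.id for p in participants],
            "age": age,
            "sex": sex,
            "sbp": sbp,
            "dbp": dbp,
            "baseline_egfr": egfr,
            "senescence_pct": senescence_pct,
            "uccr": uccr,
            "uacr": uacr,
        }
    )
    return participants, truth


def gen_biopsy_cells(
    senescence_pct: float,
    n_cells: int,
    n_sections: int = 2,
    seed: int = 0,
    participant_id: str = "P0000",
    epithelial_frac: float = 0.75,
) -> list:
    """Per-cell classification table for one biopsy.

    Epithelial cells are P21+KI67- with probability ``senescence_pct``/100;
    the remaining epithelia split between proliferating (KI67+), rare double
    positives and double negatives.  Cells are spread uniformly across
    ``n_sections`` sections.
    """
    from .core_io import CellRecord  # local to avoid import-order noise

    if not 0.0 <= senescence_pct <= 100.0:
        raise ValueError("senescence_pct must lie in [0, 100]")
    rng = _rng(seed, "biopsy")
    p_sen = senescence_pct / 100.0
    records = []
    for i in range(n_cells):
        section = f"S{rng.integers(n_sections)}"
        epithelial = rng.random() < epithelial_frac
        if epithelial:
            if rng.random() < p_sen:
                p21, ki67 = True, False
            else:
                u = rng.random()
                if u < 0.01:
                    p21, ki67 = True, True
                elif u < 0.06:
                    p21, ki67 = False, True
                else:
                    p21, ki67 = False, False
        else:
            p21 = rng.random() < 0.02
            ki67 = rng.random() < 0.03
        records.append(
            CellRecord(
                participant_id=participant_id,
                section_id=section,
                cell_id=f"{participant_id}_C{i:06d}",
                epithelial=epithelial,
                p21_nuclear=p21,
                ki67_nuclear=ki67,
            )
        )
    return records


# non-marker proteins that nevertheless appear in the packaged SASP list,
# so that SASP membership is informative rather than a marker synonym
_SASP_DECOYS = ("GDF15", "TIMP1", "IGFBP7", "SERPINE1", "MMP7")


def gen_proteome(
    senescence_pct: Sequence[float], cfg: SimConfig
) -> tuple[list[ProteomicsSample], pd.DataFrame]:
    """Urinary proteomics panel coupled to per-participant senescence.

    Exactly ``cfg.n_true_markers`` proteins carry a monotone (log-linear)
    dependence on the senescence normal score, scaled so each attains its
    ``marker_rhos`` Spearman target at the reference noise level; the first
    marker is the clusterin analogue "CLU".  All observed intensities are
    multiplied by a per-sample urine-concentration factor (shared with the
    creatinine column) and an instrument-response factor (shared with the
    alcohol-dehydrogenase spike-in), so spike-in + creatinine normalisation
    recovers the biological signal.  ~2% of intensities are missing at
    random; ~5% of noise proteins carry only one unique peptide and must be
    removed by the peptide filter.
    """
    cfg.validate()
    s = np.asarray(senescence_pct, dtype=float)
    n = len(s)
    rng = _rng(cfg.seed, "proteome")
    z_sen = _normal_scores(s)

    n_markers = cfg.n_true_markers
    names = []
    for k in range(n_markers):
        names.append("CLU" if k == 0 else f"SEN_MARKER_{k + 1:02d}")
    n_noise = cfg.n_proteins - n_markers
    noise_names = list(_SASP_DECOYS[: min(len(_SASP_DECOYS), n_noise)])
    noise_names += [f"PROT_{j:04d}" for j in range(n_noise - len(noise_names))]
    names += noise_names

    mu = rng.normal(12.0, 2.0, cfg.n_proteins)
    log_signal = np.empty((n, cfg.n_proteins))
    target_rho = np.full(cfg.n_proteins, np.nan)
    for j in range(cfg.n_proteins):
        if j < n_markers:
            rho_j = cfg.marker_rhos[j]
            r = _copula_r(rho_j)
            beta = _REF_NOISE_SD * r / math.sqrt(1.0 - r * r)
            log_signal[:, j] = (
                mu[j]
                + beta * z_sen
                + cfg.proteome_noise_sd * rng.standard_normal(n)
            )
            target_rho[j] = rho_j
        else:
            log_signal[:, j] = mu[j] + 1.0 * rng.standard_normal(n)

    urine_factor = np.exp(rng.normal(0.0, 0.6, n))
    instrument_factor = np.exp(rng.normal(0.0, 0.3, n))
    observed = np.exp(log_signal) * (urine_factor * instrument_factor)[:, None]
    missing = rng.random((n, cfg.n_proteins)) < 0.02

    base_peptides = 2 + rng.poisson(3.0, cfg.n_proteins)
    n_low = max(1, int(0.05 * n_noise)) if n_noise else 0
    low_idx = (
        n_markers + rng.choice(n_noise, size=n_low, replace=False)
        if n_low
        else np.array([], dtype=int)
    )
    base_peptides[low_idx] = 1

    samples = []
    for i in range(n):
        intens = {
            names[j]: float(observed[i, j])
            for j in range(cfg.n_proteins)
            if not missing[i, j]
        }
        peptides = {names[j]: int(base_peptides[j]) for j in range(cfg.n_proteins)}
        samples.append(
            ProteomicsSample(
                sample_id=f"P{i:04d}",
                intensities=intens,
                adh_intensity=float(5.0e5 * instrument_factor[i]),
                urinary_creatinine=float(10.0 * urine_factor[i]),
                unique_peptides=peptides,
            )
        )
    truth = pd.DataFrame(
        {
            "protein": names,
            "is_marker": [j < n_markers for j in range(cfg.n_proteins)],
            "target_rho": target_rho,
            "low_evidence": [j in set(low_idx.tolist()) for j in range(cfg.n_proteins)],
        }
    )
    return samples, truth


def gen_spatial(cfg: SimConfig) -> SpatialField:
    """One synthetic tissue field with typed cells and a CLU point cloud.

    Cell centroids are uniform on the square field.  ``cdkn1a_pos_frac`` of
    proximal-tubule (PT) cells carry >= 2 CDKN1A transcripts (half that rate
    in other types).  CLU transcripts form a homogeneous Poisson background
    of rate ``clu_rate_background`` plus, around every CDKN1A+ PT centroid,
    an additional uniform-in-disc Poisson component of rate
    ``clu_rate_near_pos`` within ``enrichment_radius``.  Per-cell CLU counts
    are the transcripts within ``cell_radius`` of each centroid.
    """
    cfg.validate()
    sp = cfg.spatial
    rng = _rng(cfg.seed, "spatial")
    L = sp.field_size
    n = sp.n_cells

    xy = rng.uniform(0.0, L, size=(n, 2))
    types = rng.choice(
        list(sp.celltype_props), size=n, p=list(sp.celltype_props.values())
    )
    pos_prob = np.where(types == "PT", sp.cdkn1a_pos_frac, sp.cdkn1a_pos_frac / 2.0)
    is_pos = rng.random(n) < pos_prob
    cdkn1a = np.where(
        is_pos, 2 + rng.poisson(1.0, n), (rng.random(n) < 0.3).astype(int)
    )

    n_bg = rng.poisson(sp.clu_rate_background * L * L)
    pts = [rng.uniform(0.0, L, size=(n_bg, 2))]
    hot = xy[is_pos & (types == "PT")]
    disc_mean = sp.clu_rate_near_pos * math.pi * sp.enrichment_radius**2
    for cx, cy in hot:
        k = rng.poisson(disc_mean)
        if k:
            radii = sp.enrichment_radius * np.sqrt(rng.random(k))
            theta = rng.uniform(0.0, 2.0 * math.pi, k)
            pts.append(
                np.column_stack([cx + radii * np.cos(theta), cy + radii * np.sin(theta)])
            )
    clu_xy = np.vstack(pts) if pts else np.empty((0, 2))

    from scipy.spatial import cKDTree

    clu_counts = np.zeros(n, dtype=int)
    if len(clu_xy):
        tree = cKDTree(clu_xy)
        clu_counts = np.array(
            [len(ix) for ix in tree.query_ball_point(xy, sp.cell_radius)]
        )

    cell_ids = [f"c{i:05d}" for i in range(n)]
    cells = pd.DataFrame(
        {"cell_id": cell_ids, "x": xy[:, 0], "y": xy[:, 1], "cell_type": types}
    )
    counts = pd.DataFrame(
        {"CDKN1A": cdkn1a, "CLU": clu_counts}, index=pd.Index(cell_ids, name="cell_id")
    )
    transcripts = pd.DataFrame(
        {"gene": "CLU", "x": clu_xy[:, 0], "y": clu_xy[:, 1]}
        if len(clu_xy)
        else {"gene": [], "x": [], "y": []}
    )
    return SpatialField(cells=cells, counts=counts, transcripts=transcripts)


def gen_outcomes(
    participants: list[Participant], truth: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, dict]:
    """Progression events, censoring and longitudinal eGFR series.

    Event times are exponential under a proportional-hazards model whose
    linear predictor combines the high-uCCR indicator with baseline eGFR,
    ln(uACR), age and systolic blood pressure at the configured log hazard
    ratios.  Censoring is independent (administrative at ``followup_days``,
    a random-loss process, and death, which the analysis treats as
    censoring).  eGFR trajectories decline linearly toward ~50% of baseline
    at the event time; the serum-creatinine series of each participant is
    updated to be consistent with the trajectory.

    Returns a survival-record table (id, time, event, covariates) and a dict
    of per-participant eGFR visit series.
    """
    cfg.validate()
    oc = cfg.outcome
    rng = _rng(cfg.seed, "outcome")
    t = truth.set_index("participant_id")

    records = []
    series: dict[str, list] = {}
    for p in participants:
        row = t.loc[p.id]
        egfr0 = float(row["baseline_egfr"])
        ln_acr = math.log(max(p.uacr, 0.1))
        high = p.uccr > oc.uccr_threshold
        lp = (
            oc.log_hr_uccr_high * high
            + oc.log_hr_egfr * (egfr0 - 45.0)
            + oc.log_hr_lnacr * (ln_acr - math.log(80.0))
            + oc.log_hr_age * (p.age - 60.0)
            + oc.log_hr_sbp * (p.sbp - 135.0)
        )
        hazard = oc.baseline_hazard * math.exp(lp)
        t_event = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
        t_loss = (
            rng.exponential(1.0 / oc.censor_rate) if oc.censor_rate > 0 else math.inf
        )
        t_death = (
            rng.exponential(1.0 / oc.death_rate) if oc.death_rate > 0 else math.inf
        )
        t_obs = min(t_event, t_loss, t_death, oc.followup_days)
        event = t_event <= min(t_loss, t_death, oc.followup_days)
        # guard against zero-duration records from very early events
        t_obs = max(t_obs, 1.0)

        if event and rng.random() < 0.3:
            p.rrt_start = t_obs
        if (not event) and t_obs == t_death:
            p.death = t_death
        p.last_followup = t_obs

        # visit series: confirmatory visits continue past the event time
        last_visit = t_obs + 2 * oc.visit_interval if event else t_obs
        days = np.arange(0.0, last_visit + 1e-9, oc.visit_interval)
        visits = []
        for d in days:
            if event:
                frac = min(d, t_event) / t_event
                e = egfr0 * (1.0 - 0.5 * frac)
                if d > t_event:
                    e *= math.exp(-0.001 * (d - t_event))
            else:
                e = egfr0 - 1.5 * d / 365.0
            e = max(e, 5.0) * math.exp(rng.normal(0.0, 0.03))
            visits.append((float(d), float(e)))
        series[p.id] = visits
        p.serum_creatinine = [
            (d, egfr_to_creatinine(e, p.age, p.sex)) for d, e in visits
        ]

        records.append(
            {
                "id": p.id,
                "time": float(t_obs),
                "event": int(event),
                "uccr_high": int(high),
                "baseline_egfr": egfr0,
                "ln_acr": ln_acr,
                "age": p.age,
                "sbp": p.sbp,
                "sex_f": int(p.sex == "F"),
            }
        )
    return pd.DataFrame(records), series
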