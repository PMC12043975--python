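"""Synthetic longitudinal myeloma cohort generator.

Emulates the statistical structure of real follow-up panels so that the
forecasting and annotation models can be exercised end-to-end without access
to registration-gated trial data: cross-correlated patient baseline levels,
mean-reverting per-analyte momentum, an induction-response phase in which the
disease markers (M-protein and the involved free light chain) fall toward a
residual-disease floor, stochastic relapse onset with multiplicative marker
regrowth and downstream coupling (creatinine and beta-2-microglobulin rise,
albumin and hemoglobin fall), a deterministic progression-labeling rule of
the 25%-from-nadir-plus-absolute-minimum form, and per-cell missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    FEATURE_INDEX,
    LABEL_NON_PD,
    LABEL_PD,
    LABEL_UNKNOWN,
    MONTHS_PER_VISIT,
    N_FEATURES,
    CohortDataset,
    PatientTrajectory,
)
from .seeding import component_rng

IDX_HB = FEATURE_INDEX["hb"]
IDX_CA = FEATURE_INDEX["ca"]
IDX_CR = FEATURE_INDEX["cr"]
IDX_ALB = FEATURE_INDEX["alb"]
IDX_B2M = FEATURE_INDEX["b2m"]
IDX_MPR = FEATURE_INDEX["m_protein"]
IDX_SFL_L = FEATURE_INDEX["sfl_lambda"]
IDX_SFL_K = FEATURE_INDEX["sfl_kappa"]

#: Analytes whose first visit always stays observed so labels remain computable.
LABEL_CRITICAL = (IDX_MPR, IDX_SFL_L, IDX_SFL_K)


def _default_baseline_mean() -> np.ndarray:
    # Raw physiologic units at diagnosis; see FEATURE_LABELS for units.
    return np.array([11.0, 9.5, 1.1, 180.0, 3.8, 3.5, 3.0, 50.0, 50.0, 6.0])


def _default_baseline_sd() -> np.ndarray:
    return np.array([1.5, 0.6, 0.35, 45.0, 0.45, 1.5, 1.2, 22.0, 22.0, 1.8])


def _default_baseline_corr() -> np.ndarray:
    corr = np.eye(N_FEATURES)

    def put(i: int, j: int, rho: float) -> None:
        corr[i, j] = corr[j, i] = rho

    put(IDX_CR, IDX_B2M, 0.60)     # renal clearance drives both
    put(IDX_SFL_L, IDX_ALB, -0.30)  # light-chain burden vs albumin
    put(IDX_SFL_K, IDX_ALB, -0.30)
    put(IDX_SFL_L, IDX_CR, 0.25)    # light chains and renal function
    put(IDX_SFL_K, IDX_CR, 0.25)
    put(IDX_SFL_L, IDX_B2M, 0.20)
    put(IDX_SFL_K, IDX_B2M, 0.20)
    put(IDX_SFL_L, IDX_SFL_K, -0.20)  # clonal excess of one chain
    put(IDX_HB, IDX_ALB, 0.30)
    put(IDX_HB, IDX_B2M, -0.25)
    put(IDX_HB, IDX_MPR, -0.20)     # marrow infiltration causes anemia
    put(IDX_MPR, IDX_B2M, 0.20)
    put(IDX_CA, IDX_CR, 0.15)
    return corr


def default_baseline_cov() -> np.ndarray:
    sd = _default_baseline_sd()
    return _default_baseline_corr() * np.outer(sd, sd)


@dataclass
class ProgressionRule:
    """Relapse-from-nadir rule used to define synthetic ground-truth labels.

    A visit is progressive disease (PD) when either the M-protein or the
    involved-minus-uninvolved free-light-chain difference has risen at least
    25% above its running nadir with the corresponding absolute minimum
    increase (0.5 g/dL for M-protein, 100 mg/L for the light-chain
    difference).  This mirrors the consensus relapse convention in shape; it
    is a ground-truth generator, not a claim of clinical equivalence.
    """

    mpr_relative: float = 1.25
    mpr_absolute: float = 0.5     # g/dL
    sfl_relative: float = 1.25
    sfl_absolute: float = 100.0   # mg/L


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a trial-like newly diagnosed cohort followed every 3
    months: induction response over the first 4 visits down to a 20%
    residual-disease floor, then a 2%/visit relapse hazard with 30%/visit
    multiplicative marker regrowth, which yields a per-visit PD prevalence
    near the 7% regime the models are designed for.
    """

    n_patients: int = 200
    n_visits: int = 20
    baseline_mean: np.ndarray = field(default_factory=_default_baseline_mean)
    baseline_cov: np.ndarray = field(default_factory=default_baseline_cov)
    ar_coefficient: np.ndarray = field(default_factory=lambda: np.full(N_FEATURES, 0.7))
    noise_sd: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.45, 0.20, 0.10, 15.0, 0.14, 0.40, 0.10, 4.0, 4.0, 0.60]
        )
    )
    relapse_hazard: float = 0.02       # per eligible visit
    relapse_growth: float = 0.30       # multiplicative marker growth per visit
    missing_rate: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.05, 0.05, 0.05, 0.25, 0.05, 0.30, 0.10, 0.10, 0.10, 0.05]
        )
    )
    seed: int = 0

    # Dynamics constants (documented, not expected to need tuning).
    response_visits: int = 4           # induction ramp length, in visits
    response_floor: float = 0.2        # residual disease fraction after response
    involved_clone_factor: float = 3.0  # clonal excess of the involved chain
    relapse_onset_visit: int = 7       # first visit eligible for relapse onset

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.baseline_cov = np.asarray(self.baseline_cov, dtype=float)
        self.ar_coefficient = np.broadcast_to(
            np.asarray(self.ar_coefficient, dtype=float), (N_FEATURES,)
        ).copy()
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (N_FEATURES,)
        ).copy()
        self.missing_rate = np.broadcast_to(
            np.asarray(self.missing_rate, dtype=float), (N_FEATURES,)
        ).copy()
        self.validate()

    def validate(self) -> None:
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_mean.shape != (N_FEATURES,):
            raise ValueError(f"baseline_mean must have length {N_FEATURES}")
        if self.baseline_cov.shape != (N_FEATURES, N_FEATURES):
            raise ValueError("baseline_cov must be 10x10")
        if not np.allclose(self.baseline_cov, self.baseline_cov.T, atol=1e-10):
            raise ValueError("baseline_cov must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.baseline_cov).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(self.baseline_cov).max())):
            raise ValueError(f"baseline_cov is not positive semi-definite (min eig {eigmin:g})")
        if np.any(self.ar_coefficient < 0) or np.any(self.ar_coefficient >= 1):
            raise ValueError("ar_coefficient must lie in [0, 1) per feature")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.relapse_hazard <= 1:
            raise ValueError("relapse_hazard must lie in [0, 1]")
        if self.relapse_growth < 0:
            raise ValueError("relapse_growth must be non-negative")
        if np.any(self.missing_rate < 0) or np.any(self.missing_rate >= 1):
            raise ValueError("missing_rate must lie in [0, 1) per feature")


def _response_factor(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Induction ramp: 1 at diagnosis, linear to the residual floor, then flat."""
    ramp = np.minimum(t, config.response_visits) / config.response_visits
    return 1.0 - (1.0 - config.response_floor) * ramp


def _simulate_patient(
    config: SimulationConfig, rng: np.random.Generator, patient_id: str
) -> PatientTrajectory:
    n, p = config.n_visits, N_FEATURES
    level = rng.multivariate_normal(config.baseline_mean, config.baseline_cov)
    level = np.maximum(level, 0.05 * config.baseline_mean)

    # Involved light chain: the larger baseline draw, amplified by clonality.
    involved = IDX_SFL_K if level[IDX_SFL_K] >= level[IDX_SFL_L] else IDX_SFL_L
    level[involved] *= config.involved_clone_factor

    t = np.arange(n)
    targets = np.tile(level, (n, 1))
    resp = _response_factor(t, config)
    for j in (IDX_MPR, involved):
        targets[:, j] = level[j] * resp

    # Stochastic relapse onset after the response phase; the draw is made for
    # every eligible visit so the stream length is seed-stable.
    eligible = np.arange(max(config.response_visits + 1, config.relapse_onset_visit), n)
    draws = rng.random(eligible.size)
    hits = eligible[draws < config.relapse_hazard]
    onset = int(hits[0]) if hits.size else None

    if onset is not None:
        since = t - onset  # >= 0 from onset onward
        grow = np.where(since >= 0, (1.0 + config.relapse_growth) ** (since + 1), 1.0)
        for j in (IDX_MPR, involved):
            targets[:, j] = np.where(since >= 0, targets[onset, j] * grow, targets[:, j])
        # Downstream coupling scaled by the relative M-protein excess over floor.
        floor_mpr = level[IDX_MPR] * config.response_floor
        excess = np.where(
            since >= 0, np.minimum(targets[:, IDX_MPR] / max(floor_mpr, 1e-9) - 1.0, 3.0), 0.0
        )
        targets[:, IDX_CR] += 0.15 * level[IDX_CR] * excess
        targets[:, IDX_B2M] += 0.40 * level[IDX_B2M] * excess
        targets[:, IDX_ALB] -= 0.10 * level[IDX_ALB] * excess
        targets[:, IDX_HB] -= 0.08 * level[IDX_HB] * excess

    noise = rng.standard_normal((n, p)) * config.noise_sd
    values = np.empty((n, p))
    values[0] = targets[0] + noise[0]
    phi = config.ar_coefficient
    for i in range(1, n):
        values[i] = targets[i] + phi * (values[i - 1] - targets[i - 1]) + noise[i]
    # physiologic floors; light chains must stay strictly positive
    values = np.maximum(values, 0.01 * config.baseline_mean)

    return PatientTrajectory(
        patient_id=patient_id,
        visit_months=MONTHS_PER_VISIT * t.astype(float),
        values=values,
        observed_mask=np.ones((n, p), dtype=bool),
        pd_labels=np.full(n, LABEL_UNKNOWN, dtype=int),
    )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a fully observed cohort; labels start unknown."""
    config.validate()
    rng = component_rng(config.seed, "simulate")
    width = len(str(max(config.n_patients - 1, 1)))
    trajectories = [
        _simulate_patient(config, rng, f"SYN_{i:0{width}d}")
        for i in range(config.n_patients)
    ]
    return CohortDataset(trajectories=trajectories)


def _involved_chain_index(traj: PatientTrajectory) -> int:
    """Involved chain from the first visit with both chains available."""
    both = traj.observed_mask[:, IDX_SFL_L] & traj.observed_mask[:, IDX_SFL_K]
    row = int(np.argmax(both)) if both.any() else 0
    if traj.values[row, IDX_SFL_K] >= traj.values[row, IDX_SFL_L]:
        return IDX_SFL_K
    return IDX_SFL_L


def label_progression(
    traj: PatientTrajectory, rule: ProgressionRule | None = None
) -> PatientTrajectory:
    """Label every visit PD / non-PD by the relapse-from-nadir rule.

    Deterministic and prefix-causal: the label at visit ``t`` depends only on
    visits ``<= t``.  Visits where the M-protein and both light chains are all
    unobserved are labeled unknown.
    """
    rule = rule or ProgressionRule()
    out = traj.copy()
    involved = _involved_chain_index(traj)
    uninvolved = IDX_SFL_L if involved == IDX_SFL_K else IDX_SFL_K

    mpr = traj.values[:, IDX_MPR]
    dflc = traj.values[:, involved] - traj.values[:, uninvolved]
    mpr_nadir = np.minimum.accumulate(mpr)
    dflc_nadir = np.minimum.accumulate(dflc)

    pd_mpr = (mpr >= rule.mpr_relative * mpr_nadir) & (mpr - mpr_nadir >= rule.mpr_absolute)
    pd_sfl = (dflc >= rule.sfl_relative * dflc_nadir) & (
        dflc - dflc_nadir >= rule.sfl_absolute
    )
    labels = np.where(pd_mpr | pd_sfl, LABEL_PD, LABEL_NON_PD)

    marker_missing = ~(
        traj.observed_mask[:, IDX_MPR]
        | traj.observed_mask[:, IDX_SFL_L]
        | traj.observed_mask[:, IDX_SFL_K]
    )
    labels = np.where(marker_missing, LABEL_UNKNOWN, labels)
    out.pd_labels = labels.astype(int)
    return out


def label_cohort(cohort: CohortDataset, rule: ProgressionRule | None = None) -> CohortDataset:
    """Apply :func:`label_progression` to every trajectory."""
    return CohortDataset(
        trajectories=[label_progression(t, rule) for t in cohort],
        fold_assignment=dict(cohort.fold_assignment),
    )


def inject_missingness(cohort: CohortDataset, config: SimulationConfig) -> CohortDataset:
    """Hide cells independently per feature at ``config.missing_rate``.

    Visit 1 of the M-protein and both light chains always stays observed so
    that progression labels remain computable.  Hidden cells keep their
    generating values under the mask for oracle use downstream.
    """
    config.validate()
    for traj in cohort:
        if not traj.observed_mask.all():
            raise ValueError("inject_missingness expects a fully observed cohort")
    rng = component_rng(config.seed, "missingness")
    out = cohort.copy()
    for traj in out.trajectories:
        hide = rng.random(traj.values.shape) < config.missing_rate
        hide[0, list(LABEL_CRITICAL)] = False
        traj.observed_mask = ~hide
    return out


def pd_prevalence(cohort: CohortDataset) -> float:
    """Fraction of labeled visits marked PD across the cohort."""
    n_pd = 0
    n_labeled = 0
    for traj in cohort:
        known = traj.pd_labels != LABEL_UNKNOWN
        n_labeled += int(known.sum())
        n_pd += int((traj.pd_labels[known] == LABEL_PD).sum())
    if n_labeled == 0:
        raise ValueError("cohort has no labeled visits")
    return n_pd / n_labeled
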