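"""Patient exclusion, LOCF imputation, power transformation and fold splits.

All statistics that touch the data (the Yeo-Johnson exponents and the
post-transform centering/scaling) are fitted strictly on training folds;
test and external data only ever pass through pre-fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import PowerTransformer

from .cohort import CohortDataset, PatientTrajectory
from .seeding import component_rng


@dataclass
class PowerTransformParams:
    """Per-column Yeo-Johnson exponents with post-transform standardization.

    ``lambdas``, ``means`` and ``sds`` each have one entry per column of the
    matrix the params were fitted on (10 analytes for the forecaster panel,
    6 derived features for the annotator).
    """

    lambdas: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    fitted_on: str = ""
    column_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.lambdas.shape == self.means.shape == self.sds.shape):
            raise ValueError("lambdas/means/sds shape mismatch")
        if not np.all(np.isfinite(self.lambdas)):
            raise ValueError("non-finite Yeo-Johnson exponent")
        if not np.all(np.isfinite(self.means)) or not np.all(np.isfinite(self.sds)):
            raise ValueError("non-finite centering/scaling parameter")
        if np.any(self.sds <= 0):
            raise ValueError("scaling sd must be positive")

    @property
    def n_columns(self) -> int:
        return self.lambdas.shape[0]

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "fitted_on": self.fitted_on,
            "column_names": list(self.column_names) if self.column_names else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerTransformParams":
        return cls(
            lambdas=np.array(d["lambdas"], dtype=float),
            means=np.array(d["means"], dtype=float),
            sds=np.array(d["sds"], dtype=float),
            fitted_on=d.get("fitted_on", ""),
            column_names=tuple(d["column_names"]) if d.get("column_names") else None,
        )


@dataclass
class FoldSplit:
    """Patient-level k-fold partition; fold i's test set is partition i."""

    k: int
    test_ids: list[list[str]] = field(default_factory=list)

    def train_ids(self, fold: int) -> list[str]:
        self._check(fold)
        return [p for i, ids in enumerate(self.test_ids) for p in ids if i != fold - 1]

    def fold_test_ids(self, fold: int) -> list[str]:
        self._check(fold)
        return list(self.test_ids[fold - 1])

    def _check(self, fold: int) -> None:
        if not 1 <= fold <= self.k:
            raise ValueError(f"fold must be in 1..{self.k}")

    def assignment(self) -> dict[str, int]:
        return {p: i + 1 for i, ids in enumerate(self.test_ids) for p in ids}


def exclude_unmeasured(cohort: CohortDataset) -> tuple[CohortDataset, list[str]]:
    """Drop patients having at least one analyte never measured at any visit.

    Returns the filtered cohort and the removed patient ids.  A single
    measurement at any visit is enough to retain the patient.
    """
    keep, removed = [], []
    for traj in cohort:
        if traj.observed_mask.any(axis=0).all():
            keep.append(traj)
        else:
            removed.append(traj.patient_id)
    if not keep:
        raise ValueError("cohort is empty after excluding never-measured patients")
    folds = {p: f for p, f in cohort.fold_assignment.items() if p not in set(removed)}
    return CohortDataset(trajectories=keep, fold_assignment=folds), removed


def impute_trajectory(traj: PatientTrajectory) -> PatientTrajectory:
    """LOCF imputation with leading backfill, per feature, within one patient.

    Unobserved cells take the most recent earlier observed value; leading
    unobserved cells take the earliest observed value.  Backfilled and
    carried-forward cells are flagged in ``imputed_mask``.
    """
    out = traj.copy()
    n = traj.n_visits
    values = out.values
    mask = out.observed_mask
    imputed = ~mask
    for j in range(values.shape[1]):
        obs = np.flatnonzero(mask[:, j])
        if obs.size == 0:
            raise ValueError(
                f"feature column {j} has no observations for patient {traj.patient_id}; "
                "run exclude_unmeasured first"
            )
        # LOCF: index of the latest observation at or before each visit
        locf_idx = np.maximum.accumulate(np.where(mask[:, j], np.arange(n), -1))
        locf_idx = np.where(locf_idx >= 0, locf_idx, obs[0])  # leading backfill
        values[:, j] = values[locf_idx, j]
    out.values = values
    out.imputed_mask = imputed
    return out


def impute_cohort(cohort: CohortDataset) -> CohortDataset:
    return CohortDataset(
        trajectories=[impute_trajectory(t) for t in cohort],
        fold_assignment=dict(cohort.fold_assignment),
    )


# ---------------------------------------------------------------------------
# Yeo-Johnson power transform


def fit_power_transform(
    train_matrix: np.ndarray,
    fitted_on: str = "",
    column_names: tuple[str, ...] | None = None,
) -> PowerTransformParams:
    """Fit per-column Yeo-Johnson exponents by maximum likelihood, then record
    the post-transform mean/sd of the training rows for standardization."""
    x = np.asarray(train_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("train_matrix must be 2-D (rows x features)")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 training rows to fit the transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("train_matrix contains non-finite values")
    spreads = x.max(axis=0) - x.min(axis=0)
    if np.any(spreads == 0):
        j = int(np.flatnonzero(spreads == 0)[0])
        name = column_names[j] if column_names else f"column {j}"
        raise ValueError(f"cannot fit power transform: feature {name} is constant")
    pt = PowerTransformer(method="yeo-johnson", standardize=False)
    pt.fit(x)
    lambdas = np.asarray(pt.lambdas_, dtype=float)
    transformed = _yeo_johnson(x, lambdas)
    means = transformed.mean(axis=0)
    sds = transformed.std(axis=0, ddof=0)
    return PowerTransformParams(
        lambdas=lambdas, means=means, sds=sds, fitted_on=fitted_on, column_names=column_names
    )


def _yeo_johnson(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    lam = np.broadcast_to(lam, x.shape)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    lam_pos = pos & (np.abs(lam) > 1e-12)
    lam_zero = pos & ~(np.abs(lam) > 1e-12)
    out[lam_pos] = (np.power(x[lam_pos] + 1.0, lam[lam_pos]) - 1.0) / lam[lam_pos]
    out[lam_zero] = np.log1p(x[lam_zero])
    neg = ~pos
    two = 2.0 - lam
    lam_neg = neg & (np.abs(two) > 1e-12)
    lam_two = neg & ~(np.abs(two) > 1e-12)
    out[lam_neg] = -(np.power(1.0 - x[lam_neg], two[lam_neg]) - 1.0) / two[lam_neg]
    out[lam_two] = -np.log1p(-x[lam_two])
    return out


def _yeo_johnson_inverse(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    # For lambda < 0 the transform's range is bounded above by -1/lambda, and
    # for lambda > 2 it is bounded below by -1/(lambda - 2); inputs beyond a
    # bound (possible for model forecasts) saturate just inside it.
    lam = np.broadcast_to(lam, y.shape)
    margin = 1e-9
    y = np.asarray(y, dtype=float).copy()
    upper_bounded = lam < 0
    if np.any(upper_bounded):
        bound = -1.0 / np.where(upper_bounded, lam, -1.0)
        y = np.where(upper_bounded, np.minimum(y, bound * (1.0 - margin)), y)
    lower_bounded = lam > 2
    if np.any(lower_bounded):
        bound = -1.0 / np.where(lower_bounded, lam - 2.0, 1.0)
        y = np.where(lower_bounded, np.maximum(y, bound * (1.0 - margin)), y)
    out = np.empty_like(y, dtype=float)
    pos = y >= 0
    lam_pos = pos & (np.abs(lam) > 1e-12)
    lam_zero = pos & ~(np.abs(lam) > 1e-12)
    out[lam_pos] = np.power(y[lam_pos] * lam[lam_pos] + 1.0, 1.0 / lam[lam_pos]) - 1.0
    out[lam_zero] = np.expm1(y[lam_zero])
    neg = ~pos
    two = 2.0 - lam
    lam_neg = neg & (np.abs(two) > 1e-12)
    lam_two = neg & ~(np.abs(two) > 1e-12)
    out[lam_neg] = 1.0 - np.power(1.0 - y[lam_neg] * two[lam_neg], 1.0 / two[lam_neg])
    out[lam_two] = -np.expm1(-y[lam_two])
    return out


def apply_power_transform(params: PowerTransformParams, matrix: np.ndarray) -> np.ndarray:
    """Transform then standardize columns with fitted parameters (monotone)."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[-1] != params.n_columns:
        raise ValueError(f"matrix has {x.shape[-1]} columns, params expect {params.n_columns}")
    if not np.all(np.isfinite(x)):
        i = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite input at cell {tuple(i)}")
    return (_yeo_johnson(x, params.lambdas) - params.means) / params.sds


def invert_power_transform(params: PowerTransformParams, matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`apply_power_transform` on the raw domain."""
    y = np.asarray(matrix, dtype=float)
    if y.shape[-1] != params.n_columns:
        raise ValueError(f"matrix has {y.shape[-1]} columns, params expect {params.n_columns}")
    if not np.all(np.isfinite(y)):
        i = np.argwhere(~np.isfinite(y))[0]
        raise ValueError(f"non-finite input at cell {tuple(i)}")
    return _yeo_johnson_inverse(y * params.sds + params.means, params.lambdas)


def stack_observed(cohort: CohortDataset, patient_ids=None) -> np.ndarray:
    """Stack all visits of the given patients into one (rows x 10) matrix."""
    if patient_ids is None:
        trajs = list(cohort)
    else:
        wanted = set(patient_ids)
        trajs = [t for t in cohort if t.patient_id in wanted]
    return np.vstack([t.values for t in trajs])


def transform_trajectory(
    params: PowerTransformParams, traj: PatientTrajectory
) -> PatientTrajectory:
    out = traj.copy()
    out.values = apply_power_transform(params, traj.values)
    return out


def transform_cohort(params: PowerTransformParams, cohort: CohortDataset) -> CohortDataset:
    return CohortDataset(
        trajectories=[transform_trajectory(params, t) for t in cohort],
        fold_assignment=dict(cohort.fold_assignment),
    )


def make_folds(cohort: CohortDataset, k: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded patient-level partition into k near-equal test sets."""
    ids = cohort.patient_ids
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of patients ({len(ids)})")
    rng = component_rng(seed, "folds")
    order = np.array(ids, dtype=object)
    rng.shuffle(order)
    parts = np.array_split(order, k)
    return FoldSplit(k=k, test_ids=[list(p) for p in parts])
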