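"""Core containers for longitudinal myeloma blood-work data.

A cohort is a collection of per-patient visit-indexed matrices over a fixed
10-analyte panel: hemoglobin (Hb), calcium (Ca), creatinine (Cr), lactate
dehydrogenase (LDH), albumin (Alb), beta-2-microglobulin (b2m), M-protein
(M-Pr), serum free light chains lambda and kappa (SFL-l, SFL-k), and white
blood cells (WBC).  Visits sit on a regular 3-month follow-up lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical analyte order, shared by every matrix in the package.
FEATURE_NAMES = (
    "hb", "ca", "cr", "ldh", "alb", "b2m",
    "m_protein", "sfl_lambda", "sfl_kappa", "wbc",
)

N_FEATURES = len(FEATURE_NAMES)

#: Index lookup by analyte name.
FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: Human-readable labels with units (raw physiologic scale).
FEATURE_LABELS = {
    "hb": "Hemoglobin (g/dL)",
    "ca": "Calcium (mg/dL)",
    "cr": "Creatinine (mg/dL)",
    "ldh": "Lactate dehydrogenase (U/L)",
    "alb": "Albumin (g/dL)",
    "b2m": "Beta-2-microglobulin (mg/L)",
    "m_protein": "M-protein (g/dL)",
    "sfl_lambda": "Serum free light chain lambda (mg/L)",
    "sfl_kappa": "Serum free light chain kappa (mg/L)",
    "wbc": "White blood cells (10^9/L)",
}

MONTHS_PER_VISIT = 3

#: Per-visit progression labels.
LABEL_NON_PD = 0
LABEL_PD = 1
LABEL_UNKNOWN = -1


@dataclass
class PatientTrajectory:
    """One patient's visit-indexed analyte matrix.

    Attributes
    ----------
    patient_id:
        Stable string identifier.
    visit_months:
        Strictly increasing visit times in months (multiples of 3).
    values:
        ``(n_visits, 10)`` float array on the raw physiologic scale.  Cells
        where ``observed_mask`` is False may still hold the generating truth
        (the synthetic generator keeps them for oracle comparisons); consumers
        must honour the mask.
    observed_mask:
        ``(n_visits, 10)`` boolean array; True where the value was measured.
    pd_labels:
        ``(n_visits,)`` int array in {0 non-PD, 1 PD, -1 unknown}.
    imputed_mask:
        ``(n_visits, 10)`` boolean array marking cells filled by imputation
        (empty until :func:`mmforecast.preprocess.impute_trajectory` runs).
    """

    patient_id: str
    visit_months: np.ndarray
    values: np.ndarray
    observed_mask: np.ndarray
    pd_labels: np.ndarray
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.visit_months = np.asarray(self.visit_months, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.pd_labels = np.asarray(self.pd_labels, dtype=int)
        n = self.values.shape[0]
        if self.values.shape != (n, N_FEATURES):
            raise ValueError(
                f"values must be (n_visits, {N_FEATURES}), got {self.values.shape}"
            )
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape mismatch")
        if self.visit_months.shape != (n,) or self.pd_labels.shape != (n,):
            raise ValueError("visit_months/pd_labels length mismatch")
        if n >= 2 and not np.all(np.diff(self.visit_months) > 0):
            raise ValueError(f"visit_months not strictly increasing for {self.patient_id}")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError(f"non-finite observed value for patient {self.patient_id}")

    @property
    def n_visits(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "PatientTrajectory":
        return PatientTrajectory(
            patient_id=self.patient_id,
            visit_months=self.visit_months.copy(),
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
            pd_labels=self.pd_labels.copy(),
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask.copy(),
        )

    def truncated(self, n_visits: int) -> "PatientTrajectory":
        """Prefix of the trajectory containing the first ``n_visits`` visits."""
        if not 1 <= n_visits <= self.n_visits:
            raise ValueError(f"n_visits must be in [1, {self.n_visits}]")
        return PatientTrajectory(
            patient_id=self.patient_id,
            visit_months=self.visit_months[:n_visits].copy(),
            values=self.values[:n_visits].copy(),
            observed_mask=self.observed_mask[:n_visits].copy(),
            pd_labels=self.pd_labels[:n_visits].copy(),
            imputed_mask=None
            if self.imputed_mask is None
            else self.imputed_mask[:n_visits].copy(),
        )


@dataclass
class CohortDataset:
    """A set of patient trajectories plus fold assignments.

    ``fold_assignment`` maps patient_id to a fold index in ``{1..k}``; it may
    be empty before :func:`mmforecast.preprocess.make_folds` has run.
    """

    trajectories: list[PatientTrajectory]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError("feature_names must equal the canonical 10-analyte order")
        ids = [t.patient_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")
        extra = set(self.fold_assignment) - set(ids)
        if extra:
            raise ValueError(f"fold_assignment references unknown patients: {sorted(extra)}")

    @property
    def patient_ids(self) -> list[str]:
        return [t.patient_id for t in self.trajectories]

    @property
    def n_patients(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, patient_id: str) -> PatientTrajectory:
        for t in self.trajectories:
            if t.patient_id == patient_id:
                return t
        raise KeyError(patient_id)

    def subset(self, patient_ids) -> "CohortDataset":
        wanted = set(patient_ids)
        trajs = [t for t in self.trajectories if t.patient_id in wanted]
        missing = wanted - {t.patient_id for t in trajs}
        if missing:
            raise KeyError(f"patients not in cohort: {sorted(missing)}")
        folds = {p: f for p, f in self.fold_assignment.items() if p in wanted}
        return CohortDataset(trajectories=trajs, fold_assignment=folds)

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            trajectories=[t.copy() for t in self.trajectories],
            fold_assignment=dict(self.fold_assignment),
        )
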