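"""Long-format cohort CSV reading and writing.

Schema (one row per patient visit): ``patient_id, visit_index, visit_months,
hb, ca, cr, ldh, alb, b2m, m_protein, sfl_lambda, sfl_kappa, wbc, pd_label``.
Empty analyte cells mean "not observed"; ``pd_label`` is 0, 1 or empty
(unknown).  Unknown extra columns are preserved on read but ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    FEATURE_NAMES,
    LABEL_UNKNOWN,
    CohortDataset,
    PatientTrajectory,
)

REQUIRED_COLUMNS = ("patient_id", "visit_index", "visit_months") + FEATURE_NAMES + ("pd_label",)


def write_cohort_csv(cohort: CohortDataset, path) -> None:
    """Write a cohort in the long format; masked cells become empty."""
    rows = []
    for traj in cohort:
        for i in range(traj.n_visits):
            row = {
                "patient_id": traj.patient_id,
                "visit_index": i,
                "visit_months": traj.visit_months[i],
            }
            for j, name in enumerate(FEATURE_NAMES):
                row[name] = traj.values[i, j] if traj.observed_mask[i, j] else np.nan
            label = traj.pd_labels[i]
            row["pd_label"] = np.nan if label == LABEL_UNKNOWN else int(label)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    frame.to_csv(path, index=False)


def read_cohort_csv(path) -> CohortDataset:
    """Read a long-format cohort CSV back into a :class:`CohortDataset`."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required column(s): {missing}")
    dup = frame.duplicated(subset=["patient_id", "visit_index"])
    if dup.any():
        bad = frame.loc[dup, ["patient_id", "visit_index"]].iloc[0]
        raise ValueError(
            f"duplicate (patient_id, visit_index) = ({bad['patient_id']}, {bad['visit_index']})"
        )
    trajectories = []
    # keep first-appearance patient order for reproducibility
    for pid, group in frame.groupby("patient_id", sort=False):
        group = group.reset_index(drop=True)
        vidx = group["visit_index"].to_numpy()
        if not np.all(np.diff(vidx) > 0):
            raise ValueError(f"visit_index not strictly increasing for patient {pid}")
        values = group[list(FEATURE_NAMES)].to_numpy(dtype=float)
        mask = np.isfinite(values)
        values = np.where(mask, values, 0.0)
        labels = group["pd_label"].to_numpy(dtype=float)
        pd_labels = np.where(np.isfinite(labels), labels, LABEL_UNKNOWN).astype(int)
        trajectories.append(
            PatientTrajectory(
                patient_id=str(pid),
                visit_months=group["visit_months"].to_numpy(dtype=float),
                values=values,
                observed_mask=mask,
                pd_labels=pd_labels,
            )
        )
    return CohortDataset(trajectories=trajectories)
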