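"""Metamodel composition and the verification / validation / UQ metric suite.

The progression-forecasting metamodel chains the blood-work forecaster and
the annotation model: forecast the next ``m`` visits, invert them to the raw
scale, derive the myeloma-specific annotation features on the concatenated
(observed + forecasted) trajectory, and score the forecasted positions for
progression.  The evaluation functions quantify forecast accuracy (MSE vs
LOCF/MA with one-sided Mann-Whitney comparisons), statistical fidelity
(cross- and lag-correlation structure), discrimination (AUROC / AUPRC /
sensitivity / specificity, including prior-observation x horizon grids) and
prevalence-dependent clinical utility (PPV, flagged fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .annotator import (
    AnnotatorParams,
    ThresholdCalibration,
    annotate,
    annotation_inputs,
)
from .cohort import FEATURE_INDEX, FEATURE_NAMES, LABEL_UNKNOWN
from .forecaster import (
    ForecasterConfig,
    ForecasterParams,
    baseline_forecast,
    forecast_trajectories,
)
from .preprocess import (
    PowerTransformParams,
    apply_power_transform,
    invert_power_transform,
)

DEFAULT_HORIZONS = (1, 2, 3, 4, 5)  # visits ahead; x3 for months


# ---------------------------------------------------------------------------
# scalar statistics


def mann_whitney_one_sided(a, b) -> float:
    """One-sided Mann-Whitney U p-value for "a stochastically less than b".

    Uses the exact null distribution when both samples have at most 8
    observations and there are no ties; otherwise the midrank statistic with
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="less", method=method).pvalue)


def significance_tier(p: float) -> str:
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "p<0.1"
    return "ns"


def classification_metrics(scores, labels, threshold: float | None = None) -> dict:
    """AUROC (midranks for ties), AUPRC (average precision) and, given a
    threshold, the confusion-table sensitivity / specificity / precision.

    Flagging convention: a visit is called positive when score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC/AUPRC require both classes present")
    out = {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "prevalence": n_pos / (n_pos + n_neg),
    }
    if threshold is not None:
        flagged = scores >= threshold
        tp = int((flagged & (labels == 1)).sum())
        fp = int((flagged & (labels == 0)).sum())
        out["sensitivity"] = tp / n_pos
        out["specificity"] = (n_neg - fp) / n_neg
        out["precision"] = tp / (tp + fp) if (tp + fp) else float("nan")
        out["threshold"] = float(threshold)
    return out


def clinical_utility(sensitivity: float, specificity: float, prevalence: float) -> dict:
    """Prevalence-dependent utility of a binary progression alert.

    ppv = sens*prev / (sens*prev + (1-spec)*(1-prev)); flagged_fraction is
    that same denominator — the share of all visits the alert would flag.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    true_flags = sensitivity * prevalence
    false_flags = (1.0 - specificity) * (1.0 - prevalence)
    flagged = true_flags + false_flags
    ppv = true_flags / flagged if flagged > 0 else float("nan")
    return {"ppv": ppv, "flagged_fraction": flagged}


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN (reported as missing) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# metamodel


def predict_progression(
    forecaster_params: ForecasterParams,
    annotator_params: AnnotatorParams,
    prefix_raw: np.ndarray,
    horizon: int,
    panel_transform: PowerTransformParams,
    annotation_transform: PowerTransformParams,
    config: ForecasterConfig | None = None,
    seed: int = 0,
    n_trajectories: int | None = None,
    forecast_fn=None,
) -> np.ndarray:
    """PD probabilities for the next ``horizon`` forecasted visits.

    ``prefix_raw`` is the observed (imputed) raw-scale history.  The
    forecaster runs on the transformed scale; its mean point forecast is
    inverted back to raw units, appended to the prefix, and the annotation
    model scores the forecasted positions.  ``forecast_fn(prefix_t, horizon)``
    may replace the sampler (e.g. with an oracle) and must return a
    (horizon, 10) transformed-scale matrix.
    """
    prefix_raw = np.asarray(prefix_raw, dtype=float)
    if prefix_raw.ndim != 2 or prefix_raw.shape[0] < 1:
        raise ValueError("prefix must be a non-empty (visits, features) matrix")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    prefix_t = apply_power_transform(panel_transform, prefix_raw)
    if forecast_fn is not None:
        point_t = np.asarray(forecast_fn(prefix_t, horizon), dtype=float)
    else:
        point_t = forecast_trajectories(
            forecaster_params, prefix_t, horizon, config, seed=seed,
            n_trajectories=n_trajectories,
        ).point_forecast
    forecast_raw = invert_power_transform(panel_transform, point_t)
    # light chains must stay strictly positive for the ratio feature
    for col in (FEATURE_INDEX["sfl_lambda"], FEATURE_INDEX["sfl_kappa"]):
        forecast_raw[:, col] = np.maximum(forecast_raw[:, col], 1e-3)
    full_raw = np.vstack([prefix_raw, forecast_raw])
    probs = annotate(annotator_params, annotation_inputs(full_raw, annotation_transform))
    return probs[-horizon:]


# ---------------------------------------------------------------------------
# forecast collection (shared by MSE and correlation analyses)


@dataclass
class ForecastCollection:
    """Point forecasts for every (patient, prefix, horizon) of one test fold.

    For each horizon h, ``forecast[h]``, ``actual[h]`` and ``last_known[h]``
    are (n_obs, 10) stacks on the transformed scale; ``meta[h]`` records the
    (patient index, prefix length) of each row.  ``skipped`` counts
    (patient, horizon) pairs beyond the available visits.
    """

    horizons: tuple
    forecast: dict = field(default_factory=dict)
    actual: dict = field(default_factory=dict)
    last_known: dict = field(default_factory=dict)
    prev_actual: dict = field(default_factory=dict)
    ma_forecast: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    skipped: int = 0


def collect_forecasts(
    test_matrices: list[np.ndarray],
    params: ForecasterParams,
    horizons=DEFAULT_HORIZONS,
    config: ForecasterConfig | None = None,
    seed: int = 0,
    n_trajectories: int | None = None,
    ma_window: int = 3,
    min_prefix: int = 1,
) -> ForecastCollection:
    """Run the forecaster over every prefix of every test patient.

    The moving-average baseline uses a trailing window of ``ma_window``
    visits, shrunk to the prefix length when the prefix is shorter.
    """
    horizons = tuple(sorted(horizons))
    hmax = horizons[-1]
    rows: dict[int, list] = {h: [] for h in horizons}
    coll = ForecastCollection(horizons=horizons)
    skipped = 0
    for pi, m in enumerate(test_matrices):
        T = m.shape[0]
        for p in range(min_prefix, T):
            avail = T - p
            run = min(hmax, avail)
            res = forecast_trajectories(
                params, m[:p], run, config, seed=seed, n_trajectories=n_trajectories
            )
            ma = baseline_forecast(m[:p], run, "MA", window=min(ma_window, p))
            for h in horizons:
                if h > avail:
                    skipped += 1
                    continue
                rows[h].append(
                    (pi, p, res.point_forecast[h - 1], m[p + h - 1], m[p - 1],
                     m[p + h - 2], ma[h - 1])
                )
    for h in horizons:
        if rows[h]:
            coll.forecast[h] = np.array([r[2] for r in rows[h]])
            coll.actual[h] = np.array([r[3] for r in rows[h]])
            coll.last_known[h] = np.array([r[4] for r in rows[h]])
            coll.prev_actual[h] = np.array([r[5] for r in rows[h]])
            coll.ma_forecast[h] = np.array([r[6] for r in rows[h]])
            coll.meta[h] = [(r[0], r[1]) for r in rows[h]]
    coll.skipped = skipped
    return coll


def mse_report(
    collection: ForecastCollection,
    train_matrices: list[np.ndarray] | None = None,
) -> dict:
    """Per-feature / per-horizon mean squared error for model, LOCF and MA.

    When ``train_matrices`` is given, also reports the extreme-change subset:
    squared errors restricted to cells whose actual change from the previous
    visit exceeds one standard deviation of all such changes in the training
    split (per feature).
    """
    out: dict = {"per_feature": {}, "pooled": {}, "n_obs": {}, "skipped": collection.skipped}
    extreme_sd = None
    if train_matrices is not None:
        diffs = np.vstack([np.diff(m, axis=0) for m in train_matrices])
        extreme_sd = diffs.std(axis=0, ddof=0)
        out["extreme"] = {}
        out["extreme_sd"] = extreme_sd
        out["extreme_fraction"] = {}
    for h in collection.horizons:
        if h not in collection.forecast:
            continue
        F, A, L, MA_ = (
            collection.forecast[h],
            collection.actual[h],
            collection.last_known[h],
            collection.ma_forecast[h],
        )
        errs = {"model": (F - A) ** 2, "LOCF": (L - A) ** 2, "MA": (MA_ - A) ** 2}
        out["per_feature"][h] = {k: v.mean(axis=0) for k, v in errs.items()}
        out["pooled"][h] = {k: float(v.mean()) for k, v in errs.items()}
        out["n_obs"][h] = F.shape[0]
        if extreme_sd is not None:
            # cells whose actual change from the immediately previous visit
            # exceeds one training-split SD of such changes (per feature)
            big = np.abs(A - collection.prev_actual[h]) > extreme_sd
            counts = big.sum(axis=0)
            out["extreme"][h] = {
                k: np.where(
                    counts > 0,
                    np.where(big, v, 0.0).sum(axis=0) / np.maximum(counts, 1),
                    np.nan,
                )
                for k, v in errs.items()
            }
            out["extreme_fraction"][h] = float(big.mean())
    return out


def extreme_change_fraction(matrices: list[np.ndarray]) -> float:
    """Fraction of per-feature visit-to-visit changes beyond one SD of all
    such changes (per feature), pooled across features."""
    diffs = np.vstack([np.diff(m, axis=0) for m in matrices])
    sd = diffs.std(axis=0, ddof=0)
    return float((np.abs(diffs) > sd).mean())


# ---------------------------------------------------------------------------
# correlation fidelity


def _regress(x: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares y = m x + b with coefficient of determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.std(x) == 0:
        return {"slope": float("nan"), "intercept": float("nan"), "r2": float("nan")}
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"slope": float(slope), "intercept": float(intercept), "r2": float(r2)}


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def lag_correlation_matrix(
    matrices: list[np.ndarray], lag: int, center: str = "patient"
) -> np.ndarray:
    """Feature x feature correlation between visit t and visit t - lag.

    Pools within-patient pairs across patients; ``center='patient'`` removes
    each patient's mean level first, isolating the temporal dynamics from
    between-patient level differences.
    """
    now, past = [], []
    for m in matrices:
        if m.shape[0] <= lag:
            continue
        x = m - m.mean(axis=0) if center == "patient" else m
        now.append(x[lag:])
        past.append(x[:-lag] if lag else x)
    now = np.vstack(now)
    past = np.vstack(past)
    nf = now.shape[1]
    out = np.empty((nf, nf))
    for i in range(nf):
        for j in range(nf):
            out[i, j] = pearson_r(now[:, i], past[:, j])
    return out


def correlation_fidelity(
    collection: ForecastCollection,
    test_matrices: list[np.ndarray],
    lags=(1, 2, 3, 4),
    segment_prefix: int = 7,
    segment_len: int = 5,
) -> dict:
    """Correlation structure of forecasts vs actual data.

    Reports, per feature and horizon: Pearson r between forecast and actual,
    and r between the model's predicted change from the last known value
    (delta_model) and the actual change (delta_true).  Cross-correlation
    matrices (pooled over observations at each horizon) and lag-correlation
    matrices over forecasted segments are compared to the actual data by
    least-squares regression (slope, intercept, R^2) on their off-diagonal /
    all entries respectively.
    """
    per_feature: dict = {}
    cross: dict = {}
    for h in collection.horizons:
        if h not in collection.forecast:
            continue
        F, A, L = collection.forecast[h], collection.actual[h], collection.last_known[h]
        per_feature[h] = {}
        for j, name in enumerate(FEATURE_NAMES):
            per_feature[h][name] = {
                "r": pearson_r(F[:, j], A[:, j]),
                "r_delta": pearson_r(F[:, j] - L[:, j], A[:, j] - L[:, j]),
            }
        corr_f = np.corrcoef(F.T)
        corr_a = np.corrcoef(A.T)
        cross[h] = _regress(_offdiag(corr_a), _offdiag(corr_f))

    # lag-correlation over a common forecasted segment per patient
    lag_summary: dict = {}
    seg_f, seg_a = [], []
    hmax = collection.horizons[-1]
    if 1 in collection.meta:
        by_patient: dict[int, dict[int, int]] = {}
        for h in collection.horizons:
            for row, (pi, p) in enumerate(collection.meta[h]):
                if p == segment_prefix:
                    by_patient.setdefault(pi, {})[h] = row
        for pi, rows in by_patient.items():
            if len(rows) >= min(segment_len, hmax):
                hs = sorted(rows)[:segment_len]
                seg_f.append(np.array([collection.forecast[h][rows[h]] for h in hs]))
                seg_a.append(np.array([collection.actual[h][rows[h]] for h in hs]))
    if seg_f:
        for lag in lags:
            if lag >= min(m.shape[0] for m in seg_f):
                continue
            lc_f = lag_correlation_matrix(seg_f, lag, center="none")
            lc_a = lag_correlation_matrix(seg_a, lag, center="none")
            lag_summary[lag] = _regress(lc_a.ravel(), lc_f.ravel())
    return {"per_feature": per_feature, "cross_correlation": cross, "lag_correlation": lag_summary}


# ---------------------------------------------------------------------------
# prior-observation x horizon grids


def horizon_grid(
    test_trajectories,
    forecaster_params: ForecasterParams,
    annotator_params: AnnotatorParams,
    panel_transform: PowerTransformParams,
    annotation_transform: PowerTransformParams,
    calibration: ThresholdCalibration,
    prior_lengths=(2, 4, 6, 8, 10, 12),
    horizons=DEFAULT_HORIZONS,
    config: ForecasterConfig | None = None,
    seed: int = 0,
    n_trajectories: int | None = None,
    forecast_fn=None,
) -> dict:
    """Metamodel discrimination across prior-observation length and horizon.

    For each (prior length n, horizon m): every patient with at least n + m
    visits and a known label at the target visit contributes the metamodel's
    PD probability at the m-th forecasted visit.  Cells and pooled
    per-horizon sets are scored at the calibrated threshold; single-class
    cells report metrics as missing (None).
    """
    horizons = tuple(sorted(horizons))
    prior_lengths = tuple(sorted(prior_lengths))
    hmax = horizons[-1]
    cells: dict = {(n, m): {"scores": [], "labels": []} for n in prior_lengths for m in horizons}
    for traj in test_trajectories:
        T = traj.n_visits
        for n in prior_lengths:
            if n >= T:
                continue
            run = min(hmax, T - n)
            probs = predict_progression(
                forecaster_params,
                annotator_params,
                traj.values[:n],
                run,
                panel_transform,
                annotation_transform,
                config=config,
                seed=seed,
                n_trajectories=n_trajectories,
                forecast_fn=forecast_fn,
            )
            for m in horizons:
                if m > run:
                    continue
                label = traj.pd_labels[n + m - 1]
                if label == LABEL_UNKNOWN:
                    continue
                cells[(n, m)]["scores"].append(float(probs[m - 1]))
                cells[(n, m)]["labels"].append(int(label))

    metric_names = ("auroc", "auprc", "sensitivity", "specificity")
    grids = {
        k: np.full((len(prior_lengths), len(horizons)), np.nan) for k in metric_names
    }
    for i, n in enumerate(prior_lengths):
        for j, m in enumerate(horizons):
            cell = cells[(n, m)]
            labels = np.array(cell["labels"], dtype=int)
            if labels.size and 0 < labels.sum() < labels.size:
                mets = classification_metrics(
                    np.array(cell["scores"]), labels, threshold=calibration.threshold
                )
                for k in metric_names:
                    grids[k][i, j] = mets[k]

    per_horizon: dict = {}
    for j, m in enumerate(horizons):
        scores = np.concatenate(
            [np.array(cells[(n, m)]["scores"]) for n in prior_lengths]
        ) if any(cells[(n, m)]["scores"] for n in prior_lengths) else np.array([])
        labels = np.concatenate(
            [np.array(cells[(n, m)]["labels"], dtype=int) for n in prior_lengths]
        ) if scores.size else np.array([], dtype=int)
        if labels.size and 0 < labels.sum() < labels.size:
            per_horizon[m] = classification_metrics(
                scores, labels, threshold=calibration.threshold
            )
        else:
            per_horizon[m] = None
    return {
        "prior_lengths": prior_lengths,
        "horizons": horizons,
        "grids": grids,
        "per_horizon": per_horizon,
    }
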