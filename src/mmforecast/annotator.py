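"""Per-visit progression-probability model and F-beta threshold calibration.

A small LSTM (6 myeloma-specific inputs, 8 memory cells) reads the prefix of
a patient's trajectory up to and including the current visit; a dense 2-way
softmax head on its final state yields the probability that the current
visit is progressive disease.  Training balances the rare PD class by
upsampling (prefix, label) instances to parity; evaluation always runs on
the natural, imbalanced data.  The decision threshold is calibrated on
training data by maximizing the F-beta score with beta = 5, weighting recall
five-fold over precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    FEATURE_INDEX,
    LABEL_PD,
    LABEL_UNKNOWN,
    CohortDataset,
    PatientTrajectory,
)
from .nn import LSTM, AdamW, Linear
from .preprocess import PowerTransformParams, apply_power_transform, fit_power_transform
from .seeding import component_rng

ANNOTATION_FEATURES = (
    "m_protein",
    "sfl_kappa",
    "sfl_lambda",
    "sfl_ratio",       # kappa / lambda
    "sfl_diff_kl",     # kappa - lambda
    "sfl_diff_lk",     # lambda - kappa
)
N_ANNOTATION_FEATURES = len(ANNOTATION_FEATURES)

IDX_MPR = FEATURE_INDEX["m_protein"]
IDX_SFL_L = FEATURE_INDEX["sfl_lambda"]
IDX_SFL_K = FEATURE_INDEX["sfl_kappa"]


@dataclass
class AnnotatorConfig:
    n_features: int = N_ANNOTATION_FEATURES
    hidden: int = 8
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.hidden < 1 or self.n_classes != 2:
            raise ValueError("invalid annotator config")


@dataclass
class AnnotatorHyper:
    """Training hyperparameters (defaults as published for the full-scale study)."""

    epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-4
    weight_decay: dict = field(default_factory=lambda: {"encoder": 1.0, "dense": 1.0})


class AnnotatorParams:
    def __init__(self, config: AnnotatorConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.encoder = LSTM(config.n_features, config.hidden, rng)
        self.dense = Linear(config.hidden, config.n_classes, rng)

    @property
    def n_params(self) -> int:
        return self.encoder.n_params + self.dense.n_params

    def parameters(self) -> dict[str, np.ndarray]:
        return {**self.encoder.parameters("encoder"), **self.dense.parameters("dense")}

    def load(self, tensors: dict[str, np.ndarray]) -> None:
        self.encoder.load("encoder", tensors)
        self.dense.load("dense", tensors)


@dataclass
class ThresholdCalibration:
    beta: float
    threshold: float
    achieved_fbeta: float
    precision_at: float
    recall_at: float

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "threshold": self.threshold,
            "achieved_fbeta": self.achieved_fbeta,
            "precision_at": self.precision_at,
            "recall_at": self.recall_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdCalibration":
        return cls(**d)


def derive_annotation_features(raw_matrix: np.ndarray) -> np.ndarray:
    """Raw-scale 6-feature panel per visit, before any transformation.

    Columns: M-protein, SFL-kappa, SFL-lambda, kappa/lambda ratio and both
    signed differences.  Requires strictly positive SFL-lambda (denominator).
    """
    x = np.asarray(raw_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (visits, features) matrix")
    mpr = x[:, IDX_MPR]
    kappa = x[:, IDX_SFL_K]
    lam = x[:, IDX_SFL_L]
    if np.any(lam <= 0):
        raise ValueError("SFL-lambda must be strictly positive to form the ratio")
    return np.column_stack([mpr, kappa, lam, kappa / lam, kappa - lam, lam - kappa])


def fit_annotation_transform(
    cohort_train: CohortDataset, fitted_on: str = ""
) -> PowerTransformParams:
    """Fold-fitted power transform for the 6 derived features (raw scale)."""
    derived = np.vstack([derive_annotation_features(t.values) for t in cohort_train])
    return fit_annotation_transform_from_matrix(derived, fitted_on)


def fit_annotation_transform_from_matrix(
    derived: np.ndarray, fitted_on: str = ""
) -> PowerTransformParams:
    return fit_power_transform(derived, fitted_on=fitted_on, column_names=ANNOTATION_FEATURES)


def annotation_inputs(
    traj_or_matrix, transform: PowerTransformParams
) -> np.ndarray:
    """Transformed (visits x 6) annotator input for one raw-scale trajectory."""
    values = (
        traj_or_matrix.values
        if isinstance(traj_or_matrix, PatientTrajectory)
        else np.asarray(traj_or_matrix, dtype=float)
    )
    return apply_power_transform(transform, derive_annotation_features(values))


def _softmax2(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def annotate(params: AnnotatorParams, inputs: np.ndarray) -> np.ndarray:
    """PD probability at every visit of one transformed 6-feature sequence.

    The probability at visit t is a function of visits <= t only (the LSTM is
    causal), matching training on prefix instances.
    """
    x = np.asarray(inputs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("inputs must be a non-empty (visits, 6) matrix")
    if x.shape[1] != params.config.n_features:
        raise ValueError(f"expected {params.config.n_features} features, got {x.shape[1]}")
    hs, _, _ = params.encoder.forward(x[:, None, :])
    logits = params.dense.forward(hs[:, 0, :])
    return _softmax2(logits)[:, 1]


def _collect_instances(sequences, labels):
    """(sequence index, prefix length, label) for every labeled visit."""
    out = []
    for i, (seq, lab) in enumerate(zip(sequences, labels)):
        for t in range(seq.shape[0]):
            if lab[t] != LABEL_UNKNOWN:
                out.append((i, t + 1, int(lab[t])))
    return out


def balance_to_parity(pos, neg, n_instances, rng: np.random.Generator) -> np.ndarray:
    """Instance index pool with the minority class resampled to exact parity.

    Only indices are duplicated; feature values are never altered.
    """
    if len(pos) < len(neg):
        extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
    elif len(neg) < len(pos):
        extra = rng.choice(neg, size=len(pos) - len(neg), replace=True)
    else:
        return np.arange(n_instances)
    return np.concatenate([np.arange(n_instances), extra])


def _pad_batch(sequences, instances, idx):
    lengths = [instances[i][1] for i in idx]
    maxlen = max(lengths)
    B = len(idx)
    nf = sequences[0].shape[1]
    xs = np.zeros((maxlen, B, nf))
    mask = np.zeros((maxlen, B))
    ys = np.empty(B, dtype=int)
    for k, i in enumerate(idx):
        si, t, lab = instances[i]
        xs[maxlen - t :, k, :] = sequences[si][:t]
        mask[maxlen - t :, k] = 1.0
        ys[k] = lab
    return xs, mask, ys


def train_annotator(
    sequences: list[np.ndarray],
    labels: list[np.ndarray],
    config: AnnotatorConfig | None = None,
    hyper: AnnotatorHyper | None = None,
    seed: int = 0,
) -> tuple[AnnotatorParams, list[float]]:
    """Cross-entropy training on class-balanced prefix instances.

    ``sequences`` are transformed (visits x 6) matrices; ``labels`` the
    matching per-visit PD labels (unknown visits are skipped).  PD instances
    are resampled with replacement up to parity with non-PD before each run.
    Returns trained parameters and the per-epoch mean loss trace.
    """
    config = config or AnnotatorConfig()
    hyper = hyper or AnnotatorHyper()
    instances = _collect_instances(sequences, labels)
    pos = [i for i, inst in enumerate(instances) if inst[2] == LABEL_PD]
    neg = [i for i, inst in enumerate(instances) if inst[2] != LABEL_PD]
    if not pos or not neg:
        raise ValueError("training data must contain both PD and non-PD instances")

    rng_init = component_rng(seed, "annotator-init")
    rng = component_rng(seed, "annotator-train")
    params = AnnotatorParams(config, rng_init)
    tensors = params.parameters()
    opt = AdamW(tensors, lr=hyper.lr, weight_decay=hyper.weight_decay)

    index_pool = balance_to_parity(pos, neg, len(instances), rng)

    n = index_pool.size
    loss_trace: list[float] = []
    for _ in range(hyper.epochs):
        order = index_pool[rng.permutation(n)]
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            xs, mask, ys = _pad_batch(sequences, instances, idx)
            B = len(idx)
            _, (h, _), cache = params.encoder.forward(xs, mask)
            logits = params.dense.forward(h)
            probs = _softmax2(logits)
            eps = 1e-12
            loss = float(-np.log(probs[np.arange(B), ys] + eps).mean())
            epoch_loss += loss * B
            dlogits = probs.copy()
            dlogits[np.arange(B), ys] -= 1.0
            dlogits /= B
            dh, dW_dense, db_dense = params.dense.backward(h, dlogits)
            enc_grads = params.encoder.backward(cache, dh_last=dh)
            grads = {
                **{f"encoder.{k}": v for k, v in enc_grads.items()},
                "dense.weight": dW_dense,
                "dense.bias": db_dense,
            }
            opt.step(grads)
        loss_trace.append(epoch_loss / n)
    return params, loss_trace


def fbeta(precision: float, recall: float, beta: float) -> float:
    """Recall-weighted harmonic mean of precision and recall.

    Defined as 0 when precision = recall = 0 (documented convention).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, beta: float = 5.0
) -> ThresholdCalibration:
    """Exhaustive F-beta maximization over all distinct-score thresholds.

    A visit is flagged when its score is >= the threshold.  Candidates are
    the distinct scores plus {0, 1}; ties in F-beta break toward the lower
    threshold (higher recall).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration requires both classes present")

    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best = None
    for thr in candidates:  # ascending; strict > keeps the lowest tied threshold
        flagged = scores >= thr
        tp = int((flagged & (labels == 1)).sum())
        fp = int((flagged & (labels == 0)).sum())
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / n_pos
        f = fbeta(precision, recall, beta)
        if best is None or f > best[0]:
            best = (f, thr, precision, recall)
    f, thr, precision, recall = best
    return ThresholdCalibration(
        beta=beta,
        threshold=float(thr),
        achieved_fbeta=float(f),
        precision_at=float(precision),
        recall_at=float(recall),
    )
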