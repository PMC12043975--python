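"""Recurrent-encoder conditional Gaussian-Bernoulli RBM blood-work forecaster.

An LSTM encoder summarizes a patient's history (on the power-transformed
scale) into a 32-dimensional state c.  Three affine conditioning networks map
c to the parameters of a Gaussian-Bernoulli restricted Boltzmann machine over
the next visit: a visible bias b(c), a diagonal precision d(c) = softplus(.)
> 0, and a hidden-visible coupling matrix W(c) of shape (16, 10).  The model
has no hidden bias.  Its energy, in whitened coordinates
z = sqrt(d) * (v - b), is

    E(v, h) = 0.5 * ||z||^2 - h . (W z)

so block Gibbs sampling alternates p(h_j = 1 | v) = logistic((W z)_j) and
v_i | h ~ Normal(b_i + (W^T h)_i / sqrt(d_i), 1 / d_i).  Training minimizes
contrastive divergence: the free energy of the observed next visit minus the
free energy of a short-chain Gibbs reconstruction, with gradients blocked
through the reconstruction's sampled values.  Multi-step forecasts feed each
sampled visit back into the encoder and repeat; the point forecast averages
an ensemble of whole sampled trajectories and the 95% sleeves are its
empirical 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import N_FEATURES, CohortDataset
from .nn import LSTM, AdamW, Linear, sigmoid, softplus
from .seeding import component_rng

#: softplus(x) = 1  =>  x = log(e - 1); used to start precisions near 1.
_SOFTPLUS_INV_ONE = float(np.log(np.e - 1.0))


@dataclass
class ForecasterConfig:
    n_features: int = N_FEATURES    # visible units v
    encoder_hidden: int = 32        # LSTM memory cells; encoded state c
    crbm_hidden: int = 16           # hidden units h
    gibbs_steps: int = 32           # Markov-chain alternations per sample
    gibbs_samples: int = 1000       # samples per single-step prediction
    trajectories: int = 1000        # sampled multi-step trajectories

    def __post_init__(self) -> None:
        for name in ("n_features", "encoder_hidden", "crbm_hidden",
                     "gibbs_steps", "gibbs_samples", "trajectories"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ForecasterHyper:
    """Training hyperparameters (defaults as published for the full-scale study)."""

    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: dict = field(
        default_factory=lambda: {"encoder": 0.1, "bias": 0.1, "precision": 0.1, "weights": 0.2}
    )
    cd_k: int = 1  # Gibbs steps for the contrastive-divergence reconstruction


class ForecasterParams:
    """Encoder weights plus the three conditioning affine maps.

    Initialization starts the generative model at the trivial carry-forward
    baseline: the first ``n_features`` memory cells are wired to pass the
    most recent visit through their gates, the bias network reads them back
    at the matching gain, the coupling network starts near zero and the
    precisions near one — so before any training the forecaster is an
    (approximately) unit-variance Gaussian centered on the last observation,
    and contrastive divergence refines from there instead of having to
    rediscover the carried-forward level at a small learning rate.
    """

    def __init__(
        self,
        config: ForecasterConfig,
        rng: np.random.Generator | None = None,
        init: str = "carry",
    ):
        self.config = config
        nf, H, nh = config.n_features, config.encoder_hidden, config.crbm_hidden
        self.encoder = LSTM(nf, H, rng)
        self.bias_net = Linear(H, nf, rng)
        self.precision_net = Linear(H, nf, rng)
        self.weights_net = Linear(H, nh * nf, rng)
        if rng is not None:
            # start with unit precisions: softplus(bias) = 1
            self.precision_net.bias[:] = _SOFTPLUS_INV_ONE
            if init == "carry" and H >= nf:
                self._carry_forward_init()
            elif init not in ("carry", "random"):
                raise ValueError(f"unknown init scheme {init!r}")

    def _carry_forward_init(self) -> None:
        nf, H = self.config.n_features, self.config.encoder_hidden
        gate_bias = 2.0   # per bias vector; the two biases add
        squash = 0.1      # keeps tanh in its near-linear range
        enc = self.encoder
        for j in range(nf):
            for gate, sign in (("i", 1), ("f", -1), ("o", 1)):
                row = {"i": j, "f": H + j, "o": 3 * H + j}[gate]
                enc.w_ih[row, :] = 0.0
                enc.w_hh[row, :] = 0.0
                enc.b_ih[row] = sign * gate_bias
                enc.b_hh[row] = sign * gate_bias
            grow = 2 * H + j
            enc.w_ih[grow, :] = 0.0
            enc.w_hh[grow, :] = 0.0
            enc.w_ih[grow, j] = squash
            enc.b_ih[grow] = 0.0
            enc.b_hh[grow] = 0.0
        # effective scalar response of such a cell to its input; gain fitted
        # by least squares under a standard-normal input weighting
        i_gate = 1.0 / (1.0 + np.exp(-2 * gate_bias))
        grid = np.linspace(-2.5, 2.5, 101)
        weight = np.exp(-(grid**2) / 2.0)
        response = i_gate * np.tanh(i_gate * np.tanh(squash * grid))
        gain = float(np.dot(weight * response, grid) / np.dot(weight * grid, grid))
        # bias net reads the pass-through cells back; cross terms start at 0
        self.bias_net.weight[:, :nf] = 0.0
        self.bias_net.weight[:, nf:] *= 0.1
        self.bias_net.weight[np.arange(nf), np.arange(nf)] = 1.0 / gain
        self.bias_net.bias[:] = 0.0
        # near-zero couplings: the initial model is close to independent Gaussians
        self.weights_net.weight *= 0.1
        self.weights_net.bias *= 0.1
        self.precision_net.weight[:, :nf] = 0.0

    @property
    def n_params(self) -> int:
        return (
            self.encoder.n_params
            + self.bias_net.n_params
            + self.precision_net.n_params
            + self.weights_net.n_params
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            **self.encoder.parameters("encoder"),
            **self.bias_net.parameters("bias"),
            **self.precision_net.parameters("precision"),
            **self.weights_net.parameters("weights"),
        }

    def load(self, tensors: dict[str, np.ndarray]) -> None:
        self.encoder.load("encoder", tensors)
        self.bias_net.load("bias", tensors)
        self.precision_net.load("precision", tensors)
        self.weights_net.load("weights", tensors)


@dataclass
class ForecastResult:
    """Per-horizon point forecast with a sampled trajectory ensemble.

    All values live on the transformed scale; invert with the fold's
    power-transform parameters for raw units.  ``point_forecast`` is the
    entrywise ensemble mean; the sleeves are empirical 2.5/97.5 percentiles.
    """

    point_forecast: np.ndarray       # (horizon, n_features)
    trajectory_ensemble: np.ndarray  # (n_trajectories, horizon, n_features)
    lower: np.ndarray                # (horizon, n_features)
    upper: np.ndarray                # (horizon, n_features)


def count_parameters(model_kind: str, config=None) -> int:
    """Exact trainable-scalar count for either model at the given config."""
    if model_kind == "forecaster":
        return ForecasterParams(config or ForecasterConfig()).n_params
    if model_kind == "annotator":
        from .annotator import AnnotatorConfig, AnnotatorParams

        return AnnotatorParams(config or AnnotatorConfig()).n_params
    raise ValueError(f"unknown model kind {model_kind!r}")


def encode_history(params: ForecasterParams, prefix: np.ndarray) -> np.ndarray:
    """Final encoder state after consuming the prefix in visit order."""
    prefix = np.asarray(prefix, dtype=float)
    if prefix.ndim != 2 or prefix.shape[0] < 1:
        raise ValueError("prefix must be a non-empty (visits, features) matrix")
    _, (h, _), _ = params.encoder.forward(prefix[:, None, :])
    return h[0]


def condition_crbm(params: ForecasterParams, c: np.ndarray):
    """Map encoded state(s) to CRBM parameters (b, d, W).

    Accepts a single state ``(H,)`` or a batch ``(B, H)``; returns arrays with
    the matching leading shape.  ``d`` is strictly positive by construction.
    """
    c = np.asarray(c, dtype=float)
    single = c.ndim == 1
    cb = c[None, :] if single else c
    nf, nh = params.config.n_features, params.config.crbm_hidden
    b = params.bias_net.forward(cb)
    d = softplus(params.precision_net.forward(cb))
    W = params.weights_net.forward(cb).reshape(-1, nh, nf)
    if single:
        return b[0], d[0], W[0]
    return b, d, W


def _gibbs_chains(
    b: np.ndarray,
    d: np.ndarray,
    W: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    v0: np.ndarray | None = None,
) -> np.ndarray:
    """Run one block-Gibbs chain per row of ``b`` and return the final v.

    ``b, d`` are (B, nf), ``W`` is (B, nh, nf).  Chains start at ``v0`` (the
    conditional-mean start v = b when omitted).
    """
    sqd = np.sqrt(d)
    v = b.copy() if v0 is None else v0.copy()
    for _ in range(n_steps):
        z = sqd * (v - b)
        s = np.einsum("bij,bj->bi", W, z)
        p = sigmoid(s)
        h = (rng.random(p.shape) < p).astype(float)
        mean = b + np.einsum("bij,bi->bj", W, h) / sqd
        v = mean + rng.standard_normal(v.shape) / sqd
    return v


def gibbs_sample(
    b: np.ndarray,
    d: np.ndarray,
    W: np.ndarray,
    n_samples: int,
    n_steps: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n_samples`` independent chains from the conditioned CRBM."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(d <= 0):
        raise ValueError("precision d must be strictly positive")
    rng = component_rng(seed, "gibbs")
    bb = np.tile(b, (n_samples, 1))
    dd = np.tile(d, (n_samples, 1))
    WW = np.tile(W, (n_samples, 1, 1))
    return _gibbs_chains(bb, dd, WW, n_steps, rng)


def _free_energy_grads(v, b, d, W):
    """Free energy F(v) and its gradients w.r.t. (b, d, W), batched.

    F(v) = 0.5 ||z||^2 - sum_j softplus((W z)_j),  z = sqrt(d) * (v - b).
    """
    sqd = np.sqrt(d)
    z = sqd * (v - b)
    s = np.einsum("bij,bj->bi", W, z)
    p = sigmoid(s)
    F = 0.5 * (z * z).sum(axis=1) - softplus(s).sum(axis=1)
    gz = z - np.einsum("bij,bi->bj", W, p)
    gW = -p[:, :, None] * z[:, None, :]
    gb = -gz * sqd
    gd = gz * (v - b) / (2.0 * sqd)
    return F, gb, gd, gW


def forecast_trajectories(
    params: ForecasterParams,
    prefix: np.ndarray,
    horizon: int,
    config: ForecasterConfig | None = None,
    seed: int = 0,
    n_trajectories: int | None = None,
) -> ForecastResult:
    """Sample an ensemble of multi-step trajectories and summarize it.

    Each of the ``n_trajectories`` chains repeatedly: conditions the CRBM on
    the current encoder state, draws one next visit (one chain of
    ``gibbs_steps`` alternations), feeds the sampled visit back into the
    encoder, and advances — so later steps see earlier *sampled* visits, not
    ensemble means.
    """
    config = config or params.config
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    prefix = np.asarray(prefix, dtype=float)
    if prefix.ndim != 2 or prefix.shape[0] < 1:
        raise ValueError("prefix must be a non-empty (visits, features) matrix")
    n = int(n_trajectories or config.trajectories)
    rng = component_rng(seed, "forecast")

    _, (h, cell), _ = params.encoder.forward(prefix[:, None, :])
    h = np.repeat(h, n, axis=0)
    cell = np.repeat(cell, n, axis=0)

    ensemble = np.empty((n, horizon, config.n_features))
    for step in range(horizon):
        b, d, W = condition_crbm(params, h)
        v = _gibbs_chains(b, d, W, config.gibbs_steps, rng)
        ensemble[:, step, :] = v
        h, cell = params.encoder.step(v, h, cell)

    point = ensemble.mean(axis=0)
    lower = np.percentile(ensemble, 2.5, axis=0)
    upper = np.percentile(ensemble, 97.5, axis=0)
    return ForecastResult(
        point_forecast=point, trajectory_ensemble=ensemble, lower=lower, upper=upper
    )


def baseline_forecast(
    prefix: np.ndarray, horizon: int, method: str, window: int = 3
) -> np.ndarray:
    """Naive benchmarks: repeat the last visit (LOCF) or a trailing mean (MA)."""
    prefix = np.asarray(prefix, dtype=float)
    if prefix.ndim != 2 or prefix.shape[0] < 1:
        raise ValueError("prefix must be a non-empty (visits, features) matrix")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if method == "LOCF":
        row = prefix[-1]
    elif method == "MA":
        if window > prefix.shape[0]:
            raise ValueError(
                f"MA window {window} exceeds prefix length {prefix.shape[0]}"
            )
        row = prefix[-window:].mean(axis=0)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return np.tile(row, (horizon, 1))


def _build_instances(matrices: list[np.ndarray]) -> list[tuple[int, int]]:
    """(patient index, prefix length) pairs; the target is the next visit."""
    instances = []
    for i, m in enumerate(matrices):
        for t in range(1, m.shape[0]):
            instances.append((i, t))
    return instances


def _pad_batch(matrices, instances, idx):
    """Left-padded (T, B, nf) prefix tensor, (T, B) mask, (B, nf) targets."""
    lengths = [instances[i][1] for i in idx]
    maxlen = max(lengths)
    B = len(idx)
    nf = matrices[0].shape[1]
    xs = np.zeros((maxlen, B, nf))
    mask = np.zeros((maxlen, B))
    targets = np.empty((B, nf))
    for k, i in enumerate(idx):
        pi, t = instances[i]
        xs[maxlen - t :, k, :] = matrices[pi][:t]
        mask[maxlen - t :, k] = 1.0
        targets[k] = matrices[pi][t]
    return xs, mask, targets


def train_forecaster(
    cohort_train: CohortDataset | list[np.ndarray],
    config: ForecasterConfig | None = None,
    hyper: ForecasterHyper | None = None,
    seed: int = 0,
) -> tuple[ForecasterParams, list[float]]:
    """Contrastive-divergence training on (prefix, next visit) instances.

    ``cohort_train`` must already be imputed and power-transformed; it may be
    a cohort or a bare list of (visits x features) matrices.  Returns the
    trained parameters and the per-epoch mean CD loss trace.
    """
    config = config or ForecasterConfig()
    hyper = hyper or ForecasterHyper()
    if isinstance(cohort_train, CohortDataset):
        matrices = [t.values for t in cohort_train]
    else:
        matrices = [np.asarray(m, dtype=float) for m in cohort_train]
    if any(m.shape[0] < 2 for m in matrices):
        raise ValueError("every training patient needs at least 2 visits")

    rng_init = component_rng(seed, "forecaster-init")
    rng = component_rng(seed, "forecaster-train")
    params = ForecasterParams(config, rng_init)
    tensors = params.parameters()
    opt = AdamW(tensors, lr=hyper.lr, weight_decay=hyper.weight_decay)

    instances = _build_instances(matrices)
    n = len(instances)
    loss_trace: list[float] = []
    nh, nf = config.crbm_hidden, config.n_features

    for _ in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            xs, mask, v_pos = _pad_batch(matrices, instances, idx)
            B = len(idx)

            _, (ctx, _), cache = params.encoder.forward(xs, mask)
            b = params.bias_net.forward(ctx)
            a = params.precision_net.forward(ctx)
            d = softplus(a)
            W = params.weights_net.forward(ctx).reshape(B, nh, nf)

            # CD-k reconstruction starting from the data; gradients are
            # blocked through the sampled values.
            v_neg = _gibbs_chains(b, d, W, hyper.cd_k, rng, v0=v_pos)

            F_pos, gb_p, gd_p, gW_p = _free_energy_grads(v_pos, b, d, W)
            F_neg, gb_n, gd_n, gW_n = _free_energy_grads(v_neg, b, d, W)
            # the monitored loss is the reconstruction error (the CD gap is
            # the optimized objective but is not a proper loss to track)
            epoch_loss += float(((v_pos - v_neg) ** 2).mean()) * B

            gb = (gb_p - gb_n) / B
            gd = (gd_p - gd_n) / B
            gWf = (gW_p - gW_n).reshape(B, nh * nf) / B
            ga = gd * sigmoid(a)  # through softplus

            dctx_b, dW_bias, db_bias = params.bias_net.backward(ctx, gb)
            dctx_p, dW_prec, db_prec = params.precision_net.backward(ctx, ga)
            dctx_w, dW_wts, db_wts = params.weights_net.backward(ctx, gWf)
            enc_grads = params.encoder.backward(cache, dh_last=dctx_b + dctx_p + dctx_w)

            grads = {
                **{f"encoder.{k}": v for k, v in enc_grads.items()},
                "bias.weight": dW_bias,
                "bias.bias": db_bias,
                "precision.weight": dW_prec,
                "precision.bias": db_prec,
                "weights.weight": dW_wts,
                "weights.bias": db_wts,
            }
            opt.step(grads)
        loss_trace.append(epoch_loss / n)
    return params, loss_trace
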