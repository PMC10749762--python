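"""Deep adaptation network: an MK-MMD-regularized fully connected classifier.

Cohorts ("domains") differ systematically because of diet, geography and
technical batch effects. To learn features that transfer across cohorts, a
multi-layer fully connected network is trained on the labeled source domain
with an added multiple-kernel maximum-mean-discrepancy (MK-MMD) penalty that
pulls the hidden representations of source and (unlabeled) target samples
toward the same distribution:

    loss = CE(source logits, source labels) + lambda * MMD^2(h_s^(l'), h_t^(l'))

where h^(l') are the hidden activations at the regularized layer(s). After
training, latent features h^(l) = ReLU(h^(l-1) W + b) are extracted and used
to build the inter-host similarity graph.

The MK-MMD here is a biased (V-statistic) estimator under an equal-weight
mixture of Gaussian kernels whose bandwidths are the median pairwise distance
of the pooled batch scaled by fixed multipliers. The V-statistic form makes
the estimate non-negative and exactly zero for identical inputs, and it stays
defined for a single target sample (the degenerate single-run case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, cross_entropy_and_grad, glorot_uniform, relu

DEFAULT_BANDWIDTH_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class DANConfig:
    """Training configuration for the adaptation network.

    ``layer_sizes`` are the three hidden widths; ``regularized_layers`` are the
    hidden layers (1-based) where the MK-MMD penalty is applied, defaulting to
    the last hidden layer only.
    """

    layer_sizes: tuple[int, ...] = (256, 128, 64)
    lambda_penalty: float = 0.3
    regularized_layers: tuple[int, ...] | None = None
    kernel_bandwidth_multipliers: tuple[float, ...] = DEFAULT_BANDWIDTH_MULTIPLIERS
    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 5e-2
    batch_mode: str = "full-batch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not self.layer_sizes or any(w <= 0 for w in self.layer_sizes):
            raise ValueError("layer_sizes must be positive")
        if self.regularized_layers is None:
            self.regularized_layers = (len(self.layer_sizes),)
        valid = set(range(1, len(self.layer_sizes) + 1))
        if not set(self.regularized_layers) <= valid:
            raise ValueError(f"regularized_layers must be within {sorted(valid)}")
        if any(m <= 0 for m in self.kernel_bandwidth_multipliers):
            raise ValueError("bandwidth multipliers must be positive")
        if self.batch_mode not in ("full-batch", "minibatch"):
            raise ValueError("batch_mode must be 'full-batch' or 'minibatch'")


@dataclass
class DomainPair:
    """Labeled source domain and unlabeled target domain feature matrices."""

    source_x: np.ndarray
    source_y: np.ndarray
    target_x: np.ndarray

    def __post_init__(self) -> None:
        self.source_x = np.asarray(self.source_x, dtype=float)
        self.target_x = np.asarray(self.target_x, dtype=float)
        self.source_y = np.asarray(self.source_y, dtype=int)
        if self.source_x.ndim != 2 or self.target_x.ndim != 2:
            raise ValueError("feature matrices must be 2-D")
        if self.source_x.shape[1] != self.target_x.shape[1]:
            raise ValueError("source and target feature dimensions differ")
        if self.source_y.shape != (self.source_x.shape[0],):
            raise ValueError("source labels do not match source samples")
        if len(np.unique(self.source_y)) < 2:
            raise ValueError("source domain must contain both classes")


@dataclass
class DANModel:
    """Trained adaptation network: per-layer weights/biases plus a 2-class head."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: DANConfig
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    def hidden_activations(self, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Forward through the hidden stack; returns (pre-activations, activations).

        ``activations[0]`` is the input; ``activations[l]`` is h(l).
        """
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.weights[0].shape[0]}"
            )
        pre: list[np.ndarray] = [x]
        act: list[np.ndarray] = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = h @ w + b
            h = relu(a)
            pre.append(a)
            act.append(h)
        return pre, act

    def logits(self, x: np.ndarray) -> np.ndarray:
        _, act = self.hidden_activations(x)
        return act[-1] @ self.weights[-1] + self.biases[-1]

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, n_layers=len(self.weights), **arrays)

    @classmethod
    def load(cls, path: str | Path, config: DANConfig | None = None) -> "DANModel":
        data = np.load(path)
        n = int(data["n_layers"])
        return cls(
            weights=[data[f"w{i}"] for i in range(n)],
            biases=[data[f"b{i}"] for i in range(n)],
            config=config or DANConfig(),
        )


def _pairwise_sq_dists(z: np.ndarray) -> np.ndarray:
    g = z @ z.T
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    return d2


def _mmd_and_grad(
    a: np.ndarray,
    b: np.ndarray,
    multipliers: tuple[float, ...],
    base_bandwidth: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Biased MK-MMD^2 and its gradient w.r.t. both inputs.

    With signed weights e_i = 1/n on source rows and -1/m on target rows,
    MMD^2 = e' K e over the pooled kernel matrix. Bandwidths follow the median
    heuristic (unless ``base_bandwidth`` is given) and are treated as
    constants in the gradient.
    """
    n, m = a.shape[0], b.shape[0]
    z = np.vstack([a, b])
    d2 = _pairwise_sq_dists(z)
    if base_bandwidth is not None:
        med = float(base_bandwidth)
    else:
        iu = np.triu_indices(n + m, k=1)
        med = float(np.median(np.sqrt(d2[iu]))) if len(iu[0]) else 1.0
    if not np.isfinite(med) or med <= 0.0:
        med = 1.0
    e = np.concatenate([np.full(n, 1.0 / n), np.full(m, -1.0 / m)])
    k_sum = np.zeros_like(d2)
    w_sum = np.zeros_like(d2)  # kernel / sigma^2, for the gradient
    for mult in multipliers:
        s2 = (med * mult) ** 2
        g = np.exp(-d2 / (2.0 * s2))
        k_sum += g
        w_sum += g / s2
    k_sum /= len(multipliers)
    w_sum /= len(multipliers)
    value = float(e @ k_sum @ e)
    coeff = (e[:, None] * e[None, :]) * w_sum
    grad_z = 2.0 * (coeff @ z - coeff.sum(axis=1)[:, None] * z)
    return value, grad_z[:n], grad_z[n:]


def mk_mmd(
    a: np.ndarray,
    b: np.ndarray,
    bandwidth_multipliers: tuple[float, ...] = DEFAULT_BANDWIDTH_MULTIPLIERS,
) -> float:
    """Multiple-kernel MMD^2 between two sample sets (biased V-statistic).

    Symmetric in its arguments, invariant to row permutations, zero for
    identical inputs and non-negative in general.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mk_mmd requires non-empty inputs")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("inputs must be 2-D with equal feature dimension")
    if any(m <= 0 for m in bandwidth_multipliers):
        raise ValueError("bandwidth multipliers must be positive")
    # averaging both argument orders makes the value exactly symmetric
    # (the raw estimator's summation order otherwise differs at ~1e-16)
    v_ab, _, _ = _mmd_and_grad(a, b, tuple(bandwidth_multipliers))
    v_ba, _, _ = _mmd_and_grad(b, a, tuple(bandwidth_multipliers))
    return max(0.5 * (v_ab + v_ba), 0.0)


def _init_params(
    rng: np.random.Generator, d_in: int, layer_sizes: tuple[int, ...]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    dims = [d_in, *layer_sizes, 2]
    weights = [glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    return weights, biases


def _train(
    x_s: np.ndarray,
    y_s: np.ndarray,
    x_t: np.ndarray | None,
    config: DANConfig,
) -> DANModel:
    """Shared training loop; ``x_t is None`` trains a plain classifier."""
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(rng, x_s.shape[1], tuple(config.layer_sizes))
    params = weights + biases
    opt = Adam(params, lr=config.learning_rate)
    n_hidden = len(config.layer_sizes)
    lam = config.lambda_penalty
    reg_layers = tuple(config.regularized_layers)
    log: list[dict] = []

    for epoch in range(config.epochs):
        # forward
        pre_s: list[np.ndarray] = [x_s]
        act_s: list[np.ndarray] = [x_s]
        h = x_s
        for l in range(n_hidden):
            a = h @ weights[l] + biases[l]
            h = relu(a)
            pre_s.append(a)
            act_s.append(h)
        logits = h @ weights[-1] + biases[-1]
        ce, dlogits = cross_entropy_and_grad(logits, y_s)

        mmd_total = 0.0
        dh_s = [np.zeros_like(a) for a in act_s]
        dh_t: list[np.ndarray] | None = None
        act_t: list[np.ndarray] = []
        pre_t: list[np.ndarray] = []
        if x_t is not None:
            pre_t, act_t = [x_t], [x_t]
            h_t = x_t
            for l in range(n_hidden):
                a_t = h_t @ weights[l] + biases[l]
                h_t = relu(a_t)
                pre_t.append(a_t)
                act_t.append(h_t)
            dh_t = [np.zeros_like(a) for a in act_t]
            for l in reg_layers:
                val, g_s, g_t = _mmd_and_grad(
                    act_s[l], act_t[l], tuple(config.kernel_bandwidth_multipliers)
                )
                mmd_total += val
                if lam > 0.0:
                    dh_s[l] += lam * g_s
                    dh_t[l] += lam * g_t

        loss = ce + lam * mmd_total
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        log.append({"epoch": epoch, "classification_loss": ce, "mmd": mmd_total})

        # backward (L2 weight decay on weights, not biases)
        g_w = [config.weight_decay * w for w in weights]
        g_b = [np.zeros_like(b) for b in biases]
        g_w[-1] = act_s[-1].T @ dlogits
        g_b[-1] = dlogits.sum(axis=0)
        dh_s[-1] += dlogits @ weights[-1].T
        for l in range(n_hidden, 0, -1):
            da = dh_s[l] * (pre_s[l] > 0)
            g_w[l - 1] += act_s[l - 1].T @ da
            g_b[l - 1] += da.sum(axis=0)
            if l > 1:
                dh_s[l - 1] += da @ weights[l - 1].T
        if dh_t is not None and lam > 0.0:
            for l in range(n_hidden, 0, -1):
                da = dh_t[l] * (pre_t[l] > 0)
                g_w[l - 1] += act_t[l - 1].T @ da
                g_b[l - 1] += da.sum(axis=0)
                if l > 1:
                    dh_t[l - 1] += da @ weights[l - 1].T

        opt.step(params, g_w + g_b)

    return DANModel(weights=weights, biases=biases, config=config, training_log=log)


def train_dan(pair: DomainPair, config: DANConfig | None = None) -> DANModel:
    """Train the adaptation network on a labeled source / unlabeled target pair.

    Deterministic: identical seed and inputs reproduce identical weights. With
    ``lambda_penalty == 0`` the MK-MMD term is still logged but contributes no
    gradient, so training coincides with a plain classifier.
    """
    config = config or DANConfig()
    return _train(pair.source_x, pair.source_y, pair.target_x, config)


def train_classifier(
    x: np.ndarray, y: np.ndarray, config: DANConfig | None = None
) -> DANModel:
    """Train the same architecture without any target domain or MMD term."""
    config = config or DANConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    return _train(x, y, None, config)


def extract_latent(model: DANModel, x: np.ndarray, layer: int | None = None) -> np.ndarray:
    """Latent features h(layer) from the trained network (pure function).

    ``layer`` is 1-based over hidden layers; default is the last hidden layer.
    All entries are non-negative (post-ReLU).
    """
    if layer is None:
        layer = model.n_hidden
    if not 1 <= layer <= model.n_hidden:
        raise ValueError(f"layer must be in [1, {model.n_hidden}]")
    _, act = model.hidden_activations(x)
    return act[layer]
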