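"""Semi-supervised graph convolutional classification of disease status.

Each convolution layer propagates node features through the symmetric
normalized adjacency with self-loops,

    H(l+1) = ReLU(S H(l) W(l)),    S = D^{-1/2} (A + I) D^{-1/2},

followed by a linear 2-class head. All nodes — labeled training samples and
unlabeled test samples — participate in convolution, but the cross-entropy
loss is computed over labeled (masked) nodes only, so test labels can never
leak into training.

Class convention: index 0 = health, index 1 = disease. Probability ties are
broken toward health.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, cross_entropy_and_grad, glorot_uniform, relu, softmax
from .similarity_graph import SimilarityGraph


@dataclass
class GCNConfig:
    n_layers: int = 2
    hidden_width: int = 64
    epochs: int = 200
    learning_rate: float = 1e-2
    dropout_rate: float = 0.5
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass
class GCNModel:
    """Per-layer convolution weights plus the linear output head."""

    conv_weights: list[np.ndarray]
    head_weight: np.ndarray
    head_bias: np.ndarray
    config: GCNConfig


@dataclass
class ClassificationResult:
    node_ids: list[str]
    prob_health: np.ndarray
    prob_disease: np.ndarray
    predicted_label: np.ndarray
    is_train_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.node_ids,
                "prob_disease": self.prob_disease,
                "prob_health": self.prob_health,
                "predicted_label": np.where(
                    self.predicted_label == 1, "disease", "health"
                ),
                "split": np.where(self.is_train_mask, "train", "test"),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def gcn_forward(
    graph: SimilarityGraph, node_features: np.ndarray, model: GCNModel
) -> np.ndarray:
    """Deterministic forward pass (dropout disabled); returns per-node logits."""
    x = np.asarray(node_features, dtype=float)
    if x.shape[0] != graph.n:
        raise ValueError(f"{x.shape[0]} feature rows for a {graph.n}-node graph")
    if x.shape[1] != model.conv_weights[0].shape[0]:
        raise ValueError("feature dimension does not match model")
    s = graph.norm_operator
    h = x
    for w in model.conv_weights:
        h = relu(s @ h @ w)
    return h @ model.head_weight + model.head_bias


def _probabilities(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = softmax(logits)
    return p[:, 0], p[:, 1]


def predict(
    model: GCNModel, graph: SimilarityGraph, node_features: np.ndarray,
    is_train_mask: np.ndarray | None = None,
) -> ClassificationResult:
    """Class probabilities for every node; argmax label, ties toward health."""
    logits = gcn_forward(graph, node_features, model)
    p_health, p_disease = _probabilities(logits)
    if is_train_mask is None:
        is_train_mask = np.zeros(graph.n, dtype=bool)
    return ClassificationResult(
        node_ids=list(graph.node_order),
        prob_health=p_health,
        prob_disease=p_disease,
        predicted_label=(p_disease > p_health).astype(int),
        is_train_mask=np.asarray(is_train_mask, dtype=bool),
    )


def train_gcn(
    graph: SimilarityGraph,
    node_features: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    config: GCNConfig | None = None,
) -> tuple[GCNModel, ClassificationResult]:
    """Train the GCN with a masked cross-entropy loss.

    ``labels`` entries outside ``train_mask`` are never read (entries may be
    any placeholder); unlabeled node *features* still participate in every
    convolution. Seeded training is fully deterministic.
    """
    config = config or GCNConfig()
    x = np.asarray(node_features, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool)
    if x.shape[0] != graph.n or train_mask.shape != (graph.n,):
        raise ValueError("features / mask do not match the graph")
    # copy the masked labels immediately: unlabeled entries must not influence anything
    y_masked = np.asarray(labels)[train_mask].astype(int)
    if y_masked.size == 0 or len(np.unique(y_masked)) < 2:
        raise ValueError("train_mask must cover at least one node of each class")

    rng = np.random.default_rng(config.seed)
    dims = [x.shape[1]] + [config.hidden_width] * config.n_layers
    conv_w = [glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(config.n_layers)]
    head_w = glorot_uniform(rng, dims[-1], 2)
    head_b = np.zeros(2)
    params = conv_w + [head_w, head_b]
    opt = Adam(params, lr=config.learning_rate)
    s = graph.norm_operator
    keep = 1.0 - config.dropout_rate

    for epoch in range(config.epochs):
        # forward with dropout on hidden activations
        h = x
        cache = []  # (input to layer, S @ input, pre-activation, dropout mask)
        for w in conv_w:
            sh = s @ h
            a = sh @ w
            act = relu(a)
            if config.dropout_rate > 0.0:
                mask = (rng.random(act.shape) < keep) / keep
                act = act * mask
            else:
                mask = None
            cache.append((sh, a, mask))
            h = act
        logits = h @ head_w + head_b
        loss, dlogits_full = cross_entropy_and_grad(logits[train_mask], y_masked)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        dlogits = np.zeros_like(logits)
        dlogits[train_mask] = dlogits_full

        g_head_w = h.T @ dlogits + config.weight_decay * head_w
        g_head_b = dlogits.sum(axis=0)
        dh = dlogits @ head_w.T
        g_conv = [None] * config.n_layers
        for l in range(config.n_layers - 1, -1, -1):
            sh, a, mask = cache[l]
            if mask is not None:
                dh = dh * mask
            da = dh * (a > 0)
            g_conv[l] = sh.T @ da + config.weight_decay * conv_w[l]
            if l > 0:
                dh = s @ (da @ conv_w[l].T)  # S is symmetric
        opt.step(params, g_conv + [g_head_w, g_head_b])

    model = GCNModel(
        conv_weights=conv_w, head_weight=head_w, head_bias=head_b, config=config
    )
    result = predict(model, graph, x, is_train_mask=train_mask)
    return model, result
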