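"""End-to-end orchestration: batch and single-sample classification runs.

A batch run takes labeled training samples and a label-blinded test set and
executes: feature alignment -> log10 + train-statistics z-score -> adaptation
network (train = source, test = target) -> latent extraction -> kNN similarity
graph over all samples -> semi-supervised GCN (loss on training nodes only)
-> per-node class probabilities. A single run is the same computation with a
one-sample test set; the MK-MMD term remains defined for a single target
point under the V-statistic estimator, but is a degenerate estimate (a warning
is logged, and adaptation can be disabled via ``lambda_penalty = 0``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_io
from .data_io import AbundanceMatrix, NormalizationStats
from .domain_adaptation import DANConfig, DANModel, DomainPair, extract_latent, train_dan
from .gcn_classifier import ClassificationResult, GCNConfig, GCNModel, train_gcn
from .similarity_graph import SimilarityGraph, build_graph

logger = logging.getLogger(__name__)


def derive_seed(base: int, stream: int) -> int:
    """Deterministic child seed below 2**31."""
    return int((base * 1000003 + stream * 7919 + 17) % (2**31 - 1))


@dataclass
class RunConfig:
    mode: str = "batch_run"
    k_neighbors: int = 5
    dan: DANConfig = field(default_factory=DANConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    pseudocount: float = 1e-5
    extract_layer: int | None = None  # default: last hidden layer
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("batch_run", "single_run"):
            raise ValueError("mode must be 'batch_run' or 'single_run'")
        if self.k_neighbors <= 0:
            raise ValueError("k_neighbors must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "dan" in d and isinstance(d["dan"], dict):
            dan = dict(d["dan"])
            for key in ("layer_sizes", "regularized_layers", "kernel_bandwidth_multipliers"):
                if key in dan and dan[key] is not None:
                    dan[key] = tuple(dan[key])
            d["dan"] = DANConfig(**dan)
        if "gcn" in d and isinstance(d["gcn"], dict):
            d["gcn"] = GCNConfig(**d["gcn"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BatchRunResult:
    """Everything a batch run produced, kept for inspection and biomarker analysis."""

    result: ClassificationResult
    graph: SimilarityGraph
    gcn_model: GCNModel
    dan_model: DANModel
    node_features: np.ndarray  # normalized features in node order (train, then test)
    raw_values: np.ndarray  # aligned raw abundances in node order
    taxa: list[str]
    stats: NormalizationStats
    train_mask: np.ndarray
    train_labels: np.ndarray  # labels of training nodes (node order restricted to mask)
    config: RunConfig

    @property
    def test_prob_disease(self) -> np.ndarray:
        return self.result.prob_disease[~self.train_mask]


def _require_labeled(train: AbundanceMatrix) -> np.ndarray:
    if train.label is None or not np.all(train.labeled_mask):
        raise ValueError("stage data_io: training samples must all be labeled")
    y = train.label.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("stage data_io: training data must contain both classes")
    return y


def run_batch(
    train: AbundanceMatrix, test: AbundanceMatrix, config: RunConfig | None = None
) -> BatchRunResult:
    """Classify a test set against a labeled training set (batch_run strategy).

    Test labels, if present on ``test``, are ignored entirely.
    """
    config = config or RunConfig()
    y = _require_labeled(train)

    # --- normalization (train statistics only) ---
    train_al, test_al = data_io.align_features(train, test)
    x_tr, x_te, stats = data_io.normalize_fit_apply(
        train_al, test_al, config.pseudocount
    )

    # --- adaptation network: source = train, target = test ---
    dan_cfg = dataclasses.replace(config.dan, seed=derive_seed(config.seed, 0))
    if test.n_samples == 1 and dan_cfg.lambda_penalty > 0:
        logger.warning(
            "single-sample target domain: MK-MMD estimate is degenerate "
            "(set lambda_penalty=0 to disable adaptation in single mode)"
        )
    dan_model = train_dan(DomainPair(x_tr, y, x_te), dan_cfg)
    layer = config.extract_layer
    lat_tr = extract_latent(dan_model, x_tr, layer)
    lat_te = extract_latent(dan_model, x_te, layer)

    # --- similarity graph over all samples (train first, then test) ---
    node_order = list(train_al.sample_ids) + list(test_al.sample_ids)
    graph = build_graph(lat_tr, lat_te, config.k_neighbors, node_order=node_order)

    # --- semi-supervised GCN on normalized abundance node features ---
    node_features = np.vstack([x_tr, x_te])
    train_mask = np.zeros(graph.n, dtype=bool)
    train_mask[: train.n_samples] = True
    labels_full = np.full(graph.n, -1, dtype=int)
    labels_full[train_mask] = y
    gcn_cfg = dataclasses.replace(config.gcn, seed=derive_seed(config.seed, 1))
    gcn_model, result = train_gcn(graph, node_features, labels_full, train_mask, gcn_cfg)

    out = BatchRunResult(
        result=result,
        graph=graph,
        gcn_model=gcn_model,
        dan_model=dan_model,
        node_features=node_features,
        raw_values=np.vstack([train_al.values, test_al.values]),
        taxa=list(train_al.taxa),
        stats=stats,
        train_mask=train_mask,
        train_labels=y,
        config=config,
    )
    if config.outdir is not None:
        _write_artifacts(out)
    return out


def run_single(
    train: AbundanceMatrix, one_sample: AbundanceMatrix, config: RunConfig | None = None
) -> BatchRunResult:
    """Classify exactly one sample (single_run strategy).

    Identical to a batch run with a one-sample test set by construction.
    """
    if one_sample.n_samples != 1:
        raise ValueError(
            f"single_run takes exactly 1 test sample, got {one_sample.n_samples}"
        )
    config = config or RunConfig(mode="single_run")
    return run_batch(train, one_sample, config)


def _write_artifacts(res: BatchRunResult) -> None:
    outdir = Path(res.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.result.write_tsv(outdir / "predictions.tsv")
    res.graph.write_edge_list(outdir / "graph_edges.tsv")
    res.stats.save(outdir / "normalization_stats.tsv")
    np.savetxt(
        outdir / "node_features_normalized.tsv",
        res.node_features,
        delimiter="\t",
        fmt="%.10g",
        header="\t".join(res.taxa),
    )
    manifest = {
        "config": res.config.to_dict(),
        "config_hash": res.config.config_hash(),
        "seeds": {
            "base": res.config.seed,
            "dan": derive_seed(res.config.seed, 0),
            "gcn": derive_seed(res.config.seed, 1),
        },
        "n_train": int(res.train_mask.sum()),
        "n_test": int((~res.train_mask).sum()),
        "n_taxa": len(res.taxa),
        "k_neighbors": res.config.k_neighbors,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def pipeline_predict_fn(config: RunConfig):
    """Adapter for the evaluation harnesses: (train, test, seed) -> P(disease)."""

    def _fn(train: AbundanceMatrix, test: AbundanceMatrix, seed: int) -> np.ndarray:
        cfg = dataclasses.replace(config, seed=seed, outdir=None)
        return run_batch(train, test, cfg).test_prob_disease

    return _fn
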