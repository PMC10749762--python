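"""Biomarker discovery and contribution analysis.

Two complementary analyses:

* **Performance-based ranking** — with the similarity graph held fixed, the
  GCN is retrained once per species using that species' (normalized) abundance
  as the *only* node feature; each species is ranked by the training-data AUC
  it achieves alone. Species that alone support good classification are
  candidate biomarkers.

* **Contribution scores** — for each identified biomarker and each correctly
  predicted training sample, the biomarker's *raw* abundance is perturbed by
  within-sample substitution rules (Max2Median, Max2Min, Middle2Max,
  Middle2Min, Min2Max, Min2Median; exactly two rules apply depending on
  whether the biomarker holds the sample's maximum, minimum, or an in-between
  abundance). After re-normalizing with the frozen training statistics and
  re-running GCN inference (graph topology unchanged), the absolute change in
  the predicted health probability is the contribution value. Values accrue
  to one of four contribution types — Increase2Disease, Increase2Health,
  Decrease2Disease, Decrease2Health — according to whether the rule raised or
  lowered the abundance and whether the health probability fell or rose, and
  each type's score is the mean value over the n correctly predicted samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, log10_transform, zscore_apply, zscore_fit
from .domain_adaptation import DANConfig, extract_latent, train_classifier
from .evaluation import auc
from .gcn_classifier import GCNConfig, gcn_forward, train_gcn
from .pipeline import BatchRunResult, derive_seed
from .similarity_graph import build_graph

CONTRIBUTION_TYPES = (
    "Increase2Disease",
    "Increase2Health",
    "Decrease2Disease",
    "Decrease2Health",
)


class ModificationRule(Enum):
    """Within-sample raw-abundance substitution rules."""

    MAX2MEDIAN = ("max", "median")
    MAX2MIN = ("max", "min")
    MIDDLE2MAX = ("middle", "max")
    MIDDLE2MIN = ("middle", "min")
    MIN2MAX = ("min", "max")
    MIN2MEDIAN = ("min", "median")

    @property
    def applicability(self) -> str:
        """Which within-sample abundance rank the biomarker must hold."""
        return self.value[0]

    @property
    def replacement(self) -> str:
        """Target statistic of the sample's abundances."""
        return self.value[1]

    @property
    def increases(self) -> bool:
        """Whether the rule moves the abundance up (Min2*, Middle2Max)."""
        return self in (
            ModificationRule.MIN2MAX,
            ModificationRule.MIN2MEDIAN,
            ModificationRule.MIDDLE2MAX,
        )


@dataclass
class BiomarkerRanking:
    taxon: str
    auc: float
    rank: int


@dataclass
class ContributionReport:
    taxon: str
    scores: dict[str, float]
    n_samples_used: int
    per_sample_values: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def _rule_applies(abundances: np.ndarray, taxon_index: int, rule: ModificationRule) -> bool:
    v = abundances[taxon_index]
    hi, lo = abundances.max(), abundances.min()
    if rule.applicability == "max":
        return v == hi
    if rule.applicability == "min":
        return v == lo
    return v != hi and v != lo


def applicable_rules(
    abundances: np.ndarray, taxon_index: int
) -> tuple[ModificationRule, ModificationRule]:
    """The two rules applying to this (sample, biomarker) pair.

    Determined by the biomarker's within-sample abundance rank; if the sample
    has constant abundances the taxon is simultaneously maximum and minimum
    and the maximum pair is returned (all substitutions are then no-ops).
    """
    abundances = np.asarray(abundances, dtype=float)
    if not 0 <= taxon_index < abundances.size:
        raise ValueError(f"taxon index {taxon_index} out of range")
    v = abundances[taxon_index]
    if v == abundances.max():
        return (ModificationRule.MAX2MEDIAN, ModificationRule.MAX2MIN)
    if v == abundances.min():
        return (ModificationRule.MIN2MAX, ModificationRule.MIN2MEDIAN)
    return (ModificationRule.MIDDLE2MAX, ModificationRule.MIDDLE2MIN)


def modify_abundance(
    abundances: np.ndarray, taxon_index: int, rule: ModificationRule
) -> np.ndarray:
    """Replace the biomarker's raw abundance per the rule; other taxa untouched.

    The replacement statistic (max/median/min) is computed over all species
    abundances of the sample, including the biomarker's current value.
    """
    abundances = np.asarray(abundances, dtype=float)
    if not _rule_applies(abundances, taxon_index, rule):
        raise ValueError(
            f"rule {rule.name} not applicable: taxon does not hold the "
            f"{rule.applicability} abundance of this sample"
        )
    stat = {"max": np.max, "median": np.median, "min": np.min}[rule.replacement]
    out = abundances.copy()
    out[taxon_index] = stat(abundances)
    return out


def classify_change(p_health_before: float, p_health_after: float) -> tuple[float, str | None]:
    """Contribution value |delta P(health)| and the direction of the change."""
    value = abs(p_health_after - p_health_before)
    if p_health_after < p_health_before:
        return value, "toward_disease"
    if p_health_after > p_health_before:
        return value, "toward_health"
    return 0.0, None


def contribution_value(
    ctx: BatchRunResult, node_index: int, taxon: str, rule: ModificationRule
) -> tuple[float, str | None]:
    """Probability shift caused by one abundance modification of one sample.

    The raw abundance is modified, re-normalized with the frozen training
    statistics, and GCN inference is re-run with the graph topology held
    fixed; only the queried node's feature row changes.
    """
    j = ctx.taxa.index(taxon)
    modified_raw = modify_abundance(ctx.raw_values[node_index], j, rule)
    logged = log10_transform(modified_raw[None, :], ctx.stats.pseudocount)
    new_row = zscore_apply(logged, ctx.stats)[0]
    features = ctx.node_features.copy()
    features[node_index] = new_row
    logits = gcn_forward(ctx.graph, features, ctx.gcn_model)
    z = logits[node_index] - logits[node_index].max()
    e = np.exp(z)
    p_health_after = float(e[0] / e.sum())
    return classify_change(float(ctx.result.prob_health[node_index]), p_health_after)


def _correct_training_nodes(ctx: BatchRunResult) -> np.ndarray:
    n_train = int(ctx.train_mask.sum())
    predicted = ctx.result.predicted_label[:n_train]
    return np.flatnonzero(predicted == ctx.train_labels)


def contribution_scores(
    ctx: BatchRunResult, biomarkers: list[str]
) -> list[ContributionReport]:
    """Four contribution-type scores per biomarker over correctly predicted samples.

    For every correctly predicted training sample, each biomarker's two
    applicable rules are applied; each outcome accrues to the contribution
    type given by the rule's abundance direction and the sign of the
    probability change. Scores are means over all n such samples (samples
    contributing nothing to a type still count in the denominator).
    """
    correct = _correct_training_nodes(ctx)
    n = correct.size
    if n == 0:
        raise ValueError("no correctly predicted training samples")
    missing = [t for t in biomarkers if t not in ctx.taxa]
    if missing:
        raise ValueError(f"unknown taxa: {missing}")

    reports = []
    for taxon in biomarkers:
        j = ctx.taxa.index(taxon)
        per_sample: dict[str, list[tuple[str, float]]] = {
            t: [] for t in CONTRIBUTION_TYPES
        }
        for idx in correct:
            for rule in applicable_rules(ctx.raw_values[idx], j):
                value, direction = contribution_value(ctx, int(idx), taxon, rule)
                if direction is None:
                    continue
                kind = "Increase" if rule.increases else "Decrease"
                target = "Disease" if direction == "toward_disease" else "Health"
                per_sample[f"{kind}2{target}"].append(
                    (ctx.graph.node_order[idx], value)
                )
        scores = {
            t: float(sum(v for _, v in per_sample[t]) / n) for t in CONTRIBUTION_TYPES
        }
        reports.append(
            ContributionReport(
                taxon=taxon, scores=scores, n_samples_used=n, per_sample_values=per_sample
            )
        )
    return reports


def rank_species_by_auc(
    train: AbundanceMatrix,
    k_neighbors: int = 5,
    dan_config: DANConfig | None = None,
    gcn_config: GCNConfig | None = None,
    pseudocount: float = 1e-5,
    seed: int = 0,
) -> list[BiomarkerRanking]:
    """Rank every species by the training AUC it attains as the sole node feature.

    The similarity graph is built once, from the latent space of a classifier
    trained on the full feature set of the training data (no target domain
    exists in this train-only setting, so no adaptation term applies), and
    held fixed across the per-species GCN runs. Descending AUC; ties share a
    dense rank and are listed in lexicographic taxon order.
    """
    if train.label is None or not np.all(train.labeled_mask):
        raise ValueError("ranking requires fully labeled training data")
    y = train.label.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    logged = log10_transform(train, pseudocount)
    stats = zscore_fit(logged, pseudocount)
    x = zscore_apply(logged, stats)

    dan_cfg = dataclasses.replace(
        dan_config or DANConfig(), seed=derive_seed(seed, 0), lambda_penalty=0.0
    )
    net = train_classifier(x, y, dan_cfg)
    latent = extract_latent(net, x)
    graph = build_graph(
        latent, np.empty((0, latent.shape[1])), k_neighbors, node_order=train.sample_ids
    )

    gcn_cfg = dataclasses.replace(
        gcn_config or GCNConfig(hidden_width=32, epochs=100),
        seed=derive_seed(seed, 1),
    )
    mask = np.ones(train.n_samples, dtype=bool)
    aucs = []
    for j, taxon in enumerate(train.taxa):
        _, res = train_gcn(graph, x[:, [j]], y, mask, gcn_cfg)
        aucs.append((taxon, auc(res.prob_disease, y)))

    order = sorted(aucs, key=lambda t: (-t[1], t[0]))
    rankings, rank, prev = [], 0, None
    for taxon, a in order:
        if a != prev:
            rank += 1
            prev = a
        rankings.append(BiomarkerRanking(taxon=taxon, auc=a, rank=rank))
    return rankings


def write_ranking_tsv(rankings: list[BiomarkerRanking], path: str | Path) -> None:
    pd.DataFrame(
        [(r.taxon, r.auc, r.rank) for r in rankings], columns=["taxon", "auc", "rank"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_contribution_tsv(reports: list[ContributionReport], path: str | Path) -> None:
    rows = [
        {"taxon": r.taxon, **r.scores, "n_samples_used": r.n_samples_used}
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
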