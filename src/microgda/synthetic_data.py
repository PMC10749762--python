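"""Multi-cohort synthetic compositional microbiome data.

Emulates the structure of multi-study case/control collections: per-taxon
log-normal base abundances shared across cohorts, planted disease-associated
taxa whose log10 abundance is shifted up (promoters) or down (protectors) in
case samples, per-cohort additive log-scale offsets mimicking study-level
batch/dietary effects, per-sample noise, and compositional closure (each
sample's abundances renormalized to sum to 1).

Defaults model a shotgun-profile collection with a clearly separable planted
signal: abundance base means spanning orders of magnitude (sd 1.5 on the
log10 scale), between-subject biological variation of 0.5 log10 units plus
0.2 units of measurement noise, planted effects of 1 log10 unit (comparable
to reported fold changes of established disease markers), and cohort offsets
larger than biological variation (sd 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AbundanceMatrix


@dataclass
class SynthConfig:
    n_taxa: int = 100
    n_samples_per_cohort: int = 100
    n_cohorts: int = 3
    #: (taxon index, 'promote' | 'protect', log10-fold effect size in cases)
    planted_taxa: tuple[tuple[int, str, float], ...] = (
        (0, "promote", 1.0),
        (1, "promote", 1.0),
        (2, "promote", 1.0),
        (3, "protect", 1.0),
        (4, "protect", 1.0),
    )
    base_log_mean_sd: float = 1.5
    base_log_sd: float = 0.5
    domain_shift: float = 0.7
    noise_sd: float = 0.2
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_taxa <= 0 or self.n_samples_per_cohort <= 0 or self.n_cohorts <= 0:
            raise ValueError("sizes must be positive")
        for idx, direction, effect in self.planted_taxa:
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"planted taxon index {idx} out of range")
            if direction not in ("promote", "protect"):
                raise ValueError(f"unknown effect direction {direction!r}")
            if effect < 0:
                raise ValueError("effect sizes must be non-negative")
        if self.domain_shift < 0 or self.noise_sd < 0 or self.base_log_sd < 0:
            raise ValueError("spread parameters must be non-negative")

    @property
    def planted_indices(self) -> list[int]:
        return [idx for idx, _, _ in self.planted_taxa]


def _base_means(config: SynthConfig) -> np.ndarray:
    """Per-taxon base log10 means, shared by all cohorts (seed-determined)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    return rng.normal(0.0, config.base_log_mean_sd, size=config.n_taxa)


def _cohort_offsets(config: SynthConfig, cohort_index: int) -> np.ndarray:
    """Per-taxon additive log-scale offsets for one cohort."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11, cohort_index])
    )
    return rng.normal(0.0, config.domain_shift, size=config.n_taxa) if config.domain_shift > 0 else np.zeros(config.n_taxa)


def generate_cohort(config: SynthConfig, cohort_index: int) -> AbundanceMatrix:
    """One cohort of labeled compositional samples, fully seed-determined."""
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} out of range")
    n, p = config.n_samples_per_cohort, config.n_taxa
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, cohort_index]))

    n_cases = int(round(n * config.case_fraction))
    labels = np.zeros(n)
    labels[:n_cases] = 1.0
    rng.shuffle(labels)

    log_ab = _base_means(config) + rng.normal(0.0, config.base_log_sd, size=(n, p))
    log_ab += _cohort_offsets(config, cohort_index)
    if config.noise_sd > 0:
        log_ab += rng.normal(0.0, config.noise_sd, size=(n, p))
    cases = labels == 1.0
    for idx, direction, effect in config.planted_taxa:
        sign = 1.0 if direction == "promote" else -1.0
        log_ab[cases, idx] += sign * effect

    values = np.power(10.0, log_ab)
    values /= values.sum(axis=1, keepdims=True)  # compositional closure

    return AbundanceMatrix(
        sample_ids=[f"c{cohort_index}_s{j:04d}" for j in range(n)],
        taxa=[f"sp_{t:04d}" for t in range(p)],
        values=values,
        cohort=[f"cohort{cohort_index}"] * n,
        label=labels,
    )


def generate_multidomain(config: SynthConfig) -> list[AbundanceMatrix]:
    """All cohorts of the study design; shared planted effects, distinct shifts."""
    if config.n_cohorts < 2:
        raise ValueError("need at least 2 cohorts")
    return [generate_cohort(config, c) for c in range(config.n_cohorts)]


def standard_config(seed: int = 0, **overrides) -> SynthConfig:
    """The standard fixture design: 3 cohorts x 100 samples x 100 taxa, 5 planted taxa."""
    return SynthConfig(seed=seed, **overrides)
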