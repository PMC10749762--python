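import dataclasses

import numpy as np
import pytest

import microgda as mg
from microgda.data_io import concat_samples
from microgda.evaluation import auc


def fast_run_config(seed: int = 0, lam: float | None = None, **kwargs) -> mg.RunConfig:
    """Reduced-size run configuration for mechanical (non-performance) tests."""
    dan = mg.DANConfig(layer_sizes=(32, 16, 8), epochs=80)
    if lam is not None:
        dan = dataclasses.replace(dan, lambda_penalty=lam)
    gcn = mg.GCNConfig(hidden_width=16, epochs=80)
    return mg.RunConfig(seed=seed, dan=dan, gcn=gcn, **kwargs)


@pytest.fixture(scope="session")
def small_multidomain():
    """Two small cohorts with a strong planted signal, for mechanical tests."""
    cfg = mg.SynthConfig(
        n_taxa=40,
        n_samples_per_cohort=40,
        n_cohorts=2,
        planted_taxa=(
            (0, "promote", 1.5),
            (1, "promote", 1.5),
            (2, "protect", 1.5),
        ),
        seed=11,
    )
    return cfg, mg.generate_multidomain(cfg)


@pytest.fixture(scope="session")
def small_batch_run(small_multidomain):
    """One completed batch run on the small fixture (train cohort 0, test cohort 1)."""
    _, cohorts = small_multidomain
    return mg.run_batch(cohorts[0], cohorts[1], fast_run_config(seed=5))


@pytest.fixture(scope="session")
def loso_auc_table():
    """Held-out-cohort AUCs on the standard fixture across effect sizes and seeds.

    Train on cohorts 0+1, test on cohort 2, with adaptation at the default
    penalty and (for effect 1.0) with adaptation disabled. Computed once per
    session; shared by the end-to-end and ablation tests.
    """
    table = {}
    base_planted = mg.SynthConfig().planted_taxa
    for effect in (0.0, 0.5, 1.0, 2.0):
        planted = tuple((i, d, effect) for i, d, _ in base_planted)
        for seed in range(10):
            cfg = mg.SynthConfig(seed=seed, planted_taxa=planted)
            cohorts = mg.generate_multidomain(cfg)
            train = concat_samples(cohorts[:2])
            test = cohorts[2]
            rc = mg.RunConfig(seed=seed + 100)
            table[(effect, seed, "adapt")] = auc(
                mg.run_batch(train, test, rc).test_prob_disease, test.label
            )
            if effect == 1.0:
                rc0 = dataclasses.replace(
                    rc, dan=dataclasses.replace(rc.dan, lambda_penalty=0.0)
                )
                table[(effect, seed, "noadapt")] = auc(
                    mg.run_batch(train, test, rc0).test_prob_disease, test.label
                )
    return table
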