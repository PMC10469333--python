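"""Shared fixtures.

Two tiers: a tiny regulome (seconds) for unit/integration tests, and the
default desk-scale regulome with fully trained models (minutes, session-
scoped, built once) for the benchmark-style acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from edscan import enhancer_model as em
from edscan import synthetic_regulome as sr


TINY_CONFIG = dict(
    n_chromosomes=3,
    chromosome_length=60_000,
    n_enhancers=12,
    n_signals=4,
    n_tf_tracks=3,
    n_decoys_per_track=6,
    snps_per_signal=(2, 4),
    seed=7,
)

TRAIN_SEED = 1
STRIDE = 200
HOLDOUT = ("chr4",)
VALIDATION = "chr3"
P1_CONFIG = {"epochs": 70, "patience": 15}


@pytest.fixture(scope="session")
def tiny_regulome():
    cfg = sr.RegulomeConfig(**TINY_CONFIG)
    genome, truth = sr.generate_regulome(cfg)
    truth = sr.generate_snps_and_credible_sets(cfg, genome, truth)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def default_regulome():
    cfg = sr.RegulomeConfig(seed=1)
    genome, truth = sr.generate_regulome(cfg)
    truth = sr.generate_snps_and_credible_sets(cfg, genome, truth)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def phase1_dataset(default_regulome):
    _, genome, truth = default_regulome
    return em.make_phase1_dataset(
        genome, truth.tracks, stride=STRIDE,
        holdout_chroms=HOLDOUT, validation_chrom=VALIDATION,
    )


@pytest.fixture(scope="session")
def trained_models(default_regulome, phase1_dataset):
    """Phase-1 + phase-2 models trained once on the default regulome."""
    _, genome, truth = default_regulome
    p1 = em.train_phase1(phase1_dataset, config=dict(P1_CONFIG), seed=TRAIN_SEED)
    enhancers = em.call_enhancers(
        truth.tracks[sr.H3K27AC], truth.tracks[sr.ACCESSIBILITY], genome
    )
    p2_dataset = em.make_phase2_dataset(p1, enhancers, genome, seed=TRAIN_SEED)
    p2 = em.train_phase2(p1, enhancers, genome, seed=TRAIN_SEED, dataset=p2_dataset)
    return {
        "phase1": p1,
        "phase2": p2,
        "enhancers": enhancers,
        "p2_dataset": p2_dataset,
        "oracle": em.EnhancerOracle(p1, p2),
    }


@pytest.fixture(scope="session")
def ed_profiles(default_regulome, trained_models):
    """Saturated-mutagenesis profiles over 40 called enhancer windows."""
    from edscan import saturated_mutagenesis as sm

    _, genome, _ = default_regulome
    oracle = trained_models["oracle"]
    intervals = trained_models["enhancers"].intervals
    # spread the selection across chromosomes so region-level models keep a
    # holdout split
    take = np.linspace(0, len(intervals) - 1, 40).round().astype(int)
    windows = [intervals[i] for i in take]
    return [sm.saturated_mutagenesis(oracle, genome, iv) for iv in windows]


@pytest.fixture(scope="session")
def iep_score_table(default_regulome, trained_models):
    from edscan import snp_perturbation as sp

    _, genome, truth = default_regulome
    return sp.score_snp_catalog(trained_models["oracle"], genome, truth.snps)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
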