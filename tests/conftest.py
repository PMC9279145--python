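"""Shared fixtures: tiny genomes, synthetic cohorts and a trained
miniature model (session-scoped, reused by the expensive acceptance
tests)."""

from __future__ import annotations

import numpy as np
import pytest

from seqclass import synthetic
from seqclass.chromnet import (
    ModelConfig,
    Partition,
    TrainConfig,
    build_model,
    train,
)
from seqclass.formats import GenomeSequence

#: Miniature architecture for the planted-motif cohort: 384-bp windows,
#: pooled to 24 spatial bins with an 8-df spline basis.
MINI_MODEL = dict(
    seq_len=384,
    channels=32,
    stem_kernel=11,
    n_dual_blocks=2,
    dual_kernel=5,
    pool_factors=(4, 4),
    dilations=(2, 4),
    dilated_kernel=3,
    n_spatial_bins=24,
    spline_df=8,
    hidden=64,
)


@pytest.fixture(scope="session")
def mini_model_kwargs() -> dict:
    return dict(MINI_MODEL)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_genome() -> GenomeSequence:
    return GenomeSequence(
        {
            "c1": "ACGTACGTAC",  # length 10
            "c2": "GGGNNNN",  # length 7, with Ns
        }
    )


@pytest.fixture(scope="session")
def cohort() -> synthetic.SyntheticCohort:
    """Motif-driven cohort: 4 contigs (2 train / 1 val / 1 test), 2 cell
    types, 18 profiles. Contigs are larger than the nominal 50 kb so that
    motif learning, not landscape memorization, is the optimal strategy
    (see the decisions ledger)."""
    grammar = synthetic.default_grammar(n_cell_types=2, seed=1)
    genome, elements = synthetic.gen_genome(
        4, 150_000, seed=2, grammar=grammar, elements_per_contig=120, margin=500
    )
    profiles = synthetic.gen_profiles(
        genome, grammar, elements, n_profiles_per_type=3, seed=3
    )
    return synthetic.SyntheticCohort(
        genome=genome, grammar=grammar, elements=elements, profiles=profiles
    )


@pytest.fixture(scope="session")
def partition(cohort) -> Partition:
    return Partition(("chr1", "chr2"), ("chr3",), ("chr4",))


@pytest.fixture(scope="session")
def trained_model(cohort, partition):
    """Miniature model trained on the planted-motif cohort; shared by the
    training-recovery and directional-effect acceptance tests (the single
    most expensive fixture in the suite, ~6 min on one CPU)."""
    config = ModelConfig(n_targets=len(cohort.profiles), init_seed=0, **MINI_MODEL)
    model = build_model(config)
    train(
        model,
        cohort.genome,
        cohort.profiles,
        partition,
        TrainConfig(
            n_steps=3000,
            batch_size=64,
            optimizer="adam",
            lr=1e-3,
            lr_decay=0.3,
            lr_decay_interval=2400,
            seed=0,
            val_interval=250,
            n_val_samples=384,
        ),
    )
    return model
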