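"""Shared fixtures: generated worlds and trained models, session-scoped.

Everything is generated programmatically at test time; the heavier artifacts
(the default world, the trained fusion network, the zero-shot benchmark runs)
are computed once per session and shared by the tests that inspect them.
"""

import dataclasses

import numpy as np
import pytest

from assaymatch import WorldConfig, generate_world, train_bt
from assaymatch.cli_io import BENCH_BT_CONFIG, run_zero_shot_benchmark
from assaymatch.synthetic_world import zero_shot_split


@pytest.fixture(scope="session")
def small_world():
    """A compact world for fast structural tests."""
    return generate_world(WorldConfig(seed=11, n_assays=24, mols_per_assay=40))


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions (240 assays, 80 held out)."""
    return generate_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_world_arrays(default_world):
    train_pairs, heldout_pairs = zero_shot_split(default_world)
    return {
        "train": default_world.pair_arrays(train_pairs),
        "heldout": default_world.pair_arrays(heldout_pairs),
    }


@pytest.fixture(scope="session")
def trained_bt(default_world_arrays):
    """Fusion network trained once on the default world's training assays."""
    return train_bt(
        default_world_arrays["train"], dataclasses.replace(BENCH_BT_CONFIG, seed=7)
    )


@pytest.fixture(scope="session")
def bench_fused(default_world):
    """Zero-shot benchmark of the full pipeline on the default world."""
    return run_zero_shot_benchmark(default_world, n_replicates=3, seed=1)


@pytest.fixture(scope="session")
def bench_fp_only(default_world):
    """Same benchmark with the fingerprint-only (no-text) ablation."""
    return run_zero_shot_benchmark(
        default_world, n_replicates=3, seed=1, fingerprint_only=True
    )
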