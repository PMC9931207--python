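"""Shared fixtures: calibrated motifs, toy scorers and the trained tiny CNN.

The CNN training fixtures are session-scoped because training, although
scaled down, dominates suite runtime; every test that needs a trained model
shares one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from enhancergain.cnn import ModelConfig, train
from enhancergain.motifs import PWMScorer, pwm_from_consensus
from enhancergain.simulate import SimConfig, default_activator_pwm, random_sequence

CHROMS = [f"chr{c}" for c in range(1, 11)]  # includes train/val/test chroms


@pytest.fixture(scope="session")
def activator_pwm():
    return default_activator_pwm()


@pytest.fixture(scope="session")
def pwm_scorer(activator_pwm):
    return PWMScorer(activator_pwm)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1234)


def make_training_set(rng, n_per_class, length, consensus):
    """Planted-motif positives vs uniform negatives, spread over chromosomes."""
    def build(planted):
        out = []
        for i in range(n_per_class):
            s = random_sequence(rng, length)
            if planted:
                off = int(rng.integers(0, length - len(consensus) + 1))
                s = s[:off] + consensus + s[off + len(consensus):]
            out.append((s, CHROMS[i % len(CHROMS)]))
        return out

    return build(True), build(False)


@pytest.fixture(scope="session")
def separable_dataset(activator_pwm):
    rng = np.random.default_rng(20240917)
    return make_training_set(rng, 2000, 200, activator_pwm.consensus)


@pytest.fixture(scope="session")
def trained_tiny_scorer(separable_dataset):
    """Tiny CNN trained on the separable planted-motif construction."""
    pos, neg = separable_dataset
    scorer, metrics = train(ModelConfig(), pos, neg, seed=1, epochs=20)
    return scorer, metrics


@pytest.fixture(scope="session")
def shuffled_label_metrics(separable_dataset):
    """Same data with labels permuted: the uninformative null fit."""
    pos, neg = separable_dataset
    pool = pos + neg
    perm = np.random.default_rng(5).permutation(len(pool))
    half = len(pool) // 2
    pos_s = [pool[i] for i in perm[:half]]
    neg_s = [pool[i] for i in perm[half:]]
    _, metrics = train(ModelConfig(), pos_s, neg_s, seed=1, epochs=5)
    return metrics
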