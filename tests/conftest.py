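import numpy as np
import pytest

from fairpost import CohortConfig, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def binary_mixed():
    return make_fixture("binary_mixed")


@pytest.fixture
def binary_biased():
    return make_fixture("binary_biased")


@pytest.fixture
def disparity_config():
    """Two-group binary design with a deliberate accuracy disparity.

    AUC 0.80 vs 0.65 at a shared operating threshold of 0.7 gives the
    stronger group a substantially higher TPR, mimicking a classifier that
    was trained mostly on the majority group.
    """

    def _make(n_total=20000, seed=11, threshold=0.7):
        return CohortConfig(
            n_total=n_total,
            group_fractions={"White": 0.78, "nonWhite": 0.22},
            prevalence_per_group={"White": [0.61, 0.39], "nonWhite": [0.61, 0.39]},
            auc_per_group={"White": 0.80, "nonWhite": 0.65},
            threshold=threshold,
            seed=seed,
        )

    return _make


@pytest.fixture
def multiclass_config():
    """Three-class design with group-dependent confusion tendencies."""

    def _make(n_total=20000, seed=13):
        strong = [[0.80, 0.12, 0.08], [0.10, 0.80, 0.10], [0.08, 0.17, 0.75]]
        weak = [[0.55, 0.30, 0.15], [0.25, 0.55, 0.20], [0.15, 0.35, 0.50]]
        return CohortConfig(
            n_total=n_total,
            group_fractions={"White": 0.6, "nonWhite": 0.4},
            prevalence_per_group={"White": [0.18, 0.66, 0.16], "nonWhite": [0.18, 0.66, 0.16]},
            confusion_per_group={"White": strong, "nonWhite": weak},
            seed=seed,
        )

    return _make
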