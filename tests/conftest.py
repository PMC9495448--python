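"""Shared fixtures: tiny deterministic datasets built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from ensint import (LabelVector, ModalityTable, MultimodalDataset, RunConfig,
                    align_entities)
from ensint.synthetic import (SyntheticModalitySpec, SyntheticSpec,
                              generate_multimodal)

FAST_ROSTER = ["logistic_regression", "naive_bayes", "decision_tree"]


@pytest.fixture
def toy_table() -> ModalityTable:
    """3 entities x 2 features, one missing cell."""
    values = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
    return ModalityTable("toy", ["e1", "e2", "e3"], ["f1", "f2"], values)


@pytest.fixture
def toy_labels() -> LabelVector:
    return LabelVector(["e1", "e2", "e3", "e4"], [1, 0, 1, 0])


@pytest.fixture
def small_dataset() -> tuple[MultimodalDataset, dict]:
    """120 entities, one informative modality + one noise modality, aligned."""
    spec = SyntheticSpec(
        n_entities=120, prevalence=0.4, seed=11, scenario="redundant",
        modalities=[SyntheticModalitySpec("sig", n_features=5, n_informative=2,
                                          effect_size=2.0),
                    SyntheticModalitySpec("noise", n_features=5,
                                          n_informative=0)])
    dataset, ground_truth, _ = generate_multimodal(spec)
    return dataset, ground_truth


@pytest.fixture
def fast_config() -> RunConfig:
    return RunConfig(seed=11, k_outer=3, k_inner=3,
                     local_roster=list(FAST_ROSTER),
                     meta_roster=["logistic_regression"],
                     n_permutations=20)


def make_complementary(n_entities: int = 200, seed: int = 0,
                       n_features: int = 8, n_informative: int = 1,
                       effect_size: float = 2.0, with_noise: bool = True,
                       prevalence: float = 0.25) -> tuple:
    mods = [SyntheticModalitySpec("mod_a", n_features, n_informative, effect_size),
            SyntheticModalitySpec("mod_b", n_features, n_informative, effect_size)]
    if with_noise:
        mods.append(SyntheticModalitySpec("mod_c", n_features, 0))
    spec = SyntheticSpec(n_entities=n_entities, prevalence=prevalence,
                         modalities=mods, scenario="complementary", seed=seed)
    return generate_multimodal(spec)
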