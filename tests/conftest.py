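"""Shared fixtures: a toy genome for exact hand-checks and one synthetic
dataset at the canonical study conditions (1 Mb, 50k tags, 6-bit injected
preference, five-fold open-region enrichment, default seed) reused across
the slower end-to-end tests."""

import numpy as np
import pytest

from dnasebias import bias_model as bm
from dnasebias import synthetic_data as sd
from dnasebias.filtering import ScoredTagSet
from dnasebias.io_formats import GenomeSequence


@pytest.fixture
def toy_genome():
    return GenomeSequence({"c1": "AACCGGTTAACCGGTTAACC"})


@pytest.fixture
def all_a_genome():
    return GenomeSequence({"c1": "A" * 60})


@pytest.fixture(scope="session")
def biased_truth():
    return sd.simulate(sd.SimulationConfig())


@pytest.fixture(scope="session")
def unbiased_truth():
    return sd.simulate(sd.unbiased_config(sd.SimulationConfig()))


@pytest.fixture(scope="session")
def bias_models(biased_truth):
    return bm.build_bias_models(biased_truth.tags, biased_truth.genome)


@pytest.fixture(scope="session")
def scored_set(biased_truth, bias_models):
    m, b = bias_models
    scores = bm.score_tags(biased_truth.tags, m, b, biased_truth.genome)
    return ScoredTagSet(biased_truth.tags, scores)
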