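import warnings

import numpy as np
import pytest

import varmatch as vm

# the capped-negative-pool warning fires constantly on the standard corpus
# (k=200 against a 240-variable target study) and is expected there
warnings.filterwarnings(
    "ignore", message="negative pool for", category=UserWarning
)


@pytest.fixture(scope="session")
def standard_corpus():
    """The standard synthetic corpus: 60 source / 240 target variables."""
    return vm.generate_paired_dictionaries()


@pytest.fixture(scope="session")
def standard_matrix(standard_corpus):
    """Featurizer plus the full (matched source x all target) feature table."""
    src, tgt, truth = standard_corpus
    featurizer = vm.PairFeaturizer(src, tgt)
    matched = [s for s in src.variable_names if s in truth.targets_of]
    matrix = featurizer.matrix(matched, truth)
    return featurizer, matrix


@pytest.fixture(scope="session")
def standard_experiment(standard_corpus, standard_matrix):
    """The 10-trial ensemble experiment on the standard corpus."""
    src, tgt, truth = standard_corpus
    _, matrix = standard_matrix
    config = vm.ExperimentConfig(n_trials=10, master_seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vm.run_experiment(src, tgt, truth, config, full_matrix=matrix)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small, fast corpus for unit tests of the experiment machinery."""
    config = vm.SynthConfig(n_source=14, n_target=40, seed=3)
    return vm.generate_paired_dictionaries(config)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_corpus):
    src, tgt, truth = tiny_corpus
    featurizer = vm.PairFeaturizer(src, tgt)
    matched = [s for s in src.variable_names if s in truth.targets_of]
    return featurizer, featurizer.matrix(matched, truth)


@pytest.fixture()
def hash_embedder():
    return vm.get_backend("offline-hash")


@pytest.fixture(scope="session")
def corpus_vocabulary(standard_corpus):
    """Realistic word list drawn from generated labels and rules."""
    src, tgt, _ = standard_corpus
    words = set()
    for d in (src, tgt):
        for rec in d:
            words.update(rec.variable_label.lower().split())
            words.update(rec.derivation_rule.lower().split())
    return sorted(words)
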