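import numpy as np
import pytest

from ca2sse.ensemble import EMLConfig, residue_dataset, train_eml
from ca2sse.evaluate import classify_trace, evaluate
from ca2sse.features import compute_feature_matrix
from ca2sse.subspace import WindowConfig, fit_sse_subspaces
from ca2sse.synthetic import make_corpus, make_hairpin, make_helix
from ca2sse.trace import LabelSequence

# corpus conditions of the end-to-end benchmark: 60 training and 20
# held-out multi-segment proteins, coordinate jitter 0.1 A
TRAIN_SEED, TEST_SEED, JITTER = 101, 202, 0.1


@pytest.fixture(scope="session")
def ideal_helix():
    trace, labels = make_helix(13)
    return trace, labels


@pytest.fixture(scope="session")
def hairpin():
    return make_hairpin(6)


@pytest.fixture(scope="session")
def small_corpus():
    return make_corpus(6, seed=5, jitter_sd=JITTER)


@pytest.fixture(scope="session")
def benchmark():
    """Train on 60 synthetic proteins, score methods on 20 held-out ones.

    Returns pooled post-processed accuracies plus the fitted artifacts,
    shared by the acceptance tests.
    """
    train = make_corpus(60, seed=TRAIN_SEED, jitter_sd=JITTER)
    test = make_corpus(20, seed=TEST_SEED, jitter_sd=JITTER)
    model = fit_sse_subspaces([t for t, _ in train], [l for _, l in train],
                              WindowConfig())
    fms = [compute_feature_matrix(t) for t, _ in train]
    X, y = residue_dataset(fms, [l for _, l in train])
    eml = train_eml(X, y, EMLConfig.scaled(), seed=0, max_samples=5000)

    accuracies = {}
    for method in ("model1", "model2", "eml"):
        pred_all, truth_all = [], []
        for trace, truth in test:
            pred = classify_trace(trace, method, subspace_model=model,
                                  eml_model=eml)
            pred_all.extend(pred)
            truth_all.extend(truth)
        rep = evaluate(LabelSequence(pred_all, provenance=method),
                       LabelSequence(truth_all))
        accuracies[method] = rep.accuracy
    return {"model": model, "eml": eml, "train": train, "test": test,
            "accuracies": accuracies}
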