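import numpy as np
import pytest

import pdivas as P
from pdivas.classifier import train


@pytest.fixture(scope="session")
def spec():
    return P.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def reference(spec):
    return P.gen_reference(spec)


@pytest.fixture(scope="session")
def pipeline(reference):
    return P.AnnotationPipeline(
        genome=reference.genome,
        transcripts=reference.transcripts,
        constraint=reference.constraint,
    )


@pytest.fixture(scope="session")
def labeled_features(reference, pipeline):
    """Sequence-level labeled variants with extracted features."""
    variants, labels = P.gen_labeled_variants(reference)
    X = pipeline.feature_frame(variants)
    y = (labels == "pathogenic").astype(int)
    return variants, X, y


@pytest.fixture(scope="session")
def trained_model(labeled_features):
    _, X, y = labeled_features
    tr, _ = P.split_dataset(y, 0.7, seed=1)
    return train(X.iloc[tr], y[tr], {"n_estimators": 200, "max_depth": 8},
                 seed=1)


class StubScorer(P.SiteScorer):
    """Site scorer backed by fixed acceptor/donor arrays keyed by sequence."""

    def __init__(self, table):
        self.table = table  # seq -> (acc array, don array)

    def score(self, seq, chrom=None, start=None):
        acc, don = self.table[seq]
        return np.asarray(acc, dtype=float), np.asarray(don, dtype=float)


@pytest.fixture
def stub_scorer_factory():
    return StubScorer
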