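import numpy as np
import pytest

from mantis import (
    ClassifierConfig,
    ProbabilityMaps,
    ScalarVolume,
    TISSUE_CODES,
)
from mantis.classifier import ClassifierResult, MixtureState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_result(posterior_maps: np.ndarray, codes=TISSUE_CODES,
                affine=None) -> ClassifierResult:
    """Assemble a ClassifierResult around hand-built posterior maps."""
    affine = np.eye(4) if affine is None else affine
    ncls = posterior_maps.shape[0]
    mix = MixtureState(tuple(codes)[:ncls],
                       weights=np.ones((ncls, 1)),
                       means=np.zeros((ncls, 1)),
                       variances=np.ones((ncls, 1)))
    return ClassifierResult(
        posteriors=ProbabilityMaps(posterior_maps, tuple(codes)[:ncls],
                                   affine),
        bias_field=ScalarVolume(np.ones(posterior_maps.shape[1:]), affine),
        mixture=mix,
        log_likelihood=[0.0],
    )


def onehot_posteriors(labels: np.ndarray, codes=TISSUE_CODES) -> np.ndarray:
    maps = np.stack([(labels == c).astype(float) for c in codes])
    return maps
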