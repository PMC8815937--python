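import numpy as np
import pytest

from dmcodex import synthetic
from dmcodex.bovw import build_codebook, build_dictionary, encode, extract_features
from dmcodex.distmat import distance_matrix, to_gray_image


@pytest.fixture(scope="session")
def contrast_corpus():
    """Seeded 10 solenoid + 10 globular corpus (~150 residues) run through
    feature extraction once; shared by the slower end-to-end tests."""
    specs = synthetic.benchmark_specs(
        n_solenoid=10, n_globular=10, n_residues=150, noise_A=0.3, seed=1
    )
    traces = [synthetic.generate(s, f"{s.kind}{i:03d}") for i, s in enumerate(specs)]
    images = [to_gray_image(distance_matrix(t)) for t in traces]
    feature_sets = [extract_features(im) for im in images]
    labels = [s.kind for s in specs]
    return {
        "specs": specs,
        "traces": traces,
        "images": images,
        "feature_sets": feature_sets,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def contrast_codebook(contrast_corpus):
    """k=200 codebook over the whole contrast corpus plus encodings."""
    dictionary = build_dictionary(contrast_corpus["feature_sets"])
    cb = build_codebook(dictionary, k=200, seed=1)
    hists = [encode(f, cb) for f in contrast_corpus["feature_sets"]]
    return cb, hists


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
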