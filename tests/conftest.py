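import numpy as np
import pytest

import chimeramap as cm


@pytest.fixture(scope="session")
def small_transcript() -> cm.Transcript:
    return cm.random_transcript(1000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def two_stem_model(small_transcript) -> cm.StructureModel:
    stems = [
        cm.StemSpec((100, 130), (400, 430), weight=1.0),
        cm.StemSpec((600, 630), (800, 830), weight=1.0),
    ]
    return cm.StructureModel(small_transcript, stems, background_rate=0.2)


def nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial counts in (mean, dispersion) parameterization:
    Var = mean + dispersion * mean^2."""
    return rng.negative_binomial(1 / dispersion, 1 / (1 + dispersion * mean), size=size)
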