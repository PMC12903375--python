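import numpy as np
import pytest

from polybg import (
    Architecture,
    EpistaticTerm,
    LocusSpec,
    model_from_background_rate,
)


@pytest.fixture
def three_locus_arch() -> Architecture:
    return Architecture(
        loci=(
            LocusSpec(0.2, 0.4),
            LocusSpec(0.5, -0.3),
            LocusSpec(0.35, 0.15),
        )
    )


@pytest.fixture
def epistatic_arch(three_locus_arch) -> Architecture:
    return Architecture(
        loci=three_locus_arch.loci,
        epistatic_terms=(
            EpistaticTerm(0, 1, 0.2),
            EpistaticTerm(1, 2, -0.1),
        ),
    )


@pytest.fixture
def rare_disease_model():
    return model_from_background_rate(0.01)
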