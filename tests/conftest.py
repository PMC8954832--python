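import warnings

import pytest

from isolocal import (
    IsotopeLibrary,
    IsotopeRecord,
    default_config,
    full_config,
    generate_library,
    stratified_split,
)

# Tiny local training sets can make LDA collinear or leave sklearn muttering
# about class balance; those warnings are expected in the exercised regimes.
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture
def toy_library() -> IsotopeLibrary:
    """Four hand-written samples, one per banner (2 PGI, 2 non-PGI)."""
    return IsotopeLibrary(
        [
            IsotopeRecord("SR-1", "SuniteRight", -19.3, 7.3, -99.5, 13.7),
            IsotopeRecord("SL-1", "SuniteLeft", -19.0, 7.1, -105.0, 13.0),
            IsotopeRecord("SZ-1", "Siziwang", -21.9, 6.4, -120.0, 8.5),
            IsotopeRecord("AB-1", "Abaga", -22.5, 6.6, -118.0, 9.1),
        ],
        label="toy",
    )


@pytest.fixture
def training_library() -> IsotopeLibrary:
    """A 93-sample synthetic library at the study conditions."""
    return generate_library(default_config(seed=7), label="train93")


@pytest.fixture
def split_116():
    """116-sample synthetic library split 93/23 by banner strata."""
    lib = generate_library(full_config(seed=11), label="full116")
    return stratified_split(lib, test_fraction=0.2, seed=11)
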