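import pytest

from sh2num.fixtures import bundled_anchors, make_synthetic_family
from sh2num.profile_numbering import propagate


@pytest.fixture(scope="session")
def stat5b():
    return bundled_anchors().stat5b


@pytest.fixture(scope="session")
def shp2_n():
    return bundled_anchors().shp2_n


@pytest.fixture(scope="session")
def family():
    """Synthetic 20-record SH2-like family at the standard study conditions."""
    return make_synthetic_family(n_records=20, mutation_rate=0.1, seed=42)


@pytest.fixture(scope="session")
def family_annotations(family):
    numbering, annotations = propagate(family.alignment, family.segmentation)
    return numbering, annotations
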