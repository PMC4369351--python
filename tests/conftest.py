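import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from multiway3c.genome import GenomeLayout, PloidySegment, build_bead_map, make_bins


@pytest.fixture
def diploid_layout():
    """Two 10-bin chromosomes at 1 kb resolution, chr2 fully diploid."""
    return GenomeLayout(
        [("chr1", 10_000), ("chr2", 10_000)],
        [PloidySegment("chr2", 0, 10_000, 2)],
    )


@pytest.fixture
def diploid_bins(diploid_layout):
    return make_bins(diploid_layout, 1000)


@pytest.fixture
def diploid_beadmap(diploid_layout, diploid_bins):
    return build_bead_map(diploid_bins, diploid_layout)


@pytest.fixture
def planted_structure(diploid_beadmap):
    """30-bead planted truth: two chromosome chains, homolog copies of the
    diploid chromosome congruent and near-coincident (the configuration the
    count model can identify: inter-homolog counts are structurally zero)."""

    def chain(n, origin):
        t = np.arange(n) * 0.7
        return np.c_[np.cos(t), np.sin(t), 0.3 * t] * 0.21 + origin

    X = np.zeros((30, 3))
    X[:10] = chain(10, np.array([0.00, 0.00, 0.00]))
    X[10:20] = chain(10, np.array([0.45, 0.18, 0.00]))
    X[20:30] = X[10:20] + np.array([0.015, 0.01, 0.01])
    return X
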