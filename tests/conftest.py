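import numpy as np
import pytest

from evinet.core import (
    AnnotationFramework,
    AssociationRecord,
    GeneSet,
    GoldStandard,
    Network,
    RankedProfile,
)


@pytest.fixture
def small_gold():
    """Gold standard of the degree-weighting worked example."""
    return GoldStandard({"C1": {"A", "B", "C"}, "C2": {"D", "E"}})


@pytest.fixture
def triangle_network():
    net = Network()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
        net.add_edge(AssociationRecord(a, b, combined=0.9))
    return net


@pytest.fixture
def null_profile():
    """1000-protein profile with i.i.d. standard-normal values."""
    rng = np.random.default_rng(7)
    names = [f"Q{i:04d}" for i in range(1000)]
    return RankedProfile(dict(zip(names, rng.standard_normal(1000).tolist())))


def make_framework(sets):
    return AnnotationFramework(name="test", sets=[GeneSet(n, "d", m) for n, m in sets])
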