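import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cmphelix import TripleHelixTopology, build_ideal_helix, parse_cmp


@pytest.fixture(scope="session")
def topo():
    """Factory: formula -> TripleHelixTopology (cached)."""
    cache = {}

    def make(formula, name=""):
        key = (formula, name)
        if key not in cache:
            cache[key] = TripleHelixTopology(parse_cmp(formula, name=name))
        return cache[key]

    return make


@pytest.fixture(scope="session")
def ideal():
    """Factory: formula -> ideal StructureModel (cached)."""
    cache = {}

    def make(formula):
        if formula not in cache:
            cache[formula] = build_ideal_helix(
                TripleHelixTopology(parse_cmp(formula))
            )
        return cache[formula]

    return make
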