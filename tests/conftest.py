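import io

import pytest
from hypothesis import HealthCheck, settings

from mapgen import kegg as kg
from mapgen import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures() -> syn.TableFixtures:
    return syn.build_table_fixtures()


@pytest.fixture(scope="session")
def pathway_graphs(fixtures) -> list[kg.PathwayGraph]:
    """All fixture pathways (decoy included, group demo excluded)."""
    return [
        kg.parse_kgml(io.BytesIO(xml.encode()), fixtures.symbol_map)
        for name, xml in sorted(fixtures.kgml.items())
        if name != "group_demo"
    ]
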