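import pytest

from cellmap.fixtures import FixtureSpec, make_organism
from cellmap.layout_engine import layout_master
from cellmap.pipeline import build_map
from cellmap.zoom_renderer import StyleConfig


@pytest.fixture(scope="session")
def demo_pgdb():
    return make_organism(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def demo_master(demo_pgdb):
    return layout_master(demo_pgdb)


@pytest.fixture(scope="session")
def style():
    return StyleConfig()


@pytest.fixture(scope="session")
def demo_build(demo_pgdb, demo_master, tmp_path_factory):
    """Full pipeline run (tiles + data bundle) in a session temp dir."""
    out = tmp_path_factory.mktemp("demo_map")
    return build_map(demo_pgdb, out, master=demo_master)
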