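import pytest

from helixscreen.model_io import BindingSiteDef
from helixscreen.synthetic import FixtureSpec, make_fixture

# Extra contacts that grow the canonical register interface past the
# screen's >7-residue requirement (receptor ids stay inside the site).
PASSING_EXTRAS = ((54, 337), (55, 343), (57, 287), (59, 222), (62, 228))


@pytest.fixture(scope="session")
def site() -> BindingSiteDef:
    return BindingSiteDef.default()


@pytest.fixture(scope="session")
def cdca4():
    """Canonical binder: patch1 at i/i+4 (56/60), patch3 at i+2, patch2 at i+5."""
    return make_fixture(FixtureSpec.cdca4_like())


@pytest.fixture(scope="session")
def passing_complex():
    """Nine-residue interface, confident and low-iPAE: passes the screen."""
    return make_fixture(FixtureSpec.cdca4_like(extra_contacts=PASSING_EXTRAS))
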