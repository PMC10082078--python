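import pytest

from balcom import make_fixture


@pytest.fixture(scope="session")
def fig1b():
    return make_fixture("fig1b")


@pytest.fixture(scope="session")
def fig2():
    return make_fixture("fig2")


@pytest.fixture(scope="session")
def fig3_base():
    return make_fixture("fig3", "base")


@pytest.fixture(scope="session")
def fig3_dashed():
    return make_fixture("fig3", "dashed")


@pytest.fixture(scope="session")
def fig3_dotted():
    return make_fixture("fig3", "dotted")


@pytest.fixture(scope="session")
def fig4():
    return make_fixture("fig4")


@pytest.fixture(scope="session")
def all_fixtures(fig1b, fig2, fig3_base, fig3_dashed, fig3_dotted, fig4):
    return {
        "fig1b": fig1b,
        "fig2": fig2,
        "fig3/base": fig3_base,
        "fig3/dashed": fig3_dashed,
        "fig3/dotted": fig3_dotted,
        "fig4": fig4,
    }
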