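import pytest

import etawithin as ew
from etawithin import CodingScheme, RandomSpec
from etawithin.mixed import fit_lmm


@pytest.fixture(scope="session")
def wm_between():
    return ew.load_fixture("wm_between")


@pytest.fixture(scope="session")
def wm_longitudinal():
    return ew.load_fixture("wm_longitudinal")


@pytest.fixture(scope="session")
def twobytwo():
    return ew.load_fixture("twobytwo")


@pytest.fixture(scope="session")
def faces():
    return ew.load_fixture("faces")


@pytest.fixture(scope="session")
def reading():
    return ew.load_fixture("reading")


def participant_means(table, factor):
    """One column per factor level of per-participant mean responses."""
    df = (table.data.groupby([table.participant, factor], sort=True)
          [table.response].mean().unstack())
    return df


# session-scoped REML fits shared across test modules (deterministic)

@pytest.fixture(scope="session")
def twobytwo_fit(twobytwo):
    return fit_lmm(
        twobytwo,
        ["day", "stimulus_type", "day:stimulus_type"],
        [RandomSpec("participant",
                    ("1", "day", "stimulus_type", "day:stimulus_type"))],
        CodingScheme("deviation"),
    )


@pytest.fixture(scope="session")
def faces_fit(faces):
    return fit_lmm(
        faces, ["age"],
        [RandomSpec("participant"), RandomSpec("stimulus", ("1", "age"))],
        CodingScheme("deviation"),
    )


@pytest.fixture(scope="session")
def reading_fit(reading):
    return fit_lmm(
        reading,
        ["language", "background", "language:background"],
        [RandomSpec("participant",
                    ("1", "language", "background", "language:background")),
         RandomSpec("text")],
        CodingScheme("deviation"),
    )
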