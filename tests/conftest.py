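import pytest

from metalrisk import io as cio
from metalrisk import risk as crisk
from metalrisk.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry("defaults")


@pytest.fixture(scope="session")
def study_means():
    return cio.load_study_means()


@pytest.fixture(scope="session")
def fixture_risks(study_means, registry):
    """Published-mode risk results for the full study fixture."""
    return crisk.risk_frames(crisk.assess(study_means, registry, "published"))


def printed_tolerance(printed: str) -> float:
    """Comparison tolerance for a published numeral: 0.5 % relative, but
    never finer than one unit in the last printed decimal place (the
    source truncates some low-magnitude cells to 2 significant figures)."""
    value = abs(float(printed))
    if "e" in printed:
        mantissa, exponent = printed.split("e")
        ulp = 10.0 ** -(len(mantissa) - mantissa.index(".") - 1)
        ulp *= 10.0 ** int(exponent)
    else:
        ulp = 10.0 ** -(len(printed) - printed.index(".") - 1)
    return max(0.005 * value, ulp)
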