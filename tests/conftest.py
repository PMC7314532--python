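import pytest

from ecsdiff.core import (
    ECSParameters,
    IontophoreticSource,
    default_times,
    generate_curve,
)
from ecsdiff.rti import fit_agar

FREE_MEDIUM = ECSParameters(alpha=1.0, lam=1.0, kprime=0.0)
TYPICAL_TISSUE = ECSParameters(alpha=0.2, lam=1.5, kprime=0.004)


@pytest.fixture(scope="session")
def source():
    """Standard TMA+ iontophoresis protocol: 20 nA bias, +180 nA for 24 s."""
    return IontophoreticSource()


@pytest.fixture(scope="session")
def times():
    return default_times()


@pytest.fixture(scope="session")
def agar_curve(source, times):
    return generate_curve(source, FREE_MEDIUM, 120.0, times, medium="agar")


@pytest.fixture(scope="session")
def agar_fit(agar_curve, source):
    fit = fit_agar(agar_curve, source)
    assert fit.converged
    return fit
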