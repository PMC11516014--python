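import numpy as np
import pytest

from paleodem import CalendarAxis, RadiocarbonDate
from paleodem.synthetic_data import identity_curve, synthetic_curve


@pytest.fixture
def axis():
    """The standard observation window, annual grid."""
    return CalendarAxis(2850, 1700)


@pytest.fixture
def padded_axis(axis):
    return axis.pad(100)


@pytest.fixture
def ident_curve():
    """mu(theta) = theta, zero curve error."""
    return identity_curve()


@pytest.fixture
def wiggly_curve():
    """Synthetic curve with a sinusoidal wiggle, 5-yr knots."""
    return synthetic_curve(wiggle_amp=15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_date(age, err=30.0, **kw):
    defaults = dict(lab_id=f"T-{age:.0f}", site_id="s1", region="EJ",
                    material="short-lived", site_type="settlement")
    defaults.update(kw)
    return RadiocarbonDate(c14_age=age, error=err, **defaults)


@pytest.fixture
def toy_dates():
    """10 dates spread over the window (identity-curve ages in cal BP)."""
    return [make_date(3600 + 100 * i, err=25 + 5 * (i % 3)) for i in range(10)]
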