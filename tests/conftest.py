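import numpy as np
import pytest

from synscreen import DoseResponseMatrix, MonotherapyCurve
from synscreen.simulate import CurveParams, SimSpec, simulate_block


@pytest.fixture
def hyperbolic_curve() -> MonotherapyCurve:
    """y(x) = 100 x / (1 + x): log-logistic with m=1, lam=1."""
    return MonotherapyCurve(d_min=0.0, d_max=100.0, m=1.0, lam=1.0,
                            c_lo=0.01, c_hi=100.0)


@pytest.fixture
def bliss_null_block() -> tuple[DoseResponseMatrix, dict]:
    return simulate_block(SimSpec(interaction="bliss_null"))


def random_curve(rng: np.random.Generator) -> MonotherapyCurve:
    """Random increasing log-logistic with the inflection inside the range."""
    m = 10 ** rng.uniform(-1.5, 1.5)
    return MonotherapyCurve(
        d_min=float(rng.uniform(-10, 20)),
        d_max=float(rng.uniform(60, 110)),
        m=float(m), lam=float(rng.uniform(0.3, 4.0)),
        c_lo=m / 100, c_hi=m * 100,
    )
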