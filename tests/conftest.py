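import numpy as np
import pytest
from hypothesis import settings

from prcmap.metrics import NetworkPhaseSeries
from prcmap.prc import PRCFunction
from prcmap.synth import PRCFamilySpec, make_prc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def constant_prc(c: float) -> PRCFunction:
    """PRC that applies the same resetting at every phase (test scaffold)."""
    return PRCFunction(
        kind="spline",
        base=lambda th: np.full_like(np.asarray(th, dtype=float), c),
        f_min=c,
        peak=c,
        argmax=0.5,
        argmin=0.0,
    )


@pytest.fixture
def zero_prc() -> PRCFunction:
    return make_prc(PRCFamilySpec(0.0))


@pytest.fixture
def parabola_prc() -> PRCFunction:
    """f(θ) = 0.2·θ(1−θ): peak 0.05 at θ=0.5."""
    return make_prc(PRCFamilySpec(0.05, 0.5, (1.0, 1.0)))


def series_from_phi(phi, P: float = 100.0, pad_transient: int = 0) -> NetworkPhaseSeries:
    """Build a schematic network-phase series from a phase sequence.

    ``pad_transient`` prepends that many constant cycles so that the
    automatic 10-cycle discard does not eat into the schedule under test.
    """
    phi = np.concatenate([np.full(pad_transient, phi[0]), np.asarray(phi, dtype=float)])
    ts = phi * P
    tr = P - ts
    return NetworkPhaseSeries(
        cycle=np.arange(len(phi)),
        ts_M=ts,
        tr_M=tr,
        phi=phi,
        P_net=np.full(len(phi), P),
    )
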