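import numpy as np
import pytest

import prespike as pk


@pytest.fixture
def calyx_params():
    """Symmetric calyx-type circuit: c_cl = 10 pF, g_cl = 1 uS (tau_cl = 10 us)."""
    return pk.CircuitParams.calyx(g_cl=1e-6, c_cl=10e-12)


@pytest.fixture
def slow_ap():
    """Surrogate AP, FWHM 0.5 ms, 120 mV from -80 mV rest, dt 5 us."""
    shape = pk.APShape(fwhm=0.5e-3, amplitude=0.120, t_peak=2e-3)
    return pk.make_action_potential(shape, dt=5e-6, duration=5e-3)


@pytest.fixture
def gaussian_ica():
    """Inward Gaussian calcium current: -1.9 nA peak, tau_Ca = 0.217 ms."""
    return pk.make_calcium_current(-1.9e-9, t_peak=2.5e-3, tau_ca=0.217e-3,
                                   dt=5e-6, duration=5e-3)


def measure_fwhm(series, baseline, amplitude):
    """Interpolated full width at half maximum of a positive pulse."""
    v, t = series.values, series.times
    half = baseline + amplitude / 2.0
    above = v > half
    i0 = int(np.argmax(above))
    i1 = len(v) - int(np.argmax(above[::-1])) - 1
    t_lo = np.interp(half, [v[i0 - 1], v[i0]], [t[i0 - 1], t[i0]])
    t_hi = np.interp(half, [v[i1 + 1], v[i1]], [t[i1 + 1], t[i1]])
    return t_hi - t_lo
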