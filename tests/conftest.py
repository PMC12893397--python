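import numpy as np
import pytest

from orgwave.presets import CONTROL, DOX


@pytest.fixture(scope="session")
def control_ca():
    """Control-group calcium kinetics target."""
    return CONTROL.transient_params_by_region[1]


@pytest.fixture(scope="session")
def dox_ca():
    """Doxorubicin-group calcium kinetics target."""
    return DOX.transient_params_by_region[1]


@pytest.fixture(scope="session")
def small_control_scene():
    """A small noisy control scene shared across tests."""
    from orgwave.synthetic import generate_scene

    return generate_scene(CONTROL, n_cells=25, seed=1234)


@pytest.fixture(scope="session")
def small_clean_scene():
    """A small noise-free, drift-free control scene."""
    from orgwave.synthetic import generate_scene

    return generate_scene(CONTROL, n_cells=25, seed=1234, noise=False, drift="none")


def dense_functionals(fn, t_max, dt=0.1):
    """Independent dense-grid oracle for waveform functionals.

    Measures amplitude, 20% widths, max rise derivative and the area
    between the 20% crossings by brute force on a fine grid.
    """
    t = np.arange(0.0, t_max, dt)
    y = np.asarray(fn(t), dtype=float)
    i = int(np.argmax(y))
    apex = y[i]
    thr = 0.2 * apex
    above = np.flatnonzero(y >= thr)
    j0, j1 = above[0], above[-1]
    tl = np.interp(thr, [y[j0 - 1], y[j0]], [t[j0 - 1], t[j0]]) if j0 > 0 else t[0]
    tr = (
        np.interp(thr, [y[j1 + 1], y[j1]], [t[j1 + 1], t[j1]])
        if j1 + 1 < len(t)
        else t[-1]
    )
    slope = float(np.diff(y[j0 : i + 1]).max() / dt) if i > j0 else 0.0
    sel = (t >= tl) & (t <= tr)
    return {
        "amplitude": float(apex),
        "left": float(t[i] - tl),
        "right": float(tr - t[i]),
        "width": float(tr - tl),
        "slope": slope,
        "auc": float(np.trapezoid(y[sel], t[sel])),
    }
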