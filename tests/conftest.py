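import numpy as np
import pytest

from minsted import LocalizerConfig, OpticsModel, Schedule, Trace


@pytest.fixture(scope="session")
def optics():
    """Default optics, saturation calibrated to 24 nm FWHM at 1 nJ."""
    return OpticsModel()


@pytest.fixture(scope="session")
def schedule(optics):
    """Default ramp schedule (shared; building it inverts the FWHM curve)."""
    cfg = LocalizerConfig(max_duration_ms=None)
    return Schedule(cfg, optics)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trace(centers, n_c=1, **kw):
    """Build a minimal Trace from a (L, 2) center array for estimator tests."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    L = len(centers)
    defaults = dict(
        energies=np.ones(L),
        radii=np.full(L, 12.0),
        fwhms=np.full(L, 24.0),
        times_ms=np.arange(L, dtype=float) * 0.02,
        is_bg=np.zeros(L, dtype=bool),
        n_c=n_c,
    )
    defaults.update(kw)
    return Trace(centers=centers, **defaults)


@pytest.fixture(scope="session")
def quiet_schedule(optics):
    """Schedule with background switched off (infinite SBR)."""
    cfg = LocalizerConfig(max_duration_ms=None)
    sch = Schedule(cfg, optics)
    sch.sbrs = np.full_like(sch.sbrs, np.inf)
    return sch
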