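import numpy as np
import pytest

from poolpk import PooledProfile, SimParams, StudyDesign, TROUT_DESIGN


@pytest.fixture
def trout_design() -> StudyDesign:
    return TROUT_DESIGN


@pytest.fixture
def monoexp_profile() -> PooledProfile:
    """Noise-free IV profile C(t) = 10*exp(-0.1 t) on a sparse grid."""
    t = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 24.0])
    return PooledProfile(
        route="IV",
        times=t,
        mean_conc=10.0 * np.exp(-0.1 * t),
        sd_conc=np.zeros_like(t),
        n=np.full(t.shape, 6),
    )


@pytest.fixture
def iv_params() -> SimParams:
    return SimParams(cl=0.03, v_central=0.09, f_abs=1.0, dose=2.0, iiv_cv=0.15, seed=7)


@pytest.fixture
def flipflop_params() -> SimParams:
    """Extravascular arm with absorption slower than elimination (ka < k)."""
    return SimParams(
        cl=0.03, v_central=0.09, ka=0.10, f_abs=0.86, dose=2.0, iiv_cv=0.15, seed=7
    )


def profile_from_arrays(route, times, conc) -> PooledProfile:
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    return PooledProfile(
        route=route,
        times=times,
        mean_conc=conc,
        sd_conc=np.zeros_like(conc),
        n=np.full(times.shape, 6),
    )
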