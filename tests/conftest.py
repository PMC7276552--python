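import warnings

import numpy as np
import pytest

from coloptics.fdtd import FdtdConfig, run_fdtd
from coloptics.structure import LatticeSpec, make_hexagonal
from coloptics.synthdata import ColonyModel, TiltDistribution, synth_goniometer_map

THETA_IN = (0.0, -45.0, -60.0)


@pytest.fixture(scope="session")
def day2_delta_maps():
    """Noiseless zero-tilt maps of the day-2 colony at the three incidences."""
    model = ColonyModel(d=395.0, tilt=TiltDistribution(0, 0, 0))
    return [synth_goniometer_map(model, t) for t in THETA_IN]


@pytest.fixture(scope="session")
def day2_tilt_maps():
    """Default-tilt (streaked) maps of the day-2 colony."""
    model = ColonyModel(d=395.0)
    return [synth_goniometer_map(model, t) for t in THETA_IN]


@pytest.fixture(scope="session")
def fdtd_kg_spectrum():
    """Perfect-lattice FDTD, stacking ('KG') incidence, full 5 um depth."""
    spec = LatticeSpec(d=395.0, a=375.0, box=(5000.0, 6 * 395.0), ff=0.6, orientation=0.0)
    cfg = FdtdConfig(box=spec.box, run_time_fs=300.0,
                     wavelengths=np.arange(300.0, 700.0 + 1e-9, 2.0))
    return run_fdtd(make_hexagonal(spec), config=cfg)


@pytest.fixture(scope="session")
def fdtd_mg_spectrum():
    """Perfect-lattice FDTD, 30-degree rotated ('MG') incidence."""
    box_y = 3 * np.sqrt(3) * 395.0
    spec = LatticeSpec(d=395.0, a=375.0, box=(5000.0, box_y), ff=0.6, orientation=30.0)
    cfg = FdtdConfig(box=spec.box, run_time_fs=300.0,
                     wavelengths=np.arange(300.0, 700.0 + 1e-9, 2.0))
    return run_fdtd(make_hexagonal(spec), config=cfg)


@pytest.fixture(scope="session")
def disorder_sweep_results():
    """7-realization disorder sweep at desk scale (the long fixture)."""
    from coloptics.fdtd import disorder_sweep, peak_metrics
    from coloptics.structure import DisorderSpec

    spec = LatticeSpec(d=395.0, a=375.0, box=(2500.0, 6 * 395.0), ff=0.6)
    cfg = FdtdConfig(box=spec.box, run_time_fs=220.0,
                     wavelengths=np.arange(300.0, 700.0 + 1e-9, 4.0))
    perfect = run_fdtd(make_hexagonal(spec), config=cfg)
    levels = (
        [DisorderSpec(sigma_k=s, sigma_phi=0.0, seed=11) for s in (0.02, 0.08)]
        + [DisorderSpec(sigma_k=0.0, sigma_phi=p, seed=11) for p in (8.0, 30.0)]
        + [DisorderSpec(sigma_k=0.0, sigma_phi=None, seed=11)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = disorder_sweep(spec, levels, cfg)
    return {"perfect": peak_metrics(perfect, (430.0, 520.0)),
            "perfect_spectrum": perfect, "rows": rows}
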