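import numpy as np
import pytest

import casfret as cf


@pytest.fixture(scope="session")
def analysis_config():
    return cf.AnalysisConfig()


def _threshold_dwells(dataset, config):
    trajs = [cf.correct_trace(t, config) for t in dataset.traces]
    dwells = []
    for t in trajs:
        dwells.extend(cf.extract_dwells(t, config))
    return trajs, dwells


@pytest.fixture(scope="session")
def dataset_5_20():
    """5-20_mm steady-state dataset shared across dwell-kinetics tests."""
    ds = cf.generate_dataset("5-20_mm", n_molecules=100, duration=120, seed=101)
    cfg = cf.AnalysisConfig.from_manifest(ds.manifest)
    trajs, dwells = _threshold_dwells(ds, cfg)
    return ds, cfg, trajs, dwells


@pytest.fixture(scope="session")
def dataset_9_20():
    ds = cf.generate_dataset("9-20_mm", n_molecules=80, duration=300, seed=103)
    cfg = cf.AnalysisConfig.from_manifest(ds.manifest)
    trajs, dwells = _threshold_dwells(ds, cfg)
    return ds, cfg, trajs, dwells


@pytest.fixture(scope="session")
def two_state_scheme():
    """Simple U <-> H scheme (binding 5/s at reference conc, unbinding 2/s)."""
    return cf.KineticScheme(
        rate_constants={
            ("U", "H"): cf.RateConstant(5.0),
            ("H", "U"): cf.RateConstant(2.0),
        }
    )


def make_fret_trajectory(fret, molecule_id="m0", dt=0.1):
    """Build a FretTrajectory directly from FRET values (all frames valid)."""
    fret = np.asarray(fret, dtype=float)
    return cf.FretTrajectory(
        molecule_id=molecule_id,
        time_s=np.arange(fret.size) * dt,
        fret=fret,
        donor_corrected=500 * (1 - fret),
        acceptor_corrected=500 * fret,
        valid_through=fret.size - 1,
        frame_interval=dt,
    )
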