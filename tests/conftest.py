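import numpy as np
import pandas as pd
import pytest

RAMP = np.arange(25.0, 56.0)


def piecewise_curve(psi, m1, m2, fvfm25=0.80, grid=RAMP):
    """Exact two-segment Fv/Fm truth anchored at the 25 degC reading."""
    return fvfm25 + m1 * (grid - grid[0]) + (m2 - m1) * np.maximum(0.0, grid - psi)


@pytest.fixture
def ramp():
    return RAMP.copy()


@pytest.fixture
def worked_curve(ramp):
    """The reference curve: Fv/Fm(25)=0.80, m1=-0.005, psi=46, m2=-0.151."""
    return ramp, piecewise_curve(46.0, -0.005, -0.151)


@pytest.fixture
def long_tables():
    """A small long-format readings table plus its sample map."""
    rows = []
    y = piecewise_curve(48.0, -0.005, -0.095)  # stays within [0, 1] over the ramp
    for t, v in zip(RAMP, y):
        rows.append({"sample_id": "S1", "temperature": t, "f_o": 1 - v, "f_m": 1.0})
    rows.append({"sample_id": "S1", "temperature": "room", "f_o": 0.2, "f_m": 1.0})
    readings = pd.DataFrame(rows)
    sample_map = pd.DataFrame(
        [
            {
                "sample_id": "S1",
                "genotype_id": "G1",
                "species": "sim",
                "round_id": "r1",
                "time_slot": "am",
                "container_id": "c1",
            }
        ]
    )
    return readings, sample_map


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic fixture bundle on disk, shared across tests."""
    from phtmap.pipeline import make_fixture

    outdir = tmp_path_factory.mktemp("bundle")
    paths = make_fixture(seed=7, preset="small", outdir=str(outdir))
    return paths
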