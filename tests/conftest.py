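import numpy as np
import pytest

import xpsprot as xp


@pytest.fixture(scope="session")
def default_grid():
    return xp.energy_grid()


@pytest.fixture(scope="session")
def pcl_spectrum(default_grid):
    """Max-normalized theoretical PCL substrate spectrum."""
    return xp.simulate_protein_spectrum(xp.pcl_theoretical_profile(),
                                        grid=default_grid)


@pytest.fixture(scope="session")
def pcl_cooh_spectrum(default_grid):
    return xp.simulate_protein_spectrum(xp.pcl_cooh_preset_profile(),
                                        grid=default_grid)


@pytest.fixture(scope="session")
def apoa1_spectrum(default_grid):
    prof = xp.composition_profile(xp.packaged_sequence("apoa1"))
    return xp.simulate_protein_spectrum(prof, grid=default_grid)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return path
    return _write


@pytest.fixture
def gaussian_spectrum():
    """Single Gaussian peak on a zero baseline, flat tails inside the grid."""
    grid = xp.energy_grid(280.0, 294.0, 0.02)
    sigma = 1.1 / (2 * np.sqrt(2 * np.log(2)))
    peak = np.exp(-0.5 * ((grid - 287.0) / sigma) ** 2)
    return xp.Spectrum(grid, 1e4 * peak, ("synthetic-gaussian",))
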