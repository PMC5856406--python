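"""Shared fixtures: presets, small grids and small synthetic ensembles.

Ensembles are module-scoped because field generation dominates test run
time; tests must not mutate them.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from rootflow import (
    PRESETS,
    Grid,
    JetFlowParams,
    PulseWaveform,
    VelocityField,
    generate_ensemble,
)


@pytest.fixture(scope="session")
def waveform():
    return PulseWaveform()


@pytest.fixture(scope="session")
def preset_m():
    return PRESETS["M"]


@pytest.fixture(scope="session")
def grid_m(preset_m):
    """1 mm grid over the whole M lumen domain."""
    return Grid.for_root(preset_m, 1.0)


@pytest.fixture(scope="session")
def coarse_grid_m(preset_m):
    """Coarse grid for ensemble statistics tests."""
    return Grid.for_root(preset_m, 2.0)


@pytest.fixture(scope="session")
def small_ensemble(preset_m, waveform, coarse_grid_m):
    jet = JetFlowParams.for_phantom(preset_m)
    return generate_ensemble(
        preset_m, jet, waveform, coarse_grid_m,
        n_replicates=6, master_seed=11, materialize=True,
    )


@dataclass
class StubEnsemble:
    """Minimal phase-ensemble duck type holding explicit field arrays."""

    grid: Grid
    mask: np.ndarray
    fields: list  # fields[j][k] -> (3, nx, ny, nz)
    dt: float = 0.03

    @property
    def n_phases(self):
        return len(self.fields)

    @property
    def n_replicates(self):
        return len(self.fields[0])

    @property
    def phase_times(self):
        return self.dt * np.arange(self.n_phases)

    def iter_phase(self, j):
        for k, u in enumerate(self.fields[j]):
            yield VelocityField(grid=self.grid, u=u, mask=self.mask,
                                t=self.dt * j, replicate=k)

    def __len__(self):
        return self.n_phases * self.n_replicates


@pytest.fixture
def stub_ensemble_factory():
    def make(fields_per_phase, spacing=1.0):
        arr = np.asarray(fields_per_phase[0][0])
        shape = arr.shape[1:]
        grid = Grid(origin=(0.0, 0.0, 0.0), spacing=(spacing,) * 3, counts=shape)
        mask = np.ones(shape, dtype=bool)
        return StubEnsemble(grid=grid, mask=mask, fields=fields_per_phase)

    return make
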