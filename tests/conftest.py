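"""Shared fixtures.  Heavy simulation products are session-scoped so the
explosion-family and intensity-scan experiments run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from spisim import (
    AtomicDataTable,
    FELPulse,
    make_toy_protein,
)
from spisim.cei_dynamics import atomization_scan, run_explosion
from spisim.footprint_analysis import project
from spisim.pipeline import stage_seed

#: printed CEI study conditions: 2.3e10 photons, 1000 nm focus, 4 nm, 12 fs
CEI_PULSE = FELPulse(2.3e10, 4.0, 1000.0, 12.0)

#: printed CDI study conditions: 1e11 photons, 4.3 nm, 5 um focus
CDI_PULSE = FELPulse(1e11, 4.3, 5000.0, 12.0)


@pytest.fixture(scope="session")
def table() -> AtomicDataTable:
    return AtomicDataTable.bundled()


@pytest.fixture(scope="session")
def cei_pulse() -> FELPulse:
    return CEI_PULSE


@pytest.fixture(scope="session")
def cdi_pulse() -> FELPulse:
    return CDI_PULSE


@pytest.fixture(scope="session")
def toy100():
    return make_toy_protein(100, seed=7)


@pytest.fixture(scope="session")
def explosion_families(table):
    """2 distinct 70-residue toy proteins x 20 seeded explosions under the
    CEI pulse.

    Returns (footprints, labels): a desk-scale version of the
    many-runs-per-protein footprint reproducibility experiment.
    """
    footprints, labels = [], []
    for s_idx, struct_seed in enumerate((101, 202)):
        structure = make_toy_protein(70, struct_seed)
        for run in range(20):
            seed = stage_seed(1, f"cei:{s_idx}:{run}")
            result = run_explosion(structure, CEI_PULSE, table, seed=seed)
            footprints.append(project(result, label=structure.label, seed=seed))
            labels.append(s_idx)
    return footprints, labels


@pytest.fixture(scope="session")
def intensity_scan(table):
    """Pulse-intensity scan on a ~500-atom toy protein, 5 seeds per point."""
    structure = make_toy_protein(33, seed=7)  # 496 atoms
    return atomization_scan(
        structure,
        CEI_PULSE,
        table,
        intensity_scales=(1.0, 10.0, 100.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0),
        seeds=(0, 1, 2, 3, 4),
    )


@pytest.fixture(scope="session")
def sphere_pattern():
    """Noise-free diffraction of a uniform sphere (R = 48 nm) on the
    printed detector geometry; used by the form-factor oracle tests."""
    import dataclasses

    from spisim import DetectorGeometry, VIRUS_LIKE, diffract, make_icosahedral_particle

    radius = 48.0
    particle = make_icosahedral_particle(2 * radius, VIRUS_LIKE, 1.5, shape="sphere")
    padded = dataclasses.replace(
        particle, grid=np.pad(particle.grid, [(0, s) for s in particle.grid.shape])
    )
    pattern = diffract(padded, CDI_PULSE, DetectorGeometry(), seed=0, noise=False)
    return pattern, radius
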