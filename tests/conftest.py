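import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from leafletlab import synth, xrr


@pytest.fixture
def two_slab_model():
    """Two-slab monolayer stack: 17.3 Å tails over 9.0 Å heads on water."""
    return xrr.SlabModel(
        slabs=[xrr.Slab(17.3, 0.30, 3.0), xrr.Slab(9.0, 0.45, 3.0)],
        subphase_rho_e=0.334, wavelength=1.55, subphase_roughness=3.0)


@pytest.fixture
def qz_grid():
    return np.linspace(0.025, 0.6, 1200)


@pytest.fixture
def single_mode_fit():
    """Δπ∞ = 1.0 mN/m, one Maxwell mode A = 0.5 mN/m, τ = 100 s."""
    from leafletlab.rheology import ExponentialFit
    return ExponentialFit(delta_pi_inf=1.0, modes=[(0.5, 100.0)])


@pytest.fixture
def hex_sterol_monolayer():
    """16 single-reference-point sterols per leaflet on a hexagonal lattice."""
    spec = synth.ToyMonolayerSpec(
        n_lipids_per_leaflet=16, species_fractions={"STE": 1.0},
        lattice="hexagonal", box=(30.0, 30.0, 100.0), water_thickness=20.0,
        seed=11)
    return synth.gen_toy_monolayer(spec), synth.toy_topology(spec)


@pytest.fixture
def phospholipid_monolayer():
    """All-trans vertical phospholipids on a square lattice."""
    spec = synth.ToyMonolayerSpec(
        n_lipids_per_leaflet=16, species_fractions={"PLA": 1.0},
        lattice="square", chain_conformation="all_trans", tilt_deg=0.0,
        box=(40.0, 40.0, 120.0), water_thickness=30.0, seed=7)
    return synth.gen_toy_monolayer(spec), synth.toy_topology(spec)
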