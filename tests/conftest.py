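import numpy as np
import pytest

import srbind as sb


@pytest.fixture(scope="session")
def hres():
    """Bundled seven-HRE GR reference panel."""
    return sb.load_reference_hres()


@pytest.fixture(scope="session")
def affinity_pairs(hres):
    """(K_app, fold-activation) pairs from the reference panel."""
    return [(h.k_app, h.fold_activation) for h in hres]


@pytest.fixture(scope="session")
def fig10_species():
    """Three competing receptor archetypes: weak/moderate/strong dimerizers.

    All share k_half = 1 uM and k_pal = 10 nM; they differ only in
    dimerization and cooperativity (red 10 uM / 200, blue 1 uM / 50,
    green 16 nM / 1).
    """
    return [
        sb.ReceptorSpecies(name="red", k_dim=10e-6, k_half=1e-6,
                           k_pal=10e-9, k_c=200.0),
        sb.ReceptorSpecies(name="blue", k_dim=1e-6, k_half=1e-6,
                           k_pal=10e-9, k_c=50.0),
        sb.ReceptorSpecies(name="green", k_dim=16e-9, k_half=1e-6,
                           k_pal=10e-9, k_c=1.0),
    ]


@pytest.fixture(scope="session")
def scaling():
    """Reference global scaling: amplitude 4, baseline 1, 1 nM per ng."""
    return sb.ScalingParameters(d=4.0, e=1.0, f=1e-9)


@pytest.fixture(scope="session")
def titration_grid():
    """12 log-spaced free-monomer concentrations, 1 nM - 3 uM."""
    return np.logspace(-9, np.log10(3e-6), 12)
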