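import numpy as np
import pytest

from tandemww.itc import default_schedule
from tandemww.synthetic import make_dumbbell_ensemble


@pytest.fixture(scope="session")
def dumbbell():
    """Ten-conformer two-domain ensemble with a mobile 8-residue linker.

    Domains span residues 1-12 and 21-32 (12 residues each), linker 13-20.
    """
    ens, truth = make_dumbbell_ensemble(
        n_conformers=10,
        domain_size=12,
        linker_length=8,
        linker_dispersion=25.0,
        seed=20240
    )
    return ens, truth


@pytest.fixture(scope="session")
def rigid_dumbbell():
    """Zero-dispersion limit: every conformer identical."""
    ens, _ = make_dumbbell_ensemble(
        n_conformers=4, domain_size=12, linker_length=8,
        linker_dispersion=0.0, seed=7,
    )
    return ens


@pytest.fixture
def itc_schedule():
    """26 injections (0.4 uL first, then 1.5 uL), peptide 30 uM in the cell,
    tandem 450 uM in the syringe, 200 uL cell."""
    return default_schedule()
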