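import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bzraman.boltzmann import WeightedEnsemble
from bzraman.ensemble_io import load_table1_fixture, load_table2_fixture
from bzraman.models import Ensemble
from bzraman.synthetic import ModePlan, SyntheticSpec, build_peptide, synthesize_ensemble

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def helical_hexapeptide():
    return build_peptide("EGEDEA", (-57.0, -47.0))


@pytest.fixture(scope="session")
def synthetic_ensemble():
    """Small fully-populated ensemble with planted, analytically known
    content: two conformers, ΔE = (0, RT·ln 2), one pure amide I mode at
    raw 1709.3 cm⁻¹ and one alphaCOO mode per conformer."""
    from bzraman.boltzmann import R_KCAL_PER_MOL_K

    rt_ln2 = R_KCAL_PER_MOL_K * 298.0 * np.log(2.0)
    plan = [
        ModePlan("amide_I", 1709.3, 12.0, 1.0),
        ModePlan("alphaCOO", 1660.0, 8.0, 0.9),
    ]
    spec = SyntheticSpec(
        sequence="EGEDEA", n_conformers=2, seed=42,
        relative_energies=[0.0, rt_ln2],
        mode_plan=[plan, plan],
    )
    return synthesize_ensemble(spec)


def weighted_from_printed(table1, fragment, temperature=298.0) -> WeightedEnsemble:
    """Fixture-route weighted ensemble: printed populations attached to the
    fragment's energy ladder."""
    ensemble = table1.to_ensemble(fragment)
    return WeightedEnsemble.from_weights(
        ensemble, table1.weights(fragment), temperature)
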