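import numpy as np
import pytest

import rdtraffic as rdt

# coarse-but-converged resolutions keep the suite fast; invariance of the
# derived responses under refinement is itself tested
COARSE = (12, 4, 24)
MEDIUM = (16, 4, 40)


@pytest.fixture(scope="session")
def default_geometry() -> rdt.Geometry:
    return rdt.Geometry()


@pytest.fixture(scope="session")
def default_params() -> rdt.KineticParameters:
    return rdt.KineticParameters()


@pytest.fixture(scope="session")
def default_diffusion() -> rdt.DiffusionCoefficients:
    return rdt.DiffusionCoefficients()


@pytest.fixture(scope="session")
def default_initial() -> rdt.InitialConditions:
    return rdt.InitialConditions()


@pytest.fixture(scope="session")
def binding_free_params() -> rdt.KineticParameters:
    """All trafficking and source processes switched off; binding only."""
    return rdt.KineticParameters(
        q_syn=0.0, k_int_free=0.0, k_int_bound=0.0, k_rec_free=0.0,
        k_rec_bound=0.0, k_deg_free=0.0, k_deg_bound=0.0, k_dephos=0.0,
    )


@pytest.fixture(scope="session")
def inert_params(binding_free_params) -> rdt.KineticParameters:
    """Everything off including binding: pure transport."""
    from dataclasses import replace
    return replace(binding_free_params, k_on=0.0, k_off=0.0)


def binding_equilibrium_amounts(
    l_total: float, r_total: float, v_free: float, v_shell: float, kd: float
) -> tuple[float, float, float]:
    """Independent closed-form equilibrium for ligand + receptor in two
    volumes: free ligand L occupies ``v_free`` (µm³), receptors and
    complexes live in ``v_shell``.  Amounts in nM·µm³.

    Solves L·RS = Kd·LRS with the two mass balances; returns
    (L nM, RS nM, LRS nM) with RS/LRS shell-referenced.
    """
    # unknown x = LRS amount (nM·µm³):
    # (l_total - x)(r_total - x) = Kd · v_free · x, smaller root
    b = -(l_total + r_total + kd * v_free)
    c = l_total * r_total
    x = (-b - np.sqrt(b * b - 4 * c)) / 2.0
    return ((l_total - x) / v_free, (r_total - x) / v_shell, x / v_shell)
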