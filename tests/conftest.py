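import numpy as np
import pytest

from simsir import (
    Domain,
    Field2D,
    OtfSpec,
    SimParams,
    make_bead_surface,
    simulate_stack,
)

# water-immersion objective, far-red emission: kc = 2*1.2/0.680 um^-1
NA = 1.2
LAMBDA_EM = 680.0
PIXEL_NM = 80.0


@pytest.fixture(scope="session")
def otf() -> OtfSpec:
    return OtfSpec(na=NA, lambda_em_nm=LAMBDA_EM)


@pytest.fixture(scope="session")
def bead_object():
    """A seeded sub-resolution bead field (the standard SIM test sample)."""
    return make_bead_surface(60, 128, PIXEL_NM, diameter_nm=120.0, seed=1)


def params_from_truth(truth: list[dict]) -> list[SimParams]:
    """Ground-truth pattern parameters in the estimator's output format."""
    out = []
    for t in truth:
        mods = tuple(t["modulations"])
        phases = tuple(((m + 1) * t["phase"] + np.pi) % (2 * np.pi) - np.pi
                       for m in range(len(mods)))
        out.append(SimParams(tuple(t["k_vector"]), phases, mods, fit_quality=1.0))
    return out


@pytest.fixture(scope="session")
def two_beam_stack(bead_object, otf):
    """Noise-free two-beam acquisition with known parameters."""
    stack, truth = simulate_stack(
        bead_object, otf, n_angles=3, n_phases=3, n_bands=2,
        phase_offsets=[0.7, -1.1, 2.0], modulation=0.8, photons=None, seed=1,
    )
    return stack, truth


@pytest.fixture(scope="session")
def three_beam_stack(bead_object, otf):
    """Noise-free three-beam acquisition (OMX-like geometry, 15 frames)."""
    stack, truth = simulate_stack(
        bead_object, otf, n_angles=3, n_phases=5, n_bands=3,
        phase_offsets=[0.4, -0.9, 1.7], modulation=(1.0, 0.5), photons=None, seed=5,
    )
    return stack, truth


def angdiff(a: float, b: float) -> float:
    """Absolute angular difference modulo 2*pi."""
    return abs((a - b + np.pi) % (2.0 * np.pi) - np.pi)


def uniform_field(n: int = 128, pixel_nm: float = PIXEL_NM) -> Field2D:
    return Field2D(np.ones((n, n)), pixel_nm, Domain.REAL)
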