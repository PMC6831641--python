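"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import brentq

from titrshape import (
    FourStateModel,
    SpinParams,
    ThreeStateModel,
    TwoStateModel,
)


# ---------------------------------------------------------------------------
# independent free-ligand oracle: binding-polynomial mass balance + bisection
# (a different algebraic route from the closed-form quadratic/cubic roots)
# ---------------------------------------------------------------------------

def _bound_ligand(ell: float, ptotal: float, model) -> float:
    """Ligand bound to protein at free-ligand concentration ell."""
    if isinstance(model, TwoStateModel):
        q = 1.0 + ell / model.kd
        return ptotal * (ell / model.kd) / q
    if isinstance(model, ThreeStateModel):
        frac = ell / model.kd + ell / (model.kd * model.keq)
        return ptotal * frac / (1.0 + frac)
    if isinstance(model, FourStateModel):
        t1 = ell / model.kd_a1
        t2 = ell / model.kd_b1
        t3 = ell * ell / (model.kd_b1 * model.kd_a2)
        q = 1.0 + t1 + t2 + t3
        return ptotal * (t1 + t2 + 2.0 * t3) / q
    raise TypeError(type(model))


def bisection_free_ligand(ptotal: float, ltotal: float, model) -> float:
    """Free [L] by bracketed root finding on L + bound(L) - Ltotal."""
    if ltotal == 0.0:
        return 0.0

    def residual(ell):
        return ell + _bound_ligand(ell, ptotal, model) - ltotal

    return brentq(residual, 0.0, ltotal, xtol=1e-300, rtol=1e-15, maxiter=300)


@pytest.fixture
def two_state_spins():
    return SpinParams.from_linewidths([0.0, 500.0], [100.0, 100.0])


@pytest.fixture
def three_state_spins():
    return SpinParams.from_linewidths([0.0, 500.0, 1000.0], [100.0] * 3)


@pytest.fixture
def four_state_spins():
    return SpinParams.from_linewidths([0.0, 400.0, 600.0, 1000.0], [100.0] * 4)


def random_models(rng: np.random.Generator, kind: str, n: int):
    """Random valid models + titration points for property suites."""
    for _ in range(n):
        ptotal = 10.0 ** rng.uniform(0, 4)
        ltotal = rng.uniform(0.0, 5.0 * ptotal)
        kd = 10.0 ** rng.uniform(-2, 4)
        koff = 10.0 ** rng.uniform(-1, 5)
        if kind == "2state":
            model = TwoStateModel(kd=kd, koff=koff)
        elif kind == "3state":
            model = ThreeStateModel(kd=kd, keq=10.0 ** rng.uniform(-2, 2),
                                    koff=koff, krev=10.0 ** rng.uniform(-1, 5))
        else:
            model = FourStateModel(
                kd_a1=kd, kd_b1=10.0 ** rng.uniform(-2, 4),
                kd_a2=10.0 ** rng.uniform(-2, 4),
                koff_a1=koff, koff_b1=10.0 ** rng.uniform(-1, 5),
                koff_a2=10.0 ** rng.uniform(-1, 5),
                koff_b2=10.0 ** rng.uniform(-1, 5))
        yield ptotal, ltotal, model
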