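"""Equilibrium species concentrations and kinetic exchange matrices.

Three binding schemes for an NMR-observed protein P titrated with ligand L:

* two-state       P + L <-> PL
* three-state     P + L <-> PL <-> P'L        (binding then isomerization)
* four-state      P + L <-> {PL, LP} + L <-> LPL   (two binding sites, A and B)

Concentrations are in µM, first-order rates in s⁻¹, so second-order on
rates carry µM⁻¹ s⁻¹.  The free-ligand concentration at each titration
point is the non-negative root of a quadratic (two- and three-state) or
cubic (four-state) mass-balance polynomial; every other species follows in
closed form.  The pseudo-first-order exchange matrix built from these
concentrations has zero column sums and is stationary on the equilibrium
species vector (detailed balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TwoStateModel",
    "ThreeStateModel",
    "FourStateModel",
    "TitrationPoint",
    "SpeciesState",
    "solve_free_ligand",
    "species_concentrations",
    "exchange_matrix",
    "solve_free_ligand_two_state",
    "solve_free_ligand_three_state",
    "solve_free_ligand_four_state",
    "species_two_state",
    "species_three_state",
    "species_four_state",
]


class InvalidInputError(ValueError):
    """Raised when model parameters or concentrations are unphysical."""


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not np.isfinite(value):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")


def _require_positive(**named: float) -> None:
    _require_finite(**named)
    for name, value in named.items():
        if value <= 0:
            raise InvalidInputError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(**named: float) -> None:
    _require_finite(**named)
    for name, value in named.items():
        if value < 0:
            raise InvalidInputError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class TwoStateModel:
    """Single-site binding P + L <-> PL.

    Parameters
    ----------
    kd : float
        Dissociation constant K_D = [P][L]/[PL], µM.
    koff : float
        Dissociation rate, s⁻¹.  ``kon = koff / kd`` is derived, never free.
    """

    kd: float
    koff: float = 0.0

    species = ("P", "PL")

    def __post_init__(self) -> None:
        _require_positive(kd=self.kd)
        _require_nonnegative(koff=self.koff)

    @property
    def kon(self) -> float:
        """Association rate, µM⁻¹ s⁻¹."""
        return self.koff / self.kd

    @property
    def n_species(self) -> int:
        return 2


@dataclass(frozen=True)
class ThreeStateModel:
    """Binding followed by isomerization: P + L <-> PL <-> P'L.

    ``keq = [PL]/[P'L]`` is the isomerization equilibrium constant; the
    forward isomerization rate ``kfwd = krev / keq`` is derived from the
    reverse rate.
    """

    kd: float
    keq: float
    koff: float = 0.0
    krev: float = 0.0

    species = ("P", "PL", "P'L")

    def __post_init__(self) -> None:
        _require_positive(kd=self.kd, keq=self.keq)
        _require_nonnegative(koff=self.koff, krev=self.krev)

    @property
    def kon(self) -> float:
        return self.koff / self.kd

    @property
    def kfwd(self) -> float:
        return self.krev / self.keq

    @property
    def n_species(self) -> int:
        return 3


@dataclass(frozen=True)
class FourStateModel:
    """Two-site binding cycle P <-> {PL, LP} <-> LPL.

    Binding at site A gives PL, at site B gives LP; the doubly ligated
    species is LPL.  Only three dissociation constants are independent:
    thermodynamic cycle closure fixes ``kd_b2 = kd_b1 * kd_a2 / kd_a1``.
    All four off rates are free; each on rate is ``koff_i / kd_i``.
    """

    kd_a1: float
    kd_b1: float
    kd_a2: float
    koff_a1: float = 0.0
    koff_b1: float = 0.0
    koff_a2: float = 0.0
    koff_b2: float = 0.0

    species = ("P", "PL", "LP", "LPL")

    def __post_init__(self) -> None:
        _require_positive(kd_a1=self.kd_a1, kd_b1=self.kd_b1, kd_a2=self.kd_a2)
        _require_nonnegative(
            koff_a1=self.koff_a1,
            koff_b1=self.koff_b1,
            koff_a2=self.koff_a2,
            koff_b2=self.koff_b2,
        )

    @property
    def kd_b2(self) -> float:
        """Fourth K_D, fixed by cycle closure (never a free parameter)."""
        return self.kd_b1 * self.kd_a2 / self.kd_a1

    @property
    def kon_a1(self) -> float:
        return self.koff_a1 / self.kd_a1

    @property
    def kon_b1(self) -> float:
        return self.koff_b1 / self.kd_b1

    @property
    def kon_a2(self) -> float:
        return self.koff_a2 / self.kd_a2

    @property
    def kon_b2(self) -> float:
        return self.koff_b2 / self.kd_b2

    @property
    def n_species(self) -> int:
        return 4


BindingModel = TwoStateModel | ThreeStateModel | FourStateModel


@dataclass(frozen=True)
class TitrationPoint:
    """Total protein and ligand concentrations (µM) at one titration point."""

    ptotal: float
    ltotal: float

    def __post_init__(self) -> None:
        _require_positive(ptotal=self.ptotal)
        _require_nonnegative(ltotal=self.ltotal)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (µM) of every protein species plus free L."""

    labels: tuple[str, ...]
    concentrations: np.ndarray
    free_ligand: float
    ptotal: float
    ltotal: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if len(self.labels) != self.concentrations.size:
            raise InvalidInputError("labels and concentrations length mismatch")

    def __getitem__(self, label: str) -> float:
        return float(self.concentrations[self.labels.index(label)])

    @property
    def n_species(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# free-ligand solvers
# ---------------------------------------------------------------------------

def _positive_quadratic_root(b: float, c: float) -> float:
    """Non-negative root of L² + b·L + c = 0 with c ≤ 0 (the '+√' branch).

    Written to avoid cancellation when b is large and positive (strong
    protein excess), where the naive −b + √(b² − 4c) loses precision.
    """
    disc = b * b - 4.0 * c
    # c <= 0 guarantees disc >= b², so the root is real and >= 0
    if b > 0:
        return -2.0 * c / (b + np.sqrt(disc))
    return 0.5 * (-b + np.sqrt(disc))


def solve_free_ligand_two_state(pt: TitrationPoint, model: TwoStateModel) -> float:
    """Free-ligand concentration for the two-state scheme.

    [L] is the unique non-negative root of
    ``L² + (Ptotal − Ltotal + K_D)·L − K_D·Ltotal = 0``.
    """
    if pt.ltotal == 0.0:
        return 0.0
    b = pt.ptotal - pt.ltotal + model.kd
    c = -model.kd * pt.ltotal
    return min(_positive_quadratic_root(b, c), pt.ltotal)


def solve_free_ligand_three_state(pt: TitrationPoint, model: ThreeStateModel) -> float:
    """Free-ligand concentration for the three-state scheme.

    [L] is the unique non-negative root of
    ``(Keq+1)·L² + ((Keq+1)(Ptotal − Ltotal) + K_D·Keq)·L − K_D·Keq·Ltotal = 0``.
    """
    if pt.ltotal == 0.0:
        return 0.0
    a = model.keq + 1.0
    b = (a * (pt.ptotal - pt.ltotal) + model.kd * model.keq) / a
    c = -model.kd * model.keq * pt.ltotal / a
    return min(_positive_quadratic_root(b, c), pt.ltotal)


def _four_state_ligand_residual(ell: float, pt: TitrationPoint, model: FourStateModel) -> float:
    """Ligand mass-balance residual; strictly increasing in [L]."""
    p = _four_state_free_protein(ell, pt.ptotal, model)
    pl = p * ell / model.kd_a1
    lp = p * ell / model.kd_b1
    lpl = p * ell * ell / (model.kd_b1 * model.kd_a2)
    return ell + pl + lp + 2.0 * lpl - pt.ltotal


def _four_state_free_protein(ell: float, ptotal: float, model: FourStateModel) -> float:
    ka1, kb1, ka2 = model.kd_a1, model.kd_b1, model.kd_a2
    denom = ka1 * ell * ell + (ka2 * kb1 + ka1 * ka2) * ell + ka1 * ka2 * kb1
    return ka1 * ka2 * kb1 * ptotal / denom


def solve_free_ligand_four_state(pt: TitrationPoint, model: FourStateModel) -> float:
    """Free-ligand concentration for the four-state scheme.

    [L] is the real root in [0, Ltotal] of the cubic mass-balance
    polynomial; if the polynomial root is numerically unreliable the solver
    falls back to bracketed root finding on the (monotone) ligand
    mass-balance residual.
    """
    if pt.ltotal == 0.0:
        return 0.0
    ka1, kb1, ka2 = model.kd_a1, model.kd_b1, model.kd_a2
    c3 = ka1
    c2 = 2.0 * ka1 * pt.ptotal - ka1 * pt.ltotal + ka2 * kb1 + ka1 * ka2
    c1 = (ka2 * kb1 + ka1 * ka2) * (pt.ptotal - pt.ltotal) + ka1 * ka2 * kb1
    c0 = -ka1 * ka2 * kb1 * pt.ltotal

    roots = np.roots([c3, c2, c1, c0])
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    pad = 1e-12 * pt.ltotal
    in_range = real[(real >= -pad) & (real <= pt.ltotal + pad)]
    if in_range.size:
        ell = float(np.clip(in_range[0], 0.0, pt.ltotal))
        # accept only if it actually satisfies the mass balance
        if abs(_four_state_ligand_residual(ell, pt, model)) <= 1e-8 * pt.ltotal:
            return ell
    # bisection fallback: residual is monotone increasing on [0, Ltotal]
    lo, hi = 0.0, pt.ltotal
    flo = _four_state_ligand_residual(lo, pt, model)
    fhi = _four_state_ligand_residual(hi, pt, model)
    if flo > 0 or fhi < 0:
        raise InvalidInputError("no free-ligand root in [0, Ltotal]")
    return float(brentq(_four_state_ligand_residual, lo, hi, args=(pt, model),
                        xtol=1e-14, rtol=1e-15, maxiter=200))


def solve_free_ligand(pt: TitrationPoint, model: BindingModel) -> float:
    """Dispatch to the scheme-specific free-ligand solver."""
    if isinstance(model, TwoStateModel):
        return solve_free_ligand_two_state(pt, model)
    if isinstance(model, ThreeStateModel):
        return solve_free_ligand_three_state(pt, model)
    if isinstance(model, FourStateModel):
        return solve_free_ligand_four_state(pt, model)
    raise InvalidInputError(f"unknown model type {type(model)!r}")


# ---------------------------------------------------------------------------
# species concentrations
# ---------------------------------------------------------------------------

def species_two_state(pt: TitrationPoint, model: TwoStateModel) -> SpeciesState:
    """[P] = K_D·Ptotal/([L] + K_D), [PL] = [P][L]/K_D."""
    ell = solve_free_ligand_two_state(pt, model)
    p = model.kd * pt.ptotal / (ell + model.kd)
    pl = ell * p / model.kd
    return SpeciesState(model.species, np.array([p, pl]), ell, pt.ptotal, pt.ltotal)


def species_three_state(pt: TitrationPoint, model: ThreeStateModel) -> SpeciesState:
    """[P], [PL], [P'L] with [PL]/[P'L] = Keq exactly."""
    ell = solve_free_ligand_three_state(pt, model)
    p = model.kd * model.keq * pt.ptotal / ((model.keq + 1.0) * ell + model.kd * model.keq)
    pl = p * ell / model.kd
    ppl = pl / model.keq
    return SpeciesState(model.species, np.array([p, pl, ppl]), ell, pt.ptotal, pt.ltotal)


def species_four_state(pt: TitrationPoint, model: FourStateModel) -> SpeciesState:
    """[P], [PL], [LP], [LPL]; the ligand balance counts [LPL] twice."""
    ell = solve_free_ligand_four_state(pt, model)
    p = _four_state_free_protein(ell, pt.ptotal, model)
    pl = p * ell / model.kd_a1
    lp = p * ell / model.kd_b1
    lpl = p * ell * ell / (model.kd_b1 * model.kd_a2)
    return SpeciesState(model.species, np.array([p, pl, lp, lpl]), ell, pt.ptotal, pt.ltotal)


def species_concentrations(pt: TitrationPoint, model: BindingModel) -> SpeciesState:
    """Equilibrium species concentrations at one titration point."""
    if isinstance(model, TwoStateModel):
        return species_two_state(pt, model)
    if isinstance(model, ThreeStateModel):
        return species_three_state(pt, model)
    if isinstance(model, FourStateModel):
        return species_four_state(pt, model)
    raise InvalidInputError(f"unknown model type {type(model)!r}")


def ligand_stoichiometry(model: BindingModel) -> np.ndarray:
    """Ligands bound per protein species, in species order."""
    if isinstance(model, TwoStateModel):
        return np.array([0.0, 1.0])
    if isinstance(model, ThreeStateModel):
        return np.array([0.0, 1.0, 1.0])
    if isinstance(model, FourStateModel):
        return np.array([0.0, 1.0, 1.0, 2.0])
    raise InvalidInputError(f"unknown model type {type(model)!r}")


# ---------------------------------------------------------------------------
# exchange matrix
# ---------------------------------------------------------------------------

def exchange_matrix(model: BindingModel, state: SpeciesState) -> np.ndarray:
    """Pseudo-first-order exchange matrix K (s⁻¹) for the Bloch-McConnell
    evolution.

    Element K[i, j] (i ≠ j) is the rate from species j into species i;
    the diagonal collects the total rate out of each species, so every
    column sums to zero and K annihilates the equilibrium species vector.
    """
    if state.n_species != model.n_species:
        raise InvalidInputError(
            f"state has {state.n_species} species, model expects {model.n_species}"
        )
    ell = state.free_ligand
    if isinstance(model, TwoStateModel):
        kon_l = model.kon * ell
        return np.array([
            [-kon_l, model.koff],
            [kon_l, -model.koff],
        ])
    if isinstance(model, ThreeStateModel):
        kon_l = model.kon * ell
        return np.array([
            [-kon_l, model.koff, 0.0],
            [kon_l, -model.koff - model.kfwd, model.krev],
            [0.0, model.kfwd, -model.krev],
        ])
    if isinstance(model, FourStateModel):
        a1, b1 = model.kon_a1 * ell, model.kon_b1 * ell
        a2, b2 = model.kon_a2 * ell, model.kon_b2 * ell
        return np.array([
            [-(a1 + b1), model.koff_a1, model.koff_b1, 0.0],
            [a1, -model.koff_a1 - b2, 0.0, model.koff_b2],
            [b1, 0.0, -model.koff_b1 - a2, model.koff_a2],
            [0.0, b2, a2, -model.koff_b2 - model.koff_a2],
        ])
    raise InvalidInputError(f"unknown model type {type(model)!r}")
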