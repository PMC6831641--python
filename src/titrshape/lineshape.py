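"""Bloch-McConnell 1D lineshape calculation for an N-site exchanging system.

The steady-state spectrum of N exchanging spins is, at each frequency ω,
the sum of the real parts of the complex magnetization vector S solving

    (M(ω) - K) · S = P

where P holds the relative spin populations, K is the exchange matrix from
:mod:`titrshape.equilibria`, and M is diagonal with
``M_ii = R2_i + i (ω - ω0_i)``.

All frequencies, linewidths, and rates are angular quantities in s⁻¹ so
that exchange rates compare directly against chemical-shift separations
Δω.  For data whose axis is in Hz set ``freq_units="hz"``, which inserts
the 2π conversion into the off-diagonal imaginary term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model as LmfitModel

from .equilibria import InvalidInputError, SpeciesState

__all__ = [
    "SpinParams",
    "Spectrum",
    "population_vector",
    "evolution_matrix",
    "compute_spectrum",
    "lorentzian_profile",
    "fit_lorentzian",
    "FitFailureError",
]


class FitFailureError(RuntimeError):
    """Lorentzian fit did not converge or the input is degenerate."""


def _freq_scale(freq_units: str) -> float:
    if freq_units == "angular":
        return 1.0
    if freq_units == "hz":
        return 2.0 * np.pi
    raise InvalidInputError(f"freq_units must be 'angular' or 'hz', got {freq_units!r}")


@dataclass(frozen=True)
class SpinParams:
    """Per-species resonance frequencies ω0 and relaxation rates R2 (s⁻¹).

    The Lorentzian full width at half maximum is ``2 R2``; construct from a
    linewidth with :meth:`from_linewidths`.
    """

    omega0: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega0", np.asarray(self.omega0, dtype=float))
        object.__setattr__(self, "r2", np.asarray(self.r2, dtype=float))
        if self.omega0.shape != self.r2.shape or self.omega0.ndim != 1:
            raise InvalidInputError("omega0 and r2 must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.omega0)) or not np.all(np.isfinite(self.r2)):
            raise InvalidInputError("spin parameters must be finite")
        if np.any(self.r2 <= 0):
            raise InvalidInputError("every R2 must be > 0")

    @classmethod
    def from_linewidths(cls, omega0, linewidths) -> "SpinParams":
        """Build from full linewidths dω = 2·R2 (s⁻¹)."""
        lw = np.asarray(linewidths, dtype=float)
        return cls(np.asarray(omega0, dtype=float), lw / 2.0)

    @property
    def linewidths(self) -> np.ndarray:
        return 2.0 * self.r2

    @property
    def n_species(self) -> int:
        return self.omega0.size


@dataclass
class Spectrum:
    """A 1D lineshape: strictly increasing frequency axis + real intensity."""

    freq: np.ndarray
    intensity: np.ndarray
    resonance: str = "res1"
    titration_index: int | None = None
    ptotal: float | None = None
    ltotal: float | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.freq.shape != self.intensity.shape or self.freq.ndim != 1:
            raise InvalidInputError("freq and intensity must be 1-D arrays of equal length")
        if self.freq.size >= 2 and not np.all(np.diff(self.freq) > 0):
            raise InvalidInputError("frequency axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidInputError("intensities must be finite")

    def __len__(self) -> int:
        return self.freq.size


def population_vector(state: SpeciesState) -> np.ndarray:
    """Relative spin populations: species concentrations / Ptotal.

    Free ligand carries no observed spin and is excluded; the components
    sum to 1 by protein mass balance.
    """
    if state.ptotal <= 0:
        raise InvalidInputError("Ptotal must be > 0")
    return state.concentrations / state.ptotal


def evolution_matrix(
    spins: SpinParams,
    exchange: np.ndarray,
    omega: float,
    freq_units: str = "angular",
) -> np.ndarray:
    """Complex evolution matrix Ω(ω) = M(ω) − K."""
    exchange = np.asarray(exchange, dtype=float)
    n = spins.n_species
    if exchange.shape != (n, n):
        raise InvalidInputError(
            f"exchange matrix shape {exchange.shape} does not match {n} species"
        )
    scale = _freq_scale(freq_units)
    m = np.diag(spins.r2 + 1j * scale * (omega - spins.omega0))
    return m - exchange


def compute_spectrum(
    state: SpeciesState,
    spins: SpinParams,
    exchange: np.ndarray,
    grid: np.ndarray,
    freq_units: str = "angular",
    resonance: str = "res1",
) -> Spectrum:
    """Solve Ω(ω)·S = P on a frequency grid and sum the real parts of S.

    A linear solve is used at each grid point (vectorized over the grid)
    rather than an explicit inverse, for stability in the near-singular
    slow-exchange limit.  For a single species this reduces to the closed
    form ``p·R2 / (R2² + (ω − ω0)²)``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("frequency grid is empty")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise InvalidInputError("frequency grid must be strictly increasing")
    exchange = np.asarray(exchange, dtype=float)
    n = spins.n_species
    if exchange.shape != (n, n) or state.n_species != n:
        raise InvalidInputError("species count mismatch between state, spins, and K")

    pops = population_vector(state).astype(complex)
    scale = _freq_scale(freq_units)
    # batched Ω: (n_freq, N, N)
    omegas = np.zeros((grid.size, n, n), dtype=complex)
    omegas -= exchange[None, :, :]
    idx = np.arange(n)
    omegas[:, idx, idx] += spins.r2[None, :] + 1j * scale * (
        grid[:, None] - spins.omega0[None, :]
    )
    try:
        rhs = np.broadcast_to(pops[:, None], (grid.size, n, 1))
        mags = np.linalg.solve(omegas, rhs)[..., 0]
    except np.linalg.LinAlgError as exc:  # only possible with R2 -> 0
        raise InvalidInputError(f"singular evolution matrix: {exc}") from exc
    intensity = mags.real.sum(axis=1)
    return Spectrum(grid, intensity, resonance=resonance,
                    ptotal=state.ptotal, ltotal=state.ltotal)


def lorentzian_profile(
    amplitude: float, omega0: float, r2: float, grid: np.ndarray
) -> Spectrum:
    """Absorption Lorentzian ``a·R2 / (R2² + (ω − ω0)²)`` on a grid.

    Its peak height is a/R2 and its full width at half maximum 2·R2.
    """
    if r2 <= 0 or not np.isfinite(r2):
        raise InvalidInputError("R2 must be > 0")
    grid = np.asarray(grid, dtype=float)
    return Spectrum(grid, _lorentz(grid, amplitude, omega0, r2, 0.0))


def _lorentz(omega, amplitude, omega0, r2, baseline):
    return amplitude * r2 / (r2 * r2 + (omega - omega0) ** 2) + baseline


def fit_lorentzian(spectrum: Spectrum) -> tuple[float, float, float, float]:
    """Least-squares Lorentzian fit of a single peak.

    Returns ``(amplitude, omega0, r2, baseline)``.  Initial values come
    from the peak maximum and its half-height width.  Raises
    :class:`FitFailureError` for flat or degenerate spectra and on
    non-convergence.
    """
    if len(spectrum) < 5:
        raise FitFailureError("need at least 5 points for a Lorentzian fit")
    y = spectrum.intensity
    x = spectrum.freq
    span = float(y.max() - y.min())
    if span <= 0 or not np.isfinite(span) or span < 1e-12 * max(1.0, abs(float(y.max()))):
        raise FitFailureError("spectrum has no discernible maximum")

    i_max = int(np.argmax(y))
    baseline0 = float(np.min(y))
    height0 = float(y[i_max] - baseline0)
    omega0_0 = float(x[i_max])
    # half-height crossing width -> R2 initial guess
    half = baseline0 + height0 / 2.0
    above = y >= half
    r2_0 = 0.5 * float(x[above].max() - x[above].min()) if above.sum() >= 2 else float(
        (x[-1] - x[0]) / 10.0
    )
    r2_0 = max(r2_0, float(np.min(np.diff(x))))

    model = LmfitModel(_lorentz)
    params = model.make_params(
        amplitude=height0 * r2_0, omega0=omega0_0, r2=r2_0, baseline=baseline0
    )
    params["r2"].set(min=1e-12)
    params["omega0"].set(min=float(x[0]), max=float(x[-1]))
    result = model.fit(y, params, omega=x)
    if not result.success:
        raise FitFailureError(f"Lorentzian fit did not converge: {result.message}")
    p = result.params
    return (
        float(p["amplitude"].value),
        float(p["omega0"].value),
        float(p["r2"].value),
        float(p["baseline"].value),
    )
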