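"""Titration-series simulation: lineshapes along a ligand series, with
optional point sampling and Gaussian noise emulating experimental spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equilibria import (
    BindingModel,
    InvalidInputError,
    SpeciesState,
    TitrationPoint,
    exchange_matrix,
    species_concentrations,
)
from .lineshape import SpinParams, Spectrum, compute_spectrum

__all__ = [
    "TitrationSeries",
    "NoiseSpec",
    "default_grid",
    "simulate_titration",
    "sample_and_noise",
    "crop_series",
]


@dataclass
class TitrationSeries:
    """Spectra of one resonance across a ligand titration.

    One :class:`~titrshape.lineshape.Spectrum` per total-ligand
    concentration, all sharing one frequency grid.  When produced by
    :func:`simulate_titration` the equilibrium species concentrations at
    each point are kept for population plots.
    """

    ptotal: float
    ltotals: np.ndarray
    spectra: list[Spectrum]
    resonance: str = "res1"
    model: BindingModel | None = None
    spins: SpinParams | None = None
    states: list[SpeciesState] | None = None

    def __post_init__(self) -> None:
        self.ltotals = np.asarray(self.ltotals, dtype=float)
        if len(self.spectra) != self.ltotals.size:
            raise InvalidInputError("one spectrum per Ltotal is required")

    def __len__(self) -> int:
        return len(self.spectra)

    def species_table(self) -> pd.DataFrame:
        """Species concentrations (µM) per titration point, plus free L."""
        if self.states is None:
            raise InvalidInputError("series carries no equilibrium states")
        rows = []
        for lt, st in zip(self.ltotals, self.states):
            row = {"Ltotal": lt, "L": st.free_ligand}
            row.update(dict(zip(st.labels, st.concentrations)))
            rows.append(row)
        return pd.DataFrame(rows)

    def max_intensity(self) -> float:
        return max(float(s.intensity.max()) for s in self.spectra)


@dataclass(frozen=True)
class NoiseSpec:
    """Sampling + noise recipe for synthetic data.

    ``snr`` is peak signal (the series-wide maximum intensity) over the
    Gaussian noise standard deviation; ``snr=None`` means noise-free.
    ``points`` spectra samples are taken evenly across the grid.
    """

    snr: float | None = 50.0
    seed: int = 0
    points: int = 50

    def __post_init__(self) -> None:
        if self.snr is not None and not self.snr > 0:
            raise InvalidInputError("SNR must be > 0")
        if self.points < 2:
            raise InvalidInputError("need at least 2 sampled points")


def default_grid(spins: SpinParams, n_points: int = 1000) -> np.ndarray:
    """Default simulation grid: ``n_points`` evenly spaced frequencies
    spanning all resonance positions with a margin of twice the largest
    linewidth on each side (so exchange-broadened wings stay visible
    without diluting the sampled points far off resonance).
    """
    lo = float(spins.omega0.min())
    hi = float(spins.omega0.max())
    pad = 2.0 * float(spins.linewidths.max())
    return np.linspace(lo - pad, hi + pad, n_points)


def simulate_titration(
    model: BindingModel,
    spins: SpinParams,
    ptotal: float,
    ltotals,
    grid: np.ndarray | None = None,
    resonance: str = "res1",
    freq_units: str = "angular",
) -> TitrationSeries:
    """Simulate one resonance's lineshape at every titration point.

    For each total-ligand concentration the equilibrium is solved, the
    exchange matrix built, and the Bloch-McConnell spectrum computed on a
    shared grid (:func:`default_grid` if none is given).
    """
    ltotals = np.asarray(ltotals, dtype=float)
    if ltotals.size == 0:
        raise InvalidInputError("Ltotal list must be non-empty")
    if spins.n_species != model.n_species:
        raise InvalidInputError("spin parameter count does not match model species")
    if grid is None:
        grid = default_grid(spins)
    spectra, states = [], []
    for j, lt in enumerate(ltotals):
        st = species_concentrations(TitrationPoint(ptotal, float(lt)), model)
        k = exchange_matrix(model, st)
        spec = compute_spectrum(st, spins, k, grid, freq_units=freq_units,
                                resonance=resonance)
        spec.titration_index = j
        spectra.append(spec)
        states.append(st)
    return TitrationSeries(ptotal, ltotals, spectra, resonance=resonance,
                           model=model, spins=spins, states=states)


def sample_and_noise(series: TitrationSeries, noise: NoiseSpec) -> TitrationSeries:
    """Reduce each spectrum to ``noise.points`` evenly spaced samples and
    add zero-mean Gaussian noise with σ = (series max intensity) / SNR.

    The noise level is referenced to the maximum over the whole series, not
    per spectrum, matching the convention of quoting one signal-to-noise
    ratio per dataset.  Deterministic under a fixed seed.
    """
    grid_len = len(series.spectra[0])
    if noise.points > grid_len:
        raise InvalidInputError("cannot sample more points than the grid has")
    idx = np.unique(np.linspace(0, grid_len - 1, noise.points).round().astype(int))
    sigma = 0.0 if noise.snr is None else series.max_intensity() / noise.snr
    rng = np.random.default_rng(noise.seed)
    sampled = []
    for spec in series.spectra:
        y = spec.intensity[idx].copy()
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=y.size)
        sampled.append(
            Spectrum(spec.freq[idx], y, resonance=spec.resonance,
                     titration_index=spec.titration_index,
                     ptotal=spec.ptotal, ltotal=spec.ltotal)
        )
    return TitrationSeries(series.ptotal, series.ltotals, sampled,
                           resonance=series.resonance, model=series.model,
                           spins=series.spins, states=series.states)


def crop_series(series: TitrationSeries, lo: float, hi: float) -> TitrationSeries:
    """Restrict every spectrum to frequencies in [lo, hi].

    Used to select one resonance region out of a wider window — e.g. to
    fit only the free and singly bound peaks of a slowly isomerizing
    system with a simpler scheme that has no species for the third peak.
    """
    cropped = []
    for spec in series.spectra:
        mask = (spec.freq >= lo) & (spec.freq <= hi)
        if mask.sum() < 2:
            raise InvalidInputError("cropping window leaves fewer than 2 points")
        cropped.append(Spectrum(spec.freq[mask], spec.intensity[mask],
                                resonance=spec.resonance,
                                titration_index=spec.titration_index,
                                ptotal=spec.ptotal, ltotal=spec.ltotal))
    return TitrationSeries(series.ptotal, series.ltotals, cropped,
                           resonance=series.resonance, model=series.model,
                           spins=series.spins, states=series.states)
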