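"""Reference simulation suites: fully specified synthetic titrations used
in the recovery experiments and the packaged examples.

Every generator reproduces one standard condition set — 300 µM protein
titrated to 3 ligand equivalents, K_D = 10 µM, 100 s⁻¹ linewidths,
resonance positions spread over 0–1000 s⁻¹ — across the slow-to-fast
exchange regimes (rates from 0.01× to 100× the frequency separation
Δω = 500 s⁻¹).  Sampled datasets carry 50 points per line with Gaussian
noise at signal/noise ≈ 50, and are byte-stable under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

from .equilibria import FourStateModel, ThreeStateModel, TwoStateModel
from .io import write_series
from .lineshape import SpinParams
from .simulate import NoiseSpec, TitrationSeries, sample_and_noise, simulate_titration

__all__ = [
    "TWO_STATE_KOFFS",
    "THREE_STATE_RATES",
    "FOUR_STATE_RATES",
    "two_state_dataset",
    "three_state_dataset",
    "four_state_dataset",
    "make_fixtures",
]

DEFAULT_SNR = 50.0
DEFAULT_POINTS = 50

# 2-state suite: koff from 0.01x to 100x the 500 s^-1 frequency separation
TWO_STATE_KOFFS = {
    "koff5": 5.0,
    "koff50": 50.0,
    "koff500": 500.0,
    "koff5000": 5000.0,
    "koff50000": 50000.0,
}
TWO_STATE_LTOTALS = (0.0, 100.0, 200.0, 300.0, 600.0, 900.0)

# 3-state suite: slow (5 s^-1) / fast (5000 s^-1) binding x isomerization
THREE_STATE_RATES = {
    "bind_slow_isom_slow": (5.0, 5.0),
    "bind_slow_isom_fast": (5.0, 5000.0),
    "bind_fast_isom_slow": (5000.0, 5.0),
    "bind_fast_isom_fast": (5000.0, 5000.0),
}
THREE_STATE_LTOTALS = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 600.0, 900.0)

# 4-state suite: slow/fast off rates per site (A1=A2, B1=B2)
FOUR_STATE_RATES = {
    "siteA_slow_siteB_slow": (5.0, 5.0),
    "siteA_slow_siteB_fast": (5.0, 5000.0),
    "siteA_fast_siteB_slow": (5000.0, 5.0),
    "siteA_fast_siteB_fast": (5000.0, 5000.0),
}
FOUR_STATE_LTOTALS = tuple(float(v) for v in range(0, 1000, 100))

PTOTAL = 300.0
KD = 10.0
LINEWIDTH = 100.0


def _finish(series: TitrationSeries, noisy: bool, snr: float, points: int,
            seed: int) -> TitrationSeries:
    if not noisy:
        return series
    return sample_and_noise(series, NoiseSpec(snr=snr, seed=seed, points=points))


def two_state_dataset(koff: float = 5.0, seed: int = 0, noisy: bool = True,
                      snr: float = DEFAULT_SNR, points: int = DEFAULT_POINTS,
                      resonance: str = "res1") -> TitrationSeries:
    """Single-site titration: K_D 10 µM, ω0 = 0/500 s⁻¹, dω = 100 s⁻¹."""
    model = TwoStateModel(kd=KD, koff=koff)
    spins = SpinParams.from_linewidths([0.0, 500.0], [LINEWIDTH, LINEWIDTH])
    series = simulate_titration(model, spins, PTOTAL, TWO_STATE_LTOTALS,
                                resonance=resonance)
    return _finish(series, noisy, snr, points, seed)


def three_state_dataset(koff: float = 5.0, krev: float = 5.0, seed: int = 0,
                        noisy: bool = True, snr: float = DEFAULT_SNR,
                        points: int = DEFAULT_POINTS,
                        resonance: str = "res1") -> TitrationSeries:
    """Binding + isomerization: K_D 10 µM, K_eq 1, ω0 = 0/500/1000 s⁻¹."""
    model = ThreeStateModel(kd=KD, keq=1.0, koff=koff, krev=krev)
    spins = SpinParams.from_linewidths([0.0, 500.0, 1000.0], [LINEWIDTH] * 3)
    series = simulate_titration(model, spins, PTOTAL, THREE_STATE_LTOTALS,
                                resonance=resonance)
    return _finish(series, noisy, snr, points, seed)


def four_state_dataset(koff_a: float = 5.0, koff_b: float = 5.0, seed: int = 0,
                       noisy: bool = True, snr: float = DEFAULT_SNR,
                       points: int = DEFAULT_POINTS,
                       resonance: str = "res1") -> TitrationSeries:
    """Two independent sites, all K_D 10 µM, ω0 = 0/400/600/1000 s⁻¹."""
    model = FourStateModel(kd_a1=KD, kd_b1=KD, kd_a2=KD,
                           koff_a1=koff_a, koff_b1=koff_b,
                           koff_a2=koff_a, koff_b2=koff_b)
    spins = SpinParams.from_linewidths([0.0, 400.0, 600.0, 1000.0], [LINEWIDTH] * 4)
    series = simulate_titration(model, spins, PTOTAL, FOUR_STATE_LTOTALS,
                                resonance=resonance)
    return _finish(series, noisy, snr, points, seed)


def make_fixtures(target_dir, which: str = "all", seed: int = 0,
                  snr: float = DEFAULT_SNR, points: int = DEFAULT_POINTS) -> dict:
    """Write the simulation suites (``two_state``, ``three_state``,
    ``four_state``, or ``all``) as on-disk datasets, one per condition.

    Per-dataset seeds derive deterministically from ``seed``; rerunning
    with the same seed reproduces identical files.
    """
    target_dir = Path(target_dir)
    wanted = ("two_state", "three_state", "four_state") if which == "all" else (which,)
    unknown = set(wanted) - {"two_state", "three_state", "four_state"}
    if unknown:
        raise ValueError(f"unknown fixture suite(s): {sorted(unknown)}")
    paths: dict[str, Path] = {}
    for suite in wanted:
        if suite == "two_state":
            items = [(name, two_state_dataset(koff=k, seed=seed + i, snr=snr,
                                              points=points), seed + i)
                     for i, (name, k) in enumerate(sorted(TWO_STATE_KOFFS.items()))]
        elif suite == "three_state":
            items = [(name, three_state_dataset(koff=k1, krev=k2, seed=seed + 10 + i,
                                                snr=snr, points=points), seed + 10 + i)
                     for i, (name, (k1, k2)) in enumerate(sorted(THREE_STATE_RATES.items()))]
        else:
            items = [(name, four_state_dataset(koff_a=k1, koff_b=k2, seed=seed + 20 + i,
                                               snr=snr, points=points), seed + 20 + i)
                     for i, (name, (k1, k2)) in enumerate(sorted(FOUR_STATE_RATES.items()))]
        for name, series, ds_seed in items:
            out = target_dir / name
            write_series(series, out, extra_config={"snr": snr, "seed": ds_seed})
            paths[name] = out
    return paths
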