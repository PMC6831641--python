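"""Global fitting of binding models to titration lineshape data.

Pipeline: normalize each resonance's series → Lorentzian pre-fit of the
apo (and last) titration points to seed spin parameters → bounded
least-squares search of the thermodynamic/kinetic parameters (in log10
space, shared across all resonances: a global fit) plus any free spin
parameters → Monte Carlo resampling for 95% confidence intervals and
boundary flags.

The target function is the sum of squared differences between predicted
and measured intensities with per-resonance intensity scale ``a_i`` and
baseline ``b_i`` correction factors; ``a_i, b_i`` are solved in closed
form (2×2 normal equations) at every objective evaluation, so they never
enter the outer search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .equilibria import (
    BindingModel,
    FourStateModel,
    InvalidInputError,
    ThreeStateModel,
    TitrationPoint,
    TwoStateModel,
    exchange_matrix,
    species_concentrations,
)
from .lineshape import FitFailureError, SpinParams, Spectrum, compute_spectrum, fit_lorentzian
from .simulate import TitrationSeries

__all__ = [
    "Param",
    "FitConfig",
    "FitResult",
    "SpinEstimate",
    "normalize_series",
    "estimate_spin_params",
    "objective",
    "fit_model",
    "monte_carlo_ci",
    "classify_boundary",
    "FitError",
]

_PENALTY = 1e6


class FitError(RuntimeError):
    """Optimization failed; carries the best point found so far."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best


@dataclass
class Param:
    """One free (or frozen) parameter of the outer search.

    ``log=True`` parameters are searched as log10(value); bounds and init
    are always given on the natural scale.
    """

    name: str
    init: float
    lb: float
    ub: float
    log: bool = True
    vary: bool = True

    def __post_init__(self) -> None:
        if not (self.lb <= self.init <= self.ub):
            raise InvalidInputError(
                f"parameter {self.name}: need lb <= init <= ub, "
                f"got {self.lb}, {self.init}, {self.ub}"
            )
        if self.log and self.lb <= 0:
            raise InvalidInputError(f"parameter {self.name}: log-scale bounds must be > 0")

    def encode(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def decode(self, x: float) -> float:
        return 10.0 ** x if self.log else x


def _geomean(lo: float, hi: float) -> float:
    return math.sqrt(lo * hi)


_MODEL_PARAM_NAMES = {
    "2state": ("kd", "koff"),
    "3state": ("kd", "keq", "koff", "krev"),
    "4state": ("kd_a1", "kd_b1", "kd_a2", "koff_a1", "koff_b1", "koff_a2", "koff_b2"),
}
_TIED_4STATE = {
    "independent": ("kd_a", "kd_b", "koff_a", "koff_b"),
    "independent_equal_kd": ("kd", "koff_a", "koff_b"),
}


@dataclass
class FitConfig:
    """Configuration of one fit: model choice, bounds, and MC settings.

    ``tie_sites`` (4-state only) constrains the binding cycle:
    ``"independent"`` makes each site's affinity and kinetics independent
    of the other site's occupancy (K_D and k_off shared between first and
    second binding at the same site); ``"independent_equal_kd"``
    additionally ties the two sites to one K_D.
    """

    model: str
    params: dict[str, Param]
    tie_sites: str = "none"
    spins: dict[str, SpinParams] | None = None
    fix_spins: bool = False
    normalize: bool = True
    mc_reps: int = 50
    mc_max_reps: int = 500
    noise_sigma: float | None = None
    snr: float | None = None
    n_starts: int = 5
    seed: int = 0
    mc_restart_from_best: bool = True
    freq_units: str = "angular"

    def __post_init__(self) -> None:
        if self.model not in _MODEL_PARAM_NAMES:
            raise InvalidInputError(f"model must be one of {sorted(_MODEL_PARAM_NAMES)}")
        expected = self.param_names()
        missing = [n for n in expected if n not in self.params]
        if missing:
            raise InvalidInputError(f"missing parameter specs: {missing}")
        if self.mc_reps < 50:
            raise InvalidInputError("Monte Carlo requires at least 50 repetitions")

    def param_names(self) -> tuple[str, ...]:
        if self.model == "4state" and self.tie_sites != "none":
            return _TIED_4STATE[self.tie_sites]
        return _MODEL_PARAM_NAMES[self.model]

    # -- convenience constructors with the printed default search ranges --

    @classmethod
    def two_state(cls, kd_bounds=(1e-3, 1e3), koff_bounds=(0.1, 1e5),
                  inits: dict | None = None, **kw) -> "FitConfig":
        return cls("2state", _make_params(
            {"kd": kd_bounds, "koff": koff_bounds}, inits), **kw)

    @classmethod
    def three_state(cls, kd_bounds=(1.0, 1e3), keq_bounds=(0.01, 100.0),
                    koff_bounds=(1.0, 1e4), krev_bounds=(1.0, 1e4),
                    inits: dict | None = None, **kw) -> "FitConfig":
        return cls("3state", _make_params(
            {"kd": kd_bounds, "keq": keq_bounds,
             "koff": koff_bounds, "krev": krev_bounds}, inits), **kw)

    @classmethod
    def four_state(cls, kd_bounds=(1.0, 1e3), koff_bounds=(1.0, 1e4),
                   tie_sites: str = "independent_equal_kd",
                   inits: dict | None = None, **kw) -> "FitConfig":
        if tie_sites == "none":
            names = _MODEL_PARAM_NAMES["4state"]
        else:
            names = _TIED_4STATE[tie_sites]
        spec = {n: (kd_bounds if n.startswith("kd") else koff_bounds) for n in names}
        return cls("4state", _make_params(spec, inits), tie_sites=tie_sites, **kw)


def _make_params(spec: dict[str, tuple[float, float]], inits: dict | None) -> dict[str, Param]:
    inits = inits or {}
    return {
        name: Param(name, inits.get(name, _geomean(lo, hi)), lo, hi)
        for name, (lo, hi) in spec.items()
    }


def _build_model(config: FitConfig, values: dict[str, float]) -> BindingModel:
    m = config.model
    if m == "2state":
        return TwoStateModel(kd=values["kd"], koff=values["koff"])
    if m == "3state":
        return ThreeStateModel(kd=values["kd"], keq=values["keq"],
                               koff=values["koff"], krev=values["krev"])
    if config.tie_sites == "independent":
        return FourStateModel(
            kd_a1=values["kd_a"], kd_b1=values["kd_b"], kd_a2=values["kd_a"],
            koff_a1=values["koff_a"], koff_b1=values["koff_b"],
            koff_a2=values["koff_a"], koff_b2=values["koff_b"])
    if config.tie_sites == "independent_equal_kd":
        return FourStateModel(
            kd_a1=values["kd"], kd_b1=values["kd"], kd_a2=values["kd"],
            koff_a1=values["koff_a"], koff_b1=values["koff_b"],
            koff_a2=values["koff_a"], koff_b2=values["koff_b"])
    return FourStateModel(
        kd_a1=values["kd_a1"], kd_b1=values["kd_b1"], kd_a2=values["kd_a2"],
        koff_a1=values["koff_a1"], koff_b1=values["koff_b1"],
        koff_a2=values["koff_a2"], koff_b2=values["koff_b2"])


_N_SPECIES = {"2state": 2, "3state": 3, "4state": 4}


# ---------------------------------------------------------------------------
# normalization and spin-parameter pre-fit
# ---------------------------------------------------------------------------

def normalize_series(series: TitrationSeries) -> TitrationSeries:
    """Divide one resonance's intensities by the maximum over its series."""
    peak = series.max_intensity()
    if peak <= 0 or not np.isfinite(peak):
        raise InvalidInputError("cannot normalize an all-zero (or negative) series")
    spectra = [
        Spectrum(s.freq, s.intensity / peak, resonance=s.resonance,
                 titration_index=s.titration_index, ptotal=s.ptotal, ltotal=s.ltotal)
        for s in series.spectra
    ]
    return TitrationSeries(series.ptotal, series.ltotals, spectra,
                           resonance=series.resonance, model=series.model,
                           spins=series.spins, states=series.states)


@dataclass
class SpinEstimate:
    """Initial spin parameters for one resonance plus a per-species mask of
    which of them stay fixed during fitting (True = fixed)."""

    spins: SpinParams
    fixed: np.ndarray  # bool per species


def _pick_peaks(spectrum: Spectrum, n_wanted: int) -> list[tuple[float, float]]:
    """Up to ``n_wanted`` (ω0, height) local maxima, ascending in frequency."""
    y = spectrum.intensity
    prominence = 0.1 * max(float(y.max()) - float(y.min()), 1e-12)
    idx, props = find_peaks(y, prominence=prominence)
    if idx.size == 0:
        idx = np.array([int(np.argmax(y))])
        props = {"prominences": np.array([float(y.max() - y.min())])}
    order = np.argsort(props["prominences"])[::-1][:n_wanted]
    chosen = np.sort(idx[order])
    return [(float(spectrum.freq[i]), float(y[i])) for i in chosen]


def estimate_spin_params(
    data: TitrationSeries, model: str, fix_bound: bool = False
) -> SpinEstimate:
    """Seed per-species spin parameters from Lorentzian pre-fits.

    The first titration point must be apo (Ltotal = 0): its Lorentzian fit
    pins the free-protein ω0 and R2, which stay fixed.  Bound-state
    parameters are initialized from peaks picked in the last titration
    point (assigned in ascending frequency to the bound species in scheme
    order) and are searched as fitting parameters unless ``fix_bound``.
    If the pre-fit fails, all spin parameters are left free with a warning.
    """
    n = _N_SPECIES[model]
    grid_lo = float(min(s.freq[0] for s in data.spectra))
    grid_hi = float(max(s.freq[-1] for s in data.spectra))
    mid = 0.5 * (grid_lo + grid_hi)
    default_r2 = 0.05 * (grid_hi - grid_lo)

    omega0 = np.full(n, mid)
    r2 = np.full(n, default_r2)
    fixed = np.zeros(n, dtype=bool)

    try:
        if data.ltotals[0] != 0.0:
            raise FitFailureError("first titration point is not apo (Ltotal != 0)")
        _, w0_apo, r2_apo, _ = fit_lorentzian(data.spectra[0])
        omega0[0], r2[0] = w0_apo, r2_apo
        fixed[0] = True
    except FitFailureError as exc:
        warnings.warn(f"apo Lorentzian pre-fit failed ({exc}); "
                      "all spin parameters left free")
        return SpinEstimate(SpinParams(omega0, r2), fixed)

    if len(data.spectra) > 1:
        last = data.spectra[-1]
        try:
            _, w0_last, r2_last, _ = fit_lorentzian(last)
        except FitFailureError:
            w0_last, r2_last = mid, default_r2
        peaks = _pick_peaks(last, n - 1)
        bound_w0 = [w for w, _ in peaks]
        while len(bound_w0) < n - 1:
            bound_w0.append(bound_w0[-1] if bound_w0 else w0_last)
        omega0[1:] = bound_w0[: n - 1]
        r2[1:] = max(r2_last, 1e-6)
        if len(peaks) == 1 and abs(omega0[-1] - w0_last) < r2_last:
            # a single clean final-state peak: trust the Lorentzian fit
            omega0[n - 1] = w0_last
    fixed[1:] = fix_bound
    return SpinEstimate(SpinParams(omega0, r2), fixed)


# ---------------------------------------------------------------------------
# the fit problem
# ---------------------------------------------------------------------------

class _FitProblem:
    """Parameter packing, prediction, and residuals for one global fit."""

    def __init__(self, data: list[TitrationSeries], config: FitConfig):
        if not data:
            raise InvalidInputError("no titration data")
        ref = data[0]
        for s in data[1:]:
            if not np.array_equal(s.ltotals, ref.ltotals) or s.ptotal != ref.ptotal:
                raise InvalidInputError("resonances must share titration concentrations")
        self.config = config
        self.data = [normalize_series(s) for s in data] if config.normalize else list(data)
        self.ptotal = ref.ptotal
        self.ltotals = np.asarray(ref.ltotals, dtype=float)
        self.n_species = _N_SPECIES[config.model]

        # spin parameter seeds per resonance
        self.spin_estimates: dict[str, SpinEstimate] = {}
        for series in self.data:
            res = series.resonance
            if config.spins is not None and res in config.spins:
                sp = config.spins[res]
                if sp.n_species != self.n_species:
                    raise InvalidInputError(f"spins for {res!r} have wrong species count")
                self.spin_estimates[res] = SpinEstimate(
                    sp, np.ones(self.n_species, dtype=bool) if config.fix_spins
                    else np.zeros(self.n_species, dtype=bool))
            else:
                self.spin_estimates[res] = estimate_spin_params(
                    series, config.model, fix_bound=config.fix_spins)

        # flat parameter layout: kinetic/thermodynamic params first,
        # then free spin params per resonance
        self.free: list[Param] = [config.params[n] for n in config.param_names()
                                  if config.params[n].vary]
        self.fixed_values = {n: config.params[n].init
                             for n in config.param_names()
                             if not config.params[n].vary}
        grid_lo = min(float(s.spectra[0].freq[0]) for s in self.data)
        grid_hi = max(float(s.spectra[0].freq[-1]) for s in self.data)
        for series in self.data:
            res = series.resonance
            est = self.spin_estimates[res]
            for i in range(self.n_species):
                if est.fixed[i]:
                    continue
                w0 = float(np.clip(est.spins.omega0[i], grid_lo, grid_hi))
                self.free.append(Param(f"omega0[{res}][{i}]", w0,
                                       grid_lo, grid_hi, log=False))
                r2i = float(est.spins.r2[i])
                self.free.append(Param(f"r2[{res}][{i}]", r2i,
                                       r2i / 30.0, r2i * 30.0, log=True))
        self.names = [p.name for p in self.free]
        self.x0 = np.array([p.encode(p.init) for p in self.free])
        self.lb = np.array([p.encode(p.lb) for p in self.free])
        self.ub = np.array([p.encode(p.ub) for p in self.free])
        self.n_data = sum(len(spec) for s in self.data for spec in s.spectra)

    # -- decoding -----------------------------------------------------------

    def decode(self, x: np.ndarray) -> tuple[BindingModel, dict[str, SpinParams]]:
        values = dict(self.fixed_values)
        spin_w0 = {s.resonance: self.spin_estimates[s.resonance].spins.omega0.copy()
                   for s in self.data}
        spin_r2 = {s.resonance: self.spin_estimates[s.resonance].spins.r2.copy()
                   for s in self.data}
        for p, xi in zip(self.free, x):
            v = p.decode(float(xi))
            if p.name.startswith("omega0["):
                res, i = _parse_spin_name(p.name)
                spin_w0[res][i] = v
            elif p.name.startswith("r2["):
                res, i = _parse_spin_name(p.name)
                spin_r2[res][i] = v
            else:
                values[p.name] = v
        model = _build_model(self.config, values)
        spins = {res: SpinParams(spin_w0[res], spin_r2[res]) for res in spin_w0}
        return model, spins

    def kinetic_values(self, x: np.ndarray) -> dict[str, float]:
        values = dict(self.fixed_values)
        for p, xi in zip(self.free, x):
            if not p.name.startswith(("omega0[", "r2[")):
                values[p.name] = p.decode(float(xi))
        return values

    # -- prediction and residuals ------------------------------------------

    def predict(self, model: BindingModel, spins: dict[str, SpinParams]
                ) -> dict[str, list[np.ndarray]]:
        states, mats = [], []
        for lt in self.ltotals:
            st = species_concentrations(TitrationPoint(self.ptotal, float(lt)), model)
            states.append(st)
            mats.append(exchange_matrix(model, st))
        out: dict[str, list[np.ndarray]] = {}
        for series in self.data:
            sp = spins[series.resonance]
            preds = [
                compute_spectrum(st, sp, k, spec.freq,
                                 freq_units=self.config.freq_units).intensity
                for st, k, spec in zip(states, mats, series.spectra)
            ]
            peak = max(float(p.max()) for p in preds)
            if peak > 0:
                preds = [p / peak for p in preds]
            out[series.resonance] = preds
        return out

    @staticmethod
    def _scale_offset(pred: np.ndarray, meas: np.ndarray) -> tuple[float, float]:
        """Closed-form least-squares (a, b) minimizing ||a·pred + b − meas||²."""
        n = pred.size
        sm = float(pred.sum())
        smm = float(pred @ pred)
        sd = float(meas.sum())
        smd = float(pred @ meas)
        det = n * smm - sm * sm
        if det <= 1e-300 * max(1.0, n * smm):
            return 1.0, float((sd - sm) / n)
        a = (n * smd - sm * sd) / det
        b = (smm * sd - sm * smd) / det
        return a, b

    def residuals(self, x: np.ndarray, data_override=None) -> np.ndarray:
        try:
            model, spins = self.decode(x)
            preds = self.predict(model, spins)
        except (InvalidInputError, FloatingPointError):
            return np.full(self.n_data, _PENALTY)
        res = []
        for series in self.data:
            pred_list = preds[series.resonance]
            pred = np.concatenate(pred_list)
            if data_override is not None:
                meas = data_override[series.resonance]
            else:
                meas = np.concatenate([s.intensity for s in series.spectra])
            if not np.all(np.isfinite(pred)):
                warnings.warn("non-finite prediction; returning penalty residuals")
                return np.full(self.n_data, _PENALTY)
            a, b = self._scale_offset(pred, meas)
            res.append(a * pred + b - meas)
        return np.concatenate(res)

    def scale_offsets(self, x: np.ndarray) -> dict[str, tuple[float, float]]:
        model, spins = self.decode(x)
        preds = self.predict(model, spins)
        out = {}
        for series in self.data:
            pred = np.concatenate(preds[series.resonance])
            meas = np.concatenate([s.intensity for s in series.spectra])
            out[series.resonance] = self._scale_offset(pred, meas)
        return out

    def sse(self, x: np.ndarray, data_override=None) -> float:
        r = self.residuals(x, data_override)
        return float(r @ r)


def _parse_spin_name(name: str) -> tuple[str, int]:
    body = name[name.index("[") + 1:-1]
    res, idx = body.split("][")
    return res, int(idx)


def objective(values: dict[str, float], data: list[TitrationSeries],
              config: FitConfig) -> float:
    """Sum of squared errors Σ_{i,j,k} ([S_pred·a_i + b_i] − S_expt)² at the
    given kinetic/thermodynamic parameter values.

    Spin parameters come from ``config.spins`` (or the pre-fit seeds); the
    per-resonance correction factors a_i, b_i are solved in closed form.
    """
    cfg = replace(config, params={
        n: replace(config.params[n], init=values.get(n, config.params[n].init))
        for n in config.params
    })
    problem = _FitProblem(data, cfg)
    return problem.sse(problem.x0)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Best-fit parameters with optional Monte Carlo confidence intervals.

    ``flags`` per parameter: "" (determined), "UB"/"LB" (estimate at the
    upper/lower search bound — value not determined), or "SV" (Monte Carlo
    spread too small to define an interval).
    """

    params: dict[str, float]
    sse: float
    spins: dict[str, SpinParams]
    scales: dict[str, tuple[float, float]]
    ci: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    mc_samples: pd.DataFrame | None = None
    n_mc: int = 0
    free_names: list[str] = field(default_factory=list)
    x_best: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, value in self.params.items():
            ci = self.ci.get(name)
            rows.append({
                "parameter": name,
                "estimate": value,
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
                "flag": self.flags.get(name, ""),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _run_least_squares(problem: _FitProblem, x0: np.ndarray,
                       data_override=None, fast: bool = False):
    tol = 1e-10 if fast else 1e-12
    return least_squares(
        problem.residuals, np.clip(x0, problem.lb, problem.ub),
        bounds=(problem.lb, problem.ub), method="trf", x_scale="jac",
        xtol=tol, ftol=tol, gtol=tol,
        max_nfev=300 * x0.size if fast else 1000 * x0.size,
        kwargs={"data_override": data_override} if data_override is not None else {},
    )


def _multistart_points(problem: _FitProblem, rng: np.random.Generator) -> list[np.ndarray]:
    starts = [problem.x0.copy()]
    n_kin = sum(1 for p in problem.free
                if not p.name.startswith(("omega0[", "r2[")))
    for _ in range(problem.config.n_starts - 1):
        x = problem.x0.copy()
        for i, p in enumerate(problem.free):
            if i < n_kin:
                x[i] = rng.uniform(problem.lb[i], problem.ub[i])
            elif p.name.startswith("omega0["):
                width = 0.05 * (problem.ub[i] - problem.lb[i])
                x[i] = np.clip(x[i] + rng.uniform(-width, width),
                               problem.lb[i], problem.ub[i])
        starts.append(x)
    return starts


def fit_model(data: TitrationSeries | list[TitrationSeries],
              config: FitConfig) -> FitResult:
    """Bounded global fit of the binding model to one or more resonances.

    Thermodynamic and kinetic parameters are shared across every resonance
    (and hence across datasets concatenated into ``data``); each resonance
    carries its own spin parameters and scale/baseline factors.  The outer
    search runs in log10 space with ``config.n_starts`` multistarts
    (log-uniform over the bounds) and is deterministic for a fixed config.
    """
    if isinstance(data, TitrationSeries):
        data = [data]
    problem = _FitProblem(data, config)
    rng = np.random.default_rng(config.seed)
    best = None
    for x0 in _multistart_points(problem, rng):
        try:
            sol = _run_least_squares(problem, x0)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("all optimization starts failed", best=None)

    model_values = problem.kinetic_values(best.x)
    _, spins = problem.decode(best.x)
    sse = problem.sse(best.x)
    bounds = {n: (config.params[n].lb, config.params[n].ub)
              for n in config.param_names()}
    flags = {n: classify_boundary(model_values[n], bounds[n], None)
             for n in model_values}
    return FitResult(params=model_values, sse=sse, spins=spins,
                     scales=problem.scale_offsets(best.x),
                     flags=flags, free_names=list(problem.names),
                     x_best=best.x.copy())


def _estimate_noise_sigma(problem: _FitProblem) -> float:
    """Robust σ from the outer 10% of each spectrum's points (baseline)."""
    tails = []
    for series in problem.data:
        for spec in series.spectra:
            k = max(2, len(spec) // 10)
            tails.append(spec.intensity[:k])
            tails.append(spec.intensity[-k:])
    tail = np.concatenate(tails)
    mad = np.median(np.abs(tail - np.median(tail)))
    return float(1.4826 * mad)


def monte_carlo_ci(data: TitrationSeries | list[TitrationSeries],
                   config: FitConfig, best: FitResult) -> FitResult:
    """Monte Carlo resampling 95% confidence intervals.

    Each repetition adds fresh Gaussian noise (configured σ, or SNR
    relative to the normalized maximum, or a baseline estimate) to every
    data point and refits — from the best-fit point by default — recording
    the parameters.  At least ``config.mc_reps`` repetitions run, then
    continue until both CI endpoints of every parameter drift by <5% over
    the last 10 repetitions (cap ``config.mc_max_reps``).  The 95% CI is
    the 2.5th–97.5th percentile band; parameters at a search bound are
    flagged UB/LB and parameters whose samples barely vary are flagged SV,
    in both cases with the interval suppressed.
    """
    if isinstance(data, TitrationSeries):
        data = [data]
    problem = _FitProblem(data, config)
    if config.noise_sigma is not None:
        sigma = config.noise_sigma
    elif config.snr is not None:
        peak = max(float(s.intensity.max())
                   for series in problem.data for s in series.spectra)
        sigma = peak / config.snr
    else:
        sigma = _estimate_noise_sigma(problem)

    if sigma == 0.0:
        # degenerate resampling: every refit reproduces the point estimate
        ci = {n: (v, v) for n, v in best.params.items()}
        bounds = {n: (config.params[n].lb, config.params[n].ub) for n in best.params}
        flags = {n: classify_boundary(best.params[n], bounds[n], None)
                 for n in best.params}
        samples = pd.DataFrame({n: [v] * config.mc_reps
                                for n, v in best.params.items()})
        return replace(best, ci={n: (None if flags[n] else ci[n]) for n in ci},
                       flags=flags, mc_samples=samples, n_mc=config.mc_reps)

    x_start = best.x_best if best.x_best is not None else problem.x0
    rng = np.random.default_rng(config.seed + 1)
    names = list(best.params.keys())
    samples: list[dict[str, float]] = []
    n_failed = 0
    history: list[np.ndarray] = []

    rep = 0
    while rep < config.mc_max_reps:
        rep += 1
        noisy = {
            series.resonance: np.concatenate(
                [s.intensity + rng.normal(0.0, sigma, s.intensity.size)
                 for s in series.spectra])
            for series in problem.data
        }
        try:
            if config.mc_restart_from_best:
                sol = _run_least_squares(problem, x_start, data_override=noisy,
                                         fast=True)
            else:
                sol = None
                for x0 in _multistart_points(problem,
                                             np.random.default_rng(config.seed + rep)):
                    cand = _run_least_squares(problem, x0, data_override=noisy,
                                              fast=True)
                    if sol is None or cand.cost < sol.cost:
                        sol = cand
            if not np.all(np.isfinite(sol.x)):
                raise FitError("non-finite refit")
            samples.append(problem.kinetic_values(sol.x))
        except Exception:
            n_failed += 1
            if n_failed > 0.2 * max(rep, config.mc_reps):
                raise FitError(
                    "more than 20% of Monte Carlo refits failed; "
                    "consider widening the parameter bounds")
            continue

        if len(samples) >= config.mc_reps:
            arr = np.array([[s[n] for n in names] for s in samples])
            ends = np.percentile(arr, [2.5, 97.5], axis=0).ravel()
            history.append((len(samples), ends))
            # stop once both endpoints of every parameter have drifted <5%
            # over the most recent third of the run (the short-lag version
            # of this test stops while the tail percentiles are still
            # creeping outward)
            target = 2 * len(samples) // 3
            past = [e for n_old, e in history if n_old <= target]
            if past:
                old, new = past[-1], ends
                scale = np.maximum(np.abs(new), 1e-30)
                if np.all(np.abs(new - old) / scale < 0.05):
                    break

    arr = np.array([[s[n] for n in names] for s in samples])
    df = pd.DataFrame(arr, columns=names)
    bounds = {n: (config.params[n].lb, config.params[n].ub) for n in names}
    ci: dict[str, tuple[float, float] | None] = {}
    flags: dict[str, str] = {}
    for j, name in enumerate(names):
        col = arr[:, j]
        flag = classify_boundary(best.params[name], bounds[name], col)
        flags[name] = flag
        if flag:
            ci[name] = None
        else:
            lo, hi = np.percentile(col, [2.5, 97.5])
            lo = min(lo, best.params[name])
            hi = max(hi, best.params[name])
            ci[name] = (float(lo), float(hi))
    return replace(best, ci=ci, flags=flags, mc_samples=df, n_mc=len(samples))


def classify_boundary(estimate: float, bounds: tuple[float, float],
                      mc_samples: np.ndarray | None) -> str:
    """Flag a fitted parameter: "UB"/"LB" if it is not determined because
    the search hit a bound; "SV" if the Monte Carlo spread is too small to
    define an interval; "" otherwise.

    A parameter counts as bound-limited when the point estimate sits within
    1% of the log-scale search range of a bound, when more than half the
    Monte Carlo repetitions pin it there, or when the 95% interval itself
    is censored by the bound (its 2.5th/97.5th percentile endpoint reaches
    the bound) — in all three cases the data do not constrain the value on
    that side.  "SV" needs a coefficient of variation below 1e-3 away from
    any bound.
    """
    lb, ub = bounds
    log_range = math.log10(ub) - math.log10(lb)
    tol = 0.01 * log_range

    def _near(value: float) -> str:
        if math.log10(value) >= math.log10(ub) - tol:
            return "UB"
        if math.log10(value) <= math.log10(lb) + tol:
            return "LB"
        return ""

    flag = _near(min(max(estimate, lb), ub))
    if flag:
        return flag
    if mc_samples is not None and len(mc_samples) > 0:
        pinned = [_near(min(max(float(v), lb), ub)) for v in mc_samples]
        for side in ("UB", "LB"):
            if sum(f == side for f in pinned) > 0.5 * len(pinned):
                return side
        lo_end, hi_end = np.percentile(mc_samples, [2.5, 97.5])
        if _near(min(max(float(hi_end), lb), ub)) == "UB":
            return "UB"
        if _near(min(max(float(lo_end), lb), ub)) == "LB":
            return "LB"
        mean = float(np.mean(mc_samples))
        if mean != 0 and float(np.std(mc_samples)) / abs(mean) < 1e-3:
            return "SV"
    return ""
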