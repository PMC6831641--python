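"""Disk formats: two-column ASCII spectra, one file per titration point per
resonance, plus a YAML config recording concentrations and model metadata.

File layout of a series directory::

    series.yaml             # ptotal, ltotals, resonances, units, model, ...
    <resonance>_00.txt      # frequency  intensity (whitespace separated)
    <resonance>_01.txt
    ...

``read(write(x))`` round-trips arrays to full double precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .equilibria import (
    BindingModel,
    FourStateModel,
    InvalidInputError,
    ThreeStateModel,
    TwoStateModel,
)
from .lineshape import SpinParams, Spectrum
from .simulate import TitrationSeries

__all__ = [
    "write_series",
    "read_series",
    "model_to_dict",
    "model_from_dict",
    "spins_to_dict",
    "spins_from_dict",
    "SeriesIOError",
]

CONFIG_NAME = "series.yaml"


class SeriesIOError(IOError):
    """Malformed or inconsistent on-disk titration data."""


def model_to_dict(model: BindingModel) -> dict:
    if isinstance(model, TwoStateModel):
        return {"type": "2state", "kd": model.kd, "koff": model.koff}
    if isinstance(model, ThreeStateModel):
        return {"type": "3state", "kd": model.kd, "keq": model.keq,
                "koff": model.koff, "krev": model.krev}
    if isinstance(model, FourStateModel):
        return {"type": "4state", "kd_a1": model.kd_a1, "kd_b1": model.kd_b1,
                "kd_a2": model.kd_a2, "koff_a1": model.koff_a1,
                "koff_b1": model.koff_b1, "koff_a2": model.koff_a2,
                "koff_b2": model.koff_b2}
    raise InvalidInputError(f"unknown model type {type(model)!r}")


def model_from_dict(d: dict) -> BindingModel:
    d = dict(d)
    kind = d.pop("type")
    if kind == "2state":
        return TwoStateModel(**d)
    if kind == "3state":
        return ThreeStateModel(**d)
    if kind == "4state":
        return FourStateModel(**d)
    raise InvalidInputError(f"unknown model type {kind!r}")


def spins_to_dict(spins: SpinParams) -> dict:
    return {"omega0": [float(v) for v in spins.omega0],
            "linewidths": [float(v) for v in spins.linewidths]}


def spins_from_dict(d: dict) -> SpinParams:
    return SpinParams.from_linewidths(d["omega0"], d["linewidths"])


def _spectrum_path(directory: Path, resonance: str, index: int) -> Path:
    return directory / f"{resonance}_{index:02d}.txt"


def write_series(
    series_list: TitrationSeries | list[TitrationSeries],
    directory,
    freq_units: str = "angular",
    extra_config: dict | None = None,
) -> list[Path]:
    """Write one or more resonances' series to ``directory``.

    Each spectrum becomes a two-column text file (frequency, intensity,
    ``%.17g`` floats); a ``series.yaml`` records concentrations, resonance
    ids, units, and — when available — the generating model and spins.
    Returns the written spectrum paths.
    """
    if isinstance(series_list, TitrationSeries):
        series_list = [series_list]
    if not series_list:
        raise SeriesIOError("no series to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.ltotals, ref.ltotals) or s.ptotal != ref.ptotal:
            raise SeriesIOError("all resonances must share concentrations")

    paths = []
    for series in series_list:
        for j, spec in enumerate(series.spectra):
            path = _spectrum_path(directory, series.resonance, j)
            np.savetxt(path, np.column_stack([spec.freq, spec.intensity]), fmt="%.17g")
            paths.append(path)

    config = {
        "ptotal": float(ref.ptotal),
        "ltotals": [float(v) for v in ref.ltotals],
        "resonances": [s.resonance for s in series_list],
        "freq_units": freq_units,
    }
    if ref.model is not None:
        config["model"] = model_to_dict(ref.model)
    for s in series_list:
        if s.spins is not None:
            config.setdefault("spins", {})[s.resonance] = spins_to_dict(s.spins)
    if extra_config:
        config.update(extra_config)
    with open(directory / CONFIG_NAME, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths


def _read_spectrum_file(path: Path) -> np.ndarray:
    if not path.exists():
        raise SeriesIOError(f"missing spectrum file: {path}")
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise SeriesIOError(f"malformed spectrum file {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        raise SeriesIOError(
            f"malformed spectrum file {path}: expected 2 columns, got shape {data.shape}"
        )
    return data


def read_series(directory, config: dict | None = None) -> list[TitrationSeries]:
    """Read a series directory back into one TitrationSeries per resonance.

    ``config`` overrides the on-disk ``series.yaml`` (it must at least give
    ``ptotal``, ``ltotals``, and ``resonances``).
    """
    directory = Path(directory)
    if config is None:
        cfg_path = directory / CONFIG_NAME
        if not cfg_path.exists():
            raise SeriesIOError(f"missing config file: {cfg_path}")
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    for key in ("ptotal", "ltotals", "resonances"):
        if key not in config:
            raise SeriesIOError(f"config lacks required key {key!r}")

    ptotal = float(config["ptotal"])
    ltotals = np.asarray(config["ltotals"], dtype=float)
    model = model_from_dict(config["model"]) if "model" in config else None

    out = []
    for resonance in config["resonances"]:
        spectra = []
        for j, lt in enumerate(ltotals):
            data = _read_spectrum_file(_spectrum_path(directory, resonance, j))
            spectra.append(Spectrum(data[:, 0], data[:, 1], resonance=resonance,
                                    titration_index=j, ptotal=ptotal, ltotal=float(lt)))
        spins = None
        if "spins" in config and resonance in config["spins"]:
            spins = spins_from_dict(config["spins"][resonance])
        out.append(TitrationSeries(ptotal, ltotals, spectra, resonance=resonance,
                                   model=model, spins=spins))
        extra = sorted(directory.glob(f"{resonance}_*.txt"))
        if len(extra) != ltotals.size:
            raise SeriesIOError(
                f"resonance {resonance!r}: {len(extra)} spectrum files but "
                f"{ltotals.size} concentrations listed"
            )
    return out
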