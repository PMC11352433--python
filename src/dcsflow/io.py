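"""File formats and configuration loading.

Plain-text formats (CSV with headers) for every pipeline artifact, plus a
binary option for raw event timestamps:

* events: one arrival time per line in seconds (``.txt``/``.csv``), or raw
  little-endian unsigned 64-bit nanosecond timestamps (``.bin``);
* counts: ``# bin_width_s=...`` / ``# t0_s=...`` metadata lines, then one
  count per line;
* correlation: ``tau_s,g2`` CSV;
* fit report / BFI series: CSV with one row per window, missing BFIs as
  empty fields;
* config: TOML with [optics], [pipeline], [correlator], [fit], [gate]
  sections keyed as the corresponding dataclass fields.

Every reader rejects malformed input with a line-numbered message, and
read(write(x)) round-trips exactly for each format.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .analyzer import FitConfig, GateBounds
from .correlator import CorrelatorConfig, PhotonCountSeries
from .model import NM_TO_CM, CorrelationCurve, FlowState, OpticalConfig
from .pipeline import BFITimeSeries, PipelineConfig

__all__ = [
    "read_events",
    "write_events",
    "read_counts",
    "write_counts",
    "read_correlation",
    "write_correlation",
    "read_bfi",
    "write_bfi",
    "load_config",
    "optics_from_dict",
    "optics_to_dict",
]

PathLike = Union[str, Path]


# --- events --------------------------------------------------------------


def write_events(path: PathLike, timestamps: np.ndarray) -> None:
    """Write arrival times (s); format chosen by extension (.bin = binary)."""
    path = Path(path)
    ts = np.asarray(timestamps, dtype=float)
    if path.suffix == ".bin":
        np.round(ts * 1e9).astype("<u8").tofile(path)
    else:
        np.savetxt(path, ts, fmt="%.9f")


def read_events(path: PathLike) -> np.ndarray:
    """Read arrival times (s) from a text or ``.bin`` event file."""
    path = Path(path)
    if path.suffix == ".bin":
        return np.fromfile(path, dtype="<u8").astype(float) * 1e-9
    times = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                times.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: invalid timestamp {line!r}"
                ) from None
    return np.asarray(times)


# --- counts --------------------------------------------------------------


def write_counts(path: PathLike, series: PhotonCountSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={series.bin_width!r}\n")
        fh.write(f"# t0_s={series.t0!r}\n")
        np.savetxt(fh, series.counts, fmt="%d")


def read_counts(path: PathLike) -> PhotonCountSeries:
    path = Path(path)
    bin_width = None
    t0 = 0.0
    counts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key == "bin_width_s":
                    bin_width = float(value)
                elif key == "t0_s":
                    t0 = float(value)
                continue
            try:
                counts.append(int(line))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: invalid count {line!r}") from None
    if bin_width is None:
        raise ValueError(f"{path}: missing '# bin_width_s=' metadata line")
    return PhotonCountSeries(np.asarray(counts, dtype=np.int64), bin_width, t0)


# --- correlation curves --------------------------------------------------


def write_correlation(path: PathLike, curve: CorrelationCurve) -> None:
    df = pd.DataFrame({"tau_s": curve.taus, "g2": curve.g2})
    df.to_csv(path, index=False, float_format="%.12g")


def read_correlation(path: PathLike) -> CorrelationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("tau_s", "g2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    taus = df["tau_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(taus) <= 0)[0]
    if len(bad):
        # +2 for the header row, +1 for 1-based lines
        raise ValueError(
            f"{path}:{bad[0] + 3}: tau_s values must be strictly increasing"
        )
    return CorrelationCurve(taus=taus, g2=df["g2"].to_numpy(dtype=float))


# --- BFI series / fit report ---------------------------------------------

_BFI_COLUMNS = ["t_s", "alpha_db_cm2_s", "beta", "mse", "iterations",
                "converged", "gate_status"]


def write_bfi(path: PathLike, series: BFITimeSeries) -> None:
    """Write the per-window fit report; missing BFIs become empty fields."""
    df = pd.DataFrame(
        {
            "t_s": series.times,
            "alpha_db_cm2_s": series.alpha_db,
            "beta": series.beta,
            "mse": series.mse,
            "iterations": series.iterations,
            "converged": series.converged.astype(int),
            "gate_status": series.gate_status,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# measurement_rate_hz={series.measurement_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_bfi(path: PathLike) -> BFITimeSeries:
    path = Path(path)
    rate = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "measurement_rate_hz=" in first:
            rate = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            raise ValueError(
                f"{path}:1: missing '# measurement_rate_hz=' metadata line"
            )
    missing = [c for c in _BFI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return BFITimeSeries(
        times=df["t_s"].to_numpy(dtype=float),
        alpha_db=df["alpha_db_cm2_s"].to_numpy(dtype=float),
        beta=df["beta"].to_numpy(dtype=float),
        mse=df["mse"].to_numpy(dtype=float),
        iterations=df["iterations"].to_numpy(dtype=np.int64),
        converged=df["converged"].to_numpy(dtype=bool),
        gate_status=[str(s) for s in df["gate_status"]],
        measurement_rate=rate,
    )


# --- configuration -------------------------------------------------------


def _require(table: dict, key: str, context: str):
    if key not in table:
        raise ValueError(f"config missing required key {key!r} in [{context}]")
    return table[key]


def optics_to_dict(optics: OpticalConfig) -> dict:
    """Config-file representation of optics (wavelength in nm)."""
    table = {
        "mu_a": optics.mu_a,
        "mu_s_prime": optics.mu_s_prime,
        "rho_cm": optics.rho,
        "wavelength_nm": optics.wavelength_nm,
        "n_medium": optics.n_medium,
        "n_outside": optics.n_outside,
    }
    if optics.reff_override is not None:
        table["reff"] = optics.reff_override
    return table


def optics_from_dict(table: dict) -> OpticalConfig:
    """Build optics from a config table (wavelength given in nm)."""
    kwargs = {}
    if "n_medium" in table:
        kwargs["n_medium"] = float(table["n_medium"])
    if "n_outside" in table:
        kwargs["n_outside"] = float(table["n_outside"])
    if "reff" in table:
        kwargs["reff_override"] = float(table["reff"])
    return OpticalConfig.from_nm(
        mu_a=float(_require(table, "mu_a", "optics")),
        mu_s_prime=float(_require(table, "mu_s_prime", "optics")),
        rho=float(_require(table, "rho_cm", "optics")),
        wavelength_nm=float(table.get("wavelength_nm", 785.0)),
        **kwargs,
    )


def _correlator_from_dict(table: dict) -> CorrelatorConfig:
    if "preset" in table:
        return CorrelatorConfig.preset(
            str(table["preset"]), base_bin=float(table.get("base_bin_s", 1e-6))
        )
    kwargs = {}
    for key, name in [
        ("base_bin_s", "base_bin"),
        ("first_stage_delays", "first_stage_delays"),
        ("stage_delays", "stage_delays"),
        ("n_stages", "n_stages"),
        ("coarsening_factor", "coarsening_factor"),
    ]:
        if key in table:
            value = table[key]
            kwargs[name] = float(value) if name == "base_bin" else int(value)
    return CorrelatorConfig(**kwargs)


def _fit_from_dict(table: dict) -> FitConfig:
    kwargs = {}
    if "initial_simplex" in table:
        vertices = table["initial_simplex"]
        if len(vertices) != 3:
            raise ValueError("config [fit].initial_simplex needs 3 [beta, alpha_db] pairs")
        kwargs["initial_simplex"] = tuple(
            FlowState(beta=float(b), alpha_db=float(a)) for b, a in vertices
        )
    for key in ("reflect", "expand", "contract", "shrink", "convergence_threshold"):
        if key in table:
            kwargs[key] = float(table[key])
    if "max_iterations" in table:
        kwargs["max_iterations"] = int(table["max_iterations"])
    for key in ("beta_bounds", "alpha_db_bounds"):
        if key in table:
            kwargs[key] = tuple(float(v) for v in table[key])
    return FitConfig(**kwargs)


def _gate_from_dict(table: dict) -> GateBounds:
    return GateBounds(
        first_lo=float(table.get("first_lo", 1.05)),
        first_hi=float(table.get("first_hi", 2.0)),
        last_tol=float(table.get("last_tol", 0.1)),
    )


def load_config(path: PathLike) -> PipelineConfig:
    """Load a TOML pipeline configuration.

    Required: [optics] with mu_a, mu_s_prime, rho_cm.  Optional sections
    [pipeline], [correlator], [fit], [gate] override the defaults.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "optics" not in data:
        raise ValueError("config missing required [optics] section")
    pipe = data.get("pipeline", {})
    return PipelineConfig(
        optics=optics_from_dict(data["optics"]),
        measurement_rate=float(pipe.get("measurement_rate_hz", 1.0)),
        correlator=_correlator_from_dict(data.get("correlator", {})),
        fit=_fit_from_dict(data.get("fit", {})),
        gate=_gate_from_dict(data.get("gate", {})),
        smoothing_window=int(pipe.get("smoothing_window", 0)),
    )
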