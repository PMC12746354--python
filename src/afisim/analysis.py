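"""Spoiling-curve and TE-sweep generation and summary statistics.

A *spoiling curve* is the flip-angle estimate as a function of the
RF-spoiling phase increment Φ0 with every other sequence parameter
fixed; a *TE series* sweeps the echo time at fixed Φ0.  The summary
statistics mirror how such curves are reported: the asymmetry
Δα = α(Φ0=120°) − α(Φ0=60°) (zero for curves symmetric about 90°),
the grid location of the curve minimum, and the percent deviation of
an estimate from a reference flip angle.

Failed flip-angle estimates (arccos argument outside [−1, 1]) are
first-class values carried as NaN; statistics skip them but report
their positions, and file round trips preserve them via an explicit
``failed`` column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sequence import AFIProtocol, AFISignals, afi_flip_angle

__all__ = [
    "SpoilingCurve",
    "TESeries",
    "DEFAULT_PHI0_GRID",
    "DEFAULT_TE_GRID",
    "spoiling_curve",
    "te_sweep",
    "asymmetry",
    "curve_minimum",
    "percent_deviation",
    "write_curve_csv",
    "read_curve_csv",
    "write_te_series_csv",
    "read_te_series_csv",
]

#: Acquisition grids: Φ0 = 0°–180° in 20° steps; TE = 1.5–6.1 ms in 0.2 ms steps.
DEFAULT_PHI0_GRID = np.arange(0.0, 181.0, 20.0)
DEFAULT_TE_GRID = np.round(np.arange(1.5, 6.1001, 0.2), 10)

Simulator = Callable[[AFIProtocol], AFISignals]


@dataclass
class SpoilingCurve:
    """Flip-angle estimates over a Φ0 grid; NaN marks a failed estimate."""

    phi0_deg: np.ndarray
    alpha_deg: np.ndarray
    alpha_sd_deg: np.ndarray
    reference_alpha_deg: float | None = None
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi0_deg = np.asarray(self.phi0_deg, dtype=float)
        self.alpha_deg = np.asarray(self.alpha_deg, dtype=float)
        self.alpha_sd_deg = np.asarray(self.alpha_sd_deg, dtype=float)
        if not (len(self.phi0_deg) == len(self.alpha_deg)
                == len(self.alpha_sd_deg)):
            raise ValueError("grid and value arrays must have equal length")
        if np.any(np.diff(self.phi0_deg) <= 0):
            raise ValueError("phi0 grid must be strictly increasing")
        if np.any(self.alpha_sd_deg < 0):
            raise ValueError("alpha sd must be non-negative")

    @property
    def failed(self) -> np.ndarray:
        return ~np.isfinite(self.alpha_deg)

    def n_failed(self) -> int:
        return int(np.sum(self.failed))


@dataclass
class TESeries:
    """Flip angle and signal magnitudes over a TE grid at fixed Φ0."""

    te_ms: np.ndarray
    alpha_deg: np.ndarray
    s1_mag: np.ndarray
    s2_mag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.alpha_deg = np.asarray(self.alpha_deg, dtype=float)
        self.s1_mag = np.asarray(self.s1_mag, dtype=float)
        self.s2_mag = np.asarray(self.s2_mag, dtype=float)
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("TE grid must be strictly increasing")


def spoiling_curve(protocol_template: AFIProtocol, simulator: Simulator,
                   phi0_grid: Sequence[float] | None = None,
                   reference_alpha_deg: float | None = None,
                   provenance: str = "simulated") -> SpoilingCurve:
    """One flip-angle estimate per Φ0; failed estimates preserved as NaN."""
    grid = np.asarray(DEFAULT_PHI0_GRID if phi0_grid is None else phi0_grid,
                      dtype=float)
    n = protocol_template.n
    alpha = np.empty(len(grid))
    for i, phi0 in enumerate(grid):
        sig = simulator(replace(protocol_template, phi0_deg=float(phi0)))
        alpha[i] = afi_flip_angle(sig, n)
    return SpoilingCurve(
        phi0_deg=grid, alpha_deg=alpha, alpha_sd_deg=np.zeros(len(grid)),
        reference_alpha_deg=reference_alpha_deg, provenance=provenance,
        meta={"protocol": protocol_template.to_dict()})


def te_sweep(protocol_template: AFIProtocol, simulator: Simulator,
             te_grid: Sequence[float] | None = None) -> TESeries:
    """Sweep TE at fixed Φ0, recording α and the two signal magnitudes."""
    grid = np.asarray(DEFAULT_TE_GRID if te_grid is None else te_grid,
                      dtype=float)
    n = protocol_template.n
    alpha = np.empty(len(grid))
    s1 = np.empty(len(grid))
    s2 = np.empty(len(grid))
    for i, te in enumerate(grid):
        sig = simulator(replace(protocol_template, te_ms=float(te)))
        alpha[i] = afi_flip_angle(sig, n)
        s1[i], s2[i] = abs(sig.s1), abs(sig.s2)
    return TESeries(te_ms=grid, alpha_deg=alpha, s1_mag=s1, s2_mag=s2,
                    meta={"protocol": protocol_template.to_dict()})


def asymmetry(curve: SpoilingCurve, tol: float = 1e-9) -> float:
    """Δα = α(Φ0=120°) − α(Φ0=60°); NaN if either point is absent or failed."""
    a60 = _value_at(curve, 60.0, tol)
    a120 = _value_at(curve, 120.0, tol)
    if a60 is None or a120 is None:
        return float("nan")
    return float(a120 - a60)


def _value_at(curve: SpoilingCurve, phi0: float, tol: float) -> float | None:
    idx = np.flatnonzero(np.abs(curve.phi0_deg - phi0) <= tol)
    if len(idx) == 0:
        return None
    val = curve.alpha_deg[idx[0]]
    return None if not np.isfinite(val) else float(val)


def curve_minimum(curve: SpoilingCurve) -> tuple[float, float]:
    """Grid point of smallest α (failed points excluded, ties -> smaller Φ0)."""
    finite = np.isfinite(curve.alpha_deg)
    if not finite.any():
        raise ValueError("all flip-angle estimates failed; no minimum")
    vmin = np.min(curve.alpha_deg[finite])
    idx = int(np.flatnonzero(finite & (curve.alpha_deg == vmin))[0])
    return float(curve.phi0_deg[idx]), float(curve.alpha_deg[idx])


def percent_deviation(alpha_deg: float, reference_deg: float) -> float:
    """100·(α − ref)/ref."""
    if reference_deg <= 0:
        raise ValueError("reference flip angle must be positive")
    return 100.0 * (alpha_deg - reference_deg) / reference_deg


# --------------------------------------------------------------------------
# Delimited-table I/O (CSV + JSON sidecar)

def write_curve_csv(path: str | Path, curve: SpoilingCurve,
                    float_format: str = "%.4f") -> None:
    path = Path(path)
    df = pd.DataFrame({
        "phi0_deg": curve.phi0_deg,
        "alpha_deg": curve.alpha_deg,
        "alpha_sd_deg": curve.alpha_sd_deg,
        "failed": curve.failed.astype(int),
    })
    df.to_csv(path, index=False, float_format=float_format)
    sidecar = {
        "provenance": curve.provenance,
        "reference_alpha_deg": curve.reference_alpha_deg,
        **curve.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True))


def read_curve_csv(path: str | Path) -> SpoilingCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed curve CSV {path}: {exc}") from exc
    required = {"phi0_deg", "alpha_deg", "alpha_sd_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve CSV {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    meta: dict = {}
    ref = None
    provenance = "file"
    sc = path.with_suffix(".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
        ref = meta.pop("reference_alpha_deg", None)
        provenance = meta.pop("provenance", "file")
    alpha = df["alpha_deg"].to_numpy(dtype=float)
    if "failed" in df.columns:
        alpha = np.where(df["failed"].to_numpy(dtype=bool), np.nan, alpha)
    return SpoilingCurve(
        phi0_deg=df["phi0_deg"].to_numpy(dtype=float), alpha_deg=alpha,
        alpha_sd_deg=df["alpha_sd_deg"].to_numpy(dtype=float),
        reference_alpha_deg=ref, provenance=provenance, meta=meta)


def write_te_series_csv(path: str | Path, series: TESeries,
                        float_format: str = "%.6g") -> None:
    path = Path(path)
    pd.DataFrame({
        "te_ms": series.te_ms,
        "alpha_deg": series.alpha_deg,
        "s1_mag": series.s1_mag,
        "s2_mag": series.s2_mag,
    }).to_csv(path, index=False, float_format=float_format)
    path.with_suffix(".json").write_text(
        json.dumps(series.meta, indent=2, sort_keys=True))


def read_te_series_csv(path: str | Path) -> TESeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sc = path.with_suffix(".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
    return TESeries(te_ms=df["te_ms"].to_numpy(dtype=float),
                    alpha_deg=df["alpha_deg"].to_numpy(dtype=float),
                    s1_mag=df["s1_mag"].to_numpy(dtype=float),
                    s2_mag=df["s2_mag"].to_numpy(dtype=float), meta=meta)
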