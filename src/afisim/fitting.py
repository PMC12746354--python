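"""Fitting the interference parameters (w, φ) to a measured spoiling curve.

The interference weight and phase offset are estimated by minimizing
the root-mean-square deviation between a measured flip-angle spoiling
curve and the two-frequency simulated one, with the frequency offset
Δν and both pools' relaxation parameters held fixed.

The expensive part -- the EPG simulation of the two component signals
at each Φ0 -- does not depend on (w, φ): the candidate parameters only
recombine the cached complex component signals.  The component table
is therefore computed once per grid and the objective is a cheap
closed-form recombination, which makes a deterministic coarse grid
search plus local refinement practical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .analysis import SpoilingCurve
from .interference import (InterferenceParams, TwoComponentSystem,
                           combine_signals, component_signals, wrap_phase)
from .sequence import AFIProtocol, SimSettings, flip_angle_from_ratio

__all__ = [
    "FitSettings",
    "FitResult",
    "ComponentTable",
    "rmse",
    "component_table",
    "fit_interference",
]


def rmse(curve_a: SpoilingCurve, curve_b: SpoilingCurve) -> float:
    """Root-mean-square α difference over mutually successful grid points."""
    if len(curve_a.phi0_deg) != len(curve_b.phi0_deg) or not np.allclose(
            curve_a.phi0_deg, curve_b.phi0_deg):
        raise ValueError("spoiling curves must share the same Φ0 grid")
    ok = np.isfinite(curve_a.alpha_deg) & np.isfinite(curve_b.alpha_deg)
    if not ok.any():
        raise ValueError("no mutually successful grid points")
    d = curve_a.alpha_deg[ok] - curve_b.alpha_deg[ok]
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class FitSettings:
    """Deterministic grid-plus-refinement optimizer controls."""

    w_grid: int = 21
    phi_grid: int = 24
    w_max: float = 1.0
    n_starts: int = 3
    fail_penalty_deg: float = 180.0
    xatol: float = 1e-5
    fatol: float = 1e-8
    sim: SimSettings = field(default_factory=SimSettings)

    def hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in
             ("w_grid", "phi_grid", "w_max", "n_starts", "fail_penalty_deg")},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ComponentTable:
    """Cached complex component signals per Φ0 grid point."""

    phi0_deg: np.ndarray
    s1_res: np.ndarray
    s2_res: np.ndarray
    s1_off: np.ndarray
    s2_off: np.ndarray
    te_ms: float
    n: int


@dataclass
class FitResult:
    params: InterferenceParams
    rmse_deg: float
    n_points: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "w": self.params.w,
            "phi_pi_units": self.params.phi_pi_units,
            "delta_nu_hz": self.params.delta_nu_hz,
            "rmse_deg": self.rmse_deg,
            "n_points": self.n_points,
            "settings_hash": self.diagnostics.get("settings_hash"),
        }


def component_table(protocol_template: AFIProtocol,
                    system: TwoComponentSystem,
                    phi0_grid: np.ndarray,
                    settings: SimSettings | None = None,
                    alpha_true_deg: float | None = None) -> ComponentTable:
    """Simulate the two EPG components once per Φ0 grid point."""
    grid = np.asarray(phi0_grid, dtype=float)
    s1r = np.empty(len(grid), complex)
    s2r = np.empty(len(grid), complex)
    s1o = np.empty(len(grid), complex)
    s2o = np.empty(len(grid), complex)
    for i, phi0 in enumerate(grid):
        sig_res, sig_off = component_signals(
            replace(protocol_template, phi0_deg=float(phi0)), system,
            settings, alpha_true_deg)
        s1r[i], s2r[i] = sig_res.s1, sig_res.s2
        s1o[i], s2o[i] = sig_off.s1, sig_off.s2
    return ComponentTable(phi0_deg=grid, s1_res=s1r, s2_res=s2r,
                          s1_off=s1o, s2_off=s2o,
                          te_ms=protocol_template.te_ms,
                          n=protocol_template.n)


def _predict_alpha(table: ComponentTable, w: float, phi: float,
                   delta_nu_hz: float) -> np.ndarray:
    params = InterferenceParams(w=w, phi_rad=phi, delta_nu_hz=delta_nu_hz)
    alpha = np.empty(len(table.phi0_deg))
    for i in range(len(table.phi0_deg)):
        s1 = combine_signals(table.s1_res[i], table.s1_off[i], params,
                             table.te_ms)
        s2 = combine_signals(table.s2_res[i], table.s2_off[i], params,
                             table.te_ms)
        alpha[i] = (flip_angle_from_ratio(abs(s2) / abs(s1), table.n)
                    if abs(s1) > 0 else np.nan)
    return alpha


def fit_interference(measured: SpoilingCurve,
                     protocol_template: AFIProtocol,
                     system: TwoComponentSystem,
                     delta_nu_hz: float,
                     settings: FitSettings | None = None,
                     components: ComponentTable | None = None,
                     alpha_true_deg: float | None = None) -> FitResult:
    """Estimate (w, φ) by RMSE minimization against a measured curve.

    Coarse deterministic grid search over w ∈ [0, w_max] and φ on the
    circle, followed by Nelder-Mead refinement from the best
    ``n_starts`` grid points.  Candidate parameters at which the
    flip-angle estimate fails on a point where the measurement
    succeeded contribute ``fail_penalty_deg`` to that point's residual
    (failures are penalized, not fatal).
    """
    settings = settings or FitSettings()
    meas_ok = np.isfinite(measured.alpha_deg)
    if meas_ok.sum() < 4:
        raise ValueError("need at least 4 successful measured grid points")
    if components is None:
        components = component_table(protocol_template, system,
                                     measured.phi0_deg, settings.sim,
                                     alpha_true_deg)
    elif not np.allclose(components.phi0_deg, measured.phi0_deg):
        raise ValueError("component table grid does not match measured grid")

    meas_alpha = measured.alpha_deg[meas_ok]

    def objective(x: np.ndarray) -> float:
        w, phi = x
        wc = min(max(w, 0.0), settings.w_max)
        pred = _predict_alpha(components, wc, phi, delta_nu_hz)[meas_ok]
        resid = pred - meas_alpha
        resid[~np.isfinite(resid)] = settings.fail_penalty_deg
        value = float(np.sqrt(np.mean(resid * resid)))
        # keep w inside its physical box during refinement
        return value + 1e3 * (w - wc) ** 2

    w_vals = np.linspace(0.0, settings.w_max, settings.w_grid)
    phi_vals = np.linspace(-np.pi, np.pi, settings.phi_grid, endpoint=False)
    grid_scores = [(objective(np.array([w, p])), w, p)
                   for w in w_vals for p in phi_vals]
    grid_scores.sort(key=lambda t: (t[0], t[1], t[2]))

    candidates = []
    for score, w0, p0 in grid_scores[: settings.n_starts]:
        res = minimize(objective, np.array([w0, p0]), method="Nelder-Mead",
                       options={"xatol": settings.xatol,
                                "fatol": settings.fatol, "maxiter": 2000})
        candidates.append((float(res.fun), res.x, bool(res.success),
                           (score, w0, p0)))
    candidates.sort(key=lambda t: t[0])
    best_f, best_x, best_ok, best_start = candidates[0]
    runner_up = ([{"rmse_deg": c[0], "w": float(c[1][0]),
                   "phi_rad": wrap_phase(float(c[1][1]))}
                  for c in candidates[1:]])

    params = InterferenceParams(w=min(max(float(best_x[0]), 0.0),
                                      settings.w_max),
                                phi_rad=float(best_x[1]),
                                delta_nu_hz=delta_nu_hz)
    pred = _predict_alpha(components, params.w, params.phi_rad, delta_nu_hz)
    both = meas_ok & np.isfinite(pred)
    final_rmse = float(np.sqrt(np.mean(
        (pred[both] - measured.alpha_deg[both]) ** 2))) if both.any() else float("inf")
    return FitResult(
        params=params, rmse_deg=final_rmse, n_points=int(both.sum()),
        diagnostics={
            "converged": best_ok,
            "grid_start": {"rmse_deg": best_start[0], "w": best_start[1],
                           "phi_rad": best_start[2]},
            "runner_up": runner_up,
            "excluded_points": [float(p) for p in
                                measured.phi0_deg[~meas_ok]],
            "settings_hash": settings.hash(),
        })
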