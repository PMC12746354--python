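"""Synthetic "measured" data with the statistical structure of ROI analysis.

The imaging experiments report ROI statistics of flip-angle maps:
complex voxel signals carry additive complex Gaussian noise, magnitude
images are therefore Rician, and the reported value is the mean (and
standard deviation) over a circular ROI of voxels.  This module
synthesizes spoiling curves and TE series with exactly that structure
from the two-frequency signal model, so the full analysis and fitting
pipeline can be exercised without scanner data.

It also ships the phantom-tube catalog (polymer fraction, dielectric
properties, and the relaxation/diffusion parameters at both field
strengths) used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .analysis import (DEFAULT_PHI0_GRID, DEFAULT_TE_GRID, SpoilingCurve,
                       TESeries)
from .epg import TissueComponent
from .fitting import ComponentTable, component_table
from .interference import InterferenceParams, TwoComponentSystem, combine_signals
from .sequence import AFIProtocol, SimSettings, flip_angle_from_ratio

__all__ = [
    "TubeRecord",
    "NoiseModel",
    "tube_catalog",
    "tube",
    "tissue_for",
    "generate_measured_curve",
    "generate_te_series",
]


@dataclass(frozen=True)
class TubeRecord:
    """One phantom tube: composition, dielectric and MR parameters.

    ``eps_r`` and ``sigma_S_per_m`` are metadata only (no computation
    uses them); the water tubes carry NaN there.
    """

    name: str
    pvp_wt_percent: float
    contrast_agent_vol_percent: float
    eps_r: float
    sigma_S_per_m: float
    t1_3t_ms: float
    t1_7t_ms: float
    t2_3t_ms: float
    t2_7t_ms: float
    adc_um2_s: float


@lru_cache(maxsize=1)
def tube_catalog() -> tuple[TubeRecord, ...]:
    """The 12-tube phantom catalog (8 PVP dilutions, 4 doped-water)."""
    with resources.files("afisim.data").joinpath("tube_catalog.csv").open() as fh:
        df = pd.read_csv(fh)
    return tuple(TubeRecord(**{k: (row[k] if k == "name" else float(row[k]))
                               for k in TubeRecord.__dataclass_fields__})
                 for _, row in df.iterrows())


def tube(name: str) -> TubeRecord:
    for rec in tube_catalog():
        if rec.name == name:
            return rec
    raise KeyError(f"unknown tube {name!r}")


def tissue_for(name: str, field: str = "3T") -> TissueComponent:
    """On-resonant tissue parameters of a tube at '3T' or '7T'."""
    rec = tube(name)
    if field.upper() == "3T":
        return TissueComponent(t1_ms=rec.t1_3t_ms, t2_ms=rec.t2_3t_ms,
                               adc_um2_s=rec.adc_um2_s)
    if field.upper() == "7T":
        return TissueComponent(t1_ms=rec.t1_7t_ms, t2_ms=rec.t2_7t_ms,
                               adc_um2_s=rec.adc_um2_s)
    raise ValueError("field must be '3T' or '7T'")


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian voxel noise and ROI size.

    ``complex_noise_sd`` is the standard deviation of each quadrature
    component, as a fraction of the equilibrium magnetization.
    """

    complex_noise_sd: float = 0.002
    n_voxels: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.complex_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")


def _roi_alpha(s1: complex, s2: complex, n: int, noise: NoiseModel,
               rng: np.random.Generator,
               roi_mode: str) -> tuple[float, float, int]:
    """ROI mean/sd flip angle from noisy voxel replicates of (s1, s2)."""
    if noise.complex_noise_sd == 0:
        return flip_angle_from_ratio(abs(s2) / abs(s1), n), 0.0, 0
    nv = noise.n_voxels
    g = rng.standard_normal((4, nv)) * noise.complex_noise_sd
    m1 = np.abs(s1 + g[0] + 1j * g[1])
    m2 = np.abs(s2 + g[2] + 1j * g[3])
    if roi_mode == "mean_signal":
        return flip_angle_from_ratio(float(m2.mean()) / float(m1.mean()),
                                     n), 0.0, 0
    if roi_mode != "per_voxel":
        raise ValueError("roi_mode must be 'per_voxel' or 'mean_signal'")
    alphas = np.array([flip_angle_from_ratio(b / a, n)
                       for a, b in zip(m1, m2)])
    ok = np.isfinite(alphas)
    n_failed = int((~ok).sum())
    if not ok.any():
        return float("nan"), float("nan"), n_failed
    sd = float(np.std(alphas[ok], ddof=1)) if ok.sum() > 1 else 0.0
    return float(np.mean(alphas[ok])), sd, n_failed


def generate_measured_curve(protocol_template: AFIProtocol,
                            system: TwoComponentSystem,
                            params: InterferenceParams,
                            truth_alpha_deg: float,
                            noise: NoiseModel,
                            phi0_grid: np.ndarray | None = None,
                            settings: SimSettings | None = None,
                            roi_mode: str = "per_voxel",
                            components: ComponentTable | None = None
                            ) -> SpoilingCurve:
    """Synthetic noisy ROI-mean spoiling curve from the two-frequency model.

    For each Φ0 the noiseless two-component (S1, S2) are simulated;
    ``n_voxels`` independent complex Gaussian noise draws are added to
    each signal, magnitudes formed (Rician), and the ROI statistic
    taken over voxel-wise flip-angle estimates (default) or over the
    ROI-mean magnitudes.  Fully reproducible from ``noise.seed``.
    """
    grid = np.asarray(DEFAULT_PHI0_GRID if phi0_grid is None else phi0_grid,
                      dtype=float)
    if components is None:
        components = component_table(protocol_template, system, grid,
                                     settings, truth_alpha_deg)
    elif not np.allclose(components.phi0_deg, grid):
        raise ValueError("component table grid mismatch")
    rng = np.random.default_rng(noise.seed)
    n = protocol_template.n
    alpha = np.empty(len(grid))
    sd = np.empty(len(grid))
    n_failed = []
    for i in range(len(grid)):
        s1 = combine_signals(components.s1_res[i], components.s1_off[i],
                             params, protocol_template.te_ms)
        s2 = combine_signals(components.s2_res[i], components.s2_off[i],
                             params, protocol_template.te_ms)
        alpha[i], sd[i], nf = _roi_alpha(s1, s2, n, noise, rng, roi_mode)
        n_failed.append(nf)
    return SpoilingCurve(
        phi0_deg=grid, alpha_deg=alpha, alpha_sd_deg=sd,
        reference_alpha_deg=truth_alpha_deg, provenance="synthetic-measured",
        meta={"protocol": protocol_template.to_dict(),
              "interference": params.to_dict(),
              "noise": {"complex_noise_sd": noise.complex_noise_sd,
                        "n_voxels": noise.n_voxels, "seed": noise.seed},
              "n_failed_voxels": n_failed})


def generate_te_series(protocol_template: AFIProtocol,
                       system: TwoComponentSystem,
                       params: InterferenceParams,
                       truth_alpha_deg: float,
                       noise: NoiseModel,
                       te_grid: np.ndarray | None = None,
                       settings: SimSettings | None = None,
                       roi_mode: str = "per_voxel") -> TESeries:
    """Synthetic noisy TE series (α plus ROI-mean signal magnitudes)."""
    grid = np.asarray(DEFAULT_TE_GRID if te_grid is None else te_grid,
                      dtype=float)
    rng = np.random.default_rng(noise.seed)
    n = protocol_template.n
    alpha = np.empty(len(grid))
    s1_m = np.empty(len(grid))
    s2_m = np.empty(len(grid))
    from .interference import simulate_afi_two_component
    for i, te in enumerate(grid):
        prot = replace(protocol_template, te_ms=float(te))
        sig = simulate_afi_two_component(prot, system, params, settings,
                                         truth_alpha_deg)
        alpha[i], _, _ = _roi_alpha(sig.s1, sig.s2, n, noise, rng, roi_mode)
        if noise.complex_noise_sd == 0:
            s1_m[i], s2_m[i] = abs(sig.s1), abs(sig.s2)
        else:
            g = rng.standard_normal((4, noise.n_voxels)) * noise.complex_noise_sd
            s1_m[i] = np.mean(np.abs(sig.s1 + g[0] + 1j * g[1]))
            s2_m[i] = np.mean(np.abs(sig.s2 + g[2] + 1j * g[3]))
    return TESeries(te_ms=grid, alpha_deg=alpha, s1_mag=s1_m, s2_mag=s2_m,
                    meta={"protocol": protocol_template.to_dict(),
                          "interference": params.to_dict(),
                          "noise": {"complex_noise_sd": noise.complex_noise_sd,
                                    "n_voxels": noise.n_voxels,
                                    "seed": noise.seed}})
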