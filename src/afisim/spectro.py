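"""Closed-form spectroscopy conversions linking NMR spectra to simulation inputs.

These connect benchtop ¹H spectra of the polymer solutions to the
relaxation parameters the AFI simulation needs: a Lorentzian line of
full width Δf (Hz) at half maximum has T2* = 1/(π·Δf), and an
inversion-recovery zero crossing at delay t0 gives T1 = t0/ln 2.
All functions are pure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constants import GAMMA_HZ_PER_T

__all__ = [
    "SpectralBand",
    "ppm_to_hz",
    "t2star_from_fwhm",
    "t2star_from_fwhm_hz",
    "t1_from_zero_crossing",
    "load_bands_csv",
]


@dataclass(frozen=True)
class SpectralBand:
    """One spectral band: chemical-shift center, line width, assignment."""

    center_ppm: float
    fwhm_ppm: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.fwhm_ppm <= 0:
            raise ValueError("FWHM must be positive")


def ppm_to_hz(shift_ppm: float, field_t: float) -> float:
    """Chemical shift (ppm) to frequency offset (Hz) at a given field."""
    if field_t <= 0:
        raise ValueError("field strength must be positive")
    return shift_ppm * GAMMA_HZ_PER_T * field_t * 1e-6


def t2star_from_fwhm_hz(fwhm_hz: float) -> float:
    """T2* in ms from a Lorentzian FWHM in Hz: T2* = 1/(π·Δf)."""
    if fwhm_hz <= 0:
        raise ValueError("FWHM must be positive")
    return 1e3 / (math.pi * fwhm_hz)


def t2star_from_fwhm(fwhm_ppm: float, field_t: float) -> float:
    """T2* in ms from a Lorentzian FWHM given in ppm at a given field."""
    return t2star_from_fwhm_hz(ppm_to_hz(fwhm_ppm, field_t))


def t1_from_zero_crossing(t0_ms: float) -> float:
    """T1 (ms) from the inversion-recovery null delay: T1 = t0 / ln 2."""
    if t0_ms <= 0:
        raise ValueError("zero-crossing delay must be positive")
    return t0_ms / math.log(2.0)


def load_bands_csv(path: str | Path) -> list[SpectralBand]:
    """Read spectral bands from a CSV with columns center_ppm, fwhm_ppm, label."""
    df = pd.read_csv(path)
    return [SpectralBand(center_ppm=row["center_ppm"],
                         fwhm_ppm=row["fwhm_ppm"],
                         assignment=str(row.get("label", "")))
            for _, row in df.iterrows()]
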