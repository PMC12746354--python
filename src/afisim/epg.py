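"""Extended phase graph (EPG) engine.

Magnetization in a voxel subject to repeated RF pulses and spoiler
gradients is represented by complex configuration-state amplitudes
indexed by an integer dephasing order ``k``: ``F+(k)`` and ``F-(k)``
for transverse states and ``Z(k)`` for longitudinal states, where one
order corresponds to a 2π dephasing across the voxel.  The four
elementary operators are

* :func:`rf_rotation` -- instantaneous rotation by an RF pulse, with an
  off-resonant (tilted-axis) excitation matrix for pools that are not
  on resonance,
* :func:`relax` -- T1/T2 relaxation and recovery toward equilibrium,
* :func:`gradient_shift` -- spoiler-gradient dephasing, shifting
  configuration orders by an integer amount,
* :func:`diffusion_damping` -- attenuation of configuration states by
  isotropic diffusion through the spoiler-gradient field,

plus :func:`precess` for free off-resonance precession.

Storage convention: arrays ``f_plus[k]`` hold ``F(k)`` for ``k >= 0``,
``f_minus[k]`` hold ``conj(F(-k))``, and ``z[k]`` the longitudinal
coefficients, so a single 3x3 complex matrix acts uniformly on every
order during an RF pulse.  Arrays grow on demand (capped at ``k_max``)
and are pruned of negligible high orders for speed.

All public angles are degrees, times milliseconds, diffusivities
μm²/s, and frequencies Hz; conversions to SI happen internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TissueComponent",
    "ConfigurationStateSet",
    "TruncationError",
    "excitation_matrix",
    "cartesian_pulse_rotation",
    "rf_rotation",
    "relax",
    "gradient_shift",
    "diffusion_damping",
    "precess",
]


class TruncationError(RuntimeError):
    """Raised when amplitude lost past ``k_max`` exceeds the allowed budget."""


@dataclass(frozen=True)
class TissueComponent:
    """One magnetization pool.

    Parameters
    ----------
    t1_ms, t2_ms:
        Longitudinal / transverse relaxation times in ms.
    adc_um2_s:
        Apparent diffusion coefficient in μm²/s.
    delta_nu_hz:
        Resonance offset in Hz (0 for the on-resonant water pool).
    """

    t1_ms: float
    t2_ms: float
    adc_um2_s: float = 0.0
    delta_nu_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.adc_um2_s < 0:
            raise ValueError("ADC must be non-negative")
        if self.t2_ms > self.t1_ms:
            warnings.warn("T2 exceeds T1; permitted but physically unusual",
                          stacklevel=2)


@dataclass
class ConfigurationStateSet:
    """EPG configuration amplitudes over orders ``k = 0..len-1``.

    ``f_plus[k] = F(k)``, ``f_minus[k] = conj(F(-k))`` (so
    ``f_minus[0] == conj(f_plus[0])`` always), ``z[k]`` longitudinal.
    ``k_unit_rad`` is the dephasing per order across the voxel, fixed
    at 2π.  ``truncation_loss`` accumulates squared magnitude shifted
    past ``k_max``.
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    z: np.ndarray
    m0: float = 1.0
    k_max: int = 4096
    truncation_loss: float = 0.0
    k_unit_rad: float = field(default=2.0 * np.pi, repr=False)

    @classmethod
    def equilibrium(cls, m0: float = 1.0, k_max: int = 4096) -> "ConfigurationStateSet":
        """Thermal equilibrium: ``Z(0) = m0``, everything else zero."""
        return cls(
            f_plus=np.zeros(1, dtype=complex),
            f_minus=np.zeros(1, dtype=complex),
            z=np.array([m0], dtype=complex),
            m0=m0,
            k_max=k_max,
        )

    @property
    def n_orders(self) -> int:
        return len(self.f_plus)

    def copy(self) -> "ConfigurationStateSet":
        return replace(
            self,
            f_plus=self.f_plus.copy(),
            f_minus=self.f_minus.copy(),
            z=self.z.copy(),
        )

    def transverse_energy(self) -> float:
        """Σ |F+|² + |F-|² over stored orders (k = 0 counted twice)."""
        return float(np.sum(np.abs(self.f_plus) ** 2)
                     + np.sum(np.abs(self.f_minus) ** 2))

    def zero_transverse(self) -> None:
        """Destroy all transverse coherence in place (ideal spoiler)."""
        self.f_plus[:] = 0.0
        self.f_minus[:] = 0.0

    def prune(self, tol: float = 1e-14) -> None:
        """Drop trailing orders whose amplitudes are all below ``tol * m0``."""
        thresh = tol * self.m0
        n = self.n_orders
        while n > 1 and (
            abs(self.f_plus[n - 1]) < thresh
            and abs(self.f_minus[n - 1]) < thresh
            and abs(self.z[n - 1]) < thresh
        ):
            n -= 1
        if n < self.n_orders:
            self.f_plus = self.f_plus[:n]
            self.f_minus = self.f_minus[:n]
            self.z = self.z[:n]


# --------------------------------------------------------------------------
# RF rotation

_S = np.array([[1.0, 1j, 0.0], [1.0, -1j, 0.0], [0.0, 0.0, 1.0]], dtype=complex)
_S_INV = np.array([[0.5, 0.5, 0.0], [-0.5j, 0.5j, 0.0], [0.0, 0.0, 1.0]], dtype=complex)


def cartesian_pulse_rotation(flip_angle_deg: float, rf_phase_deg: float,
                             pulse_ms: float, delta_nu_hz: float) -> np.ndarray:
    """Real 3x3 rotation of (Mx, My, Mz) produced by a rectangular hard pulse.

    ``flip_angle_deg`` is the on-resonance nominal flip angle; off
    resonance the pulse rotates about an effective axis tilted out of
    the transverse plane by arctan(Δω/ω1), through the larger angle
    sqrt(ω1² + Δω²)·τ.  Free-precession sign convention: positive
    Δν makes M+ evolve as exp(-i·2π·Δν·t).
    """
    alpha = np.deg2rad(flip_angle_deg)
    phase = np.deg2rad(rf_phase_deg)
    if delta_nu_hz == 0.0:
        # closed form: rotation about the x-axis taking +z toward -y
        ca, sa = np.cos(alpha), np.sin(alpha)
        r0 = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    else:
        if pulse_ms <= 0:
            raise ValueError(
                "off-resonant excitation requires a positive pulse duration")
        tau = pulse_ms * 1e-3
        w1 = alpha / tau
        dw = 2.0 * np.pi * delta_nu_hz
        # generator of dMx/dt = Δω My ; dMy/dt = -Δω Mx - ω1 Mz ; dMz/dt = ω1 My
        a_gen = np.array([[0.0, dw, 0.0], [-dw, 0.0, -w1], [0.0, w1, 0.0]])
        r0 = expm(a_gen * tau)
    cp, sp = np.cos(phase), np.sin(phase)
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz @ r0 @ rz.T


def excitation_matrix(flip_angle_deg: float, rf_phase_deg: float,
                      pulse_ms: float = 0.5,
                      delta_nu_hz: float = 0.0) -> np.ndarray:
    """Complex 3x3 matrix acting on (F+, F-, Z) at every order."""
    r = cartesian_pulse_rotation(flip_angle_deg, rf_phase_deg, pulse_ms,
                                 delta_nu_hz)
    return _S @ r @ _S_INV


def rf_rotation(state: ConfigurationStateSet, flip_angle_deg: float,
                rf_phase_deg: float, pulse_ms: float = 0.5,
                delta_nu_hz: float = 0.0) -> ConfigurationStateSet:
    """Apply an RF pulse: the same 3x3 mixing at every order ``k``.

    Relaxation and diffusion are suspended during the pulse
    (instantaneous-rotation approximation; only the off-resonant axis
    tilt of the 0.5 ms hard pulse is retained).
    """
    t = excitation_matrix(flip_angle_deg, rf_phase_deg, pulse_ms, delta_nu_hz)
    out = state.copy()
    stacked = np.vstack([state.f_plus, state.f_minus, state.z])
    mixed = t @ stacked
    out.f_plus, out.f_minus, out.z = mixed[0], mixed[1], mixed[2]
    return out


# --------------------------------------------------------------------------
# Relaxation, shift, diffusion, precession

def relax(state: ConfigurationStateSet, duration_ms: float, t1_ms: float,
          t2_ms: float) -> ConfigurationStateSet:
    """T2 decay of transverse orders, T1 decay/recovery of longitudinal."""
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    out = state.copy()
    e1 = np.exp(-duration_ms / t1_ms)
    e2 = np.exp(-duration_ms / t2_ms)
    out.f_plus *= e2
    out.f_minus *= e2
    out.z *= e1
    out.z[0] += state.m0 * (1.0 - e1)
    return out


def gradient_shift(state: ConfigurationStateSet, delta_k: int) -> ConfigurationStateSet:
    """Shift transverse orders by ``delta_k`` (integer 2π dephasings).

    F(k) -> F(k + delta_k) for every signed order, with the conjugate
    hand-off through k = 0; Z is unaffected.  Amplitude shifted past
    ``k_max`` is removed and accounted in ``truncation_loss``.
    """
    delta_k = int(delta_k)
    if delta_k == 0:
        return state.copy()
    out = state.copy()
    n = state.n_orders
    # full signed-order array F(-n+1 .. n-1), index i <-> order i - (n-1)
    full = np.empty(2 * n - 1, dtype=complex)
    full[n - 1:] = state.f_plus
    full[: n] = np.conj(state.f_minus[::-1])
    new_n = min(n + abs(delta_k), state.k_max + 1)
    shifted = np.zeros(2 * new_n - 1, dtype=complex)
    c_old, c_new = n - 1, new_n - 1  # indices of order 0
    # index i in `full` (order i - c_old) lands at j = i + off in `shifted`
    off = delta_k + c_new - c_old
    lo = max(0, -off)
    hi = min(2 * n - 1, 2 * new_n - 1 - off)
    lost = 0.0
    if lo > 0:
        lost += float(np.sum(np.abs(full[:lo]) ** 2))
    if hi < 2 * n - 1:
        lost += float(np.sum(np.abs(full[hi:]) ** 2))
    if lo < hi:
        shifted[lo + off: hi + off] = full[lo:hi]
    out.f_plus = shifted[c_new:].copy()
    out.f_minus = np.conj(shifted[: c_new + 1][::-1]).copy()
    nz = np.zeros(new_n, dtype=complex)
    nz[: n] = state.z
    out.z = nz
    out.truncation_loss = state.truncation_loss + lost
    return out


def diffusion_damping(state: ConfigurationStateSet, delta_k: int,
                      interval_ms: float, adc_um2_s: float,
                      voxel_mm: float) -> ConfigurationStateSet:
    """Attenuate configuration states by isotropic diffusion.

    For a constant gradient producing an order change ``delta_k`` over
    the interval, a transverse state starting at signed order ``k`` is
    attenuated by ``exp(-ADC * κ² * (k² + k·Δk + Δk²/3) * τ)`` with
    ``κ = 2π / voxel`` -- the b-factor of a linear phase ramp -- and a
    longitudinal state by ``exp(-ADC * κ² * k² * τ)``.  Stored
    ``f_minus[k]`` represents order ``-k`` and so gets the ``-k·Δk``
    cross term.
    """
    if interval_ms < 0:
        raise ValueError("interval must be non-negative")
    if adc_um2_s < 0:
        raise ValueError("ADC must be non-negative")
    if adc_um2_s == 0 or interval_ms == 0:
        return state.copy()
    out = state.copy()
    d = adc_um2_s * 1e-12           # m²/s
    kappa = 2.0 * np.pi / (voxel_mm * 1e-3)   # rad/m per order
    tau = interval_ms * 1e-3
    k = np.arange(state.n_orders, dtype=float)
    scale = d * kappa ** 2 * tau
    b_cross = delta_k ** 2 / 3.0
    out.f_plus *= np.exp(-scale * (k * k + k * delta_k + b_cross))
    out.f_minus *= np.exp(-scale * (k * k - k * delta_k + b_cross))
    out.z *= np.exp(-scale * k * k)
    return out


def precess(state: ConfigurationStateSet, delta_nu_hz: float,
            duration_ms: float) -> ConfigurationStateSet:
    """Free precession: every F(k) gains exp(-i·2π·Δν·t); Z unchanged."""
    out = state.copy()
    if delta_nu_hz == 0.0 or duration_ms == 0.0:
        return out
    ph = np.exp(-2j * np.pi * delta_nu_hz * duration_ms * 1e-3)
    out.f_plus *= ph
    out.f_minus *= np.conj(ph)
    return out
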