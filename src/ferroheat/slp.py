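"""Specific-loss-power kernel: Langevin statics, Debye dynamics, Néel relaxation.

The heating mechanism modelled here is Néel relaxation of monodisperse,
spherical, non-interacting superparamagnetic nanoparticles held fixed in
tissue and driven by a harmonic field H·cos(2πf t). In linear-response
(Debye) form the volumetric loss converts to a specific loss power

    P_s = π μ0 χ″ f H² / ρ        (W/kg)

with the out-of-phase susceptibility χ″ = χ0·ωτ/(1+(ωτ)²), the static
susceptibility χ0 = 3 χ_i L(ξ)/ξ corrected for field saturation through the
Langevin function L(ξ) = coth ξ − 1/ξ, the initial susceptibility
χ_i = ε π μ0 Ms² D³ / (18 kB T), and the Néel time τ = τ0 exp(πKD³/(6 kB T)).

All functions are numpy-transparent: scalars in → floats out, arrays in →
arrays out. Values are strict SI; the paper-style "W/g" scale (= W/kg / 1000)
is exposed as :attr:`SLPResult.Ps_W_per_g`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_ENV, Environment
from . import materials as _materials

__all__ = [
    "ParticleSpec",
    "FieldSpec",
    "SLPResult",
    "langevin",
    "magnetization",
    "neel_relaxation_time",
    "xi_argument",
    "initial_susceptibility",
    "static_susceptibility",
    "debye_components",
    "specific_loss_power",
]

# Below this |ξ| the closed form coth ξ − 1/ξ loses digits to cancellation;
# the odd series ξ/3 − ξ³/45 is exact to ~1e-17 there.
_LANGEVIN_SERIES_SWITCH = 1e-4

# exp overflows just above 709; refuse rather than return inf.
_EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class ParticleSpec:
    """Monodisperse spherical nanoparticle ensemble.

    D : diameter, m (study range 1–20 nm)
    epsilon : packing volumetric fraction (default 0.1)
    tau0 : Néel attempt time, s (default 1e-9 s)
    """

    D: float
    epsilon: float = 0.1
    tau0: float = 1e-9

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.D) > 0):
            raise ValueError(f"diameter must be positive, got D={self.D}")
        if not (0 < self.epsilon <= 1):
            raise ValueError(f"packing fraction must be in (0, 1], got {self.epsilon}")
        if not (self.tau0 > 0):
            raise ValueError(f"attempt time must be positive, got {self.tau0}")


@dataclass(frozen=True)
class FieldSpec:
    """Harmonic applied field: amplitude H (A/m) and frequency f (Hz)."""

    H: float
    f: float

    def __post_init__(self) -> None:
        if self.H < 0 or self.f < 0:
            raise ValueError(f"field amplitude and frequency must be >= 0, got {self}")


@dataclass(frozen=True)
class SLPResult:
    """Full evaluation record of one specific-loss-power computation."""

    xi: float | np.ndarray
    langevin: float | np.ndarray
    chi_i: float | np.ndarray
    chi0: float | np.ndarray
    tau: float | np.ndarray
    omega_tau: float | np.ndarray
    chi_real: float | np.ndarray
    chi_imag: float | np.ndarray
    Ps: float | np.ndarray  # SI, W/kg
    x: float = field(default=np.nan)
    D: float | np.ndarray = field(default=np.nan)
    H: float = field(default=np.nan)
    f: float = field(default=np.nan)

    @property
    def Ps_W_per_g(self):
        """Loss power on the per-gram scale conventionally printed in the field."""
        return self.Ps / 1e3


def langevin(xi):
    """Langevin function L(ξ) = coth ξ − 1/ξ (odd; series branch near 0)."""
    arr = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("langevin: argument must be finite")
    small = np.abs(arr) <= _LANGEVIN_SERIES_SWITCH
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        closed = 1.0 / np.tanh(arr) - 1.0 / arr
    series = arr / 3.0 - arr**3 / 45.0
    out = np.where(small, series, closed)
    return float(out) if arr.ndim == 0 else out


def magnetization(Msat, xi):
    """Equilibrium ensemble magnetization M = Msat·L(ξ), A/m."""
    if np.any(np.asarray(Msat) < 0):
        raise ValueError(f"saturation magnetization must be >= 0, got {Msat}")
    return Msat * langevin(xi)


def neel_relaxation_time(K, D, env: Environment = DEFAULT_ENV, tau0: float = 1e-9):
    """Néel relaxation time τ = τ0·exp(πKD³/(6 kB T)), s.

    The exponent is the anisotropy-barrier-to-thermal-energy ratio for the
    barrier convention πKD³/6 (sphere volume times K).
    """
    K = np.asarray(K, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(K < 0):
        raise ValueError("anisotropy constant must be >= 0")
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    exponent = np.pi * K * D**3 / (6.0 * env.kB * env.T)
    if np.any(exponent > _EXP_OVERFLOW):
        raise OverflowError(
            f"Néel exponent πKD³/(6kBT) = {float(np.max(exponent)):.1f} exceeds "
            f"{_EXP_OVERFLOW:.0f}; exp would overflow"
        )
    out = tau0 * np.exp(exponent)
    return float(out) if out.ndim == 0 else out


def xi_argument(Ms, D, H, env: Environment = DEFAULT_ENV):
    """Langevin argument ξ = π μ0 Ms D³ H / (6 kB T): Zeeman vs thermal energy."""
    Ms = np.asarray(Ms, dtype=float)
    D = np.asarray(D, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(Ms < 0) or np.any(H < 0):
        raise ValueError("Ms and H must be >= 0")
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi * env.mu0 * Ms * D**3 * H / (6.0 * env.kB * env.T)
    return float(out) if out.ndim == 0 else out


def initial_susceptibility(Ms, D, epsilon, env: Environment = DEFAULT_ENV):
    """Initial (zero-field) susceptibility χ_i = ε π μ0 Ms² D³ / (18 kB T)."""
    Ms = np.asarray(Ms, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(Ms < 0) or np.any(np.asarray(epsilon) < 0):
        raise ValueError("Ms and epsilon must be >= 0")
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    out = epsilon * np.pi * env.mu0 * Ms**2 * D**3 / (18.0 * env.kB * env.T)
    return float(out) if out.ndim == 0 else out


def static_susceptibility(chi_i, xi):
    """Field-dependent static susceptibility χ0 = 3 χ_i L(ξ)/ξ.

    3 L(ξ)/ξ → 1 as ξ → 0, so χ0 → χ_i in the linear-response limit; at
    finite ξ the factor is < 1 (saturation suppresses the response).
    """
    chi_i = np.asarray(chi_i, dtype=float)
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(chi_i < 0) or np.any(xi_arr < 0):
        raise ValueError("chi_i and xi must be >= 0")
    small = xi_arr <= _LANGEVIN_SERIES_SWITCH
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_closed = 3.0 * langevin(np.where(small, 1.0, xi_arr)) / np.where(small, 1.0, xi_arr)
    ratio_series = 1.0 - xi_arr**2 / 15.0  # 3 L(ξ)/ξ = 1 − ξ²/15 + O(ξ⁴)
    out = chi_i * np.where(small, ratio_series, ratio_closed)
    return float(out) if out.ndim == 0 else out


def debye_components(chi0, f, tau):
    """In-phase and out-of-phase susceptibilities of first-order relaxation.

    With u = ωτ = 2πfτ: χ′ = χ0/(1+u²), χ″ = χ0·u/(1+u²). χ″ is computed as
    χ0/(u + 1/u), which cannot overflow for huge u and peaks at χ0/2 at u = 1.
    """
    chi0 = np.asarray(chi0, dtype=float)
    f = np.asarray(f, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(chi0 < 0) or np.any(f < 0):
        raise ValueError("chi0 and f must be >= 0")
    if np.any(tau <= 0):
        raise ValueError("relaxation time must be positive")
    u = 2.0 * np.pi * f * tau
    safe_u = np.where(u > 0, u, 1.0)
    with np.errstate(over="ignore"):
        usq = u * u
        chi_real = np.where(np.isinf(usq), 0.0, chi0 / (1.0 + usq))
    chi_imag = np.where(u > 0, chi0 / (safe_u + 1.0 / safe_u), 0.0)
    if chi_real.ndim == 0:
        return float(chi_real), float(chi_imag)
    return chi_real, chi_imag


def specific_loss_power(
    x: float,
    particle: ParticleSpec,
    fieldspec: FieldSpec,
    env: Environment = DEFAULT_ENV,
    model: "_materials.MaterialModel | None" = None,
) -> SLPResult:
    """Specific loss power of the ferrite ensemble at composition ``x``.

    Composes the saturation-corrected Debye loss: P_s = π μ0 χ″ f H² / ρ
    (SI, W/kg), with ρ(x), Ms(x), K(x) from the material model. ``particle.D``
    may be an array, in which case every field of the result is an array over
    that diameter grid.
    """
    m = model if model is not None else _materials._default_model()
    K = m.anisotropy_constant(x)
    Ms = m.spontaneous_magnetization(x)
    rho = m.density(x)

    D, H, f = particle.D, fieldspec.H, fieldspec.f
    xi = xi_argument(Ms, D, H, env)
    chi_i = initial_susceptibility(Ms, D, particle.epsilon, env)
    chi0 = static_susceptibility(chi_i, xi)
    tau = neel_relaxation_time(K, D, env, particle.tau0)
    chi_real, chi_imag = debye_components(chi0, f, tau)
    Ps = np.pi * env.mu0 * chi_imag * f * H**2 / rho
    L = langevin(xi)
    omega_tau = 2.0 * np.pi * f * np.asarray(tau)
    scalar = np.asarray(Ps).ndim == 0
    return SLPResult(
        xi=xi,
        langevin=L,
        chi_i=chi_i,
        chi0=chi0,
        tau=tau,
        omega_tau=float(omega_tau) if scalar else omega_tau,
        chi_real=chi_real,
        chi_imag=chi_imag,
        Ps=float(Ps) if scalar else Ps,
        x=x,
        D=D,
        H=H,
        f=f,
    )
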