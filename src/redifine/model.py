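"""Forward model for diffusion decay of a biphasic (phase-separated) sample.

The sample is modelled as spherical condensed droplets of radius ``R_drop``
holding a fraction ``nu_cond`` of the observed molecules, in equilibrium with
a dilute phase holding the remainder.  Molecules diffuse freely in the dilute
phase (``D_dil``), diffuse restrictedly inside the droplets (``D_cond``
confined on the length scale ``R_drop``) and cross the interface with
permeability ``p`` (m/s), giving a condensed-to-dilute exchange rate
``k_cd = 3 p / R_drop`` through the surface-to-volume ratio of a sphere.

The pulsed-gradient signal of the two exchanging pools obeys a pair of
coupled linear (McConnell-type) magnetization equations

    d/dt [M_cond, M_dil] = A [M_cond, M_dil]
    A = [[-q^2 D_app - k_cd,  k_dc],
         [ k_cd,             -q^2 D_dil - k_dc]]

with ``k_dc = nu_cond k_cd / (1 - nu_cond)`` fixed by detailed balance and
initial condition ``(nu_cond, 1 - nu_cond)``.  The total observed signal is
``S(q, Delta) = M_cond(Delta) + M_dil(Delta)``, evaluated here through the
closed-form eigen-solution of the 2x2 system.  ``D_app`` is the apparent
intradroplet diffusion coefficient implied by the narrow-pulse restricted
attenuation series (parallel reflecting boundaries separated by ``R``),
evaluated per (q, Delta) point and held constant over [0, Delta].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, compute_q

__all__ = [
    "CondensateParams",
    "DerivedRates",
    "SignalSurface",
    "free_decay",
    "restricted_attenuation",
    "apparent_diffusion",
    "rates_from_params",
    "two_pool_propagate",
    "redifine_signal",
    "phase_concentrations",
]

#: Floor applied to attenuation values before taking a logarithm.
ATTENUATION_FLOOR = 1e-300

#: exp(-745) underflows to subnormal; series terms beyond this are dropped.
_EXP_CUTOFF = 745.0


@dataclass(frozen=True)
class CondensateParams:
    """The five physical parameters of the biphasic model (SI units).

    Attributes
    ----------
    D_dil : float
        Free diffusion coefficient in the dilute phase, m^2/s.
    D_cond : float
        Intrinsic diffusion coefficient inside the droplets, m^2/s.
    nu_cond : float
        Fraction of the observed species in the condensed phase, in [0, 1].
        The dilute fraction is always ``1 - nu_cond``.
    R_drop : float
        Average droplet radius, m.
    p : float
        Interface permeability, m/s (>= 0; 0 means impermeable droplets).
    """

    D_dil: float
    D_cond: float
    nu_cond: float
    R_drop: float
    p: float

    def __post_init__(self) -> None:
        if self.D_dil <= 0 or self.D_cond <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.R_drop <= 0:
            raise ValueError("R_drop must be positive")
        if self.p < 0:
            raise ValueError("permeability p must be non-negative")
        if not 0.0 <= self.nu_cond <= 1.0:
            raise ValueError("nu_cond must lie in [0, 1]")

    @property
    def nu_dil(self) -> float:
        return 1.0 - self.nu_cond


@dataclass(frozen=True)
class DerivedRates:
    """Exchange quantities derived from :class:`CondensateParams`.

    ``k_cd`` is the condensed-to-dilute rate ``3 p / R_drop``; ``k_dc`` the
    reverse rate from detailed balance; ``k_ex = nu_cond * k_cd`` the
    population-weighted global exchange rate (comparable to FRAP recovery
    rates); ``t_half = ln 2 / k_ex`` (infinite for a non-exchanging system).
    """

    k_cd: float
    k_dc: float
    k_ex: float
    t_half: float


@dataclass(frozen=True)
class SignalSurface:
    """Normalized signal on the (diffusion time, gradient) grid of a scheme.

    ``values[i, j]`` is S at ``diffusion_times[i]``, ``gradient_fractions[j]``.
    """

    values: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        expected = (
            len(self.scheme.diffusion_times),
            len(self.scheme.gradient_fractions),
        )
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match scheme grid {expected}"
            )


def free_decay(D: float, b) -> np.ndarray | float:
    """Mono-exponential decay ``exp(-b D)`` of a freely diffusing species."""
    if D <= 0:
        raise ValueError("D must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = np.exp(-b * D)
    return float(out) if out.ndim == 0 else out


def _mode_count(tau_min: float, n_max: int) -> int:
    """Number of eigenmode terms to retain: terms whose exponent would
    underflow (n^2 pi^2 tau > ~745) are dropped."""
    if tau_min <= 0:
        raise ValueError("D * Delta / R^2 must be positive")
    n_eff = int(min(n_max, math.floor(math.sqrt(_EXP_CUTOFF / (math.pi**2 * tau_min))) + 1))
    return max(n_eff, 1)


def _attenuation_points(
    q: np.ndarray, t: np.ndarray, R: float, D_cond: float, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Series attenuation E and its small-q limit of -ln(E)/b, per point.

    ``q`` and ``t`` are equal-length arrays of wavevector / diffusion-time
    pairs.  Returns ``(E, D_app_limit)`` where the limit column is the
    analytic q -> 0 value of the apparent diffusion coefficient (mean
    squared displacement over 2 t).  Vectorized over points and modes.
    """
    x = q * R
    x2 = x * x
    tau = D_cond * t / (R * R)
    n_eff = _mode_count(float(np.min(tau)), n_max)
    n = np.arange(1.0, n_eff + 1.0)
    a2 = (n * math.pi) ** 2
    parity = np.where(n.astype(int) % 2 == 0, 1.0, -1.0)

    cosx = np.cos(x)
    small = np.abs(x) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        lead = 2.0 * (1.0 - cosx) / x2
    lead = np.where(small, 1.0 - x2 / 12.0, lead)

    with np.errstate(under="ignore"):
        w = np.exp(-a2[None, :] * tau[:, None])  # (n_points, n_modes)
    num = 1.0 - parity[None, :] * cosx[:, None]
    den = x2[:, None] - a2[None, :]
    singular = np.abs(den) < 1e-9 * a2[None, :]
    den_safe = np.where(singular, 1.0, den)
    terms = 4.0 * x2[:, None] * w * num / (den_safe * den_safe)
    terms = np.where(singular, w / 2.0, terms)
    E = lead + terms.sum(axis=1)

    if np.any(E <= 0):
        warnings.warn(
            "restricted attenuation series produced non-positive values "
            "(truncation near a diffraction null); clamping to the positive floor",
            RuntimeWarning,
            stacklevel=3,
        )
    E = np.clip(E, ATTENUATION_FLOOR, 1.0)
    E = np.where(x == 0.0, 1.0, E)

    odd = n.astype(int) % 2 == 1
    s_odd = (w[:, odd] / a2[odd][None, :] ** 2).sum(axis=1)
    limit = np.maximum((R * R / t) * (1.0 / 12.0 - 8.0 * s_odd), 0.0)
    return E, limit


def restricted_attenuation(q, R: float, D_cond: float, Delta: float, n_max: int = 2000):
    """Narrow-pulse attenuation E(q, Delta) for diffusion restricted on scale R.

    Evaluates the reflecting-boundary eigenmode series

        E = 2 (1 - cos(qR)) / (qR)^2
            + 4 (qR)^2 sum_n exp(-n^2 pi^2 D_cond Delta / R^2)
                        (1 - (-1)^n cos(qR)) / ((qR)^2 - (n pi)^2)^2

    truncated at ``n_max`` terms (terms whose exponent underflows are
    dropped).  Terms whose denominator vanishes at the diffraction condition
    ``qR = n pi`` are replaced by their analytic removable-singularity limit
    ``exp(-n^2 pi^2 D_cond Delta / R^2) / 2``.  The result is clamped into
    ``[ATTENUATION_FLOOR, 1]``; ``q = 0`` returns exactly 1.

    Accepts scalar or array ``q``; returns the matching shape.
    """
    if R <= 0 or D_cond <= 0 or Delta <= 0:
        raise ValueError("R, D_cond and Delta must be positive")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr < 0):
        raise ValueError("q must be non-negative")
    E, _ = _attenuation_points(q_arr, np.full_like(q_arr, Delta), R, D_cond, n_max)
    return float(E[0]) if np.isscalar(q) or np.asarray(q).ndim == 0 else E


def apparent_diffusion(q, R: float, D_cond: float, Delta: float, b=None, n_max: int = 2000):
    """Apparent intradroplet diffusion coefficient ``-ln E(q, Delta) / b``.

    ``b`` defaults to ``q^2 Delta``.  At ``q = 0`` (b = 0) the analytic
    small-q series limit (mean squared displacement over ``2 Delta``) is
    returned instead of 0/0.  When E has been clamped at the floor the
    result is a finite ceiling ``-ln(floor)/b``.
    """
    if R <= 0 or D_cond <= 0 or Delta <= 0:
        raise ValueError("R, D_cond and Delta must be positive")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr < 0):
        raise ValueError("q must be non-negative")
    if b is None:
        b_arr = q_arr * q_arr * Delta
    else:
        b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    E, limit = _attenuation_points(q_arr, np.full_like(q_arr, Delta), R, D_cond, n_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        D_app = -np.log(E) / b_arr
    D_app = np.where(b_arr == 0.0, limit, D_app)
    D_app = np.maximum(D_app, 0.0)
    return float(D_app[0]) if np.isscalar(q) or np.asarray(q).ndim == 0 else D_app


def rates_from_params(params: CondensateParams) -> DerivedRates:
    """Exchange rates implied by droplet geometry and interface permeability.

    ``k_cd = 3 p / R_drop`` (sphere surface-to-volume ratio times
    permeability); ``k_dc`` follows from detailed balance
    ``nu_cond k_cd = (1 - nu_cond) k_dc``.  Raises if ``nu_cond == 1``
    (no dilute pool, k_dc undefined).
    """
    if params.nu_cond >= 1.0:
        raise ValueError("nu_cond = 1: no dilute pool; k_dc undefined")
    k_cd = 3.0 * params.p / params.R_drop
    k_dc = params.nu_cond * k_cd / (1.0 - params.nu_cond)
    k_ex = params.nu_cond * k_cd
    t_half = math.log(2.0) / k_ex if k_ex > 0 else math.inf
    return DerivedRates(k_cd=k_cd, k_dc=k_dc, k_ex=k_ex, t_half=t_half)


def _propagate(a11, a12, a21, a22, t, v0, v1):
    """Closed-form ``exp(A t) @ (v0, v1)`` for a 2x2 matrix, vectorized.

    Uses the eigen-decomposition identity
    ``exp(A t) = e^{l2 t} I + phi (A - l2 I)`` with
    ``phi = (e^{l1 t} - e^{l2 t}) / (l1 - l2)``; the confluent
    (degenerate-eigenvalue) limit ``phi = t e^{l t}`` is reached smoothly via
    ``expm1``, never by naive division.
    """
    a11, a12, a21, a22 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (a11, a12, a21, a22))
    )
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc2 = tr * tr - 4.0 * det  # = (a11-a22)^2 + 4 a12 a21 >= 0 here
    disc = np.sqrt(np.maximum(disc2, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    e1 = np.exp(l1 * t)
    e2 = np.exp(l2 * t)
    z = disc * t
    # phi = (e^{l1 t} - e^{l2 t})/(l1 - l2): direct difference once z is large
    # enough that cancellation is negligible, third-order Taylor of
    # e2 (e^z - 1)/disc below that (covers the confluent z -> 0 limit)
    small = z < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_large = (e1 - e2) / np.where(disc == 0.0, 1.0, disc)
    phi_small = e2 * t * (1.0 + z / 2.0 + z * z / 6.0)
    phi = np.where(small, phi_small, phi_large)
    Av0 = a11 * v0 + a12 * v1
    Av1 = a21 * v0 + a22 * v1
    m0 = e2 * v0 + phi * (Av0 - l2 * v0)
    m1 = e2 * v1 + phi * (Av1 - l2 * v1)
    return m0, m1


def _signal_points_condensate(
    params: CondensateParams, q: np.ndarray, t: np.ndarray, n_max: int = 2000
) -> np.ndarray:
    """Total signal of the condensate model at arbitrary (q, t) point pairs.

    Single vectorized path shared by the grid evaluator and the fitter.
    """
    if params.nu_cond == 0.0:
        return np.exp(-q * q * t * params.D_dil)
    rates = rates_from_params(params)
    E, limit = _attenuation_points(q, t, params.R_drop, params.D_cond, n_max)
    q2 = q * q
    b = q2 * t
    with np.errstate(divide="ignore", invalid="ignore"):
        D_app = -np.log(E) / b
    D_app = np.maximum(np.where(b == 0.0, limit, D_app), 0.0)
    m0, m1 = _propagate(
        -q2 * D_app - rates.k_cd,
        np.full_like(q, rates.k_dc),
        np.full_like(q, rates.k_cd),
        -q2 * params.D_dil - rates.k_dc,
        t,
        params.nu_cond,
        params.nu_dil,
    )
    return m0 + m1


def two_pool_propagate(
    params: CondensateParams, q, Delta: float, n_max: int = 2000
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Magnetization of the condensed and dilute pools after time ``Delta``.

    Solves the exchange-coupled magnetization system at wavevector ``q`` with
    initial condition ``(nu_cond, 1 - nu_cond)``.  Returns ``(M_cond, M_dil)``
    matching the shape of ``q``.
    """
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    rates = rates_from_params(params)
    D_app = np.atleast_1d(
        apparent_diffusion(q_arr, params.R_drop, params.D_cond, Delta, n_max=n_max)
    )
    q2 = q_arr * q_arr
    m_cond, m_dil = _propagate(
        -q2 * D_app - rates.k_cd,
        np.full_like(q_arr, rates.k_dc),
        np.full_like(q_arr, rates.k_cd),
        -q2 * params.D_dil - rates.k_dc,
        Delta,
        params.nu_cond,
        params.nu_dil,
    )
    scalar = np.isscalar(q) or np.asarray(q).ndim == 0
    if scalar:
        return float(m_cond[0]), float(m_dil[0])
    return m_cond, m_dil


def redifine_signal(
    params: CondensateParams, scheme: AcquisitionScheme, n_max: int = 2000
) -> SignalSurface:
    """Total normalized signal ``S(q, Delta) = M_cond + M_dil`` on a scheme grid.

    The pure-dilute limit ``nu_cond = 0`` reduces to mono-exponential decay;
    ``p = 0`` reduces to the static two-population mixture.  ``S`` is exactly
    1 at zero gradient for every diffusion time (magnetization conservation).
    """
    q = scheme.q_values()
    n_g = len(q)
    t_all = np.repeat([scheme.effective_delta(d) for d in scheme.diffusion_times], n_g)
    q_all = np.tile(q, len(scheme.diffusion_times))
    values = _signal_points_condensate(params, q_all, t_all, n_max)
    return SignalSurface(values=values.reshape(-1, n_g), scheme=scheme)


def phase_concentrations(
    total_moles_solute: float,
    nu_cond_solute: float,
    total_solvent_volume: float,
    nu_cond_solvent: float,
) -> tuple[float, float, float]:
    """Solute concentration in each phase and their fold ratio.

    Distributes ``total_moles_solute`` between the phases according to the
    solute condensed fraction and divides by the phase volumes implied by the
    solvent condensed fraction (volume in litres).  Returns
    ``(C_cond, C_dil, fold_ratio)`` in mol/L, mol/L, dimensionless.
    """
    if total_moles_solute <= 0 or total_solvent_volume <= 0:
        raise ValueError("amounts and volumes must be positive")
    for name, frac in (("nu_cond_solute", nu_cond_solute), ("nu_cond_solvent", nu_cond_solvent)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1): one phase is empty")
    c_cond = total_moles_solute * nu_cond_solute / (total_solvent_volume * nu_cond_solvent)
    c_dil = (
        total_moles_solute
        * (1.0 - nu_cond_solute)
        / (total_solvent_volume * (1.0 - nu_cond_solvent))
    )
    return c_cond, c_dil, c_cond / c_dil
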