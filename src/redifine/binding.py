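"""Dispersed two-pool exchange model for soluble complexes.

A molecule that reversibly binds a partner in solution alternates between a
free state (fast diffusion ``D_free``) and a complexed state (slow diffusion
``D_complex``).  When the exchange happens on the diffusion-time scale
(roughly 10-1000 ms) the decay curves are exchange-averaged, and a global fit
of the same two-pool propagator used for condensates - with the restricted
term replaced by isotropic ``-q^2 D_complex`` - yields the complex
population ``nu_complex`` and dissociation rate ``k_off``.  Combined with
known total concentrations and stoichiometry these give the equilibrium
dissociation constant ``K_d`` and association rate ``k_on = k_off / K_d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme
from .model import SignalSurface, _propagate

__all__ = [
    "BindingParams",
    "MixtureTotals",
    "dispersed_signal",
    "equilibrium_concentrations",
    "dissociation_constant",
    "association_rate",
]


@dataclass(frozen=True)
class BindingParams:
    """The four parameters of the dispersed binding model (SI units).

    ``D_free`` and ``D_complex`` are the diffusion coefficients of the free
    species and of the complex (m^2/s); ``nu_complex`` the bound fraction of
    the observed species; ``k_off`` the complex dissociation rate (1/s).
    A complex diffusing faster than the free species is physically odd and
    triggers a warning, not an error.
    """

    D_free: float
    D_complex: float
    nu_complex: float
    k_off: float

    def __post_init__(self) -> None:
        if self.D_free <= 0 or self.D_complex <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if not 0.0 <= self.nu_complex <= 1.0:
            raise ValueError("nu_complex must lie in [0, 1]")
        if self.k_off < 0:
            raise ValueError("k_off must be non-negative")
        if self.D_complex > self.D_free:
            warnings.warn(
                "D_complex > D_free: the complex diffuses faster than the free "
                "species, which is unusual",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MixtureTotals:
    """Total concentrations of the two binding partners (mol/L) and their
    binding stoichiometry (species1 : species2, small positive integers,
    default 1:1)."""

    total_conc_species1: float
    total_conc_species2: float
    stoichiometry: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.total_conc_species1 <= 0 or self.total_conc_species2 <= 0:
            raise ValueError("total concentrations must be positive")
        s1, s2 = self.stoichiometry
        if s1 < 1 or s2 < 1 or s1 != int(s1) or s2 != int(s2):
            raise ValueError("stoichiometry must be positive integers")


def dispersed_signal(bp: BindingParams, scheme: AcquisitionScheme) -> SignalSurface:
    """Normalized decay surface of a free/complex exchanging mixture.

    Same 2x2 exchange propagator as the condensate model with both pools
    isotropic: complex pool decays at ``q^2 D_complex``, free pool at
    ``q^2 D_free``; exchange rates are ``k_off`` (complex -> free) and the
    pseudo-first-order ``nu_complex k_off / (1 - nu_complex)`` (free ->
    complex); initial condition ``(nu_complex, 1 - nu_complex)``.
    """
    q = scheme.q_values()
    n_g = len(q)
    t_all = np.repeat([scheme.effective_delta(d) for d in scheme.diffusion_times], n_g)
    q_all = np.tile(q, len(scheme.diffusion_times))
    values = _signal_points_binding(bp, q_all, t_all)
    return SignalSurface(values=values.reshape(-1, n_g), scheme=scheme)


def _signal_points_binding(bp: BindingParams, q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Total dispersed-mixture signal at arbitrary (q, t) point pairs."""
    if bp.nu_complex >= 1.0:
        raise ValueError("nu_complex = 1: no free pool")
    k_off = bp.k_off
    k_on_pseudo = bp.nu_complex * k_off / (1.0 - bp.nu_complex)
    q2 = q * q
    m_c, m_f = _propagate(
        -q2 * bp.D_complex - k_off,
        np.full_like(q, k_on_pseudo),
        np.full_like(q, k_off),
        -q2 * bp.D_free - k_on_pseudo,
        t,
        bp.nu_complex,
        1.0 - bp.nu_complex,
    )
    return m_c + m_f


def equilibrium_concentrations(
    totals: MixtureTotals, nu_complex: float, reference_species: int = 1
) -> tuple[float, float, float]:
    """Free and complex concentrations implied by a fitted bound fraction.

    ``nu_complex`` is the bound fraction of the stated reference species
    (default species 1, the observed one).  Returns
    ``(c1_free, c2_free, c_complex)`` in mol/L; raises if the implied free
    concentration of either species would be negative.
    """
    if not 0.0 <= nu_complex <= 1.0:
        raise ValueError("nu_complex must lie in [0, 1]")
    if reference_species not in (1, 2):
        raise ValueError("reference_species must be 1 or 2")
    s1, s2 = totals.stoichiometry
    c1, c2 = totals.total_conc_species1, totals.total_conc_species2
    if reference_species == 1:
        c_complex = nu_complex * c1 / s1
    else:
        c_complex = nu_complex * c2 / s2
    c1_free = c1 - s1 * c_complex
    c2_free = c2 - s2 * c_complex
    tol = 1e-12 * max(c1, c2)
    if c1_free < -tol or c2_free < -tol:
        raise ValueError(
            "nu_complex inconsistent with totals/stoichiometry: implied negative "
            "free concentration"
        )
    return max(c1_free, 0.0), max(c2_free, 0.0), c_complex


def dissociation_constant(c1_free: float, c2_free: float, c_complex: float) -> float:
    """Equilibrium dissociation constant ``K_d = c1_free c2_free / c_complex``
    (mol/L).  All three concentrations must be positive."""
    if c1_free <= 0 or c2_free <= 0:
        raise ValueError("free concentrations must be positive")
    if c_complex <= 0:
        raise ValueError("complex concentration must be positive")
    return c1_free * c2_free / c_complex


def association_rate(k_off: float, K_d: float) -> float:
    """Association rate constant ``k_on = k_off / K_d`` (1/(M s))."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return k_off / K_d
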