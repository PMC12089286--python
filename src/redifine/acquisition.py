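"""Pulsed-gradient acquisition parameters and diffusion-weighting variables.

A pulsed-gradient (stimulated) spin-echo experiment encodes translational
motion with a pair of gradient pulses of strength ``g`` and duration ``delta``
separated by the diffusion time ``Delta``.  The two derived quantities used
throughout the package are the gradient wavevector ``q = gamma * g * delta``
(rad/m) and the diffusion weighting ``b = q**2 * Delta`` (s/m^2).

The ``b`` convention here is the plain ``gamma^2 g^2 delta^2 * Delta`` product
with no ``Delta - delta/3`` finite-pulse correction; an optional
``effective_diffusion_time`` flag applies that correction for users fitting
real bipolar-gradient data (it changes nothing for self-consistent
simulation + fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "DEFAULT_MAX_GRADIENT",
    "AcquisitionScheme",
    "compute_q",
    "compute_b",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752218744e8

#: Typical maximum gradient output of a cryoprobe z-gradient, T/m (53.5 G/cm).
DEFAULT_MAX_GRADIENT = 0.535


@dataclass(frozen=True)
class AcquisitionScheme:
    """Instrument settings mapping gradient increments to q and b values.

    Parameters
    ----------
    gradient_fractions:
        Dimensionless gradient amplitudes in [0, 1], as fractions of
        ``max_gradient``.
    diffusion_times:
        Diffusion times Delta in seconds, all positive.
    gradient_duration:
        Gradient pulse length delta in seconds.
    max_gradient:
        Maximum gradient amplitude in T/m.
    gyromagnetic_ratio:
        In rad s^-1 T^-1; defaults to the proton value.
    effective_diffusion_time:
        If True, use ``Delta - delta/3`` in b-value computations.
    """

    gradient_fractions: tuple[float, ...]
    diffusion_times: tuple[float, ...]
    gradient_duration: float
    max_gradient: float = DEFAULT_MAX_GRADIENT
    gyromagnetic_ratio: float = GAMMA_PROTON
    effective_diffusion_time: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gradient_fractions", tuple(float(f) for f in self.gradient_fractions)
        )
        object.__setattr__(
            self, "diffusion_times", tuple(float(d) for d in self.diffusion_times)
        )
        if self.gyromagnetic_ratio <= 0:
            raise ValueError("gyromagnetic_ratio must be positive")
        if self.max_gradient <= 0:
            raise ValueError("max_gradient must be positive")
        if self.gradient_duration <= 0:
            raise ValueError("gradient_duration must be positive")
        if not self.gradient_fractions:
            raise ValueError("at least one gradient fraction is required")
        if not self.diffusion_times:
            raise ValueError("at least one diffusion time is required")
        for f in self.gradient_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"gradient fraction {f} outside [0, 1]")
        for d in self.diffusion_times:
            if d <= 0:
                raise ValueError(f"diffusion time {d} must be positive")

    # -- derived quantities -------------------------------------------------

    def effective_delta(self, Delta: float) -> float:
        """Diffusion time entering b, after the optional delta/3 correction."""
        if self.effective_diffusion_time:
            return Delta - self.gradient_duration / 3.0
        return Delta

    def q_values(self) -> np.ndarray:
        """q for every gradient fraction, rad/m."""
        return np.array([compute_q(self, f) for f in self.gradient_fractions])

    def with_diffusion_times(self, diffusion_times: Sequence[float]) -> "AcquisitionScheme":
        return replace(self, diffusion_times=tuple(float(d) for d in diffusion_times))


def compute_q(scheme: AcquisitionScheme, fraction: float) -> float:
    """Gradient wavevector ``q = gamma * (fraction * g_max) * delta`` in rad/m.

    Raises
    ------
    ValueError
        If ``fraction`` lies outside [0, 1].
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"gradient fraction {fraction} outside [0, 1]")
    return (
        scheme.gyromagnetic_ratio
        * fraction
        * scheme.max_gradient
        * scheme.gradient_duration
    )


def compute_b(scheme: AcquisitionScheme, fraction: float, Delta: float) -> float:
    """Diffusion weighting ``b = q^2 * Delta`` in s/m^2.

    ``Delta`` must be positive; the optional effective-diffusion-time
    correction of the scheme is applied.
    """
    if Delta <= 0:
        raise ValueError(f"diffusion time {Delta} must be positive")
    q = compute_q(scheme, fraction)
    return q * q * scheme.effective_delta(Delta)
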