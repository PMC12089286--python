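"""Synthetic decay-curve generation and brute-force validation oracles.

``default_scheme`` reproduces the acquisition geometry the method is
designed around: 16 gradient increments from 2 to 95% of the maximum
amplitude, gradient lengths matched to the analyte (10 ms protein, 3.5 ms
RNA, 2 ms water) and six diffusion times between 50 and 1000 ms (folded
domains are usually limited to ~700 ms by T1 decay; pass a custom Delta
list for those).

``walker_attenuation`` is an independent Monte-Carlo check of the
restricted-diffusion series: 1-D Brownian walkers between reflecting
boundaries with narrow-pulse phase encoding.  Each Gaussian step folded by
mirror reflection samples the reflected-Brownian transition density exactly,
so the only error is statistical.  ``matrix_exponential_oracle`` wraps the
scaling-and-squaring matrix exponential as an independent check of the
closed-form exchange propagator; both oracles exist for the test suite and
are never used in fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .acquisition import AcquisitionScheme
from .binding import BindingParams, dispersed_signal
from .model import CondensateParams, redifine_signal
from .fitting import DecayDataset

__all__ = [
    "NoiseSpec",
    "WalkerConfig",
    "default_scheme",
    "generate_dataset",
    "walker_attenuation",
    "matrix_exponential_oracle",
]

#: gradient duration per analyte class, seconds
_DELTA_SMALL = {"protein": 10e-3, "rna": 3.5e-3, "water": 2e-3}

#: default diffusion-time ladder, seconds (6 curves spanning 50-1000 ms)
_DELTA_LADDER = (0.05, 0.1, 0.2, 0.35, 0.6, 1.0)

#: intensity floor/cap applied after adding noise, matching the dataset contract
_NOISE_FLOOR = 1e-6
_NOISE_CAP = 1.5


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise on normalized intensities.

    With ``renormalize=True`` (default) each noisy curve is divided by its
    smallest-gradient point afterwards, mimicking how experimental curves
    are normalized; set it to False for pure additive noise (the
    homoscedastic model the fitter's uncertainty estimate assumes).
    ``model="none"`` or ``sigma=0`` disables noise entirely.
    """

    model: str = "gaussian"
    sigma: float = 0.0
    seed: int = 0
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "none"):
            raise ValueError("noise model must be 'gaussian' or 'none'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class WalkerConfig:
    """Configuration of the reflecting-boundary random-walk oracle.

    The walk is 1-D between boundaries ``boundary_separation`` apart, with
    ``n_steps`` Gaussian steps covering the diffusion time ``Delta``.  The
    RMS step must not exceed ``boundary_separation / 50`` and at least 10^4
    walkers are required for oracle use.
    """

    n_walkers: int
    n_steps: int
    boundary_separation: float
    D: float
    Delta: float
    q_values: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers < 10_000:
            raise ValueError("oracle use requires n_walkers >= 10^4")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.boundary_separation <= 0 or self.D <= 0 or self.Delta <= 0:
            raise ValueError("boundary_separation, D and Delta must be positive")
        object.__setattr__(self, "q_values", tuple(float(q) for q in self.q_values))

    @property
    def rms_step(self) -> float:
        return math.sqrt(2.0 * self.D * self.Delta / self.n_steps)


def default_scheme(kind: str = "protein") -> AcquisitionScheme:
    """Acquisition defaults for a given analyte class.

    16 linearly spaced gradient fractions from 0.02 to 0.95 of a 0.535 T/m
    maximum gradient; delta = 10 ms (protein), 3.5 ms (rna) or 2 ms (water);
    diffusion times 50, 100, 200, 350, 600, 1000 ms.
    """
    if kind not in _DELTA_SMALL:
        raise ValueError(f"kind must be one of {sorted(_DELTA_SMALL)}, got {kind!r}")
    return AcquisitionScheme(
        gradient_fractions=tuple(np.linspace(0.02, 0.95, 16)),
        diffusion_times=_DELTA_LADDER,
        gradient_duration=_DELTA_SMALL[kind],
    )


def generate_dataset(
    params: CondensateParams | BindingParams,
    scheme: AcquisitionScheme,
    noise: NoiseSpec | None = None,
    provenance: str = "simulated",
) -> DecayDataset:
    """Forward-model dataset on the full (Delta, gradient) grid of a scheme.

    With Gaussian noise enabled, seeded noise is added to every point and
    each curve is then re-normalized to its smallest-gradient point,
    mimicking how experimental curves are normalized.  Deterministic under a
    fixed seed.
    """
    if isinstance(params, CondensateParams):
        surface = redifine_signal(params, scheme)
    elif isinstance(params, BindingParams):
        surface = dispersed_signal(params, scheme)
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    values = surface.values.copy()
    fractions = np.asarray(scheme.gradient_fractions)
    if noise is not None and noise.model == "gaussian" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        values = values + rng.normal(0.0, noise.sigma, size=values.shape)
        if noise.renormalize:
            ref = np.argmin(fractions)
            values = values / values[:, ref][:, None]
        values = np.clip(values, _NOISE_FLOOR, _NOISE_CAP)
    deltas = np.repeat(scheme.diffusion_times, len(fractions))
    fracs = np.tile(fractions, len(scheme.diffusion_times))
    return DecayDataset(
        diffusion_times=deltas,
        fractions=fracs,
        intensities=values.ravel(),
        scheme=scheme,
        provenance=provenance,
    )


def _walk_displacements(
    n_walkers: int, n_steps: int, sigma: float, L: float, seed: int
) -> np.ndarray:
    """Net displacement of each walker after n_steps reflected Gaussian steps.

    Vectorized over walkers; each Gaussian step is folded back into [0, L]
    by mirror reflection (``x -> L - |x mod 2L - L|``), which samples the
    reflected-Brownian transition density exactly at any step size.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, L, n_walkers)
    x = x0.copy()
    two_L = 2.0 * L
    for _ in range(n_steps):
        x += rng.standard_normal(n_walkers) * sigma
        np.remainder(x, two_L, out=x)
        x -= L
        np.abs(x, out=x)
        np.subtract(L, x, out=x)
    return x - x0


def walker_attenuation(config: WalkerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo narrow-pulse attenuation with standard errors.

    Simulates 1-D diffusion between reflecting boundaries; the narrow-pulse
    attenuation at wavevector q is ``E(q) = <cos(q (x_Delta - x_0))>`` over
    walkers starting from the uniform equilibrium distribution.  Returns
    ``(E, standard_error)`` arrays over ``config.q_values``.
    """
    L = config.boundary_separation
    if config.rms_step > L / 50.0:
        raise ValueError(
            f"RMS step {config.rms_step:.3g} exceeds boundary_separation/50 = "
            f"{L / 50:.3g}; increase n_steps"
        )
    sigma = math.sqrt(2.0 * config.D * config.Delta / config.n_steps)
    disp = _walk_displacements(config.n_walkers, config.n_steps, sigma, L, config.seed)
    q = np.asarray(config.q_values)
    phases = np.cos(q[:, None] * disp[None, :])
    E = phases.mean(axis=1)
    se = phases.std(axis=1, ddof=1) / math.sqrt(config.n_walkers)
    return E, se


def matrix_exponential_oracle(
    rate_matrix: np.ndarray, initial: np.ndarray, Delta: float
) -> np.ndarray:
    """``expm(A * Delta) @ initial`` via scaling-and-squaring (test oracle)."""
    A = np.asarray(rate_matrix, dtype=float)
    v = np.asarray(initial, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("rate matrix must be finite")
    return expm(A * Delta) @ v
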