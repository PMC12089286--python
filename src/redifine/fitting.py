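"""Global least-squares estimation of condensate and binding parameters.

All diffusion-decay curves (one per diffusion time Delta) are fit jointly:
the objective is the Euclidean norm of the residuals over every
(Delta, gradient) point,

    chi = sqrt( sum_i | I_i/I0 - S_i(theta) |^2 ).

The minimizer is a derivative-free simplex (Nelder-Mead) run from multiple
seeded starting points, because a single simplex start on this 5-parameter
surface is not reliably global.  Positivity and [0, 1] bounds are enforced
by fitting in transformed coordinates (log for diffusion coefficients,
radius, permeability and rates; logit for fractions).  Uncertainties come
from the covariance matrix ``s^2 (J^T J)^{-1}`` built from a numerical
Jacobian of the residuals at the optimum, mapped back to natural parameter
scale by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
from scipy.optimize import minimize

from .acquisition import AcquisitionScheme
from .binding import (
    BindingParams,
    MixtureTotals,
    association_rate,
    dissociation_constant,
    equilibrium_concentrations,
)
from .binding import _signal_points_binding
from .model import (
    CondensateParams,
    DerivedRates,
    rates_from_params,
    _signal_points_condensate,
)

__all__ = [
    "DecayDataset",
    "FitSpec",
    "FitResult",
    "FitError",
    "chi_objective",
    "predict_intensities",
    "fit_redifine",
    "fit_binding",
    "parameter_uncertainties",
    "fit_monoexponential",
    "estimate_kurtosis",
    "CONDENSATE_PARAM_NAMES",
    "BINDING_PARAM_NAMES",
]

CONDENSATE_PARAM_NAMES = ("D_dil", "D_cond", "nu_cond", "R_drop", "p")
BINDING_PARAM_NAMES = ("D_free", "D_complex", "nu_complex", "k_off")

#: transform family per parameter: positive quantities on log scale,
#: fractions on logit scale.
_LOGIT_PARAMS = {"nu_cond", "nu_complex"}


class FitError(RuntimeError):
    """Raised when the optimization cannot produce a usable result."""


# ---------------------------------------------------------------------------
# dataset container


@dataclass(frozen=True)
class DecayDataset:
    """Observed or simulated normalized intensities indexed by (Delta, g).

    Stored as parallel arrays: ``diffusion_times`` (s), ``fractions``
    (dimensionless gradient amplitudes) and ``intensities`` (I/I0), plus the
    acquisition scheme that maps fractions to q.  Intensities must lie in
    (0, 1.5] (noise overshoot above 1 is tolerated) and every (Delta, g)
    pair must be unique.  A dataset with a single diffusion time constructs
    with a warning; fitting requires at least two.
    """

    diffusion_times: np.ndarray
    fractions: np.ndarray
    intensities: np.ndarray
    scheme: AcquisitionScheme
    provenance: str = ""

    def __post_init__(self) -> None:
        dt = np.asarray(self.diffusion_times, dtype=float)
        fr = np.asarray(self.fractions, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if not (dt.shape == fr.shape == it.shape) or dt.ndim != 1 or dt.size == 0:
            raise ValueError("diffusion_times, fractions, intensities must be equal-length 1-D")
        if not np.all(np.isfinite(it)):
            raise ValueError("non-finite intensities")
        if np.any(it <= 0) or np.any(it > 1.5):
            raise ValueError("intensities must lie in (0, 1.5]")
        if np.any(dt <= 0):
            raise ValueError("diffusion times must be positive")
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("gradient fractions must lie in [0, 1]")
        pairs = {(t, g) for t, g in zip(dt, fr)}
        if len(pairs) != dt.size:
            raise ValueError("duplicate (Delta, gradient) points")
        object.__setattr__(self, "diffusion_times", dt)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "intensities", it)
        if len(set(dt.tolist())) < 2:
            warnings.warn(
                "dataset contains a single diffusion time; the global fit "
                "requires at least two curves",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.diffusion_times.size

    @property
    def unique_deltas(self) -> np.ndarray:
        return np.unique(self.diffusion_times)

    def curve(self, Delta: float) -> tuple[np.ndarray, np.ndarray]:
        """(b, intensity) arrays of the curve at one diffusion time, b-sorted."""
        mask = self.diffusion_times == Delta
        if not np.any(mask):
            raise ValueError(f"no points at Delta = {Delta}")
        q = (
            self.scheme.gyromagnetic_ratio
            * self.fractions[mask]
            * self.scheme.max_gradient
            * self.scheme.gradient_duration
        )
        b = q * q * self.scheme.effective_delta(float(Delta))
        order = np.argsort(b)
        return b[order], self.intensities[mask][order]


# ---------------------------------------------------------------------------
# model prediction at dataset points


def _point_arrays(dataset: DecayDataset) -> tuple[np.ndarray, np.ndarray]:
    """(q, effective diffusion time) arrays for every dataset point."""
    scheme = dataset.scheme
    q = (
        scheme.gyromagnetic_ratio
        * dataset.fractions
        * scheme.max_gradient
        * scheme.gradient_duration
    )
    t = dataset.diffusion_times.copy()
    if scheme.effective_diffusion_time:
        t = t - scheme.gradient_duration / 3.0
    return q, t


def predict_intensities(dataset: DecayDataset, params) -> np.ndarray:
    """Forward-model signal at every point of the dataset, in point order."""
    q, t = _point_arrays(dataset)
    if isinstance(params, CondensateParams):
        return _signal_points_condensate(params, q, t)
    if isinstance(params, BindingParams):
        return _signal_points_binding(params, q, t)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def chi_objective(dataset: DecayDataset, params) -> float:
    """Euclidean norm of (data - model) over all curves jointly."""
    pred = predict_intensities(dataset, params)
    return float(np.sqrt(np.sum((dataset.intensities - pred) ** 2)))


# ---------------------------------------------------------------------------
# fit specification and result


@dataclass(frozen=True)
class FitSpec:
    """Controls for the multistart simplex fit.

    ``free_parameters``: subset of parameter names to vary (None = all);
    fixed parameters take their values from ``fixed_values`` (or the
    heuristic guess if absent).  ``initial_guesses`` overrides the heuristic
    starting point per parameter, in natural (SI) units.  ``n_starts``
    seeded simplex runs are launched from log/logit-space perturbations of
    the starting point (scale ``perturbation_scale``); the loop stops early
    once a start reaches ``chi < early_stop_chi``, which for noiseless data
    identifies the global minimum.  ``fit_curve_scales`` adds one free
    multiplicative normalization scale per curve.
    """

    free_parameters: tuple[str, ...] | None = None
    initial_guesses: Mapping[str, float] | None = None
    fixed_values: Mapping[str, float] | None = None
    n_starts: int = 20
    random_seed: int = 0
    max_iter: int = 5000
    chi_tol: float = 1e-12
    param_tol: float = 1e-8
    perturbation_scale: float = 1.0
    early_stop_chi: float = 1e-10
    fit_curve_scales: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``params`` are the best-fit physical parameters; ``uncertainties`` the
    per-parameter standard errors on natural scale (NaN for fixed
    parameters); ``covariance`` the natural-scale covariance over
    ``free_names``; ``chi`` the objective at the optimum.  ``derived`` holds
    the exchange rates for condensate fits; ``binding_derived`` the
    K_d / k_on chain for binding fits when totals were supplied.
    ``unidentifiable`` lists parameters whose uncertainty exceeds their
    value (or whose information matrix is singular); they are reported, not
    suppressed.
    """

    model: str
    params: Any
    uncertainties: dict[str, float]
    covariance: np.ndarray
    free_names: tuple[str, ...]
    chi: float
    n_starts_converged: int
    best_start_index: int
    unidentifiable: tuple[str, ...] = ()
    derived: DerivedRates | None = None
    binding_derived: dict[str, float] | None = None
    curve_scales: dict[float, float] | None = None
    n_points: int = 0
    random_seed: int = 0

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "model": self.model,
            "params": {
                name: getattr(self.params, name)
                for name in (
                    CONDENSATE_PARAM_NAMES
                    if self.model == "condensate"
                    else BINDING_PARAM_NAMES
                )
            },
            "uncertainties": dict(self.uncertainties),
            "covariance": np.asarray(self.covariance).tolist(),
            "free_names": list(self.free_names),
            "chi": self.chi,
            "n_starts_converged": self.n_starts_converged,
            "best_start_index": self.best_start_index,
            "unidentifiable": list(self.unidentifiable),
            "n_points": self.n_points,
            "random_seed": self.random_seed,
        }
        if self.derived is not None:
            d["derived"] = {
                "k_cd": self.derived.k_cd,
                "k_dc": self.derived.k_dc,
                "k_ex": self.derived.k_ex,
                "t_half": self.derived.t_half,
            }
        if self.binding_derived is not None:
            d["binding_derived"] = dict(self.binding_derived)
        if self.curve_scales is not None:
            d["curve_scales"] = {str(k): v for k, v in self.curve_scales.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FitResult":
        model = d["model"]
        if model == "condensate":
            params = CondensateParams(**d["params"])
        else:
            params = BindingParams(**d["params"])
        derived = None
        if "derived" in d:
            derived = DerivedRates(**d["derived"])
        curve_scales = None
        if "curve_scales" in d:
            curve_scales = {float(k): v for k, v in d["curve_scales"].items()}
        return cls(
            model=model,
            params=params,
            uncertainties=dict(d["uncertainties"]),
            covariance=np.asarray(d["covariance"], dtype=float),
            free_names=tuple(d["free_names"]),
            chi=d["chi"],
            n_starts_converged=d["n_starts_converged"],
            best_start_index=d["best_start_index"],
            unidentifiable=tuple(d["unidentifiable"]),
            derived=derived,
            binding_derived=dict(d["binding_derived"]) if "binding_derived" in d else None,
            curve_scales=curve_scales,
            n_points=d.get("n_points", 0),
            random_seed=d.get("random_seed", 0),
        )


# ---------------------------------------------------------------------------
# transforms


def _to_transformed(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        v = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(v / (1.0 - v))
    return math.log(max(value, 1e-300))


def _from_transformed(name: str, theta: float) -> float:
    theta = min(max(theta, -700.0), 700.0)  # saturate, simplex may overshoot
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-theta))
    return math.exp(theta)


def _natural_jacobian_factor(name: str, value: float) -> float:
    """d(natural)/d(transformed) at the optimum, for the delta method."""
    if name in _LOGIT_PARAMS:
        return value * (1.0 - value)
    return value


# ---------------------------------------------------------------------------
# heuristic initial guesses


def _early_slope_and_plateau(dataset: DecayDataset) -> tuple[float, float]:
    """(apparent D from the early decay, large-gradient plateau) of the
    shortest-Delta curve."""
    Delta = float(np.min(dataset.unique_deltas))
    b, inten = dataset.curve(Delta)
    k = min(4, len(b))
    y = np.log(inten[:k])
    bb = b[:k]
    denom = float(np.dot(bb, bb))
    slope = float(np.dot(bb, y)) / denom if denom > 0 else 0.0
    plateau = float(np.mean(inten[-2:]))
    return max(-slope, 1e-14), min(max(plateau, 1e-3), 0.99)


def _default_guess_condensate(dataset: DecayDataset) -> dict[str, float]:
    D_eff, plateau = _early_slope_and_plateau(dataset)
    nu0 = min(max(plateau, 0.02), 0.95)
    D_dil0 = D_eff / max(1.0 - nu0, 0.05)
    return {
        "D_dil": D_dil0,
        "D_cond": D_dil0 / 100.0,
        "nu_cond": nu0,
        "R_drop": 1e-6,
        "p": 0.5e-6,
    }


def _default_guess_binding(dataset: DecayDataset) -> dict[str, float]:
    D_eff, plateau = _early_slope_and_plateau(dataset)
    nu0 = min(max(plateau, 0.05), 0.95)
    return {
        "D_free": D_eff,
        "D_complex": D_eff / 3.0,
        "nu_complex": nu0,
        "k_off": 1.0,
    }


# ---------------------------------------------------------------------------
# residuals with optional per-curve scales


def _residuals(dataset: DecayDataset, params, scales: np.ndarray | None) -> np.ndarray:
    pred = predict_intensities(dataset, params)
    if scales is not None:
        deltas = dataset.unique_deltas
        for s, Delta in zip(scales, deltas):
            pred[dataset.diffusion_times == Delta] *= s
    return dataset.intensities - pred


def _make_params(model: str, values: Mapping[str, float]):
    if model == "condensate":
        return CondensateParams(**{k: values[k] for k in CONDENSATE_PARAM_NAMES})
    return BindingParams(**{k: values[k] for k in BINDING_PARAM_NAMES})


def _run_global_fit(dataset: DecayDataset, spec: FitSpec, model: str) -> FitResult:
    names = CONDENSATE_PARAM_NAMES if model == "condensate" else BINDING_PARAM_NAMES
    n_curves = len(dataset.unique_deltas)
    if n_curves < 2:
        raise FitError("global fitting requires at least 2 diffusion-time curves")
    if n_curves < 6:
        warnings.warn(
            f"only {n_curves} diffusion-time curves: for accurate multiparametric "
            "fitting a minimum of six diffusion curves should be acquired",
            stacklevel=3,
        )
    if not np.all(np.isfinite(dataset.intensities)):
        raise FitError("non-finite data")

    guess = (
        _default_guess_condensate(dataset)
        if model == "condensate"
        else _default_guess_binding(dataset)
    )
    if spec.initial_guesses:
        guess.update({k: float(v) for k, v in spec.initial_guesses.items()})
    fixed = dict(spec.fixed_values or {})
    free = tuple(spec.free_parameters) if spec.free_parameters is not None else tuple(names)
    for name in free:
        if name not in names:
            raise ValueError(f"unknown parameter {name!r} for {model} model")
    for name in names:
        if name not in free and name not in fixed:
            if spec.free_parameters is not None:
                raise ValueError(f"fixed parameter {name!r} requires a value")
    values0 = {**guess, **fixed}

    scale_names: tuple[str, ...] = ()
    if spec.fit_curve_scales:
        scale_names = tuple(f"scale_{i}" for i in range(n_curves))
    theta0 = np.array(
        [_to_transformed(n, values0[n]) for n in free]
        + [0.0] * len(scale_names)  # log-scale 1.0
    )

    n_free = len(free)

    def unpack(theta: np.ndarray):
        values = dict(values0)
        for i, n in enumerate(free):
            values[n] = _from_transformed(n, theta[i])
        scales = np.exp(theta[n_free:]) if scale_names else None
        return values, scales

    def objective(theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return np.inf
        values, scales = unpack(theta)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = _make_params(model, values)
                res = _residuals(dataset, params, scales)
        except (ValueError, ArithmeticError):
            return np.inf
        if not np.all(np.isfinite(res)):
            return np.inf
        return float(np.sqrt(np.sum(res * res)))

    rng = np.random.default_rng(spec.random_seed)
    best = None
    best_idx = -1
    n_conv = 0
    diagnostics = []
    for k in range(spec.n_starts):
        start = theta0.copy()
        if k > 0:
            start = start + rng.normal(0.0, spec.perturbation_scale, size=start.size)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": spec.max_iter,
                "maxfev": 2 * spec.max_iter,
                "xatol": spec.param_tol,
                "fatol": spec.chi_tol,
            },
        )
        diagnostics.append((k, res.status, res.fun, res.message))
        if np.isfinite(res.fun):
            n_conv += 1
            if best is None or res.fun < best.fun:
                best = res
                best_idx = k
        if best is not None and best.fun < spec.early_stop_chi:
            break
    if best is None:
        raise FitError(f"all {spec.n_starts} starts failed to converge: {diagnostics}")

    values, scales = unpack(best.x)
    params = _make_params(model, values)
    result = FitResult(
        model=model,
        params=params,
        uncertainties={},
        covariance=np.zeros((n_free, n_free)),
        free_names=free,
        chi=float(best.fun),
        n_starts_converged=n_conv,
        best_start_index=best_idx,
        n_points=len(dataset),
        random_seed=spec.random_seed,
        curve_scales=(
            dict(zip((float(d) for d in dataset.unique_deltas), scales.tolist()))
            if scales is not None
            else None
        ),
    )
    _attach_uncertainties(result, dataset)
    return result


def _attach_uncertainties(result: FitResult, dataset: DecayDataset) -> None:
    free = result.free_names
    scales = None
    if result.curve_scales is not None:
        scales = np.array([result.curve_scales[float(d)] for d in dataset.unique_deltas])
    theta = np.array([_to_transformed(n, getattr(result.params, n)) for n in free])

    def resid(th: np.ndarray) -> np.ndarray:
        values = {n: getattr(result.params, n) for n in (
            CONDENSATE_PARAM_NAMES if result.model == "condensate" else BINDING_PARAM_NAMES
        )}
        for i, n in enumerate(free):
            values[n] = _from_transformed(n, th[i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _residuals(dataset, _make_params(result.model, values), scales)

    n_pts = len(dataset)
    J = np.empty((n_pts, len(free)))
    for i in range(len(free)):
        h = 1e-5 * max(abs(theta[i]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (resid(tp) - resid(tm)) / (2.0 * h)

    dof = max(n_pts - len(free), 1)
    s2 = result.chi**2 / dof
    jtj = J.T @ J
    # near-null directions of the information matrix mark parameters (or
    # combinations) the data do not constrain
    eigval, eigvec = np.linalg.eigh(jtj)
    max_eig = float(eigval[-1]) if eigval.size else 0.0
    null = eigval < 1e-12 * max(max_eig, 1e-300)
    singular = bool(np.any(null)) or max_eig == 0.0
    if singular:
        cov_t = s2 * np.linalg.pinv(jtj, rcond=1e-12)
        null_weight = (eigvec[:, null] ** 2).sum(axis=1)
    else:
        cov_t = s2 * np.linalg.inv(jtj)
        null_weight = np.zeros(len(free))

    g = np.array([_natural_jacobian_factor(n, getattr(result.params, n)) for n in free])
    cov_nat = cov_t * np.outer(g, g)
    se = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
    uncertainties = {}
    for n in (CONDENSATE_PARAM_NAMES if result.model == "condensate" else BINDING_PARAM_NAMES):
        uncertainties[n] = float("nan")
    flagged = []
    for i, n in enumerate(free):
        uncertainties[n] = float(se[i])
        value = abs(getattr(result.params, n))
        if null_weight[i] > 0.1 or (value > 0 and se[i] > value):
            flagged.append(n)
    result.uncertainties = uncertainties
    result.covariance = cov_nat
    result.unidentifiable = tuple(flagged)


def parameter_uncertainties(result: FitResult, dataset: DecayDataset) -> dict[str, float]:
    """Standard errors from the residual covariance at the optimum.

    Recomputes ``s^2 (J^T J)^{-1}`` with a central-difference Jacobian
    (relative step 1e-5 in transformed coordinates) and maps the diagonal
    back to natural scale.  A singular information matrix falls back to the
    pseudo-inverse and flags the affected parameters on
    ``result.unidentifiable`` instead of suppressing them.
    """
    _attach_uncertainties(result, dataset)
    return dict(result.uncertainties)


# ---------------------------------------------------------------------------
# public fit entry points


def fit_redifine(dataset: DecayDataset, spec: FitSpec | None = None) -> FitResult:
    """Global five-parameter fit of the condensate model to all curves.

    Returns the best of ``spec.n_starts`` simplex minimizations with derived
    exchange rates attached.  Warns when fewer than six diffusion-time
    curves are available (accurate multiparametric fitting wants >= 6).
    """
    spec = spec or FitSpec()
    result = _run_global_fit(dataset, spec, "condensate")
    if result.params.nu_cond < 1.0:
        result.derived = rates_from_params(result.params)
    return result


def fit_binding(
    dataset: DecayDataset,
    totals: MixtureTotals | None = None,
    spec: FitSpec | None = None,
    reference_species: int = 1,
) -> FitResult:
    """Global four-parameter fit of the dispersed binding model.

    When ``totals`` is supplied the equilibrium concentrations, ``K_d`` and
    ``k_on`` are derived from the fitted bound fraction and ``k_off``; a
    derivation failure (inconsistent totals) is recorded on the result
    rather than discarding the fit.
    """
    spec = spec or FitSpec()
    result = _run_global_fit(dataset, spec, "binding")
    if totals is not None:
        try:
            c1f, c2f, cc = equilibrium_concentrations(
                totals, result.params.nu_complex, reference_species
            )
            K_d = dissociation_constant(c1f, c2f, cc)
            result.binding_derived = {
                "c1_free": c1f,
                "c2_free": c2f,
                "c_complex": cc,
                "K_d": K_d,
                "k_on": association_rate(result.params.k_off, K_d),
            }
        except ValueError as exc:
            result.binding_derived = {"error": str(exc)}  # type: ignore[dict-item]
    return result


# ---------------------------------------------------------------------------
# single-curve diagnostics


def _single_curve(dataset: DecayDataset, Delta: float | None) -> tuple[np.ndarray, np.ndarray]:
    deltas = dataset.unique_deltas
    if Delta is None:
        if len(deltas) != 1:
            raise ValueError("dataset holds several curves; specify Delta")
        Delta = float(deltas[0])
    return dataset.curve(float(Delta))


def fit_monoexponential(
    dataset: DecayDataset, Delta: float | None = None
) -> tuple[float, float]:
    """Mono-exponential fit of one curve: ``ln(I/I0) = -b D``.

    Returns ``(D, residual_norm)``; the residual norm (on ln intensities) is
    a cheap deviation-from-Gaussian-diffusion diagnostic.  Requires at least
    3 points and positive intensities.
    """
    b, inten = _single_curve(dataset, Delta)
    if len(b) < 3:
        raise ValueError("mono-exponential fit needs >= 3 points")
    if np.any(inten <= 0):
        raise ValueError("nonpositive intensities")
    y = np.log(inten)
    denom = float(np.dot(b, b))
    if denom == 0:
        raise ValueError("all b values are zero")
    slope = float(np.dot(b, y)) / denom
    resid = y - slope * b
    return abs(slope), float(np.linalg.norm(resid))


def estimate_kurtosis(
    dataset: DecayDataset, Delta: float | None = None
) -> tuple[float, float]:
    """Apparent diffusion and kurtosis from a quadratic b-expansion.

    Fits ``ln(I/I0) = -b D_app + (1/6) b^2 D_app^2 K`` to one curve.
    K = 0 for Gaussian (mono-exponential) diffusion; a static mixture of
    diffusion coefficients gives K > 0.  Requires >= 4 points spanning more
    than one b value.
    """
    b, inten = _single_curve(dataset, Delta)
    if len(b) < 4:
        raise ValueError("kurtosis estimation needs >= 4 points")
    if np.any(inten <= 0):
        raise ValueError("nonpositive intensities")
    if np.ptp(b) == 0:
        raise ValueError("ill-conditioned design: all b values equal")
    y = np.log(inten)
    X = np.column_stack([b, b * b])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c1, c2 = float(coef[0]), float(coef[1])
    D_app = -c1
    if D_app <= 0:
        return D_app, 0.0
    K = 6.0 * c2 / (D_app * D_app)
    return D_app, K
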