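"""File formats: run configuration, decay tables and fingerprint reports.

On disk, timing parameters are in milliseconds and lengths in micrometres
(human-friendly); everything is converted to SI on ingest.  Decay tables are
plain delimited text (comma or tab, header mandatory) with columns
``delta_time`` (ms), ``gradient`` (fraction of maximum, or T/m if declared)
and ``intensity``, plus an optional ``i0`` reference column.  Spectral
processing (Fourier transform, apodization, baseline, peak integration)
happens upstream in the spectrometer software and is out of scope here.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .acquisition import DEFAULT_MAX_GRADIENT, GAMMA_PROTON, AcquisitionScheme
from .binding import BindingParams, MixtureTotals
from .fitting import DecayDataset, FitResult, FitSpec
from .model import CondensateParams, rates_from_params
from ._version import __version__

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_decay_table",
    "write_decay_table",
    "write_fingerprint",
    "read_fingerprint",
    "plot_fingerprint",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message carries the key path."""


_ALLOWED = {
    "acquisition": {
        "gyromagnetic_ratio",
        "max_gradient_T_per_m",
        "gradient_duration_ms",
        "diffusion_times_ms",
        "gradient_fractions",
        "gradient_unit",
        "effective_diffusion_time",
    },
    "model": {
        "kind",
        "D_dil",
        "D_cond",
        "nu_cond",
        "R_drop_um",
        "p_um_per_s",
        "D_free",
        "D_complex",
        "nu_complex",
        "k_off",
    },
    "fit": {
        "n_starts",
        "random_seed",
        "max_iter",
        "free_parameters",
        "initial_guesses",
        "fixed_values",
        "fit_curve_scales",
        "perturbation_scale",
    },
    "noise": {"model", "sigma", "seed"},
    "totals": {"conc1_uM", "conc2_uM", "stoichiometry", "reference_species"},
    "io": {"input", "output_dir", "report_formats"},
}


def _check_keys(block: Mapping[str, Any], name: str) -> None:
    allowed = _ALLOWED[name]
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key '{name}.{key}' (allowed: {sorted(allowed)})")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for a CLI run."""

    scheme: AcquisitionScheme
    model_kind: str = "condensate"
    condensate_params: CondensateParams | None = None
    binding_params: BindingParams | None = None
    fit: FitSpec = field(default_factory=FitSpec)
    noise_sigma: float = 0.0
    noise_seed: int = 0
    totals: MixtureTotals | None = None
    reference_species: int = 1
    gradient_unit: str = "fraction"
    source_hash: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
        digest = hashlib.sha256(text.encode()).hexdigest()[:16]
        return cls.from_dict(raw, source_hash=digest)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], source_hash: str = "") -> "RunConfig":
        for key in raw:
            if key not in _ALLOWED:
                raise ConfigError(f"unknown top-level key '{key}' (allowed: {sorted(_ALLOWED)})")
        acq = dict(raw.get("acquisition") or {})
        _check_keys(acq, "acquisition")
        try:
            scheme = AcquisitionScheme(
                gradient_fractions=tuple(
                    acq.get("gradient_fractions", tuple(np.linspace(0.02, 0.95, 16)))
                ),
                diffusion_times=tuple(
                    t * 1e-3 for t in acq.get("diffusion_times_ms", (50, 100, 200, 350, 600, 1000))
                ),
                gradient_duration=float(acq.get("gradient_duration_ms", 10.0)) * 1e-3,
                max_gradient=float(acq.get("max_gradient_T_per_m", DEFAULT_MAX_GRADIENT)),
                gyromagnetic_ratio=float(acq.get("gyromagnetic_ratio", GAMMA_PROTON)),
                effective_diffusion_time=bool(acq.get("effective_diffusion_time", False)),
            )
        except ValueError as exc:
            raise ConfigError(f"acquisition: {exc}") from exc
        gradient_unit = acq.get("gradient_unit", "fraction")
        if gradient_unit not in ("fraction", "T_per_m"):
            raise ConfigError("acquisition.gradient_unit must be 'fraction' or 'T_per_m'")

        model = dict(raw.get("model") or {})
        _check_keys(model, "model")
        kind = model.pop("kind", "condensate")
        condensate = binding = None
        try:
            if kind == "condensate":
                if model:
                    condensate = CondensateParams(
                        D_dil=float(model["D_dil"]),
                        D_cond=float(model["D_cond"]),
                        nu_cond=float(model["nu_cond"]),
                        R_drop=float(model["R_drop_um"]) * 1e-6,
                        p=float(model["p_um_per_s"]) * 1e-6,
                    )
            elif kind == "binding":
                if model:
                    binding = BindingParams(
                        D_free=float(model["D_free"]),
                        D_complex=float(model["D_complex"]),
                        nu_complex=float(model["nu_complex"]),
                        k_off=float(model["k_off"]),
                    )
            else:
                raise ConfigError("model.kind must be 'condensate' or 'binding'")
        except KeyError as exc:
            raise ConfigError(f"model: missing key {exc}") from exc
        except ValueError as exc:
            raise ConfigError(f"model: {exc}") from exc

        fit_block = dict(raw.get("fit") or {})
        _check_keys(fit_block, "fit")
        try:
            fit = FitSpec(
                free_parameters=(
                    tuple(fit_block["free_parameters"])
                    if "free_parameters" in fit_block
                    else None
                ),
                initial_guesses=fit_block.get("initial_guesses"),
                fixed_values=fit_block.get("fixed_values"),
                n_starts=int(fit_block.get("n_starts", 20)),
                random_seed=int(fit_block.get("random_seed", 0)),
                max_iter=int(fit_block.get("max_iter", 5000)),
                perturbation_scale=float(fit_block.get("perturbation_scale", 1.0)),
                fit_curve_scales=bool(fit_block.get("fit_curve_scales", False)),
            )
        except ValueError as exc:
            raise ConfigError(f"fit: {exc}") from exc

        noise = dict(raw.get("noise") or {})
        _check_keys(noise, "noise")
        sigma = float(noise.get("sigma", 0.0))
        if sigma < 0:
            raise ConfigError("noise.sigma must be >= 0")

        totals_block = dict(raw.get("totals") or {})
        _check_keys(totals_block, "totals")
        totals = None
        reference_species = int(totals_block.get("reference_species", 1))
        if totals_block.get("conc1_uM") is not None:
            try:
                totals = MixtureTotals(
                    total_conc_species1=float(totals_block["conc1_uM"]) * 1e-6,
                    total_conc_species2=float(totals_block["conc2_uM"]) * 1e-6,
                    stoichiometry=tuple(totals_block.get("stoichiometry", (1, 1))),
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"totals: {exc}") from exc

        io_block = dict(raw.get("io") or {})
        _check_keys(io_block, "io")

        return cls(
            scheme=scheme,
            model_kind=kind,
            condensate_params=condensate,
            binding_params=binding,
            fit=fit,
            noise_sigma=sigma,
            noise_seed=int(noise.get("seed", 0)),
            totals=totals,
            reference_species=reference_species,
            gradient_unit=gradient_unit,
            source_hash=source_hash,
        )


# ---------------------------------------------------------------------------
# decay tables


_REQUIRED_COLUMNS = ("delta_time", "gradient", "intensity")


def read_decay_table(path: str | Path, config: RunConfig) -> DecayDataset:
    """Read a delimited decay table into a :class:`DecayDataset`.

    ``delta_time`` is in ms; ``gradient`` is a fraction of the maximum
    amplitude, or T/m when the config declares ``gradient_unit: T_per_m``.
    Intensities are normalized per curve by the ``i0`` column when present,
    otherwise by the smallest-gradient point of the curve.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns {missing} in {path}")
    for col in _REQUIRED_COLUMNS + (("i0",) if "i0" in df.columns else ()):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            raise ValueError(f"non-numeric values in column '{col}' at rows {bad}")
        df[col] = numeric

    grad = df["gradient"].to_numpy(dtype=float)
    if config.gradient_unit == "T_per_m":
        fractions = grad / config.scheme.max_gradient
    else:
        if np.any(grad > 1.0):
            raise ValueError(
                "gradient column exceeds 1 but config declares fractions; declare "
                "acquisition.gradient_unit: T_per_m if the column is in T/m"
            )
        fractions = grad
    deltas = df["delta_time"].to_numpy(dtype=float) * 1e-3

    dup = df.duplicated(subset=["delta_time", "gradient"])
    if dup.any():
        raise ValueError(f"duplicate (delta_time, gradient) rows: {df.index[dup].tolist()}")

    intensity = df["intensity"].to_numpy(dtype=float)
    normalized = np.empty_like(intensity)
    for Delta in np.unique(deltas):
        mask = deltas == Delta
        if not np.any(intensity[mask] > 0):
            raise ValueError(f"empty or nonpositive curve at delta_time = {Delta * 1e3} ms")
        if "i0" in df.columns:
            ref = df["i0"].to_numpy(dtype=float)[mask]
        else:
            ref = intensity[mask][np.argmin(fractions[mask])]
        normalized[mask] = intensity[mask] / ref

    scheme = AcquisitionScheme(
        gradient_fractions=tuple(sorted(set(fractions.tolist()))),
        diffusion_times=tuple(sorted(set(deltas.tolist()))),
        gradient_duration=config.scheme.gradient_duration,
        max_gradient=config.scheme.max_gradient,
        gyromagnetic_ratio=config.scheme.gyromagnetic_ratio,
        effective_diffusion_time=config.scheme.effective_diffusion_time,
    )
    return DecayDataset(
        diffusion_times=deltas,
        fractions=fractions,
        intensities=np.clip(normalized, 1e-12, 1.5),
        scheme=scheme,
        provenance=str(path),
    )


def write_decay_table(dataset: DecayDataset, path: str | Path) -> None:
    """Write a dataset as a CSV decay table (ms / fraction / normalized I)."""
    df = pd.DataFrame(
        {
            "delta_time": dataset.diffusion_times * 1e3,
            "gradient": dataset.fractions,
            "intensity": dataset.intensities,
            "i0": np.ones(len(dataset)),  # already normalized
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fingerprint reports


def write_fingerprint(result: FitResult, path: str | Path, extra: Mapping[str, Any] | None = None) -> None:
    """Serialize a fit result (the sample's 'fingerprint') to JSON.

    Contains all fitted parameters, standard errors, derived exchange rates,
    the objective value, seeds and the software version; unidentifiable
    parameters carry explicit flags.  Reloading with :func:`read_fingerprint`
    reproduces the result bit-exactly.
    """
    payload = {"software_version": __version__, "fit_result": result.to_dict()}
    if extra:
        payload.update(dict(extra))
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fingerprint(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    return FitResult.from_dict(payload["fit_result"])


def plot_fingerprint(result: FitResult, path: str | Path) -> None:
    """Radar-chart summary of a condensate fit (requires matplotlib).

    Axes: D_dil, D_cond, nu_cond, R_drop, p and the derived k_cd, each
    log-scaled into a typical observed range so fingerprints of different
    samples are visually comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.model != "condensate":
        raise ValueError("fingerprint plot is defined for condensate fits")
    p = result.params
    rates = result.derived or rates_from_params(p)
    axes = [
        ("D_dil", p.D_dil, 1e-12, 1e-9),
        ("D_cond", p.D_cond, 1e-14, 1e-11),
        ("nu_cond", p.nu_cond, 1e-2, 1.0),
        ("R_drop", p.R_drop, 1e-7, 1e-5),
        ("p", p.p, 1e-8, 1e-5),
        ("k_cd", rates.k_cd, 1e-2, 1e2),
    ]
    values = [
        np.clip(
            (math.log10(max(v, lo)) - math.log10(lo)) / (math.log10(hi) - math.log10(lo)),
            0.0,
            1.0,
        )
        for _, v, lo, hi in axes
    ]
    labels = [a[0] for a in axes]
    angles = np.linspace(0, 2 * np.pi, len(axes), endpoint=False).tolist()
    values = values + values[:1]
    angles = angles + angles[:1]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.plot(angles, values, "o-")
    ax.fill(angles, values, alpha=0.25)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(labels)
    ax.set_yticklabels([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
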