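"""Two-component FCS autocorrelation model and bound-fraction extraction.

A dye-labeled RNA in a binding reaction exists in two states — free, or
bound to the ~100 kD ribonucleoprotein — that differ in diffusion time
through the confocal volume. The autocorrelation function of the
fluorescence fluctuations is modeled as a two-component mixture

    G(t) = (1/N) [ (1-p) X1(t) D1(t) + p X2(t) D2(t) ]

where N is the mean number of labeled molecules in the focal volume, p the
bound fraction, Xi(t) = 1 + K_i exp(-t/tau_Ti) the dye photophysics factor
(K_i an equilibrium amplitude, tau_Ti a relaxation time), and

    Di(t) = (1 + t/tau_Di)^-1 (1 + t/(kappa^2 tau_Di))^-1/2

the 3-D diffusion factor of species i with diffusion time tau_Di and focal
volume aspect ratio kappa. Equal molecular brightness of free and bound
species is assumed (a single dye label, unchanged by binding), so the
mixture weights are molecular fractions.

Workflow: the photophysics and diffusion parameters of both species are
calibrated once from pure-free (p = 0) and pure-bound (p = 1) reference
curves (:func:`calibrate_reference`); these are then held fixed and only
(N, p) are fitted per measurement (:func:`fit_bound_fraction`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fitting import FitResult, multistart_least_squares
from .errors import ValidationError

__all__ = [
    "SpeciesFcsParams",
    "MixtureFcsModel",
    "FcsCurve",
    "acf_mixture",
    "acf_single_species",
    "calibrate_reference",
    "fit_bound_fraction",
    "multitau_lags",
]

DEFAULT_KAPPA = 5.0  # focal-volume axial/lateral ratio; typical confocal value


@dataclass(frozen=True)
class SpeciesFcsParams:
    """Diffusion + photophysics parameters of one diffusing species."""

    tau_D: float  # characteristic diffusion time (s)
    K_ph: float = 0.0  # photophysics equilibrium amplitude
    tau_T: float = 1e-6  # photophysics relaxation time (s)
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self):
        if not self.tau_D > 0:
            raise ValidationError("tau_D must be > 0")
        if not self.tau_T > 0:
            raise ValidationError("tau_T must be > 0")
        if not self.kappa > 1:
            raise ValidationError("kappa must be > 1")
        if self.K_ph < 0:
            raise ValidationError("K_ph must be >= 0")
        if self.tau_T >= self.tau_D:
            warnings.warn(
                "photophysics relaxation slower than diffusion (tau_T >= tau_D)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MixtureFcsModel:
    """Two-species mixture: free and bound forms of the labeled RNA."""

    N: float
    p: float
    free: SpeciesFcsParams
    bound: SpeciesFcsParams

    def __post_init__(self):
        if not self.N > 0:
            raise ValidationError("N must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must be in [0, 1]")


@dataclass
class FcsCurve:
    """An empirical or synthetic autocorrelation curve."""

    lags: np.ndarray
    G: np.ndarray
    sigma: np.ndarray | None = None
    duration: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.G = np.asarray(self.G, float)
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValidationError("lags must be a nonempty 1-D array")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be positive and strictly increasing")
        if self.G.shape != self.lags.shape:
            raise ValidationError("G must have the same length as lags")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.lags.shape:
                raise ValidationError("sigma must have the same length as lags")
            if np.any(self.sigma < 0):
                raise ValidationError("sigma must be >= 0")


def _diffusion_factor(t, tau_D, kappa):
    return 1.0 / ((1.0 + t / tau_D) * np.sqrt(1.0 + t / (kappa**2 * tau_D)))


def _photophysics_factor(t, K, tau_T, normalized=False):
    # default: unnormalized multiplicative form 1 + K exp(-t/tauT); the
    # normalized triplet-fraction alternative is available behind the flag
    if normalized:
        T = K / (1.0 + K)
        return (1.0 - T + T * np.exp(-t / tau_T)) / (1.0 - T)
    return 1.0 + K * np.exp(-t / tau_T)


def acf_single_species(t, N, species: SpeciesFcsParams, normalized_triplet=False):
    """Single-species autocorrelation G(t)."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValidationError("lag times must be > 0")
    X = _photophysics_factor(t, species.K_ph, species.tau_T, normalized_triplet)
    D = _diffusion_factor(t, species.tau_D, species.kappa)
    return (X * D) / N


def acf_mixture(t, model: MixtureFcsModel, normalized_triplet=False):
    """Two-component autocorrelation of a free/bound mixture at lag(s) t."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValidationError("lag times must be > 0")
    Xf = _photophysics_factor(t, model.free.K_ph, model.free.tau_T, normalized_triplet)
    Df = _diffusion_factor(t, model.free.tau_D, model.free.kappa)
    Xb = _photophysics_factor(t, model.bound.K_ph, model.bound.tau_T, normalized_triplet)
    Db = _diffusion_factor(t, model.bound.tau_D, model.bound.kappa)
    return ((1.0 - model.p) * Xf * Df + model.p * Xb * Db) / model.N


def multitau_lags(t_min: float = 1e-6, t_max: float = 1.0,
                  points_per_octave: int = 14) -> np.ndarray:
    """Quasi-logarithmic lag grid mimicking a hardware multi-tau correlator.

    Each octave [2^k t_min, 2^(k+1) t_min] carries ``points_per_octave``
    linearly spaced lags, giving the dense-short/sparse-long structure of a
    cascaded correlator.
    """
    if t_min <= 0 or t_max <= t_min:
        raise ValidationError("need 0 < t_min < t_max")
    lags = []
    lo = t_min
    while lo < t_max:
        hi = min(lo * 2.0, t_max)
        lags.append(np.linspace(lo, hi, points_per_octave, endpoint=False))
        lo = hi
    grid = np.unique(np.concatenate(lags + [np.array([t_max])]))
    return grid[grid > 0]


def _curve_weights(curve: FcsCurve) -> np.ndarray:
    if curve.sigma is not None and np.all(curve.sigma > 0):
        return 1.0 / curve.sigma
    return np.ones_like(curve.G)


def _check_reference_curve(curve: FcsCurve) -> None:
    if curve.lags.size < 20:
        raise ValidationError("reference curve needs >= 20 lag points")
    if curve.lags[-1] / curve.lags[0] < 1e3:
        raise ValidationError("reference curve must span >= 3 decades of lag")


def calibrate_reference(
    curve: FcsCurve,
    role: str,
    kappa: float = DEFAULT_KAPPA,
    seed: int | None = None,
) -> FitResult:
    """Fit the single-species model to a pure-free or pure-bound control.

    ``role`` is ``"free"`` (p = 0 control) or ``"bound"`` (p = 1 control,
    measured with saturating enzyme). Returns a FitResult with parameters
    N, tau_D, K_ph, tau_T (kappa fixed, not fitted) plus standard errors;
    ``extras['species']`` carries the fitted SpeciesFcsParams.

    Fitting is weighted by 1/sigma when the curve carries per-lag errors,
    multistarted from 8 log-spaced tau_D initializations.
    """
    if role not in ("free", "bound"):
        raise ValidationError(f"role must be 'free' or 'bound', got {role!r}")
    _check_reference_curve(curve)

    w = _curve_weights(curve)
    t = curve.lags
    G = curve.G

    def residual(x):
        logN, log_tauD, K, log_tauT = x
        X = _photophysics_factor(t, K, np.exp(log_tauT))
        D = _diffusion_factor(t, np.exp(log_tauD), kappa)
        return (X * D * np.exp(-logN) - G) * w

    # crude N guess from the short-lag amplitude; tau_T guess near short lags
    G0 = max(G[0], 1e-12)
    n0 = max(1.0 / G0, 1e-3)
    tau_span = np.log(curve.lags[2]), np.log(curve.lags[-3])
    starts = [
        np.array([np.log(n0), ltd, 0.1, np.log(curve.lags[0] * 5.0)])
        for ltd in np.linspace(*tau_span, 8)
    ]
    bounds = (
        np.array([-30.0, np.log(t[0] / 10), 0.0, np.log(t[0] / 10)]),
        np.array([30.0, np.log(t[-1] * 10), 50.0, np.log(t[-1])]),
    )

    def transform(x):
        return {
            "N": float(np.exp(x[0])),
            "tau_D": float(np.exp(x[1])),
            "K_ph": float(x[2]),
            "tau_T": float(np.exp(x[3])),
        }

    result = multistart_least_squares(
        residual, starts, ["N", "tau_D", "K_ph", "tau_T"],
        bounds=bounds, transform=transform, seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result.extras["species"] = SpeciesFcsParams(
            tau_D=result["tau_D"], K_ph=result["K_ph"],
            tau_T=result["tau_T"], kappa=kappa,
        )
    result.extras["role"] = role
    return result


def fit_bound_fraction(
    curve: FcsCurve,
    free: SpeciesFcsParams,
    bound: SpeciesFcsParams,
    seed: int | None = None,
) -> FitResult:
    """Fit (N, p) to a mixture curve with both reference species fixed.

    p is constrained to [0, 1]. The free species must diffuse faster than
    the bound one (tau_D1 < tau_D2); otherwise the labeling is inconsistent
    and a ValidationError is raised.
    """
    if free.tau_D >= bound.tau_D:
        raise ValidationError(
            "free species must diffuse faster than bound (tau_D free < tau_D bound)"
        )
    w = _curve_weights(curve)
    t = curve.lags
    G = curve.G
    Xf = _photophysics_factor(t, free.K_ph, free.tau_T)
    Df = _diffusion_factor(t, free.tau_D, free.kappa)
    Xb = _photophysics_factor(t, bound.K_ph, bound.tau_T)
    Db = _diffusion_factor(t, bound.tau_D, bound.kappa)
    comp_free = Xf * Df
    comp_bound = Xb * Db

    def residual(x):
        logN, p = x
        return (((1 - p) * comp_free + p * comp_bound) * np.exp(-logN) - G) * w

    G0 = max(G[0], 1e-12)
    n0 = max(1.0 / G0, 1e-3)
    starts = [np.array([np.log(n0), p0]) for p0 in (0.1, 0.5, 0.9)]
    bounds = (np.array([-30.0, 0.0]), np.array([30.0, 1.0]))

    def transform(x):
        return {"N": float(np.exp(x[0])), "p": float(x[1])}

    return multistart_least_squares(
        residual, starts, ["N", "p"], bounds=bounds, transform=transform, seed=seed,
    )
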