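"""Elementary binding fits: association, dissociation, titration, activity.

These are the workhorse analyses applied to time-resolved bound-fraction
data read out from FCS curves:

* single-exponential association, p(t) = p_eq (1 - e^(-kobs t)), giving the
  apparent pseudo-first-order binding rate kobs at one enzyme concentration;
* weighted linear regression of kobs against enzyme concentration,
  kobs = kon [E] + koff, whose slope is the association rate kon (the
  intercept is a poor estimator of koff and is flagged as such — koff is
  measured directly by dilution instead);
* single-exponential dissociation after strong dilution,
  p(t) = p(0) e^(-koff t);
* the quadratic tight-binding titration isotherm for the apparent Kd;
* a single-turnover activity fit, f(t) = 1 - e^(-k t), whose rate k (often
  written kcat') conflates substrate loading and chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._fitting import FitResult, multistart_least_squares
from .errors import UnidentifiableError, ValidationError
from .reaction_scheme import equilibrium_occupancy

__all__ = [
    "BoundFractionSeries",
    "FitResult",
    "fit_association",
    "fit_kobs_line",
    "fit_dissociation",
    "fit_titration",
    "fit_single_turnover_activity",
    "fold_change",
]

SERIES_KINDS = ("association", "dissociation", "activity")


@dataclass
class BoundFractionSeries:
    """Time-resolved bound fraction p(t) with its concentration context.

    CE and CS are the total enzyme and labeled-RNA concentrations (M) during
    the measurement. Noise may push individual p values slightly outside
    [0, 1]; values are kept unclipped and the fitters tolerate them.
    """

    times: np.ndarray
    p: np.ndarray
    CE: float = 0.0
    CS: float = 0.0
    kind: str = "association"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.p = np.asarray(self.p, float)
        if self.times.ndim != 1 or self.times.size < 5:
            raise ValidationError("series needs >= 5 time points")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be nonnegative and strictly increasing")
        if self.p.shape != self.times.shape:
            raise ValidationError("p must have the same length as times")
        if self.kind not in SERIES_KINDS:
            raise ValidationError(f"kind must be one of {SERIES_KINDS}")
        if np.any(self.p < -0.25) or np.any(self.p > 1.25):
            raise ValidationError("p values far outside [0, 1]; wrong column?")


def _exp_rate_guess(times, values, rising: bool) -> float:
    """Initial rate from log-linear regression of the decaying quantity."""
    v = np.asarray(values, float)
    if rising:
        v = np.max(v) * 1.05 - v  # residual amplitude decays at the same rate
    v = np.clip(v, 1e-6, None)
    n = len(v)
    third = max(n // 3, 2)
    t1, v1 = np.mean(times[:third]), np.mean(np.log(v[:third]))
    t2, v2 = np.mean(times[-third:]), np.mean(np.log(v[-third:]))
    if t2 <= t1 or v2 >= v1:
        return 1.0 / max(times[-1], 1e-9)
    return (v1 - v2) / (t2 - t1)


def fit_association(series: BoundFractionSeries, baseline: float = 0.0) -> FitResult:
    """Fit p(t) = baseline + (p_eq - baseline)(1 - e^(-kobs t)).

    Returns kobs (s^-1) and the plateau p_eq; the default baseline of 0
    reflects mixing that starts fully unbound.
    """
    if series.kind != "association":
        raise ValidationError("series kind must be 'association'")
    t, p = series.times, series.p
    third = max(len(p) // 3, 2)
    if np.mean(p[-third:]) < np.mean(p[:third]) - 1e-12:
        raise ValidationError(
            "bound fraction decreases over time; is this a dissociation series?"
        )

    k0 = max(_exp_rate_guess(t, p, rising=True), 1e-9)
    peq0 = float(np.clip(np.max(p), 1e-3, 1.2))

    def residual(x):
        log_k, peq = x
        return baseline + (peq - baseline) * (1 - np.exp(-np.exp(log_k) * t)) - p

    starts = [np.array([np.log(k0 * f), peq0]) for f in (0.2, 1.0, 5.0)]
    bounds = (np.array([-30.0, 0.0]), np.array([10.0, 1.3]))

    def transform(x):
        return {"kobs": float(np.exp(x[0])), "p_eq": float(x[1])}

    return multistart_least_squares(
        residual, starts, ["kobs", "p_eq"], bounds=bounds, transform=transform
    )


def fit_kobs_line(points) -> FitResult:
    """Weighted linear regression kobs = kon*CE + koff across concentrations.

    ``points`` is a sequence of (CE in M, kobs in s^-1, sd) triples; sd may
    be None/0 for unweighted regression. The slope is kon (M^-1 s^-1). The
    intercept is a formally valid but poorly determined koff estimate and is
    flagged low-confidence; measure koff by dilution instead.
    """
    pts = [(float(ce), float(k), (float(sd) if sd else 0.0)) for ce, k, sd in points]
    ces = np.array([x[0] for x in pts])
    if len(np.unique(ces)) < 3:
        raise ValidationError("need >= 3 distinct enzyme concentrations")
    kobs = np.array([x[1] for x in pts])
    sds = np.array([x[2] for x in pts])
    w = 1.0 / sds**2 if np.all(sds > 0) else np.ones_like(kobs)

    # closed-form 2-parameter WLS
    X = np.column_stack([ces, np.ones_like(ces)])
    WX = X * w[:, None]
    A = X.T @ WX
    beta = np.linalg.solve(A, WX.T @ kobs)
    resid = kobs - X @ beta
    dof = max(len(kobs) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = np.linalg.inv(A) * s2
    se = np.sqrt(np.diag(cov))

    return FitResult(
        params={"kon": float(beta[0]), "intercept": float(beta[1])},
        stderr={"kon": float(se[0]), "intercept": float(se[1])},
        ssr=float(resid @ (w * resid)),
        residuals=resid,
        converged=True,
        n_iter=0,
        extras={"intercept_low_confidence": True},
    )


def fit_dissociation(series: BoundFractionSeries) -> FitResult:
    """Fit the single-exponential decay p(t) = p0 e^(-koff t).

    ``extras['normalized']`` carries p(t)/p0, the display normalization.
    """
    if series.kind != "dissociation":
        raise ValidationError("series kind must be 'dissociation'")
    t, p = series.times, series.p
    k0 = max(_exp_rate_guess(t, np.clip(p, 1e-6, None), rising=False), 1e-9)
    p00 = float(np.clip(p[0], 1e-3, 1.3))

    def residual(x):
        log_k, p0 = x
        return p0 * np.exp(-np.exp(log_k) * t) - p

    starts = [np.array([np.log(k0 * f), p00]) for f in (0.2, 1.0, 5.0)]
    bounds = (np.array([-30.0, 0.0]), np.array([10.0, 1.3]))

    def transform(x):
        return {"koff": float(np.exp(x[0])), "p0": float(x[1])}

    result = multistart_least_squares(
        residual, starts, ["koff", "p0"], bounds=bounds, transform=transform
    )
    result.extras["normalized"] = p / result["p0"]
    return result


def fit_titration(series, CS: float, free_amplitude: bool = False) -> FitResult:
    """Fit the quadratic tight-binding isotherm to a titration.

    ``series`` is a sequence of (CE in M, bound fraction p). The model is
    p(CE) = A * occupancy(CS, CE, Kd) with A fixed at 1 unless
    ``free_amplitude``. Kd is initialized at the CE where p crosses 0.5
    (log-interpolated).
    """
    pts = sorted((float(ce), float(p)) for ce, p in series)
    ces = np.array([x[0] for x in pts])
    ps = np.array([x[1] for x in pts])
    if len(np.unique(ces)) < 6:
        raise ValidationError("need >= 6 enzyme concentrations")
    if np.all(ps < 0.1):
        raise UnidentifiableError(
            "all bound fractions near 0; extend the titration to higher CE"
        )
    if np.all(ps > 0.9):
        raise UnidentifiableError(
            "all bound fractions near 1; extend the titration to lower CE"
        )

    # Kd init: CE at half saturation, interpolated on log CE
    half = 0.5 * np.max(ps)
    above = np.where(ps >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        x0, x1 = np.log(ces[i - 1]), np.log(ces[i])
        f = (half - ps[i - 1]) / max(ps[i] - ps[i - 1], 1e-12)
        kd0 = float(np.exp(x0 + f * (x1 - x0)))
    else:
        kd0 = float(np.exp(np.mean(np.log(ces))))
    kd0 = max(kd0, 1e-12)

    occ = np.vectorize(lambda ce, kd: equilibrium_occupancy(CS, ce, kd))

    if free_amplitude:
        def residual(x):
            return x[1] * occ(ces, np.exp(x[0])) - ps

        starts = [np.array([np.log(kd0 * f), 1.0]) for f in (0.3, 1.0, 3.0)]
        bounds = (np.array([-60.0, 0.1]), np.array([0.0, 1.3]))
        names = ["Kd", "amplitude"]

        def transform(x):
            return {"Kd": float(np.exp(x[0])), "amplitude": float(x[1])}
    else:
        def residual(x):
            return occ(ces, np.exp(x[0])) - ps

        starts = [np.array([np.log(kd0 * f)]) for f in (0.3, 1.0, 3.0)]
        bounds = (np.array([-60.0]), np.array([0.0]))
        names = ["Kd"]

        def transform(x):
            return {"Kd": float(np.exp(x[0]))}

    result = multistart_least_squares(
        residual, starts, names, bounds=bounds, transform=transform
    )
    # local-optimum sanity: fitted Kd beats doubling or halving it
    kd_hat = result["Kd"]
    for alt in (2 * kd_hat, kd_hat / 2):
        x_alt = np.array([np.log(alt)] + ([1.0] if free_amplitude else []))
        if float(np.sum(residual(x_alt) ** 2)) < result.ssr - 1e-12:
            raise UnidentifiableError("titration fit is not at a local optimum")
    return result


def fit_single_turnover_activity(times, fractions) -> FitResult:
    """Fit product accumulation f(t) = 1 - e^(-k t) under enzyme excess.

    Returns the apparent single-turnover rate k (s^-1) and the half-time
    t_half = ln2/k (s) in ``extras``.
    """
    t = np.asarray(times, float)
    f = np.asarray(fractions, float)
    if t.shape != f.shape or t.size < 3:
        raise ValidationError("need >= 3 matching time/fraction points")
    if np.any((f < -0.05) | (f > 1.05)):
        raise ValidationError("product fractions must lie in [0, 1]")
    if np.mean(f[-max(len(f) // 3, 1):]) < np.mean(f[:max(len(f) // 3, 1)]):
        raise ValidationError("product fraction must trend upward")

    k0 = max(_exp_rate_guess(t, f, rising=True), 1e-9)

    def residual(x):
        return 1.0 - np.exp(-np.exp(x[0]) * t) - f

    starts = [np.array([np.log(k0 * g)]) for g in (0.2, 1.0, 5.0)]

    def transform(x):
        return {"k": float(np.exp(x[0]))}

    result = multistart_least_squares(residual, starts, ["k"], transform=transform)
    result.extras["t_half"] = math.log(2) / result["k"]
    return result


def fold_change(a: float, b: float, rounding: str = "none") -> float:
    """Ratio a/b with the field's reporting convention.

    rounding: 'none', 'integer' (nearest integer, used for >= 10-fold
    statements) or 'one_decimal'.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("fold_change requires positive inputs")
    r = a / b
    if rounding == "integer":
        return float(round(r))
    if rounding == "one_decimal":
        return round(r, 1)
    if rounding != "none":
        raise ValidationError("rounding must be none|integer|one_decimal")
    return r
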