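"""Shared nonlinear least-squares machinery.

All model fits in the package go through :func:`multistart_least_squares`,
a thin wrapper around :func:`scipy.optimize.least_squares` that

* runs a deterministic set of starting points and keeps the best solution
  (lowest SSR, ties broken by fewest function evaluations),
* estimates parameter covariance from the Gauss-Newton approximation
  ``(J^T J)^{-1}`` scaled by the reduced chi-square, and
* returns a uniform :class:`FitResult` record with convergence metadata.

Residual functions are expected to already include any 1/sigma weighting, so
SSR is the (weighted) sum of squared residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = ["FitResult", "multistart_least_squares"]


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    params/stderr are keyed by parameter name; ``extras`` holds
    operation-specific derived quantities (normalized curves, flags, ...).
    """

    params: dict[str, float]
    stderr: dict[str, float]
    ssr: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ssr < 0:
            raise ValueError("SSR must be nonnegative")
        for name, se in self.stderr.items():
            if np.isfinite(se) and se < 0:
                raise ValueError(f"negative standard error for {name}")

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _covariance(res, n_obs: int) -> np.ndarray:
    """Gauss-Newton covariance scaled by reduced chi-square (curve_fit style)."""
    J = res.jac
    n_par = J.shape[1]
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * res.cost / dof
    # SVD-based pseudo-inverse: tolerant of near-singular Jacobians at bounds.
    _, s, VT = np.linalg.svd(J, full_matrices=False)
    threshold = np.finfo(float).eps * max(J.shape) * (s[0] if s.size else 0.0)
    s_inv2 = np.zeros_like(s)
    keep = s > threshold
    s_inv2[keep] = 1.0 / s[keep] ** 2
    return (VT.T * s_inv2) @ VT * s2


def multistart_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    names: Sequence[str],
    bounds=(-np.inf, np.inf),
    transform: Callable[[np.ndarray], dict[str, float]] | None = None,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    gtol: float = 1e-12,
    seed: int | None = None,
) -> FitResult:
    """Run ``least_squares`` from every start and keep the best solution.

    ``transform`` maps the raw parameter vector to the reported parameter
    dict (e.g. exponentiating log-rates); stderr propagation through the
    transform uses the delta method for the log->linear case, detected by the
    transform reporting values that differ from the raw vector.
    """
    best = None
    ssr_trace = []
    for x0 in starts:
        try:
            res = least_squares(
                residual, np.asarray(x0, float), bounds=bounds,
                ftol=ftol, xtol=xtol, gtol=gtol, method="trf",
            )
        except Exception:
            continue
        ssr = 2.0 * res.cost
        ssr_trace.append(ssr)
        # lowest SSR wins; ties (within relative 1e-10) by fewest evaluations
        if best is None:
            best = res
        else:
            best_ssr = 2.0 * best.cost
            if ssr < best_ssr * (1 - 1e-10) or (
                abs(ssr - best_ssr) <= 1e-10 * max(best_ssr, 1e-300)
                and res.nfev < best.nfev
            ):
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("no start converged", best_attempt=best, ssr_trace=ssr_trace)

    n_obs = best.fun.size
    cov = _covariance(best, n_obs)
    raw_se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    if transform is None:
        params = dict(zip(names, best.x))
        stderr = dict(zip(names, raw_se))
    else:
        params = transform(best.x)
        stderr = {}
        for i, name in enumerate(names):
            value = params[name]
            # delta method for exp(log-parameter); identity otherwise
            if not np.isclose(value, best.x[i]):
                stderr[name] = abs(value) * raw_se[i]
            else:
                stderr[name] = raw_se[i]

    return FitResult(
        params=params,
        stderr=stderr,
        ssr=2.0 * best.cost,
        residuals=best.fun.copy(),
        converged=bool(best.success),
        n_iter=int(best.nfev),
        seed=seed,
        extras={"ssr_trace": ssr_trace},
    )
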