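"""Seeded generators emulating the experimental designs with known truth.

Every fitting stage in the package is exercised against synthetic data
produced here: autocorrelation curves on a multi-tau lag grid, association
time courses at a ladder of enzyme concentrations, dilution chases from
slowly reacting complexes at several incubation times, and equilibrium
titrations. Generators are pure functions of (truth, noise spec): the same
seed always reproduces the same bytes.

The default design constants are the study conditions: 10 nM labeled RNA
with 0.1-1 uM enzyme for association, 2 uM RNA + 6 uM enzyme incubations
diluted 4000-fold for dissociation chases (incubations of 5-293 min for the
coupled experiment), and 10 nM RNA titrated with 10 nM-10 uM enzyme.
Bound-fraction noise defaults to sigma = 0.02 absolute; ACF noise to 2%
multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ValidationError
from .fcs_model import FcsCurve, MixtureFcsModel, SpeciesFcsParams, acf_mixture, multitau_lags
from .reaction_scheme import (
    RateSet,
    closed_form_dilution_response,
    equilibrium_occupancy,
    pre_dilution_state,
    simulate_association,
)
from .binding_fits import BoundFractionSeries
from .coupled_kinetics import CoupledExperiment
from .units import minutes, ms, nM, uM

__all__ = [
    "NoiseSpec",
    "ScenarioTruth",
    "load_scenarios",
    "default_fcs_truth",
    "make_acf_curve",
    "make_association_experiment",
    "make_dissociation_series",
    "make_coupled_experiment",
    "make_titration",
]

DEFAULT_SIGMA_P = 0.02  # absolute, bound fractions
DEFAULT_SIGMA_ACF = 0.02  # relative, ACF values


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for a generator: kind, magnitude and seed."""

    kind: str = "additive_gaussian"
    sigma: float = DEFAULT_SIGMA_P
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative_gaussian", "additive_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng=None) -> tuple[np.ndarray, np.ndarray]:
        """Return (noisy values, per-point noise scale)."""
        rng = rng or self.rng()
        values = np.asarray(values, float)
        if self.kind == "multiplicative_gaussian":
            scale = self.sigma * np.abs(values)
        else:
            scale = np.full_like(values, self.sigma)
        # values outside [0, 1] are retained; fitters must tolerate them
        return values + scale * rng.standard_normal(values.shape), scale


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth plus design constants for one simulated experiment."""

    rates: RateSet
    fcs_free: SpeciesFcsParams | None = None
    fcs_bound: SpeciesFcsParams | None = None
    CS: float = nM(10)
    CE_grid: tuple[float, ...] = (uM(0.125), uM(0.25), uM(0.5), uM(0.75))
    T_grid: tuple[float, ...] = tuple(
        minutes(x) for x in (5, 62, 121, 177, 231, 293)
    )
    sampling_interval: float = 30.0
    duration: float = 1800.0
    dilution: float = 4000.0
    # pre-dilution concentrations of the coupled (incubation-chase) design
    coupled_CS: float = uM(2)
    coupled_CE: float = uM(6)
    label: str = ""

    def __post_init__(self):
        if self.CS <= 0 or self.sampling_interval <= 0 or self.duration <= 0:
            raise ValidationError("design constants must be positive")
        if not self.CE_grid or not self.T_grid:
            raise ValidationError("CE and T grids must be nonempty")
        if any(c <= 0 for c in self.CE_grid) or any(t < 0 for t in self.T_grid):
            raise ValidationError("grids must hold positive values")


def load_scenarios() -> dict:
    """The packaged ground-truth tables (binding, coupled, fcs)."""
    text = resources.files("rnpkinetics").joinpath("data/scenarios.yaml").read_text()
    return yaml.safe_load(text)


def binding_truth(substrate: str, enzyme: str) -> RateSet:
    """RateSet for one substrate/enzyme pair from the packaged tables (SI units)."""
    for row in load_scenarios()["binding"]:
        if row["substrate"] == substrate and row["enzyme"] == enzyme:
            return RateSet(
                kon=None if row["kon"] is None else row["kon"] * 1e3,
                koff_S=None if row["koff"] is None else row["koff"] * 1e-3,
                Kd_S=None if row["Kd"] is None else uM(row["Kd"]),
            )
    raise ValidationError(f"no packaged truth for {substrate}/{enzyme}")


def default_fcs_truth() -> tuple[SpeciesFcsParams, SpeciesFcsParams]:
    """(free, bound) single-species FCS parameters from the packaged tables."""
    fcs = load_scenarios()["fcs"]
    out = []
    for role in ("free", "bound"):
        row = fcs[role]
        out.append(
            SpeciesFcsParams(
                tau_D=ms(row["tau_D_ms"]),
                K_ph=row["K_ph"],
                tau_T=ms(row["tau_T_ms"]),
            )
        )
    return tuple(out)


def make_acf_curve(
    model: MixtureFcsModel,
    noise: NoiseSpec = NoiseSpec(kind="multiplicative_gaussian", sigma=DEFAULT_SIGMA_ACF),
    lags: np.ndarray | None = None,
    duration: float = 60.0,
) -> FcsCurve:
    """Synthetic autocorrelation curve on the standard multi-tau lag grid."""
    if lags is None:
        lags = multitau_lags()
    clean = acf_mixture(lags, model)
    noisy, scale = noise.apply(clean)
    return FcsCurve(
        lags=lags, G=noisy, sigma=scale if noise.sigma > 0 else None,
        duration=duration, label=f"synthetic p={model.p:g} seed={noise.seed}",
    )


def make_association_experiment(
    truth: ScenarioTruth, noise: NoiseSpec = NoiseSpec()
) -> list[BoundFractionSeries]:
    """Association time courses at each enzyme concentration of the design.

    Trajectories come from the full second-order binding ODE; sampling
    starts one interval after mixing (the first correlation window).
    """
    if truth.rates.kon is None or truth.rates.koff_S is None:
        raise ValidationError("truth must define kon and koff_S")
    rng = noise.rng()
    times = np.arange(
        truth.sampling_interval, truth.duration + 1e-9, truth.sampling_interval
    )
    out = []
    for ce in truth.CE_grid:
        p = simulate_association(
            truth.CS, ce, truth.rates.kon, truth.rates.koff_S, times
        )
        noisy, _ = noise.apply(p, rng)
        out.append(BoundFractionSeries(times, noisy, CE=ce, CS=truth.CS,
                                       kind="association"))
    return out


def make_dissociation_series(
    koff: float,
    p0: float = 0.95,
    noise: NoiseSpec = NoiseSpec(),
    sampling_interval: float = 30.0,
    duration: float | None = None,
) -> BoundFractionSeries:
    """A single post-dilution decay p(t) = p0 e^(-koff t), sampled and noised."""
    if koff <= 0 or not 0 < p0 <= 1:
        raise ValidationError("koff must be > 0 and p0 in (0, 1]")
    if duration is None:
        duration = min(5.0 / koff, 10800.0)
    times = np.arange(sampling_interval, duration + 1e-9, sampling_interval)
    noisy, _ = noise.apply(p0 * np.exp(-koff * times))
    return BoundFractionSeries(times, noisy, kind="dissociation")


def _chase_times(k_slow: float, p0: float, interval: float) -> np.ndarray:
    """Sampling grid: every `interval` until p < 0.05 p0 or 3 h."""
    t_stop = min(3.0 / max(k_slow, 1e-12), 10800.0)
    return np.arange(interval, t_stop + 1e-9, interval)


def make_coupled_experiment(
    truth: ScenarioTruth, noise: NoiseSpec = NoiseSpec()
) -> CoupledExperiment:
    """Dilution chases after each incubation time of the coupled design.

    For each incubation time T the pre-dilution composition is computed
    exactly, then the exact closed-form post-dilution response (never the
    two-exponential approximation) is sampled on the 30 s cadence and
    noised. Ground-truth amplitudes are attached per series.
    """
    r = truth.rates
    if r.koff_S is None or r.kcat is None or r.koff_P is None or r.Kd_P is None:
        raise ValidationError("truth must define koff_S, kcat, koff_P and Kd_P")
    CS, CE = truth.coupled_CS, truth.coupled_CE
    rng = noise.rng()
    series = []
    for T in truth.T_grid:
        fS0, fPb, _ = pre_dilution_state(CS, CE, r.Kd_P, r.kcat, T)
        times = _chase_times(r.kcat + r.koff_S, fS0 + fPb, truth.sampling_interval)
        resp = closed_form_dilution_response(r, fS0, fPb, times)
        noisy, _ = noise.apply(resp.exact, rng)
        s = BoundFractionSeries(times, noisy, CE=CE / truth.dilution,
                                CS=CS / truth.dilution, kind="dissociation")
        series.append(s)
    return CoupledExperiment(T=list(truth.T_grid), series=series, CS=CS, CE=CE,
                             dilution=truth.dilution)


def make_titration(
    truth: ScenarioTruth,
    noise: NoiseSpec = NoiseSpec(sigma=0.03),
    n_points: int = 12,
    CE_min: float = nM(10),
    CE_max: float = uM(10),
) -> list[tuple[float, float]]:
    """Equilibrium titration: p at log-spaced enzyme concentrations."""
    if truth.rates.Kd_S is None:
        raise ValidationError("truth must define Kd_S")
    ces = np.geomspace(CE_min, CE_max, n_points)
    ps = np.array([equilibrium_occupancy(truth.CS, ce, truth.rates.Kd_S) for ce in ces])
    noisy, _ = noise.apply(ps)
    return list(zip(ces.tolist(), noisy.tolist()))
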