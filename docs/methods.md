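# Methods

This note documents the models, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Binding and modification scheme

The central model is a first-order scheme for a labeled RNA substrate S
bound by an RNP enzyme E, modified on the enzyme, and released as product P:

    S + E  <--(koff_S)--  ES  --(kcat)-->  EP  --(koff_P)-->  P + E

ES is the most stable pre-reaction complex and EP the most stable
post-reaction complex; faster conformational intermediates on either side
are not resolved by bound-fraction measurements and are deliberately left
out of the fitted model (a generic `LinearScheme` simulator is provided for
forward exploration of longer chains).

After a strong dilution (default 4000-fold, to sub-nanomolar RNA), the
re-association fluxes are negligible and the system is linear:

    d[ES]/dt = −(kcat + koff_S)[ES]
    d[EP]/dt = kcat[ES] − koff_P[EP]

With bound fractions fS0 = ES(0), fP0 = EP(0) and
c = kcat/(koff_P − kcat − koff_S), the total bound fraction is exactly

    p(t) = (1 + c)·fS0·e^(−(kcat+koff_S)t) + (fP0 − c·fS0)·e^(−koff_P t)

This is genuinely a sum of two exponentials with rates k₂ = kcat + koff_S
(slow) and k₁ = koff_P (fast); the conversion flux term c only reshuffles
amplitude between them. Consequently the *rates* returned by a
double-exponential fit are unbiased even when c is not small; it is the
physical reading of the *amplitudes* (A₂ = substrate bound at dilution,
A₁ = product bound at dilution) that degrades as c grows. The pipeline
monitors c and warns when c > 0.2 (our threshold). At the tabulated
slow-complex parameters c ≈ 0.033, so the amplitude reading is good to a
few percent. `closed_form_dilution_response` returns the exact curve, the
amplitude-naive two-term reading, and their maximum deviation, so the
approximation quality is always measurable rather than assumed.

Degenerate eigenvalues (koff_P = kcat + koff_S within a relative gap of
1e−9) switch to the confluent form p(t) = (fS0 + fP0 + kcat·fS0·t)e^(−kt),
flagged on the result.

Re-association can be switched on in `simulate_dilution` to audit the
linear treatment: at 0.5 nM post-dilution RNA and the tabulated kon, it
shifts p(t) by under 5% (kon·CE ≈ 4e−5 s⁻¹, an order of magnitude below
the slowest dissociation rate), which is within the noise of a single
chase.

### Pre-dilution composition

During an incubation of length T at enzyme far above the substrate
complex's Kd, unmodified substrate is taken as fully bound, so the
unmodified fraction is e^(−kcat·T) and the product fraction
1 − e^(−kcat·T). Product partitions between free and bound states by exact
mass action: the quadratic solution is used, with the enzyme available to
product taken as CE − CS·e^(−kcat·T) (substrate sequesters enzyme
stoichiometrically). A linearized CE/(CE + Kd) partition would err by
several percent at the 6 µM enzyme / 0.32 µM Kd design point; the exact
form costs nothing.

## FCS mixture model

The autocorrelation model assumes 3-D diffusion through a Gaussian focal
volume with axial/lateral ratio κ, times a multiplicative photophysics
factor 1 + K·e^(−t/τ_T) per species (the unnormalized form, treating K as
an equilibrium amplitude; a normalized triplet-fraction variant is
available behind a flag). Free and bound species are assumed equally
bright — the label is a single dye unaffected by binding — so mixture
weights are molecular fractions.

Choices that matter:

* **κ = 5**, fixed, not fitted. The structure parameter is nearly
  unidentifiable from a single curve and, because references and mixture
  curves share it, the extracted bound fraction is insensitive to its
  exact value. It is configurable.
* **Lag grid**: quasi-logarithmic multi-tau-style cascade, 1 µs–1 s,
  14 linearly spaced lags per octave (~280 points), mirroring hardware
  correlators.
* **Weighting**: 1/σ² when per-lag errors are present, else unweighted.
  Multistart from 8 log-spaced τ_D initializations; best SSR wins, ties by
  fewest function evaluations.
* **Workflow**: reference curves (pure free, pure bound at saturating
  enzyme) are fitted first with p fixed at 0 or 1; those species parameters
  are then frozen and only (N, p) are fitted per mixture curve, with p
  bounded to [0, 1].

## Fitting machinery

All fits run through one multistart trust-region least-squares wrapper
(scipy `least_squares`, ftol = xtol = gtol = 1e−12). Rate constants are
optimized as logarithms so positivity holds by construction; amplitudes
are bounded [0, 1.2] to absorb noise overshoot above full occupancy.
Standard errors come from the Gauss–Newton covariance (JᵀJ)⁻¹ scaled by
reduced chi-square, via SVD with singular-value truncation so fits pinned
at bounds do not produce spurious infinities.

Initialization: exponential rates start from a log-linear regression of
the first/last thirds of the curve; titration Kd starts at the enzyme
concentration where p crosses half its maximum, interpolated on log CE.

The global double-exponential fit shares two log-rates across all chases
with two free amplitudes per chase. The larger fitted rate is labeled k₁.
If k₁/k₂ < 3 a weak-identifiability warning is attached; if the rates
collapse (ratio < 1.05) the fit is reported as a single exponential — the
full amplitude on the slow component, the fast rate nominal, and a pooled
single-exponential fallback fit attached.

kcat is estimated twice, from the slow amplitudes A₂(T) = b·e^(−kcat·T)
and from the fast amplitudes A₁(T) = a·(1 − e^(−kcat·T)) — the saturating
form is the physically implied complement of the decaying one — and
reported as mean ± SD of the two. No floating offset is used in the
amplitude fits.

Model comparison between single- and double-exponential descriptions of
one chase uses the extra-sum-of-squares F-test (F = ((SSR₁−SSR₂)/2)/
(SSR₂/(n−4)), α = 0.05). The double fit is seeded from the single fit, so
the nested SSR ordering holds on every input. The F-test's nominal type-I
level is approximate for nonlinear models; simulation under the null shows
rejection near the nominal 5%.

The k_obs-vs-[E] regression is closed-form weighted least squares. The
intercept is formally k_off but is flagged low-confidence: with k_obs
spanning only a few-fold over the practical concentration range, the
extrapolation to [E] = 0 is poorly conditioned, and k_off should be taken
from dilution experiments.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (truth, noise spec); identical seeds give
identical bytes. Design constants default to the study conditions: 10 nM
labeled RNA with 0.125–0.75 µM enzyme for association (30 s cadence,
30 min), 2 µM RNA + 6 µM enzyme incubated 5–293 min then diluted 4000-fold
for the coupled chases (30 s cadence until the bound fraction decays to 5%
or 3 h), and 12-point log-spaced titrations from 10 nM to 10 µM enzyme.
Noise defaults: σ = 0.02 absolute on bound fractions, 2% multiplicative on
ACF values — chosen once to match the visual scatter of such measurements;
true experimental noise magnitudes are not tabulated anywhere, so the
recovery tolerances (10–20%) are engineering choices. Noise can push p
outside [0, 1]; values are retained unclipped and the fitters tolerate
them.

Limitations to keep in mind when transferring conclusions to real data:

* ACF noise is drawn independently per lag. Real correlator noise is
  strongly correlated across lags and heteroscedastic in a
  acquisition-time-dependent way, so real parameter uncertainties are
  larger than the synthetic ones. In particular, with ~280 independently
  noised lags the bound fraction is formally constrained to ~0.006 even
  when the diffusion-time ratio is only 1.4; with correlated real noise
  that configuration is practically unidentifiable. The tests therefore
  assert the *relative* identifiability degradation (the p standard error
  grows severalfold as the ratio shrinks), not an absolute error floor.
* Bound-fraction noise is Gaussian and time-independent; real FCS
  bound-fraction estimates inherit correlated errors from the upstream
  curve fits.
* No photobleaching, drift, afterpulsing or background terms are
  simulated (out of scope).
* The generators draw trajectories from the deterministic rate equations;
  stochastic (Gillespie) fluctuations are irrelevant at the simulated
  copy numbers and are not modeled.

Passing recovery tests therefore demonstrates that the estimators are
consistent and approximately unbiased under the stated designs and noise
model — not that real measurements achieve these tolerances.

## Problem sizes

The shipped studies use 20 seeded replicates for time-course recovery
(50 for the ACF diffusion-time study), six incubation times per coupled
experiment with ~150 samples per chase, and 12-point titrations. These
sizes give stable medians while keeping any study under a minute on one
CPU; all tolerances quoted above were chosen at design time for these
sizes.

## Units and interfaces

SI internally (seconds, molar); concentrations in configuration files and
CLI options are µM, diffusion times reported in ms, incubation times
accepted in minutes via `units.minutes`. Series travel as CSV with YAML
sidecars, coupled experiments as a CSV directory plus manifest, schemes as
YAML mappings {from_state, to_state, rate_per_s}, and reports as JSON with
the timestamp isolated to a single field so repeated runs are otherwise
byte-identical.
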