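# rnpkinetics

Thermodynamic and kinetic analysis of RNA–protein enzyme binding from
fluorescence correlation spectroscopy (FCS) data, built around the H/ACA
ribonucleoprotein pseudouridine synthase: a guide-RNA-directed enzyme that
converts a target uridine to pseudouridine in a short labeled substrate RNA.

The package is for quantitative biochemists who measure binding of a
dye-labeled RNA to a large RNP by FCS and want to turn autocorrelation
curves into bound fractions, and bound-fraction time courses into rate and
equilibrium constants — including the hard case where dissociation,
on-enzyme catalysis and product release all proceed at once.

## What it computes

**Bound fraction from FCS.** A labeled RNA free in solution (~5 kD) and
bound to the RNP (~100 kD) differ in diffusion time through the confocal
volume. The autocorrelation function is modeled as a two-component mixture

    G(t) = (1/N) [ (1−p) X₁(t) D₁(t) + p X₂(t) D₂(t) ]

with Dᵢ(t) = (1 + t/τ_Dᵢ)⁻¹ (1 + t/(κ²τ_Dᵢ))⁻½ the 3-D diffusion factor and
Xᵢ(t) = 1 + Kᵢ e^(−t/τ_Tᵢ) the dye photophysics factor. The reference
parameters (τ_D, K, τ_T per species) are calibrated once from pure-free and
pure-bound controls; afterwards only N and the bound fraction p are fitted
per measurement.

**Elementary binding parameters.** Association at enzyme excess is
single-exponential, p(t) = p_eq(1 − e^(−k_obs t)), and k_obs = k_on[E] +
k_off, so k_on is the slope of k_obs against [E]. Dissociation after strong
dilution is p(t) = p(0) e^(−k_off t). Equilibrium titrations are fitted with
the quadratic tight-binding isotherm

    p = [(C_S + C_E + K_d) − √((C_S + C_E + K_d)² − 4 C_S C_E)] / (2 C_S)

which remains valid when the labeled RNA depletes the enzyme.

**Coupled dissociation–catalysis–release.** For a slowly reacting
substrate–enzyme complex, dilution starts three concurrent first-order
events: substrate dissociation (k_off,S), on-enzyme modification (k_cat)
and product release (k_off,P). The total bound fraction decays
double-exponentially with fast rate k₁ = k_off,P and slow rate
k₂ = k_cat + k_off,S. Chases recorded after different incubation times T
are fitted globally (rates shared, amplitudes per chase); the amplitudes
relax in T at rate k_cat, which disentangles all three rates. The exact
three-term solution of the post-dilution linear system is implemented
alongside as an oracle.

A seeded synthetic-data module generates every experimental design with
known ground truth, so all fitting stages are validated by parameter
recovery.

## Worked example

Simulate the six-incubation-time dilution-chase design at the tabulated
slowly-reacting-complex parameters and run the full coupled analysis:

```python
from rnpkinetics import estimate_kcat, global_double_exp_fit
from rnpkinetics.pipeline import coupled_truth_from_tables
from rnpkinetics.synthetic_data import NoiseSpec, make_coupled_experiment

truth = coupled_truth_from_tables()          # koff_S=4.5e-4, koff_P=6.4e-3, kcat=1.9e-4
exp = make_coupled_experiment(truth, NoiseSpec(sigma=0.02, seed=0))
res = estimate_kcat(global_double_exp_fit(exp))
print(f"fast rate  k1 = koff_P = {res.k1:.2e} s^-1")
print(f"kcat (amplitude decay) = {res.kcat:.2e} s^-1")
print(f"koff_S = k2 - kcat     = {res.koff_S:.2e} s^-1")
```

prints

```
fast rate  k1 = koff_P = 6.31e-03 s^-1
kcat (amplitude decay) = 1.90e-04 s^-1
koff_S = k2 - kcat     = 4.46e-04 s^-1
```

i.e. the product leaves the enzyme ~14-fold faster than the unmodified
substrate, and conversion on the enzyme proceeds at ~1.9e-4 s⁻¹ — all three
rates recovered within a few percent of the generating values
(6.4e-3, 1.9e-4 and 4.5e-4 s⁻¹) from a single noisy synthetic experiment.

The same studies are available from the console script, e.g.

```
rnpkinetics coupled-suite --seeds 20 --seed 0 --out runs/coupled
rnpkinetics table1-suite  --seeds 5  --seed 0 --out runs/table1
rnpkinetics simulate-acf --p 0 --seed 5 --out acf.csv
rnpkinetics fit-acf acf.csv --role free --out fit.json
```

Each run writes `report.json` (seed provenance, convergence flags,
config hash), `estimates.csv` and a short `report.md`.

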