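# Ground-truth parameter sets for the synthetic-data generators.
#
# binding: apparent equilibrium and kinetic parameters per substrate/enzyme
#   pair (kon in 1e3 M^-1 s^-1, koff in 1e-3 s^-1, Kd in uM; null = not
#   determined). Reactive pairs (Sub-U with WT or dGar1) have no
#   conventional koff/Kd because composition drifts during the measurement.
# coupled: the slowly-reacting-complex parameters (rates in 1e-3 s^-1;
#   kcat_prime is the single-turnover activity rate).
# fcs: single-species autocorrelation parameters of the free and
#   RNP-bound labeled RNA (tau_D in ms).

binding:
  - {substrate: Sub-U,  enzyme: WT,           kon: 27,   koff: null, Kd: null}
  - {substrate: Sub-U,  enzyme: D85A,         kon: 17,   koff: 0.69, Kd: 0.031}
  - {substrate: Sub-U,  enzyme: DEL7,         kon: 18,   koff: 12,   Kd: 0.23}
  - {substrate: Sub-U,  enzyme: R154Q,        kon: 11,   koff: 11,   Kd: 0.47}
  - {substrate: Sub-U,  enzyme: RNA-only,     kon: null, koff: 27,   Kd: 1.5}
  - {substrate: Sub-Psi, enzyme: WT,          kon: 23,   koff: 12,   Kd: 1.1}
  - {substrate: Sub-Psi, enzyme: D85A,        kon: 22,   koff: 11,   Kd: 0.9}
  - {substrate: Sub-Psi, enzyme: DEL7,        kon: 15,   koff: 14,   Kd: 0.9}
  - {substrate: Sub-Psi, enzyme: R154Q,       kon: 18,   koff: 16,   Kd: 0.8}
  - {substrate: Sub-Psi, enzyme: RNA-only,    kon: null, koff: 17,   Kd: 1.72}
  - {substrate: Sub-U,  enzyme: dGar1,        kon: 12,   koff: null, Kd: null}
  - {substrate: Sub-U,  enzyme: dGar1-D85A,   kon: 26,   koff: 0.54, Kd: 0.036}
  - {substrate: Sub-U,  enzyme: dGar1-DEL7,   kon: 8.4,  koff: 7.8,  Kd: 0.15}
  - {substrate: Sub-U,  enzyme: dGar1-R154Q,  kon: 8,    koff: 7,    Kd: 0.42}
  - {substrate: Sub-Psi, enzyme: dGar1,       kon: 27,   koff: 5,    Kd: 0.32}
  - {substrate: Sub-Psi, enzyme: dGar1-D85A,  kon: 35,   koff: 5,    Kd: 0.20}
  - {substrate: Sub-Psi, enzyme: dGar1-DEL7,  kon: 22,   koff: 12,   Kd: 0.7}
  - {substrate: Sub-Psi, enzyme: dGar1-R154Q, kon: 24,   koff: 16,   Kd: 0.83}
  - {substrate: Sub-C,  enzyme: WT,           kon: null, koff: 42,   Kd: 3.5}

coupled:
  - {substrate: Sub-U, enzyme: WT,
     koff_S: null, koff_P: 12, kcat: null, kcat_prime: 3.9}
  - {substrate: Sub-U, enzyme: dGar1,
     koff_S: 0.45, koff_P: 6.4, kcat: 0.19, kcat_prime: 0.08,
     Kd_P_uM: 0.32}

fcs:
  free:  {tau_D_ms: 0.21, K_ph: 0.15, tau_T_ms: 0.004}
  bound: {tau_D_ms: 0.47, K_ph: 0.20, tau_T_ms: 0.005}
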