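# Canonical parameter set for the decoy-rich target-search model
# (HMGB1-like system). Units are explicit; internal units are nM and s.
units:
  concentration: nM
  bimolecular_rate: per_nM_per_s
equilibrium:
  K_ai: 50.0          # autoinhibition constant [X]eq/[P]eq
  K_d_PT: 1.0         # uninhibited protein / target
  K_d_PD: 500.0       # uninhibited protein / decoy
  K_d_XT: 1000.0      # autoinhibited protein / target
  K_d_XD: 500000.0    # autoinhibited protein / decoy
forward_rates:
  k_on_PT: 0.1        # = 1e8 M^-1 s^-1
  k_on_PD: 0.1
  k_on_XT: 0.1
  k_on_XD: 0.1
  k_XP: 1000.0        # X -> P, s^-1
  k_XTPT: 1000.0      # XT -> PT, s^-1
  k_XDPD: 1000.0      # XD -> PD, s^-1
totals:
  P_tot: 200.0
  T_tot: 10.0
  D_tot: 8000.0
autoinhibition_enabled: true
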