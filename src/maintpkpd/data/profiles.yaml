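# Parameter profiles for the maintenance-therapy PKPD model.
#
# Units: rates 1/day, volumes L, concentrations umol/L, base G/L,
# slopes L/umol, variances on the scales of the respective error terms.
# omega2 entries are log-normal interindividual variances; sigma entries
# are residual (observation) error variances per channel.

# Fixed oral two-compartment plasma PK of methotrexate.  The source
# publications report these only in supplementary material, so the numbers
# below are literature-derived placeholders calibrated to produce realistic
# low-dose erythrocyte MTX exposure; override via config for other uses.
plasma_mtx:
  ka: 11.0      # 1/day  absorption
  ke: 6.93      # 1/day  elimination from central
  k_cp: 1.0     # 1/day  central -> peripheral
  k_pc: 3.5     # 1/day  peripheral -> central
  vc: 30.0      # L      central volume
  vp: 10.0      # L      peripheral volume
  f_const: 0.7  # oral bioavailability (constant mode)
  bioavailability_mode: constant

# Fixed oral one-compartment plasma PK of 6-mercaptopurine.
plasma_6mp:
  ka: 21.07     # 1/day  absorption
  ke: 15.40     # 1/day  elimination
  vc: 60.0      # L      apparent central volume (placeholder, see docs)
  f: 0.12       # oral bioavailability

# Full-model population estimates (final variant: linear peripheral MTX
# influx, Michaelis-Menten 6MP influx with population Kmm, E-TGN effect).
pkpd_final:
  theta:
    kin_mtx: 0.032     # 1/day
    keff_mtx: 0.019    # 1/day
    vmm_6mp: 0.21      # umol/L/day
    kmm_6mp: 0.14      # umol/L (no IIV)
    keff_6mp: 0.050    # 1/day
    base: 2.17         # G/L
    ktr: 0.15          # 1/day
    slope_6mp: 0.16    # L/umol
    gamma: 0.79
    inieff: 0.87
  omega2:              # from CV%: ln(1 + (CV/100)^2)
    kin_mtx: 0.109392    # CV 34%
    keff_mtx: 0.091758   # CV 31%
    vmm_6mp: 0.272771    # CV 56%
    keff_6mp: 0.255882   # CV 54%
    base: 0.070365       # CV 27%
    ktr: 0.417657        # CV 72%
    slope_6mp: 0.504465  # CV 81%
    gamma: 0.012027      # CV 11%
    inieff: 0.255882     # CV 54%
  sigma:
    E-MTX: {model: combined, add_var: 1.8e-05, prop_var: 0.024}
    E-TGN: {model: combined, add_var: 0.024, prop_var: 0.061}
    ANC: {model: proportional, prop_var: 0.25}

# MTX PK submodel estimated on its own (linear influx from the peripheral
# compartment).
mtx_pk:
  theta:
    kin_mtx: 0.031
    keff_mtx: 0.018
  omega2:
    kin_mtx: 0.109392    # CV 34%
    keff_mtx: 0.091758   # CV 31%
  sigma:
    E-MTX: {model: combined, add_var: 1.8e-05, prop_var: 0.024}

# 6MP PK submodel estimated on its own (Michaelis-Menten influx,
# population Kmm).
smp_pk:
  theta:
    vmm_6mp: 0.096
    kmm_6mp: 0.016
    keff_6mp: 0.041
  omega2:
    vmm_6mp: 0.239332    # CV 52%
    keff_6mp: 0.223144   # CV 50%
  sigma:
    E-TGN: {model: combined, add_var: 0.023, prop_var: 0.064}

# Fixed-PK comparison configuration: intracellular 6MP PK fixed
# population-wide, myelosuppression parameters from the fixed-PK model
# family (effect slope already converted to L/umol).
jost:
  theta:
    vmm_6mp: 0.096
    kmm_6mp: 0.016
    keff_6mp: 0.041
    base: 2.34
    ktr: 0.148
    slope_6mp: 0.037
    gamma: 0.769
    inieff: 0.87
  omega2:
    base: 0.070365
    ktr: 0.417657
    slope_6mp: 0.504465
    gamma: 0.012027
    inieff: 0.255882
  sigma:
    ANC: {model: proportional, prop_var: 0.25}
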