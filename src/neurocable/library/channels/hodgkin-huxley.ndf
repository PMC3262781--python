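#!ndf
# Squid-axon sodium and potassium channels, SI units, rest at -0.070 V.
# Conductance densities GBAR are S/m^2; reversal potentials EREV are V.
CHANNEL /na
  PARAMETER EREV 0.045
  PARAMETER GBAR 1200
  PARAMETER GATE_h_KINETICS hh_na_h
  PARAMETER GATE_h_POWER 1
  PARAMETER GATE_m_KINETICS hh_na_m
  PARAMETER GATE_m_POWER 3
END
CHANNEL /k
  PARAMETER EREV -0.082
  PARAMETER GBAR 360
  PARAMETER GATE_n_KINETICS hh_k_n
  PARAMETER GATE_n_POWER 4
END
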