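# Default sodium-environment relaxation parameters.
#
# These are CALIBRATED STAND-INS, not measured tissue values: the spectral
# densities (1/s) and residual quadrupole splittings (Hz) were fit so that
# the simulated steady-state relaxation weightings of the three sequences
# (NaDW, NaPACMAN, NaSIRFLA) reproduce the published per-compartment
# weighting table, and so that the agar reference reproduces the measured
# control-white-matter relative intensities as closely as the model allows.
# Override any entry for sensitivity analyses.
#
# Redfield spin-3/2 rates implied by each entry:
#   R2_fast = J0 + J1 (60%), R2_slow = J1 + J2 (40%)
#   R1_fast = 2*J1    (20%), R1_slow = 2*J2    (80%)
environments:
  intra:
    J0: 190.03655734797118
    J1: 141.26291140495556
    J2: 10.02631505692896
    fQ_hz: 0.0
  extra:
    J0: 190.03655734797118
    J1: 141.26291140495556
    J2: 10.02631505692896
    fQ_hz: 0.0
  myelin:
    J0: 1386.5088163149892
    J1: 281.07442468537675
    J2: 18.99024172239359
    fQ_hz: 514.4164245873571
    fQ_model: single-value
  edema:
    J0: 30.762665353466915
    J1: 8.948243605775632
    J2: 8.836808255086417
    fQ_hz: 0.0
  csf:
    J0: 9.0
    J1: 8.6
    J2: 8.4
    fQ_hz: 0.0
  agar:
    J0: 185.26001678877503
    J1: 185.2600167887747
    J2: 9.596296039767369
    fQ_hz: 0.0
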