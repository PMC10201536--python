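# Packaged A-T preset: surrogate surface calibration and coarse-grained
# duplex parameters.  Surface magnitudes are artifact conventions chosen to
# satisfy the qualitative orderings of the landscape; the power-law exponent
# is the A-T barrier-scaling exponent.
surface:
  step1_reverse_base: 0.10        # eV
  step1_reverse_prefactor: 0.70   # eV A^-p
  step1_exponent: 1.894
  step2_slope: 0.50               # eV/A
  step2_onset: 0.30               # A
  spt_asymmetry_intercept: 0.55   # eV
  spt_asymmetry_slope: 0.25       # eV/A
  dpt_asymmetry_intercept: 0.45   # eV
  dpt_asymmetry_slope: 0.35       # eV/A
  sequential_penalty: 3.0         # eV
  stability_epsilon: 0.005        # eV
  preset_label: AT
duplex:
  n_pairs: 14
  morse_depth_B1: 0.28            # eV (B1 is the stronger bond)
  morse_depth_B2: 0.22            # eV
  morse_width: 2.0                # 1/A
  hbond_eq_length: 2.9            # A
  stacking_k: 2.0                 # eV/A^2
  lever_arm: 4.5                  # A
  bead_mass: 150.0                # amu
  temperature: 310.0              # K
  friction: 1.0                   # 1/ps
  timestep: 0.001                 # ps
# Continuum-environment metadata only (not used by any computation):
environment:
  dielectric: 8.0
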