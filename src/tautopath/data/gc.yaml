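# Packaged G-C preset.  Differs from the A-T preset in the barrier-scaling
# exponent; the remaining magnitudes are the shared artifact conventions.
surface:
  step1_reverse_base: 0.10        # eV
  step1_reverse_prefactor: 0.70   # eV A^-p
  step1_exponent: 1.783
  step2_slope: 0.50               # eV/A
  step2_onset: 0.30               # A
  spt_asymmetry_intercept: 0.55   # eV
  spt_asymmetry_slope: 0.25       # eV/A
  dpt_asymmetry_intercept: 0.45   # eV
  dpt_asymmetry_slope: 0.35       # eV/A
  sequential_penalty: 3.0         # eV
  stability_epsilon: 0.005        # eV
  preset_label: GC
duplex:
  n_pairs: 14
  morse_depth_B1: 0.28
  morse_depth_B2: 0.22
  morse_width: 2.0
  hbond_eq_length: 2.9
  stacking_k: 2.0
  lever_arm: 4.5
  bead_mass: 150.0
  temperature: 310.0
  friction: 1.0
  timestep: 0.001
environment:
  dielectric: 8.0
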