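# Seed template for the TBP-affinity estimator.
#
# The PWM is a consensus TATA-box profile (TATAWAWR core at window positions
# 4-11, uninformative context elsewhere), given as per-position base
# probabilities in A,C,G,T column order; the loader converts probabilities to
# ln(p/0.25) log-odds.  It seeds best-window assignment only: the shipped
# defaults are produced by calibrating against the packaged marker tables,
# which replaces this PWM by a data-fitted one and refits the linear
# coefficients below.
#
# slide_scale: per-dinucleotide base-stacking energy (kcal/mol), the "sliding"
# step of TBP recognition. bend_scale: per-dinucleotide propeller twist
# (degrees), the "bending" step.  Values follow the standard dinucleotide
# property compilations; the calibrated k_slide/k_bend coefficients absorb
# units and sign.
window_length: 15
k0: 20.0
k_pwm: 1.0
k_slide: 0.0
k_bend: 0.0
residual_sd: 0.5
pwm_kind: probabilities
pwm:
  - [0.25, 0.25, 0.25, 0.25]
  - [0.25, 0.25, 0.25, 0.25]
  - [0.25, 0.25, 0.25, 0.25]
  - [0.05, 0.05, 0.05, 0.85]
  - [0.85, 0.05, 0.05, 0.05]
  - [0.10, 0.02, 0.03, 0.85]
  - [0.85, 0.05, 0.05, 0.05]
  - [0.50, 0.05, 0.05, 0.40]
  - [0.75, 0.05, 0.05, 0.15]
  - [0.45, 0.05, 0.10, 0.40]
  - [0.45, 0.10, 0.35, 0.10]
  - [0.25, 0.25, 0.25, 0.25]
  - [0.25, 0.25, 0.25, 0.25]
  - [0.25, 0.25, 0.25, 0.25]
  - [0.25, 0.25, 0.25, 0.25]
slide_scale:
  AA: -5.37
  AC: -10.51
  AG: -6.78
  AT: -6.57
  CA: -6.57
  CC: -8.26
  CG: -9.61
  CT: -6.78
  GA: -9.81
  GC: -14.59
  GG: -8.26
  GT: -10.51
  TA: -3.82
  TC: -9.81
  TG: -6.57
  TT: -5.37
bend_scale:
  AA: -18.66
  AC: -13.10
  AG: -14.00
  AT: -15.01
  CA: -9.45
  CC: -8.11
  CG: -10.03
  CT: -14.00
  GA: -13.48
  GC: -11.08
  GG: -8.11
  GT: -13.10
  TA: -11.85
  TC: -13.48
  TG: -9.45
  TT: -18.66
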