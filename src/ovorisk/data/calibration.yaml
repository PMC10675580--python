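# Calibration of the synthetic egg-composition generator, version 1.
#
# Targets are study-reported component means (mg/kg dry weight) for 70 eggs
# (55 backyard/home, 15 commercial): full min/max/mean rows for the five
# macro-minerals per egg component, in-text means for the trace/heavy
# metals (some as home/commercial rearing-system means of the edible
# white+yolk fraction), and single group-level means for the REE, TCE, PGE,
# transition/post-transition and actinide panels.  Values with no reported
# counterpart (shell levels of some metals; Fe, Se, Sb) are package
# assumptions chosen at plausible food-matrix magnitudes and are marked
# "assumed".
version: 1
n_eggs:
  home: 55
  commercial: 15
default_gsd: 1.8      # geometric SD where no range is reported
z_range: 2.5758       # ~99% of lognormal mass inside a reported min-max

# group-level fallback means for elements without an individual entry
group_means:
  ree: 0.010
  tce: 0.006
  pge: 0.004
  transition_post_transition: 0.513
  actinide: 0.023

# non-detect rates (fraction of left-censored cells per element)
group_nd:
  ree: 0.02
  tce: 0.02
  pge: 0.02
nd:
  Mn: 0.05
  Cr: 0.05

elements:
  Na:
    parts:
      white: {mean: 10266.37, min: 5900.00, max: 15373.56}
      yolk: {mean: 629.06, min: 156.75, max: 1200.11}
      shell: {mean: 653.64, min: 300.22, max: 1183.84}
  Mg:
    parts:
      white: {mean: 639.20, min: 290.55, max: 965.85}
      yolk: {mean: 176.03, min: 53.10, max: 230.45}
      shell: {mean: 1488.01, min: 738.57, max: 3000.70}
  P:
    parts:
      white: {mean: 665.93, min: 220.38, max: 1400.02}
      yolk: {mean: 3856.23, min: 1331.11, max: 5000.44}
      shell: {mean: 521.04, min: 230.29, max: 873.81}
  K:
    parts:
      white: {mean: 4151.84, min: 526.95, max: 6977.12}
      yolk: {mean: 593.43, min: 280.72, max: 921.95}
      shell: {mean: 156.72, min: 85.56, max: 346.10}
  Ca:
    parts:
      white: {mean: 453.49, min: 130.11, max: 2928.81}
      yolk: {mean: 1225.18, min: 438.15, max: 1843.34}
      shell: {mean: 74643.56, min: 40813.66, max: 139519.80}
  Al:
    parts:
      white: {mean: 5.242}
      yolk: {mean: 5.242}
      shell: {mean: 2.0}          # assumed
    systems: {home: 4.783, commercial: 6.927}
  Cr:
    parts:
      white: {mean: 13.443, max: 160.167}
      yolk: {mean: 13.443, max: 33.86}
      shell: {mean: 1.0}          # assumed
    systems: {home: 12.389, commercial: 17.306}
  Mn:
    parts:
      white: {mean: 1.0, max: 25.105}
      yolk: {mean: 1.4, min: 0.580, max: 6.27}
      shell: {mean: 0.6, max: 1.772}
    systems: {home: 1.059, commercial: 1.647}
  Fe:                             # assumed (not reported); part-uniform so no
    parts:                        # unreported discriminative structure is invented
      white: {mean: 50.0}
      yolk: {mean: 50.0}
      shell: {mean: 50.0}
  Co:                             # assumed (not reported)
    parts:
      white: {mean: 0.02}
      yolk: {mean: 0.02}
      shell: {mean: 0.02}
  Ni:
    parts:
      white: {mean: 2.400}
      yolk: {mean: 2.400}
      shell: {mean: 0.5}          # assumed
  Cu:
    parts:
      white: {mean: 2.0, min: 0.496, max: 7.828}
      yolk: {mean: 2.6, min: 1.430, max: 6.074}
      shell: {mean: 0.65, min: 0.233, max: 1.808}
    systems: {home: 2.147, commercial: 2.344}
  Zn:
    parts:
      white: {mean: 3.830}
      yolk: {mean: 33.158}
      shell: {mean: 10.0}         # assumed
    systems: {home: 18.264, commercial: 19.335}
  As:                             # assumed (reference dose reported, level not)
    parts:
      white: {mean: 0.01}
      yolk: {mean: 0.01}
      shell: {mean: 0.01}
  Se:                             # assumed (not reported), part-uniform
    parts:
      white: {mean: 0.8}
      yolk: {mean: 0.8}
      shell: {mean: 0.8}
  Cd:
    parts:
      white: {mean: 0.023}
      yolk: {mean: 0.004}
      shell: {mean: 0.004}
    systems: {home: 0.016, commercial: 0.007}
  Sn:                             # assumed (reference dose reported, level not)
    parts:
      white: {mean: 0.005}
      yolk: {mean: 0.005}
      shell: {mean: 0.005}
  Sb:                             # assumed (not reported)
    parts:
      white: {mean: 0.005}
      yolk: {mean: 0.005}
      shell: {mean: 0.005}
  Hg:
    parts:
      white: {mean: 0.121}
      yolk: {mean: 0.019}
      shell: {mean: 0.0007}
    systems: {home: 0.065, commercial: 0.086}
  Pb:
    parts:
      white: {mean: 0.957}
      yolk: {mean: 1.186}
      shell: {mean: 0.103}
  Li:
    parts: {white: {mean: 0.477}, yolk: {mean: 0.477}, shell: {mean: 0.477}}
  Cs:
    parts: {white: {mean: 0.013}, yolk: {mean: 0.013}, shell: {mean: 0.013}}
  Rb:
    parts: {white: {mean: 3.8}, yolk: {mean: 3.8}, shell: {mean: 3.8}}
  Be:
    parts: {white: {mean: 0.012}, yolk: {mean: 0.012}, shell: {mean: 0.012}}
  Ba:
    parts: {white: {mean: 6.242}, yolk: {mean: 6.242}, shell: {mean: 6.242}}
  Sr:
    parts: {white: {mean: 1.945}, yolk: {mean: 1.945}, shell: {mean: 1.945}}

# Gaussian-copula correlation blocks (latent common factors); kept sparse —
# only the correlation structure described for the measured data is emulated.
blocks:
  - name: shell_matrix
    loadings: {Rh: 0.6, Sr: 0.6, Ca: 0.6, Ti: 0.6, Cs: 0.6}
  - name: light_ree
    loadings: {Tb: 0.6, Ce: 0.6, Nd: 0.6, Dy: 0.6, Pr: 0.6}
  - name: cu_mg
    loadings: {Mg: 0.95, Cu: -0.95}

outliers:
  count: 3
  sd: 10.0          # shift in log-scale SD units
  n_elements: 8     # elements perturbed per outlier sample
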