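# Default CE-SOFA model: base SOFA + hs-cTnT-points + NT-proBNP-points
# + double AF-points (composite range 0-36).
#
# SYNTHETIC defaults: the biomarker thresholds below are the 20/40/60/80%
# quantiles of the synthetic-cohort generator's log-normal biomarker
# distributions (hs-cTnT median 50 ng/L, log-sd 1.2; NT-proBNP median
# 5000 ng/L, log-sd 1.4). They are placeholders for score arithmetic and
# simulation studies; derive cut-offs on your own training cohort with
# `cesofa derive` before any real-data use.
name: CE-SOFA
includes_base_sofa: true
schemes:
  - variable: hs_ctnt
    transform: log
    thresholds: [18.0, 37.0, 68.0, 137.0]
    weight: 1
  - variable: nt_probnp
    transform: log
    thresholds: [1540.0, 3500.0, 7130.0, 16230.0]
    weight: 1
  - variable: af
    binary: true
    binary_points: 2
    weight: 2
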