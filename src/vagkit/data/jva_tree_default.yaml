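# Default joint-vibration-analysis (JVA) style decision tree.
#
# SYNTHETIC APPROXIMATION: the published JVA tree's structure and thresholds
# are not publicly reprinted; these defaults are a reconstruction anchored on
# the reported behaviour of symptomatic joints (total integral above ~80 in
# the JVA device's pressure units, high peak amplitude, energy concentrated
# below 300 Hz). Thresholds are in device units; set `scale` to convert from
# your acquisition chain's units before traversal.
#
# Nodes are evaluated from `root`. `if_true`/`if_false` name another node or
# a leaf label (symptomatic/asymptomatic). Comparators: gt, ge, lt, le.
scale: 1.0
root: total_energy
nodes:
  total_energy:
    feature: ti
    comparator: gt
    threshold: 80.0
    if_true: low_freq_dominance
    if_false: asymptomatic
  low_freq_dominance:
    feature: ibar
    comparator: gt
    threshold: 1.0
    if_true: symptomatic
    if_false: peak_check
  peak_check:
    feature: pa
    comparator: gt
    threshold: 0.5
    if_true: symptomatic
    if_false: asymptomatic
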