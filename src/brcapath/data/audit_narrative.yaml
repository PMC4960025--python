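# Six-month service audit: patients at first appointment, by pathway.
#
# The affected group includes 10 women with a known familial mutation whose
# split between predictive-positive (pathway 2) and predictive-negative
# (pathway 3) was not recorded; it is inferred by brute force against the
# recorded affected weighted mean (see calibration.infer_affected_split).
# Four relative tests were still pending at audit close; they are allocated
# between pathways 17 and 18 at the stated 50% carrier probability.

window_label: "first appointments, 6-month audit window"
total_patients: 220

affected:
  total: 84
  counts:                 # pathway id -> patients
    1: 9                  # full screen, mutation identified
    4: 7                  # declined testing, higher risk
    5: 0                  # declined testing, moderate risk
    6: 23                 # full screen negative, higher risk
    7: 3                  # full screen negative, moderate risk
    8: 4                  # not eligible, population risk
    9: 12                 # not eligible, moderate risk
    10: 16                # not eligible, higher risk
  known_familial_mutation_total: 10   # split across pathways 2 and 3 inferred
  split_positive_pathway: 2
  split_negative_pathway: 3
  target_weighted_mean_gbp: "2083.95"

unaffected:
  total: 136
  counts:
    11: 7                 # known familial mutation, predictive positive
    12: 8                 # known familial mutation, test declined
    13: 15                # known familial mutation, predictive negative
    14: 9                 # no testing recommended, higher risk
    15: 18                # no testing recommended, moderate risk
    16: 8                 # no testing recommended, population risk
    19: 11                # relative full test negative, higher risk
    20: 0                 # relative full test negative, moderate risk
    21: 1                 # relative full test negative, population risk
    22: 32                # family untested, higher risk
    23: 5                 # family untested, moderate risk
    24: 3                 # family untested, population risk
    25: 3                 # intervening relative tested negative
    26: 3                 # family already tested negative, moderate risk
    27: 9                 # family already tested negative, higher risk
    28: 0                 # family already tested negative, population risk

pending:
  n_pending: 4            # relative positive, patient predictive result outstanding
  p_positive: 0.5
  positive_pathway: 17
  negative_pathway: 18
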