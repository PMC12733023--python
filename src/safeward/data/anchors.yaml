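# Calibration anchors for the ward safety model.
#
# Each anchor is a reported (input change, output change) pair from the
# ward's sensitivity simulations. Abscissae are expressed as changes
# from baseline: behavior anchors in multiplier increments (0.10 means
# the unexpected-behavior multiplier rises from 1.00 to 1.10), SOP
# anchors in coverage-fraction increments (0.20 means coverage rises
# from 0.10 to 0.30), the PPE anchor as the absolute proper-use
# fraction reached (0.50 means use rises from 0.40 to 0.50).

behavior_official:            # official injury-rate increase (injuries/year)
  - [0.10, 1.68]
  - [0.25, 4.28]
behavior_self:                # self-reported injury-rate increase (injuries/year)
  - [0.10, 2.31]
  - [0.25, 5.78]
sop_injury:                   # official injury-rate decrease (injuries/year)
  - [0.20, 5.71]              # coverage 10% -> 30%
  - [0.40, 6.85]              # coverage 10% -> 50%
ppe_perception:               # overall risk perception reached (%)
  - [0.50, 76.48]             # proper PPE use 40% -> 50%
sop_perception:               # overall risk perception reached (%)
  calibration: [0.20, 72.68]  # coverage 10% -> 30%: fixes the saturation amplitude
  holdout: [0.40, 69.35]      # coverage 10% -> 50%: out-of-sample check only
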