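# safeward

Occupational-safety analytics and system-dynamics simulation for a
psychiatric inpatient ward.

Psychiatric wards expose nursing staff to an unusual hazard profile:
alongside the familiar physical, chemical, biological and ergonomic
risks, patients' unexpected behaviors make physical aggression the
leading cause of injury — and aggression-related injuries are
chronically underreported. `safeward` packages the full analysis chain
a safety engineer needs to study such a ward quantitatively:

* **dual-stream injury surveillance** — official accident reports (CAT)
  next to questionnaire self-reports, with descriptive statistics and
  the underreporting gap;
* **traffic-light safety indicators** — 23 ordinal indicators scored
  0–100 and banded *very poor / poor / intermediate / good / excellent*;
* **causal-loop structure** — the ward's validated signed digraph, with
  exhaustive feedback-loop enumeration and reinforcing/balancing
  classification;
* **a stock-and-flow simulator** — explicit Euler at monthly steps over
  a one-year horizon, with unit checking and a YAML model format;
* **a calibrated ward model and sensitivity scenarios** — response
  functions fitted in closed form to reported scenario anchors, then
  exercised through the five-scenario sensitivity suite.

## The model

Three controllable inputs drive three outcomes. With `b` the
unexpected-behavior multiplier (baseline 1.0), `s` the fraction of
activities covered by standard operating procedures (SOPs, baseline
0.10) and `ppe` the fraction of staff using personal protective
equipment properly (baseline 0.40):

    official(b, s) = A₀ + a(b−1) + c(b−1)² − D_max(1 − e^{−k(s−s₀)})
    self(b, s)     = S₀ + a_s(b−1) + c_s(b−1)² − D_max(1 − e^{−k(s−s₀)})·S₀/A₀
    perception(ppe, s) = R₀ − β·100·(ppe − ppe₀) − R_max(1 − e^{−k(s−s₀)})

where A₀ = 71/7 and S₀ = 93/7 injuries/year come from the ward's
seven-year registers and R₀ = 89.35 % is the staff's overall
occupational-risk perception. Behavior acts quadratically, SOP coverage
through a saturating exponential, PPE use linearly on perception only.
Every coefficient is exactly determined by a reported anchor pair; the
perception value at 50 % SOP coverage is deliberately held out of
calibration and recovered as an out-of-sample prediction (69.35 %,
predicted 69.3518). The closed-form rates are also assembled into a
stock-and-flow model (cumulative injury stocks fed by monthly inflows)
and integrated with the Euler engine; both routes agree to 1e-9.

## Worked example

```python
>>> import safeward as sw
>>> base = sw.BaselineParams()
>>> params = sw.calibrate()            # closed form, from the packaged anchors
>>> round(params.k, 3), round(params.dmax, 3)
(8.056, 7.134)
>>> for r in sw.run_standard_suite(base, params):
...     print(r.name, round(r.delta_official, 2), round(r.delta_self, 2),
...           round(r.risk_perception, 2))
S1 0.0 0.0 76.48
S2a 1.68 2.31 89.35
S2b 4.28 5.78 89.35
S3a -5.71 -7.48 72.68
S3b -6.85 -8.97 69.35
```

Reading S2b: raising unexpected patient behaviors by 25 % adds 4.28
official injuries/year (about five whole accidents) and 5.78
self-reported injuries/year (about six), while leaving risk perception
at its 89.35 % baseline; raising SOP coverage to 50 % (S3b) prevents
6.85 official injuries/year and lowers perceived risk to 69.35 %.

The same analyses are available from a shell:

```sh
safeward synth --seed 1 --out-dir data/          # synthetic surveillance data
safeward describe --records data/injury_records.csv --years 7
safeward indicators                              # 23 banded indicators
safeward cld                                     # feedback loops R1–R3, B1
safeward simulate --json-out results.json        # sensitivity suite
```

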