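# ipmrisk

Quantitative evaluation of FMEA risk assessments for biopharmaceutical
processes. Instead of ranking process parameters (PPs) by the risk
priority number (RPN = S × O × D, a product of ordinal scores with
well-known pathologies — 88 % of the nominal 1–1000 scale is unattainable,
and different score profiles collide on equal RPNs), `ipmrisk` translates
the expert scores into a simulation:

- **severity** becomes a linear effect slope: a unit operation's critical
  CQA loss ΔCQA anchors the worst-case slope ΔCQA / (judged range ⁄ 2),
  scaled by S / S_max per PP;
- **occurrence** becomes the spread of the PP's operating condition: a
  normal centered at the setpoint with sd = (O / O_max) · judged range ⁄ 2,
  truncated to the judged range;
- a Monte Carlo **integrated process model** chains every unit operation
  to drug substance, y(uoₙ) = y(uoₙ₋₁) − Σᵢ |xᵢ − setpointᵢ| · βᵢ, and counts
  out-of-specification (OOS) events at the final specification;
- **criticality** of each PP is attributed by leave-one-out re-simulation:
  the shift in mean DS CQA and the drop in OOS probability when the PP is
  removed, ranked and thresholded per CQA, optionally refined by
  detectability-based blocking.

It is aimed at process scientists and CMC statisticians doing quality-by-
design risk assessment who want pCPP shortlists grounded in an explicit
model rather than in ordinal arithmetic.

## Worked example

Generate the 25-PP characterization study (every severity × occurrence
combination once on 1–5 scales, two unit operations, judged range [6, 8],
setpoint 7, 10 % critical ΔCQA per unit operation) and run the full
pipeline:

```
$ ipm-risk synth insilico --out ra.csv
$ ipm-risk pipeline --ra ra.csv --out-dir run --cycles 10000 --seed 42
OOS probability: 1.0000
mean DS CQA: 47.13%
criticality: run/criticality.csv
rpn_compare: run/rpn_compare.csv
manifest: run/manifest.json
```

With 25 PPs each losing part of the CQA, the mean drug-substance CQA falls
to 47.13 % of start — far below the 90 % specification, so essentially
every cycle is OOS (probability 1.0000). The per-PP attribution in
`run/criticality.csv` is where the information is:

```
uo,pp,severity,occurrence,...,mean_cqa_reduction_pct,oos_reduction,rpn,rank,...
UO1,PP_S1O1,1,1,,0.318,0.0,1,1,...
UO1,PP_S1O2,1,2,,0.616,0.0,2,2,...
...
UO2,PP_S5O4,5,4,,4.355,0.0,20,24,...
UO2,PP_S5O5,5,5,,4.598,0.0,25,25,...
```

The (S=1, O=1) PP contributes a 0.32 % mean CQA reduction (rank 1, least
critical); the (S=5, O=5) PP contributes 4.60 % (rank 25, most critical).
Reading down the table shows severity weighing more than occurrence —
e.g. PP_S5O4 (4.35 %) outranks PP_S4O5 — even where their RPNs are equal
at 20, the collision the RPN approach cannot resolve (`rpn_compare.csv`
flags these as ambiguous). `manifest.json` records seed, cycles, config
and the input digest, so the run is exactly reproducible.

The same pipeline on an RA with detectability scores additionally writes
`blocks.csv`: the ranked PPs cut into 4–6 equal blocks, each block led by
its hardest-to-detect PP, with contradicting blocks escalated to critical.

Library use mirrors the CLI:

```python
from ipmrisk import make_insilico_study, SimulationConfig, leave_one_out

table = leave_one_out(make_insilico_study(), SimulationConfig(n_cycles=10_000, seed=42))
print(table.sort_values("rank").tail(3)[["pp", "mean_cqa_reduction_pct", "rpn"]])
```

Other commands: `simulate` (DS distribution and OOS only), `rank`,
`block`, `rpn-compare`, `rpn-scale` (scale-gap report), `contour`
(severity × occurrence reduction grid), `synth random` (randomized
multi-unit-operation RAs).

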