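# Methods

## The model

`ipmrisk` turns an FMEA-style risk assessment (RA) into a quantitative
estimate of how each process parameter (PP) endangers a critical quality
attribute (CQA) at drug substance (DS), without any experimental data.
Three translations carry the whole method:

**Severity → effect slope.** Each unit operation (UO) declares the maximum
acceptable CQA loss before it is out of specification, the *critical
delta-CQA* (in % of the starting CQA). The worst-case (maximum-severity)
effect of a PP is taken to be linear in the deviation from its setpoint and
to reach exactly that critical loss at the edge of the judged range:

    critical_slope = delta_CQA / (judged_range / 2)

A PP with severity score S on a 1..S_max scale gets the proportional slope

    beta = critical_slope * S / S_max      [% CQA per PP unit]

When the setpoint is off-center the two sides of the judged range have
different widths and therefore different slopes (`beta_lower`, `beta_upper`);
a one-sided harm model (`harm_side`) zeroes the harmless side. Slopes are
stored as magnitudes; the CQA direction decides the sign.

**Occurrence → operating distribution.** The occurrence score O sets the
spread of the PP's operating condition around its setpoint:

    sd = (O / O_max) * judged_range / 2

The operating condition is a normal(setpoint, sd) truncated to the judged
range (`scipy.stats.truncnorm`), so the maximum score places one standard
deviation at the judged bounds and the minimum score concentrates the mass
near the setpoint. Note that the maximum-score case is a broad truncated
normal, *not* a uniform distribution; an optional `uniform_at_max` mode
provides the uniform reading for sensitivity analysis.

**Concatenation → integrated process model (IPM).** One Monte Carlo cycle
draws one operating condition per PP and chains the CQA through the unit
operations in process order:

    y(uo_n) = y(uo_n-1) - sum_i |x_i - setpoint_i| * beta_i(side)

(for a yield-like CQA; an impurity-like CQA adds the term instead, with an
upper DS specification). OOS probability is the fraction of cycles whose
DS value strictly violates the specification limit (default: starting CQA
minus/plus 10 %).

**Attribution.** Criticality of a PP is the change the PP causes at DS,
measured by leave-one-out: re-run the IPM without the PP and record the
shift in mean DS CQA (`mean_cqa_reduction_pct`) and the drop in OOS
probability (`oos_reduction`). PPs are ranked ascending in the mean
reduction; a per-CQA threshold (no universal default is meaningful; 10 %
is the conventional starting point) flags potential critical process
parameters. Detectability, when scored, refines the ranking afterwards:
the ranked list is cut into 4 blocks (fewer than 28 PPs) or 6 blocks
(otherwise), as equal as possible with larger blocks first; within each
block the hardest-to-detect PP is the block's most critical, and a block
whose hardest-to-detect PP is *not* its top-reduction PP is escalated to
critical wholesale, with a warning so the user can override.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `critical_delta_cqa_pct` | % CQA | from the RA | anchors the maximum-severity slope per UO |
| `s_max`, `o_max`, `d_max` | scores | 5 | conventional 1–5 FMEA scales |
| `n_cycles` | cycles | 1000 | Monte Carlo size; 10^4 in oracle tests |
| `seed` | – | 0 | single root seed; all substreams derive from it |
| `propagation_mode` | – | `per_cycle` | full error propagation through the chain; `mean_transfer` restarts each UO from the previous UO's mean (same DS mean, smaller DS variance, hence smaller OOS) |
| `ds_lower/upper_spec_pct` | % CQA | start ∓ 10 | DS specification; OOS counts strict violations |
| `loo_mode` | – | common random numbers | see below |
| `severity_reference` / `occurrence_reference` | score | scale maximum | normalizer of the score ratio; can be set to the highest score actually present in the RA, but the scale maximum makes identical RAs with different populated scores linearize identically |
| blocking threshold 28 | PPs | strict (`n < 28` → 4 blocks) | front-loaded remainder reproduces the 23 → 6,6,6,5 partition |

## Randomness and leave-one-out

Every PP draws from its own generator, seeded deterministically from
`(root seed, uo_id, pp_name)` (`SeedSequence` over CRC32 labels). The
default leave-one-out therefore uses *common random numbers*: the baseline
and every leave-one-out run share the same draws, and removing a PP simply
zeroes its additive contribution. This makes several quantities exact
rather than statistical — per-PP reductions are non-negative, and the
reductions sum to the total mean DS loss to floating-point precision —
and removes resampling noise from the ranking. Literal independent
re-simulation (`loo_mode="independent"`) is retained for fidelity to the
procedure as usually described; it agrees with the default within Monte
Carlo error but its rankings are noisier at small cycle counts.

Because the substream is keyed by `(uo_id, pp_name)`, reallocating a PP to
a different unit operation changes its draws; allocation invariance of the
mean reductions (a consequence of additivity) therefore holds within Monte
Carlo error, not exactly, and is tested that way.

## Numerical choices

- `expected_abs_deviation` integrates `|x − mean|` against the truncated
  normal density with adaptive quadrature split at the mean (the kink),
  absolute tolerance below 1e-9. It is the independent oracle for Monte
  Carlo means and supports an analytic fast path for rankings.
- Losses accumulate in float64; exactness assertions use 1e-9 absolute.
- OOS comparisons are strict (`<` lower spec, `>` upper spec); a value on
  the limit is in specification.
- Ranks use first-occurrence tie-breaking, so they are always a
  permutation of 1..n.
- `linear_effect` rejects setpoints on a judged bound (a zero-width side
  has no finite slope); the validator reports zero-width judged ranges.

## The synthetic generators and what they show

`make_insilico_study()` is the algorithm-characterization design: 25 PPs
covering every severity × occurrence combination once on 1–5 scales, split
10/15 over two unit operations, all sharing judged range [6, 8] with
setpoint 7, 10 % critical delta per UO, starting CQA 100 %. Because slopes
scale as delta-CQA over half-width, the common judged range is immaterial
for reductions expressed in % CQA (unit invariance). On this design the
package reproduces the method's qualitative signatures: reductions grow
monotonically in both scores, severity dominates occurrence, (S=1,O=1)
and (S=5,O=5) bracket the ranking, and the reduction is not injective in
the RPN — (S=4,O=5) and (S=5,O=4) share RPN 20 with distinct impacts.

`make_random_ra()` emulates the structure of a multi-step purification
process (five unit operations with 5–8 PPs each by default) with judged
ranges spanning orders of magnitude and optionally off-center setpoints.
It exercises unit-scale invariance and the asymmetric-slope path.

What the generators do **not** emulate: correlated PPs, interaction or
nonlinear effects, score uncertainty between experts, and any real
manufacturing variability — the model is strictly additive in main
effects and entirely score-driven. Passing tests demonstrate the
machinery is faithful to the stated model, not that the model describes a
particular real process.

## Problem sizes

Unit tests run 500–20 000 cycles; the oracle comparisons use 10^4 cycles
where a 4-standard-error band is asserted. The endpoint-ordering property
(extreme score combinations bracket the ranking) is checked over 100
seeded replicates of the factorial design at 10^4 cycles. The whole suite
completes in well under a minute on one CPU.

## Known limitations

- Additive main effects only; no PP interactions, no nonlinearity.
- One CQA per run; multi-CQA assessment is repeated invocation.
- Per-UO acceptance boundaries are reported (fraction of cycles below the
  UO's mean input minus its critical delta) but never censor trajectories;
  only the DS specification defines OOS.
- The impurity (lower-is-better) mode mirrors the yield math with the sign
  flipped and an upper specification; its defaults (start + 10 %) are a
  convention, not a derivation.
- The escalation stopping rule for detectability blocks is inherently a
  judgement call; the implementation escalates the whole contradicting
  block and emits a warning rather than deciding silently.
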