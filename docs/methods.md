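# Methods

## Model

One gamma cycle (~20 ms) is treated as a discrete processing step: all CA1
principal cells start from a common reset state (feedback inhibition), the
active presynaptic cells fire once and simultaneously, and each CA1 cell
either initiates an action potential within the window or does not. Activity
of a population is therefore a binary vector, and an input-output
transformation is a map between binary vectors.

**Patterns.** Input patterns carry an exact number of active cells
(k of N), drawn uniformly over index sets — not i.i.d. Bernoulli components.
This matches how the experiments are driven (a fixed count of spiking cells
per pattern) and has a real statistical consequence, see "Binomial vs exact
law" below.

**Connectivity.** Per CA1 cell and pathway, its synapse slots are wired to
distinct presynaptic cells drawn uniformly without replacement (at most one
contact per pre-post pair); wiring is frozen afterwards. Per-presynaptic
fan-out is then emergent with exactly the contact-budget mean
n_post·S/n_pre; an optional "regularized" builder wires an exactly equal
fan-out for sensitivity checks. Full-scale parameters: 23,500 CA1 cells;
CA3 pathway 28,009 cells, 4407 slots/cell, fan-out 3697; EC pathway 45,073
cells, 1918 slots/cell, fan-out 1000. The integer fan-outs/counts are
computed with floor (a partial target is not a target); the CA3 presynaptic
count 28,009 is an anatomical estimate taken as a given parameter — it is
not exactly derivable from the stated ~20%-of-18,000-targets argument
(which gives 3600, not 3697), and both directions of the arithmetic are
exposed so the discrepancy is visible.

**Response model.** The spike decision is behind a small contract
(`ResponseModel`): active slots in, {0,1} out, deterministic and frozen.
The shipped implementation is a threshold unit with per-slot weights drawn
once from a lognormal(μ=0, σ=0.5) distribution and a scalar threshold θ:
spike iff the summed weight of active slots ≥ θ. Weight heterogeneity is
required — with equal weights all cells with the same active count decide
identically — and lognormal is the conventional shape for excitatory
synaptic efficacies; constant and uniform options exist for sensitivity
analysis. Feedforward inhibition is folded into θ rather than modeled as
negative inputs: its role at the operating point is to set the effective
threshold, which the calibration sets directly. The docstring of
`response_models` specifies the adapter contract a compartmental-simulator
backend would implement (20 ms window, 10 mV somatic threshold, synapses
activated at t = 0); no such backend ships.

## Calibration

The target output probability is 0.14 per gamma window (place-cell peak
rate ~7 Hz × 20 ms). Calibration proceeds in two steps per pathway:

1. **Threshold.** θ is set by bisection so the mean output spiking fraction
   over 50 fixed random patterns at the nominal activity (5.50% CA3, 6.85%
   EC) equals 0.14 ± 0.005. Bisection is valid because the fraction is
   non-increasing in θ; with atomic drive distributions (constant weights)
   the interval collapses onto the count quantile and the nearer side is
   returned. θ stays positive so silent inputs produce silent outputs; a
   target above the fraction of cells receiving any drive raises an error.
2. **Activity.** The activity level is swept (11 geometric levels, 200
   patterns per level), the unit-amplitude Boltzmann sigmoid
   f(x) = 1/(1+exp((x_half−x)/slope)) is fitted by weighted least squares,
   and the operating activity is the closed-form inverse at 0.14. Active
   counts at proportion p are round(p·n_pre).

Numerical choices: the fit weights points by their binomial counting noise
sqrt(y(1−y)/n), with the variance floored at its y=0.02 value so saturated
points keep finite weight; the covariance is on that absolute scale (this
makes the reported standard errors cover at the nominal rate in parameter-
recovery simulations, which unweighted fitting does not). The sweep grid
spans 0.8–1.3× the nominal activity: the Boltzmann form is only a local
approximation to the network's true activation curve, which is asymmetric
in its lower shoulder, and fitting a wide grid (0.5–2.5×) drags the inverse
at 0.14 off by about two active-cell steps. Amplitude is fixed at 1
(probabilities saturate at 1). Degenerate sweeps (no visible transition)
raise rather than extrapolate.

## Hamming-distance theory

For independent spiking at probability p, a component differs between two
patterns with probability pr_HD = 2p(1−p); HD is Binomial(N, pr_HD) with
mean N·pr_HD, SD sqrt(N·pr_HD(1−pr_HD)), and expected overlap
N·p − mean/2. Two rounding modes exist because published arithmetic
sometimes carries pr_HD rounded to two decimals through the computation
(0.24 at p = 0.14 gives mean 5640); the default mode is exact. Integer
presentation of analytic means uses nearest-even rounding — HDs between
equal-count patterns are necessarily even — which is also how the
"distinct" target distance is derived from the mean; SDs round to nearest.

**Binomial vs exact law.** For fixed-count patterns the exact pairwise-HD
law is hypergeometric in the overlap: P(HD = 2j) = C(k,j)C(n−k,j)/C(n,k).
Its mean, 2k(1−k/n), is *identical* to the binomial mean — but its SD is
about 3× smaller at the sizes used here (17.4 vs 51.1 for CA3), because
conditioning on the spike count removes the count variance that dominates
the binomial spread. The binomial theory is therefore used as the
chance-level reference for means, while the normal approximation supplied
for plotting is moment-matched to whichever law it overlays (the KS
distance between the exact law and its moment-matched normal, with lattice
continuity correction, is 0.006 at CA3 scale).

## Experiment design

Four conditions: {CA3, EC} × {distinct, similar}, one pathway driven at a
time, 20 independent pattern pairs per condition. Distinct pairs are built
at the nearest-even binomial-mean HD; similar pairs at 2% of the maximal
HD min(2k, 2(n−k)), nearest-even (61.6 → 62 at CA3 scale). Pairs are built
by shared-core construction — keep k − d/2 of the first pattern's active
cells, activate d/2 fresh ones — which is uniform over equal-count partners
at distance d given the first pattern; realized HD is re-verified for every
pair. All randomness flows from three named seeds (connectivity, weights,
patterns); two runs with the same config are bit-identical.

**Desk scale.** The default configuration is a 500-cell patch: CA3-like
pathway 600 cells × 90 slots (fan-out 75), EC-like 1000 cells × 40 slots
(fan-out 20). It preserves the structural ratios that matter — CA3 has more
slots per cell and a much larger fan-out than EC, activity sits near 5–7%,
output target 0.14 — and runs end-to-end in a few seconds, which is what
makes the seed-sweep tests affordable. The "paper"-scale configuration
exists to emit the full-size analytic references; simulating 23,500 cells
with a compartmental backend is out of scope.

## What the generator does and does not emulate

The synthetic layer reproduces the statistical structure of the study —
exact-count binary patterns, exact-HD pairs, uniform random wiring with the
one-contact rule — but the neuron is a point threshold unit. Consequences:

- The required qualitative results hold and are tested: outputs spike at
  the calibrated 0.14 fraction; distinct inputs yield outputs at
  chance-level HD; similar inputs yield outputs far below chance, for both
  pathways, across seeds.
- The full-scale output numbers of the compartmental model (mean HDs
  5688/5696 for distinct, 2931/4315 for similar) are *not* reproduced and
  are stored only as reference constants for comparison tables.
- The between-pathway asymmetry is inverted: in a threshold unit the
  imprint of one changed input cell scales with its fan-out, so the
  CA3-like pathway (larger fan-out) transmits small input differences more
  strongly, whereas the compartmental model is more sensitive to EC
  differences — an effect attributed to dendritic integration, which the
  surrogate does not represent. Passing tests here say nothing about
  dendritic mechanisms.

## Known limitations

- No spike timing within the window, no rate codes, no multi-cycle
  dynamics or plasticity; inhibition is implicit in θ and the reset.
- CA3 target distributions are uniform over the patch (known to be
  non-uniform anatomically).
- Joint CA3+EC drive is supported by the response model but not validated
  against any reference.
- Desk-scale similar-pair distances quantize coarsely (2% of a small
  maximum rounds to 2), so the similar condition probes near-identical
  inputs more severely than at full scale.
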