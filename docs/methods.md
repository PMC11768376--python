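# Methods

## Scope and model

`wneval` evaluates treatments of a factorial deficit-irrigation ×
nitrogen trial on a set of agronomic indicators and ranks them with an
entropy-weighted TOPSIS score. The pipeline assumes: (i) seasonal crop
water consumption is well estimated by a one-dimensional soil-water
balance over the managed profile; (ii) the evaluation indicators are
continuous, measured without missing values, and comparable across
treatments after min-max standardization; (iii) indicator importance
can be assigned objectively from within-trial dispersion (entropy
weighting), i.e. no expert prior on importance is available or wanted.

## Soil-water balance

Stage water consumption is
`ET = 10 Σᵢ γᵢHᵢ(ωᵢ₁ − ωᵢ₂) + M + P + K − C` (mm). Gravimetric contents
are handled as *fractions* everywhere in the library; percent appears
only in formatted output. This removes the classic silent ×100 error —
the factor 10 then converts (g·cm⁻³ · cm · fraction) to mm. Defaults:
three 20-cm calculation layers (0–60 cm planned wetted layer, the
managed root zone), `K = C = 0` (deep water table, drip rates below
field capacity), both settable for other sites. The design irrigation
quota `M = 10γHP(ωⱼ − ωᵢ)` is clamped at zero when the measured content
already exceeds the target: irrigation is triggered by reaching the
lower design limit, so negative demand has no physical meaning.
Effective rainfall is accepted as an input; the library does not model
how gross precipitation becomes effective.

## Efficiency indices

WUE = Y/ET and IWUE = Y/I keep yield in t·ha⁻¹ and water in mm.
NPFP = 1000·Y/F_N converts yield to kg so the index is kg of produce
per kg of nitrogen; the factor is fixed by reconstructing the trial's
published factor-level means from its per-treatment inputs. Factor-level
summaries are means of per-treatment ratios (not ratios of means), again
matching the published summaries. NPFP is undefined (an error) for the
zero-nitrogen control, which is why the control is excluded from the
9-object evaluation matrix. Percent contrasts are always computed from
unrounded intermediates and rounded only for display.

## Indicator screening

Pairwise Pearson r with exact two-sided p-values (t transform, m−2 df).
The trial's published retained set {ET, Y, WUE, NPFP, TSS, VC} was
chosen by its authors without a stated algorithm, so screening has two
modes. `paper` (default) applies that fixed set. `auto` applies a
deterministic greedy rule: scan indicators in a priority order and drop
any whose |r| with an already-retained indicator reaches the threshold
(default 0.8). The two modes genuinely differ on the packaged data: TSS
and VC correlate at 0.99, so any threshold below that drops VC — the
greedy rule cannot reproduce the fixed set, and is offered as a
principled general alternative, not as a reconstruction. Correlations
are computed over the nine fertilized treatments (the control lacks
NPFP). p-values are reported raw, with no multiplicity correction.

## Entropy weighting and TOPSIS

Standardization is min-max per column in the tagged direction; every
non-constant column attains both 0 and 1. A constant column has no
min-max image and errors by default (`constant_policy="drop"` removes
it instead — it would carry zero information utility anyway). Entropy
uses the convention 0·ln 0 = 0, which is load-bearing because min-max
produces an exact zero in every column. Weights are
wⱼ = (1−eⱼ)/Σ(1−eₖ) and always sum to 1.

Two weighted-distance conventions circulate in the EWM-TOPSIS
literature and differ numerically: weighting the squared deviations
linearly, dᵢ± = √(Σⱼ wⱼ(zᵢⱼ−zⱼ±)²), versus measuring plain Euclidean
distance on the pre-multiplied matrix vᵢⱼ = wⱼzᵢⱼ (squared weights).
The package defaults to the linear convention — the one under which the
published two-season evaluation of the fixture trial is reproduced to
printed precision — and exposes the other as `variant="literal"`.
Under the default, with Σw = 1 and z ∈ [0,1], distances are bounded by
1. Reproducing the published tables also requires standardizing *all*
six indicators in the benefit direction, including water consumption;
users who prefer to treat ET as a cost can tag it so, with the caveat
that results then deviate from the reference evaluation.

Ranks sort closeness descending with ties broken by input (fixture) row
order; ties are measure-zero on real data and the policy exists only
for determinism. Years are evaluated independently; no pooling.

Two known irreproducibilities in the reference values are documented
rather than patched. First, the reference 2022 row for W1N3 prints
d⁻ = 0.066, T = 0.064, but W1N3 is the column-wise minimum of all six
indicators in the reconstructed matrix, which forces d⁻ = T = 0 under
every convention; the pipeline reports 0 and the reproduction report
marks that row as a known anomaly (its rank, 9, still matches). Second,
the 2023 distances and closeness values are not recoverable to 3 d.p.
from the printed (rounded) 2023 inputs under any tested convention,
though the rank order of the leading treatments is; the reproduction
report therefore checks 2023 at rank level only.

## Synthetic trials

The generator emulates the 3×3 design: water levels coded by the
midpoints of their field-capacity bands (55/65/75 %FC), nitrogen by
rate (215/270/325 kg·ha⁻¹). Yield and quality follow concave quadratic
response surfaces with an interior optimum planted at (65 %FC,
270 kg·ha⁻¹); water consumption is linear and increasing in water level
(3 mm per %FC) with a weak nitrogen term (0.15 mm per kg·ha⁻¹); noise
is independent Gaussian per indicator with defaults at the scale of the
real trial's replicate standard deviations (yield 2 t·ha⁻¹, ET 5 mm,
TSS 0.1 %, VC 2 mg·kg⁻¹). WUE and NPFP are derived through the
efficiency module from the simulated primaries, never drawn directly.
What the generator does **not** emulate: replicate/block structure,
spatial correlation, water×nitrogen interaction in ET beyond
additivity, and non-Gaussian measurement error — so passing
parameter-recovery tests demonstrates pipeline correctness under the
assumed model, not robustness to real-field artifacts.

The soil-moisture generator inverts the water balance: given true
per-stage ET and an irrigation/rain schedule, it emits layer
trajectories whose balance closes exactly (optionally with Gaussian
measurement noise on contents, which leaves recovered ET unbiased).
Infeasible trajectories (contents outside [0.01, saturation 0.45])
error out rather than clipping.

The weighting stress generator exploits a property worth stating
explicitly: because min-max standardization removes scale, entropy
weights depend only on the *shape* of a column's profile across
objects. "Uninformative" columns are therefore built as tiny jitter
shaped as a plateau with one low reading — after standardization, 1 on
m−1 objects and 0 on one, the highest-entropy min-max shape, entropy
ln(m−1)/ln m ≈ 0.946 at m = 9 — while informative columns have one
dominant object (near one-hot, entropy near 0). Tiny dispersion alone
would *not* produce low weight.

## Numerical choices and problem sizes

All fixture computations are exact desk-scale linear algebra on 9×6
matrices; the full test suite, including 100-seed Monte-Carlo recovery
runs and a 200-seed symmetry check, completes in a few seconds. Oracle
equivalence between the pipeline and a loop-based, equation-by-equation
reimplementation is asserted to 1e−10 on random 4×3 matrices for both
distance variants. CSV round-trips are asserted lossless at 6 decimals
(the write precision). Reported precision follows the reference tables:
entropy/utility to 3 d.p., weights to 2 d.p. in percent, distances and
closeness to 3 d.p.

## Limitations

Indicator weights are dispersion-driven and trial-specific: a season in
which an agronomically trivial indicator happens to vary widely will
hand it weight. Min-max standardization makes all scores relative to
the treatment set evaluated — adding or removing one treatment changes
every z, weight and closeness (rank reversal is possible, as in any
TOPSIS). The fixed retained indicator set and the all-benefit direction
convention reproduce the reference evaluation but are themselves
modeling choices a user may override.
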