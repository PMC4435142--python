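# Methods

## Model

`odorvector` predicts the perceived odor intensity (OI, on an odor
intensity referencing scale, OIRS) of an n-component odorant mixture from
threshold-normalized concentrations. Writing `x_i = ln OAV_i` with
`OAV_i = C_i / C_Thr,i`:

* individual law: `OI_i = k · x_i` (log-linear, Weber–Fechner type);
* mixture (modified Vector Model, `mvm`):
  `OI_mix = k · sqrt(Σ x_i² + 2·cosα · Σ_{i<j} x_i x_j)`.

The quadratic form is the classic Vector Model — mixture intensity as the
diagonal of a parallelogram whose sides are the unmixed intensities — with
two substitutions that remove the human panel from prediction:
intensities are replaced by `k·lnOAV`, and the per-pair interaction
coefficients are replaced by one shared `cosα`. The shared coefficient is
derived, not fitted: if measured binary-mixture OI is proportional to the
sum of the constituents' intensities with counteraction factor β
(`OI_mix = β·(OI_a + OI_b)`), substituting equal-intensity constituents
into the parallelogram cosine formula gives the closed form
`cosα = 2β² − 1`.

For n = 2, 3, 4 the generalized quadratic form reduces exactly to the
explicit binary/ternary/quaternary expansions; for n > 4 it is the only
consistent extension of those expansions under a shared pairwise
coefficient, and the package uses it for any n ≥ 1 (n = 1 reduces to the
individual law).

Baselines: classic Vector Model with a per-pair `InteractionMatrix`
(`vm`), Strongest Component Model `k·max x_i` (`scm`), and intensity
summation `Σ k·max(x_i, 0)` (`sum`, the additivity reference against
which β is fitted).

### Assumptions

* One psychophysical slope `k` for the whole chemical family (pooled
  fit); per-odorant slopes differ somewhat, and that spread is treated as
  noise.
* One interaction coefficient for all pairs — justified for odorants with
  the same functional group and similar structure (the bundled reference
  family is mono-aromatic VOCs). Different families need recalibration of
  both constants; mixing families breaks the shared-coefficient premise.
* The model was built and validated on supra-threshold components
  (`lnOAV` roughly 1.6–4.5).

## Parameters

| parameter | meaning | units | default | origin |
|---|---|---|---|---|
| `k` | OI per ln-unit of OAV | OIRS/ln | 1.07 | pooled through-origin fit, aromatic reference panel |
| `β` | counteraction factor | – | 0.66 | through-origin fit of binary-mixture OI on intensity sum |
| `cosα` | shared interaction coefficient | – | −0.129 | `2β² − 1` with β = 0.66 (−0.1288 at full precision) |

Prediction uses full precision; reports round `k` to two decimals and
`cosα` to three.

## Numerical choices

* **Sub-threshold components** (`lnOAV < 0`): excluded from the quadratic
  form by default and reported in warnings (`subthreshold="drop"`;
  `keep` and `error` available). Negative `x_i` would let the cross terms
  *raise* predicted intensity, which contradicts the counteraction reading
  and lies outside the model's validated domain. Zero-concentration
  components have no logarithm and are always dropped with a warning.
* **Negative radicand**: with `cosα = −0.129` and n equal components the
  radicand is positive iff `n − 0.129·n(n−1) > 0`, i.e. n ≤ 8; from n = 9
  mutual counteraction formally exceeds the squares. The prediction clamps
  to 0 (OI is non-negative by construction of the rating scale), sets a
  `clamped` flag and warns, rather than raising — large-n exploration
  stays possible.
* **Rounding**: model outputs are full precision. `evaluate_table` offers
  `rounding_mode="table"`, which rounds predictions half-up to one decimal
  *before* taking predicted/measured ratios — reproducing printed-table
  arithmetic — and `"full"` (default for new data). Half-up is used
  because that is how the reference tables print.
* **Through-origin regression** for both calibration fits
  (`slope = Σxy/Σx²`): the laws being estimated have no intercept — OI
  vanishes at the perception threshold (`lnOAV = 0`), and a mixture of
  zero-intensity constituents has zero intensity. Degenerate inputs
  (fewer than 2 points, all x = 0) raise a labelled error. No weighting,
  no confidence intervals beyond residual RMS.
* `cosα` is accepted only in [−1, 1] (it is a cosine); a fitted β > 1
  is rejected as geometrically invalid rather than clamped.

## Reference dataset and a known caveat

The package bundles the aromatic-compound study it was calibrated on:
seven odor thresholds (mg/m³), fifteen panel-rated binary/ternary/
quaternary mixture samples with per-component `lnOAV`, and the originally
tabulated one-decimal predictions.

Direct evaluation of the model reproduces every binary and ternary
mixture-model cell and all fifteen strongest-component cells exactly at
one decimal. The three **quaternary** mixture-model cells as originally
tabulated (5.5, 4.1, 3.3) sit ≈0.1 *below* direct evaluation of the
quaternary formula with k = 1.07, cosα = −0.129 (5.63, 4.17, 3.36) —
consistent with an intermediate rounding in the source table (the printed
cells correspond to a slope near 1.05, while all other rows require 1.07).
The package follows the formula. Consequence: the mean predictive
coefficient of the mixture model over the fifteen samples, computed in
printed-table arithmetic, comes out 0.97 rather than the originally
tabulated 0.96; the strongest-component mean, 0.78, reproduces exactly.
`scripts/acceptance.py` reports the recomputed values.

## Synthetic panel generator

`synthetic_panel` emulates the structure of the sensory measurements so
calibration and evaluation are testable without human data:

* each assessor's rating is `clamp₀(round_to_step(true_OI + N(0, sd)))`;
  the sample OI is the mean over assessors. Defaults: 9 assessors,
  sd = 0.25 OIRS units (a ±2 sd band of ≈0.5, the fluctuation commonly
  acknowledged for repeated sensory tests — the reference study reports no
  inter-assessor variance, so this default is the generator's own choice),
  rating step 0.5. `rating_step = 0` gives continuous ratings; the exact
  (1e−9) noiseless round-trip checks use it, because step quantization
  imposes a small error floor that is a separate mechanism from rating
  noise.
* individual samples: each registry odorant at 4 uniform `lnOAV` draws in
  (1.5, 4.6) — supra-threshold, matching the reference study's range;
* calibration mixtures: 4 binary designs × 8 samples, generated with
  equal-intensity constituents (the standard preparation for determining
  the interaction coefficient; it also makes `OI_mix = β·OI_sum` exact
  under the model, so noiseless calibration recovers the generating
  constants to machine precision). `OI_sum` is assembled from separately
  panel-rated unmixed constituents, as a real study measures it;
* mixture "truth" is the modified Vector Model itself, so parameter
  recovery is tested under the model's own assumptions; an optional
  uniform ±δ misspecification term perturbs the true OI for robustness
  studies.

Not emulated: assessor-specific bias or drift, odorant-specific slope
deviations, dilution-olfactometry hardware. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model, not robustness to real panels.

At the reference study's scale (7 odorants × 4 individual samples, 4
binary mixtures × 8 samples, 9 assessors, sd 0.25) the test suite checks
that `k` and `cosα` are each recovered within ±0.1 in ≥95% of 200 seeded
replicates; these sizes are the study-design defaults, and the convergence
property (error shrinking with sd ∈ {0.5, 0.1, 0.01}) uses medians over 30
seeds.

## Limitations

* Constants are family-specific; applying the aromatic defaults to other
  chemical classes (aldehydes, sulfides, mixed families) is unsupported
  extrapolation.
* The shared-coefficient simplification cannot represent pair-specific
  synergy/masking; users with measured pair data can fall back to the
  classic `vm` route via `cos_alpha_from_pair` and an
  `InteractionMatrix`.
* Only the pooled individual-odorant slope is implementable from the
  bundled data; per-odorant fits would be tighter but are not tabulated in
  the source study.
* Predictions are point estimates; rating noise of real panels (≈0.5
  OIRS between repeats) bounds achievable accuracy.
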