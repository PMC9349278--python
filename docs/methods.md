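# Methods

## Model and procedure

The package computes local feature attributions for a *series of models*
`f_k = h_k ∘ … ∘ h_1` under the interventional (baseline-splicing) view of
the Shapley value. The set function being credited is the single-baseline
lift `v(S) = f(χ^S)`, where the spliced sample `χ^S` takes the explicand's
values on `S` and the baseline's elsewhere. Three facts organize the
implementation:

1. The interventional Shapley value against an empirical baseline
   distribution is exactly the *average* of single-baseline Shapley values.
   The production estimator therefore runs one chain per baseline and
   averages at the end. Averaging the baselines first and running one chain
   is a different estimator with a known bias and is deliberately not
   offered.
2. Single-baseline attributions are cheap per stage: exact for affine maps
   (`φ̂[p,q] = W[q,p]·Δz_p`) and for tree ensembles (per-tree subset
   enumeration over the few features that can re-route the spliced sample;
   additivity over trees is exact by Shapley linearity in the game), and
   rescale-multiplier based for dense networks and elementwise transforms.
   Every stage explainer returns an `m_i × o_i` matrix whose columns sum to
   the stage's output delta and whose rows vanish for unchanged inputs.
3. Those two per-stage properties are exactly what the backward recursion
   `ψ^i = φ̂(h_i)·(ψ^{i+1} ⊘ Δf_i)` needs for layerwise efficiency: every
   intermediate `ψ^i` sums to the final output delta, so the chain can stop
   at any stage boundary and still be a valid attribution for that stage's
   inputs. Stage explainers are evaluated at the *propagated* intermediates
   `(f_{i−1}(x^e), f_{i−1}(x^b))` — this is what makes the per-stage
   efficiency statement (and hence the telescoping proof) hold.

The chained estimator is exact for all-linear compositions and an
approximation otherwise; it intentionally trades axiomatic exactness for
tractability on deep or mixed pipelines. The K-partition operator
(`k_partition_shapley`) exposes the approximation family explicitly: one
cell is the rescale rule, sign-split cells are the two-partition
"reveal/cancel" variant, singleton cells are exact.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| zero-delta tolerance | `1e-9` (relative, floor 1) | a coordinate with `|Δ| ≤ tol·max(1,|a^e|,|a^b|)` is treated as unchanged: zero attribution row at the stage, zero ratio in the Hadamard division. Shared between both sites so the two conventions cancel; exact-zero tests would be fragile after float chains. |
| efficiency tolerance | `1e-6` relative | pass/fail bound for summation-to-delta checks (`check_efficiency`, CLI strict mode). Loose enough for long float chains through trees and networks. |
| log-loss clipping | `1e-12` | keeps loss deltas finite so the chain never divides by an infinity. |
| baselines per explicand | 1000 (`subsample` convention) | the size at which seed-to-seed attribution differences become small relative to the attribution scale (measured: mean relative difference 0.03–0.10 across disjoint 1000-row subsamples on the standard fixture; the test records a 0.15 ceiling). |
| oracle cap | `m ≤ 12` | the `2^m` enumeration oracle refuses larger inputs; it exists for verification, never for production. |
| k-means | 10 restarts, k-means++ seeding | restarted Lloyd on the reduced feature columns; the within-cluster sum of squares is asserted non-increasing on every iteration of every fit. No feature scaling by default (clustering features like age/sex are chosen for interpretability; standardize upstream if desired). |

## Conventions and tie-breaks

- **Hadamard zero rule.** `a/0 := 0`, with "zero" meaning the shared
  tolerance above. At a nonlinearity with ~zero pre-activation delta the
  multiplier is 0, *not* the derivative: this preserves efficiency and the
  unchanged-input ⇒ zero-credit property through the chain. A
  `gradient_fallback` flag on the dense explainer restores
  derivative-at-the-explicand behavior for users who want classic backprop
  semantics; it is excluded from the efficiency guarantees.
- **K-partition within-cell split.** Cell credit is divided in proportion
  to `β_iΔx_i`. When a cell's total linear delta is ~zero the credit is
  split uniformly over the cell's changed features (warned); a cell with no
  changed feature is a dummy player and keeps zero. The uniform fallback is
  a package choice — any within-cell split consistent with "propagate
  linearly" degenerates there.
- **Group renormalization.** Raw group values are member sums; groups plus
  the residual group are rescaled by the single factor
  `Σφ / (Σ raw + raw_residual)` so the grouped total conserves attribution
  mass. The printed form of the renormalization in the field is
  self-referential; the uniform conservation factor is the reading that
  matches its stated intent (discount excess mass from shared members).
  Whether the residual participates in rescaling is genuinely open; both
  behaviors ship (`residual_fixed`), with symmetric rescaling the default.
- **Trees.** Splits route left on ties (`x ≤ t`). Tree attribution
  enumerates subsets of the features on the union of reachable
  explicand/baseline paths — exactness (oracle equality) is the contract,
  the algorithm is an implementation detail; the enumeration refuses more
  than 18 live features per tree.
- **Ablation.** Progressive masking of the top-k *ranked* features (the
  indicator-complement variant is available as `keep_top_k` for audits).
  Rankings are per-sample, ties break by feature index; in the positive
  (negative) direction only positively (negatively) attributed features are
  eligible, so curves flatten when eligible features run out. The default
  imputation row is the mean of the active baseline distribution.
- **Cluster selection.** Nearest cluster by squared distance in the reduced
  space; ties go to the lowest cluster index. The explicand's own row stays
  in its cluster's baseline set unless explicitly excluded.

## What the synthetic fixtures emulate — and what they do not

The generator produces block-correlated Gaussian features with planted
logistic-link labels, dummy features (coefficient zero, never split on),
and three pipeline templates: stacked proprietary scores with passthrough
features (modeled as identity rows in the first linear stage so the chain
needs no special cases), a dense extractor feeding a tree ensemble, and a
fitted logistic model extended by probability and log-loss transforms with
a planted covariate shift (one feature rescaled for half the rows, as when
a unit change slips into a deployed pipeline). Model fitting inside
fixtures is deliberately minimal (closed-form or few-step full-batch
gradient descent).

Passing tests on these fixtures demonstrates the *estimator's* properties —
efficiency, oracle agreement, bias mechanisms, ordering quality — not that
attributions on real clinical or financial data will be scientifically
meaningful: real data have non-Gaussian marginals, missingness, categorical
encodings and label noise the generator does not model, and real pipelines
are deeper and wider than the test sizes below.

## Problem sizes used in verification

Oracle comparisons use 50 fixtures with `m ≤ 8`; layerwise-efficiency
sweeps use 50 mixed four-stage series with `m ≤ 20`; the decomposition
identity uses `m ≤ 6` with up to 20 baselines; ablation comparisons average
20 seeds (30 explicands, 50 baselines each) and the loss-direction
comparison 10 seeds (40 explicands); baseline-consistency uses two disjoint
1000-row subsamples of a 4000-row training set. These sizes make the whole
verification run complete in well under a minute on one CPU while keeping
every check at full precision.

## Known limitations

- Only scalar-output chains are explained (`o_k = 1`); intermediate stages
  may be wide.
- The observational (conditional-expectation) lift and causal-graph
  variants are out of scope; attributions here describe what the model
  algebraically uses, not information content under feature correlation.
- Tree ensembles must be sums of binary axis-aligned trees with scalar
  leaves; dense stages support the five listed activations only (no
  convolution, pooling or attention).
- Chained attributions on nonlinear stages are approximations to the exact
  interventional Shapley values of the composition; the oracle and the
  K-partition operator exist precisely to quantify that gap on small cases.
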