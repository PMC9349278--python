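# Model JSON schema (version 1)

A series of models is stored as a single JSON document:

```json
{
  "version": 1,
  "stages": [ <stage>, ... ]
}
```

Stages are applied in order; stage `i+1`'s input width must equal stage
`i`'s output width. Chain explanation additionally requires the final stage
to have a single output.

## Stage kinds

### linear

```json
{"kind": "linear", "weights": [[...], ...], "intercept": [...]}
```

`weights` has shape `(o, m)`; `intercept` (optional, default zeros) has
length `o`. Evaluates `z -> W z + b`.

### tree_ensemble

```json
{"kind": "tree_ensemble", "n_features": m, "trees": [ <tree>, ... ]}
```

Prediction is the sum over trees; the output is scalar. Each tree is a set
of flat, parallel node arrays indexed by node id (root = 0):

```json
{"feature":   [0, -1, -1],
 "threshold": [0.5, null, null],
 "left":      [1, -1, -1],
 "right":     [2, -1, -1],
 "value":     [null, 0.0, 1.0]}
```

`feature[i] < 0` marks a leaf with value `value[i]`. Internal nodes route a
sample left iff `x[feature] <= threshold` — **ties go left**. Feature
indices must be `< n_features` and every path must terminate at a leaf.

### dense

```json
{"kind": "dense", "layers": [
  {"type": "affine", "weights": [[...], ...], "bias": [...]},
  {"type": "activation", "name": "relu"},
  ...
]}
```

Layers alternate freely but must start with an affine layer and chain
dimensionally. Supported activation names: `relu`, `sigmoid`, `tanh`,
`identity`, `square`.

### transform

```json
{"kind": "transform", "transform": "sigmoid", "n_features": 1, "label": 1}
```

Elementwise scalar map (input and output widths equal). Kinds:

| kind              | map                                          |
|-------------------|----------------------------------------------|
| `sigmoid`         | log-odds → probability                       |
| `log_odds_to_prob`| alias of `sigmoid`                           |
| `negate`          | `z → −z`                                     |
| `log_loss`        | probability → cross-entropy vs. fixed `label` |

`label` (0 or 1) is required for `log_loss` only; probabilities are clipped
to `[1e−12, 1 − 1e−12]` so loss deltas stay finite.

## Errors

Schema violations raise errors carrying the JSON path of the offending
element (e.g. `$.stages[1].layers[2]`), including: unknown stage kinds or
activation names, missing required fields, inconsistent dimensions between
consecutive stages, and malformed tree node arrays.

## Tabular data

All tabular inputs (explicands, baselines, training data) are CSV with a
header row, one sample per row, features in the model's input order.
Attribution CSVs reuse the explicand header's feature names.
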