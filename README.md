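# ordcausal

Confounder adjustment for **ordinal outcomes**: weighted proportional-odds
cumulative-logit regression, gradient-boosted propensity-score weighting
(stabilized IPTW and ATT), covariate-balance diagnostics, and a Monte-Carlo
framework that quantifies how well covariate adjustment, propensity
weighting, and their combination remove confounding bias — under both a
correctly specified and a deliberately misspecified confounder model.

It is aimed at biostatisticians and quantitative social scientists who
analyse observational studies with Likert-scale outcomes (adherence scores,
symptom ratings, attitude items) and a non-randomised binary exposure.

## The model

Outcomes `Y ∈ {1..J}` follow a proportional-odds cumulative logit with the
minus sign convention of mainstream ordinal-regression software:

```
logit P(Y_i ≤ j) = α_j − (β X_i + γ Z_i),    j = 1..J−1
```

so a positive treatment coefficient β shifts probability mass toward higher
categories, and `OR = exp(β)` is the treatment odds ratio. The simulation
study draws a confounder `Z ~ U(0,1)`, assigns treatment `X ~ Bernoulli(Z)`
(scenario 1) or `Bernoulli(Z²)` (scenario 2, where an analysis linear in Z
is misspecified), and compares four estimators of β:

| method | outcome model | propensity weights |
|--------|---------------|--------------------|
| A | `Y ~ X` | — |
| B | `Y ~ X + Z` | — |
| C | `Y ~ X` | stabilized IPTW |
| D | `Y ~ X + Z` | stabilized IPTW |

Propensities come from a gradient-boosted classifier (depth-3 trees; the
boosting iteration is chosen by the mean-|SMD| balance criterion, with the
configured tree count as the maximum). Stabilized weights are
`WS = p_x/π̂` for treated and `(1−p_x)/(1−π̂)` for controls. Performance
per design cell is summarised by the average relative bias
`ARebias = mean((β̂_k − β)/β)` and the MSE over K replicates.

A synthetic vaccination-hesitancy survey generator and an applied pipeline
(outcome recode 7→5, sampling-weighted fits, ATT weighting with
`w = 1` for treated and `π̂/(1−π̂)` for controls, SMD/ESS balance
diagnostics, and full-pipeline bootstrap CIs) exercise the same machinery
end-to-end on realistic survey structure.

## Worked example

```python
from ordcausal import SimulationDesign, run_grid

report = run_grid(
    [SimulationDesign(scenario=1, n=2000, beta=0.25, gamma=1.0)],
    K=200, methods=["A", "B"], seed=7,
)
print(report[["method", "arebias", "arebias_se", "mse"]].to_string(index=False))
```

```
method  arebias  arebias_se      mse
     A 1.334617    0.022726 0.117749
     B 0.045771    0.027049 0.009231
```

The unadjusted estimator overstates the treatment log-odds by ~130% of its
true value (β̂ absorbs the confounder's effect, since treated units have
systematically higher Z), while covariate adjustment is unbiased to within
Monte-Carlo error and has an order of magnitude smaller MSE.

The applied workflow runs from the command line:

```bash
ordcausal synth-survey --n 1468 --seed 1 --out survey.csv
ordcausal applied --in survey.csv --outcome mask_use \
    --trees 300 --learning-rate 0.05 --boot 200 --seed 2 --out table.csv
ordcausal balance --in survey.csv --trees 300 --learning-rate 0.05 \
    --seed 3 --out love.csv
```

`applied` prints the odds-ratio table for methods A–D (Wald CIs for the
unweighted fits, percentile-bootstrap CIs for the propensity-weighted
ones) and the control-group effective-sample-size reduction; `balance`
writes tidy love-plot data (SMD per covariate before/after weighting).

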