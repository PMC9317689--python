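# selindex

Multi-trait selection-index analysis for plant breeding trials: simulate
balanced multi-environment trials with a known genetic architecture, estimate
genotype means (BLUEs) and genetic/phenotypic covariance matrices, build
Smith linear phenotypic selection indices (LPSI) and their null-restricted
variants (RLPSI), sweep large grids of economic weights, and truncation-select
superior genotypes.

It is aimed at breeders and quantitative geneticists who want to compare
single-trait and multi-trait selection — in particular when key traits are
genetically antagonistic, such as grain yield and grain protein content (GPC)
in spring wheat — and to study how the choice of economic weights changes the
selection outcome.

## The model

The net genetic merit of line *i* is `H_i = w'g_i`, where `g ~ MVN(0, C)` are
true genotypic values with genetic covariance `C` and `w` holds fixed economic
weights. The Smith index `I_i = b'y_i` on phenotypes `y` (here genotype BLUEs
with entry-mean phenotypic covariance `P`) uses the merit-optimal coefficients
solving

```
P b = C w
```

which maximize `rho_HI = w'Cb / sqrt(w'Cw · b'Pb)`, the correlation between
index and merit. Truncating at the top fraction *p* with standardized
intensity `k` gives the response to selection and per-trait expected gains

```
R = k · sigma_H · rho_HI        E = k · C b / sigma_I
```

with `sigma_H = sqrt(w'Cw)` and `sigma_I = sqrt(b'Pb)`. The constrained index
(Kempthorne–Nordskog null restrictions; Mallard predetermined proportional
gains) projects the Smith coefficients, `b = K·beta` with
`K = I − P⁻¹M(M'P⁻¹M)⁻¹M'` and `M' = D'U'C`, so the expected gain of every
restricted trait is exactly zero (null mode) or held to fixed ratios
(proportional mode).

Covariance matrices come from balanced two-way MANOVA mean cross-products:
`C = (MCP_G − MCP_GE)/(r·e)` and `P = MCP_G/(r·e)` (the covariance of genotype
means over `e` environments and `r` replicates), and entry-mean broad-sense
heritability is `H² = σ²_g / (σ²_g + σ²_ge/e + σ²_ε/(e·r))`.

## Worked example

The built-in wheat generator emulates a 196-cultivar panel, four traits
(days to maturity, plant height cm, grain yield t/ha, GPC %), five
conventional + four organic environments, two replicates, with antagonistic
genetic correlations (yield–GPC −0.56, yield–height −0.47, yield–maturity
+0.50). Run the whole pipeline — simulate, estimate, sweep the default
2304-combination weight grid under three scenarios (LPSI, RLPSI yield = 0,
RLPSI GPC = 0), shortlist weights, select the top 10 % per management, and
report consensus genotypes:

```python
from selindex.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo_run", seed=1,
    criteria={"max_gain": {"maturity": 1.5, "height": 2.5},
              "min_gain": {"yield": 0.0, "gpc": 1.0},
              "min_response": 80, "min_correlation": 0.80},
)
run_pipeline(cfg)
```

The shortlist (`demo_run/best_weights.csv`) from this exact run:

```
 w_maturity  w_height  w_yield  w_gpc scenario  E_maturity  E_height  E_yield  E_gpc  response  rho
       -1.0      -1.0    120.0   50.0     LPSI        0.82     -5.32     0.26   1.02     86.27 0.83
       -5.0      -1.0    130.0   50.0     LPSI        0.16     -5.74     0.24   1.01     86.80 0.82
       -1.0      -1.0    140.0   60.0     LPSI        0.79     -5.05     0.23   1.08    101.66 0.83
       -1.0      -5.0    120.0   60.0     LPSI        0.36     -6.67     0.23   1.00    120.79 0.84
       -5.0      -1.0    150.0   60.0     LPSI        0.23     -5.43     0.22   1.09    101.87 0.82
```

Each row is one (weight vector, scenario) cell: `E_*` are the expected
genetic gains per cycle in trait units (e.g. +0.26 t/ha yield and +1.02 %
GPC for weights (−1, −1, 120, 50)), `response` the predicted merit gain, and
`rho` the index–merit correlation. The run manifest reports 30 selection
sets (5 weights × 3 scenarios × 2 managements) and the consensus genotypes
selected under all shortlisted weights in at least two scenarios.

The same pipeline is available from the shell:

```sh
selindex run-all --config demo.yaml
selindex sweep --outdir demo_run --seed 1   # re-run one stage from artifacts
```

## Layout

- `selindex.simulate` — trial generator and the wheat default spec
- `selindex.estimation` — BLUEs, variance components, C/P matrices
- `selindex.indices` — LPSI/RLPSI coefficients and selection parameters
- `selindex.sweep` — weight grids, sweep evaluation, ANOVA, shortlisting
- `selindex.select` — truncation selection, differentials, consistency
- `selindex.pipeline`, `selindex.cli` — reproducible end-to-end runs

See `docs/methods.md` for modelling assumptions and numerical choices.
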