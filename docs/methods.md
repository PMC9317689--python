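# Methods notes

## Model and procedure

The package operates on the classical two-stage quantitative-genetics
pipeline for multi-environment trials (METs):

1. **Trial model.** A plot phenotype is
   `y_ijk = mu + g_i + env_j + ge_ij + eps_ijk` per trait, with genotypic
   values `g_i ~ MVN(0, C)`, genotype-by-environment deviations
   `ge_ij ~ MVN(0, GE)` independent across environments (a
   compound-symmetry genotype effect), and plot residuals
   `eps_ijk ~ MVN(0, Sigma)`. Environment main effects are nuisance shifts
   that cancel from every genotype contrast.
2. **Estimation.** Genotype adjusted means (BLUEs) from a two-way
   genotype + environment fixed-effects fit; on complete balanced data this
   is the plain genotype mean, and variance/covariance components come from
   the closed-form balanced ANOVA / MANOVA moment equations
   (`sigma2_e = MS_err`, `sigma2_ge = (MS_GE − MS_err)/r`,
   `sigma2_g = (MS_G − MS_GE)/(r·e)`, and their mean-cross-product
   analogues for matrices). REML on a mixed model is the common field
   practice for unbalanced data; for balanced data the two coincide, and the
   closed forms have the advantage of being verifiable against hand
   arithmetic. Unbalanced data are accepted only by the BLUE path (least
   squares); the moment estimators reject them.
3. **Index machinery.** Smith coefficients `b` solve `P b = C w`; the
   constrained family (null restrictions, predetermined proportional gains
   via the Mallard contrast matrix) projects `b = K·beta` with
   `K = I − P⁻¹M(M'P⁻¹M)⁻¹M'`, `M' = D'U'C`. `K` and the associated `Q`
   are oblique projectors (`QQ = Q`, `KK = K`), which the tests verify
   directly; the null-restricted gains vanish to numerical precision.
4. **Sweep and selection.** Every weight vector of a Cartesian grid is
   evaluated under every scenario; weight levels are compared per trait by
   one-way ANOVA (a factorial fit is deliberately not the default — the
   per-factor analysis is simpler to read and matches how breeders screen
   weight levels trait by trait); shortlisting filters on joint gain /
   response / correlation thresholds and ranks deterministically (target
   gain, then rho, then response, then lexicographic weight order — the tie
   chain makes results invariant to row order). Truncation selection keeps
   `m = round-half-up(p·n)` genotypes (196 → 20 at p = 0.10); exact ties at
   the cutoff are all included and the expansion is logged.

## Entry-mean basis

Indices are applied to BLUEs, so `P` is defined as the covariance of
genotype means across the selected environments (`MCP_G/(r·e)`), not the
plot-level phenotypic covariance. This makes `diag(P) ≥ diag(C)` an
invariant and makes `b` directly applicable to the BLUE table. All reported
selection parameters (R, E, rho) depend on this choice; a plot-basis `P`
would shrink `b` further and is not offered.

## Selection intensity

`k` defaults to the infinite-population truncation value
`phi(z)/p` (1.755 at p = 0.10). With a finite candidate set the realized
standardized differential is smaller; `selection_intensity(p, n=...)`
returns the expected mean of the top `round(p·n)` of `n` standard normal
order statistics (Blom approximation, k ≈ 1.73 for the top 20 of 196). The
theory-versus-simulation test uses the finite-sample value because it
compares against the realized mean of exactly 20 selected genotypes; at 200
replicates the ~2 % gap between the two intensities is resolvable and using
the infinite-population value would bias the predicted gains upward.

## The wheat default generator

`default_wheat_spec` emulates a 196-genotype spring-wheat panel with four
traits — days to maturity (d), plant height (cm), grain yield (t/ha), grain
protein content (%) — in 5 conventional + 4 organic environments, 2
replicates (3528 plots). Calibration targets, and what is choice versus
target:

- **Genetic correlations.** yield–GPC −0.56, yield–height −0.47,
  yield–maturity +0.50 are the anchoring antagonisms. The remaining three
  pairs (maturity–height 0.15, maturity–GPC −0.30, height–GPC 0.10) are not
  pinned by data; they are mild values consistent with the qualitative
  pattern (late lines slightly taller and lower in protein) chosen once and
  kept. The resulting correlation matrix is verified positive definite.
- **Scales.** Genetic SDs (3 d, 7 cm, 0.55 t/ha, 1.25 %) and means (89 d,
  89 cm, 4.8 t/ha, 14.3 %) put simulated genotype-mean ranges at roughly
  81–97 d, 71–107 cm, 2.8–6.7 t/ha and 10.6–17.7 %.
- **Noise.** G×E and residual variances are set per trait as multiples
  (1.0–2.5× and 1.6–5×) of the genetic variance so that entry-mean
  heritabilities land at 0.71/0.63/0.50/0.76 (conventional, e = 5) and
  0.67/0.57/0.44/0.71 (organic, e = 4) — inside the 0.32–0.80 band typical
  of such panels. No G×E covariance structure beyond sharing the genetic
  correlation matrix (scaled) is imposed; sharing the structure guarantees
  positive semi-definiteness and is a documented choice, not an estimate.
- **Environment effects.** Drawn once per environment with SDs (2 d, 5 cm,
  0.6 t/ha, 0.8 %); free parameters, since they cancel from all contrasts.

What the generator does **not** emulate: spatial field trend and incomplete
blocks (the layout is complete and balanced; real trials are lattice
designs), year/weather covariates, heteroscedasticity across environments,
marker data, and any management-specific mean shift (conventional and
organic environments differ only through their random draws). Passing
tests therefore demonstrate the correctness of the estimators and index
algebra under the stated model, and the self-consistency of theory and
simulation — not robustness to field-data pathologies.

## Numerical choices

- `P b = C w` and all projector solves use a Cholesky factorization;
  a failure raises with conditioning advice, and a pseudo-inverse fallback
  exists only behind `allow_pinv=True` (logged).
- `ensure_psd` clips eigenvalues below a floor (default 1e−8) and returns
  well-conditioned inputs untouched; estimated C matrices on small samples
  routinely need the repair and every repair is logged.
- Negative variance-component estimates are truncated at zero and flagged;
  single-environment or single-replicate layouts return the inestimable
  component as zero with a warning.
- Degenerate inputs: zero-variance index or merit is rejected; an empty
  restriction set returns the Smith coefficients exactly (same array); a
  single proportional-gain restriction imposes no contrast (empty Mallard
  matrix) and likewise returns the Smith coefficients.
- Missingness is represented by absent plot records; `mask_plots` always
  retains at least one record per genotype.

## Problem sizes in the test suite

Monte-Carlo checks use 200 replicate simulations of the full 196 × 9 × 2
panel for the gain-recovery test (three standard errors of 200 replicates
resolve gains to ~0.01–0.2 trait units), 25–30 replicates for covariance
and component recovery, and 1000 random matrix instances for the
restriction-nullity property. These sizes make the whole suite run in well
under a minute while keeping the 3-SE bands tight enough to detect scale
errors in `k`, `sigma_I` or the MCP denominators.

## Known limitations

- Moment estimation requires balance; there is no REML path for
  unbalanced covariance estimation (drop or impute first).
- The economic-weight ANOVA treats each trait's weight as a one-way factor;
  interactions between weight dimensions are visible only through the grid
  itself.
- Consistency analysis counts a genotype as selected for a
  (scenario, weight) context if it is selected in any dataset of that
  context; per-dataset consensus requires filtering the selection sets
  first.
- `rho_HI` is clipped into [−1, 1] to absorb rounding at the 1e−12 level;
  a clip larger than that indicates inconsistent (C, P) inputs and will
  surface in the projector tests instead.
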