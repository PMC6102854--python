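# Methods

## Model and procedure

screenorm treats a genetic screen as long-format observations
(feature, well type, cell line, replicate, optional plate, readout), where
well types are library features, negative controls (normal viability) and
positive controls (lethal phenotype).  Normalization proceeds in five steps
per replicate k:

1. **Lethality scores.**  Z_ik = (readout − median neg) / (median pos −
   median neg), using the control medians of the record's own scoring scope
   (replicate, or plate when `scope="plate"`).  The scope's negative-control
   median maps exactly to 0 and its positive-control median exactly to 1.
   The formula is orientation-free: negating all readouts negates numerator
   and denominator alike, so no assay orientation needs to be assumed here.
   Additive plate effects shift library wells and controls together, so
   plate-scoped medians cancel them exactly.
2. **Core set.**  A per-replicate multiset of score *values* (not features)
   assumed to represent phenotypes common to all screens.  Percentile rule:
   values at or below the empirical `alpha_high` quantile of the replicate's
   library scores (two-sided with `alpha_low > 0`); distance rule: values v
   with |v − m_N| ≤ γ·|v − m_P|, where m_N, m_P are the replicate's scored
   control medians.  Values tied with a boundary are all included.
3. **Quantile grids.**  Each core is summarized by its empirical quantiles
   at probabilities j/n, j = 1..n (n = 1000 by default), so cores of
   different sizes become comparable; the target grid is the elementwise
   mean across replicates.
4. **Linear re-expression.**  OLS of the mean grid on the replicate's grid
   yields intercept a_k and slope b_k, which reproduce the quantile
   alignment exactly whenever the quantile–quantile relation is linear and
   approximate it in least-squares sense otherwise.
5. **Tail extension.**  Inside [Z^min_k, Z^max_k] the map is a_k + b_k·Z;
   above Z^max_k it is a_k + (b_k − 1)·Z^max_k + Z (a pure shift by the same
   amount as the core maximum), and symmetrically below Z^min_k.  The map is
   continuous at both bounds and, with b_k > 0, strictly increasing, so tail
   exceedance proportions are preserved exactly.

### Lower-tail variants

The reflecting lower-tail form a_k + (b_k + 1)·Z^min_k − Z (slope −1 in Z)
is available as `tail_mode="literal_reflect"`.  It is continuous at Z^min_k
but reverses ranks in the lower tail, contradicting the principle that
outside scores move by the same amount as the nearest core value; the
order-preserving shift is therefore the default.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha_high` | 0.95 | fraction of the score distribution treated as common across screens; 0.90–0.95 is sensible for same-condition screens.  Accepts a mapping per replicate or cell line: a condition expected to yield ~20% hits should use ~0.80 so the hits stay outside the core. |
| `alpha_low` | 0 | lower-tail trim for screens where increased proliferation is a real phenotype. |
| `gamma` | 1.0 | distance rule: keep values closer to the negative than γ times the distance to the positive controls. |
| `n_quantiles` | 1000 | grid length; results are insensitive above a few hundred for genome-scale libraries. |
| `scope` | replicate | `plate` activates plate-local control medians (arrayed screens). |
| denominator tolerance | 1e−8 | minimum |median pos − median neg| on the transformed scale; smaller spans raise an error naming the scope. |

Degenerate cores (all values identical, e.g. all-zero positive-control
counts propagating into a constant grid) cannot identify a slope; the fit
falls back to pure centering (b = 1) with a warning rather than failing,
since such data occur in practice in pooled screens.

Control-count guidance enforced by `validate_controls`: ~20 of each control
type per pooled replicate; 4 of each per arrayed plate, with an absolute
minimum of 2 (ERROR below that).  `filter_reference_controls` demotes
candidate positive controls that are not consistently lethal — by default a
control counts as lethal in a replicate when its readout lies beyond the
0.10 library quantile on the lethal side (`lethal_direction`, default
`low`); the threshold quantile and the required number of replicates are
caller-supplied.  This rule is a documented interpretation: orientation and
the lethality criterion are configuration, not assumptions.

## Hit analysis

Per library feature, OLS of the score on an intercept, a two-level group
factor and optional numeric covariates; two-sided t-test on the group
coefficient (the coefficient is for the lexicographically second group
level); Benjamini–Hochberg step-up adjustment across features (via
statsmodels), with NaN p-values excluded.  `moderation="pooled"` shrinks the
per-feature residual variance toward the across-feature mean with weight
df/(df + d0) (default d0 = 4) and tests on df + d0 degrees of freedom — a
deliberately simple moderated-variance option, not a full empirical-Bayes
fit with estimated prior degrees of freedom.  Concordance between two hit
tables reports the 2×2 cross-tabulation on the common feature set, with
agreement/discordance fractions, confirmation fractions relative to the
first (primary) table, and both conventions for the not-significant overlap
(over the union of NS sets, and over the common total), since either
denominator is defensible.

## The synthetic generator

`SimulationConfig` defaults encode the study conditions the package is
evaluated under: 6 cell lines × 3 replicates; 1000 library features with
means μ_i ~ Beta(2, 6) (E = 0.25) and sd 0.2; 200 negative controls
~ N(0, 0.1²) and 200 positive controls ~ N(1, 0.1²) per replicate; a
stretch/contraction factor (0.7, 1, 1.4) per cell line multiplying the
*means* of library features and positive controls (negative-control means
are 0, so mean- and value-scaling coincide for them up to the noise term;
mean-scaling keeps the noise sd homogeneous and is the implemented choice);
in with-effect mode the first 200 features (a deterministic truth mask, for
test stability) get mean 0.5 in cell lines 4–6.  The stretch factors are
balanced across the two comparison groups, making the stretch orthogonal to
the group effect.  μ_i is drawn once per feature and shared across
replicates by default — features keep a consistent identity, as in real
libraries — with `mu_per_replicate=True` available for fully independent
draws.  `pos_bias` adds a per-cell-line offset to positive-control means to
study miscalibrated controls; it defaults to 0.

Simulated values live directly on the lethality-score scale, so the
standardization step is skipped (`readouts_are_scores=True`) when
normalizing them: re-deriving scores from the simulated controls would
divide the stretched positive controls back out and trivially cancel the
very artifact the normalization is being tested against.

What the generator does *not* emulate: spatial within-plate gradients,
count overdispersion and zero-inflation of pooled screens, guide-level
off-target structure, or correlated noise between replicates.  Passing
tests therefore demonstrate correctness of the procedure under clean
additive/multiplicative artifacts, not robustness to every real-data
pathology.

## Evaluation harness and problem sizes

`run_fdr_experiment` draws independent datasets, normalizes with each
requested method (raw scores, the core-restricted map, classic full-range
quantile normalization, robust z, median-centering), tests for the group
effect, adjusts with BH, and records the false-discovery proportion
(V/max(R, 1), 0 when nothing is discovered) and the true-positive
proportion.  The shipped experiments use 100 datasets — enough for the
Monte-Carlo standard error of a mean FDP near 0.05 to be ~0.02–0.03 — and
all stochastic assertions allow 3 Monte-Carlo standard errors.

A note on the raw-score comparison: because the stretch factors form
identical multisets in the two comparison groups, the group contrast on raw
stretched scores is unbiased and its residual variance absorbs the stretch
spread, so the raw-score t-test is mildly *conservative* in this design
rather than anticonservative; the normalized analysis matches the nominal
FDR level while recovering a calibrated variance scale.  Under a single
`alpha_high=0.95` a 20% hit fraction lies mostly inside the core and is
partially aligned away; the per-condition mapping (0.95 for reference
lines, 0.80 for the high-hit condition) preserves the upper-tail
enrichment, which is why the package exposes per-replicate/per-cell-line
alpha mappings.

## Numerical choices

- Empirical quantiles use linear interpolation between order statistics at
  position h = (m − 1)p + 1 (numpy's default), so a core of 1001 equally
  spaced values in [0, 1] reproduces j/1000 exactly and p = 1 returns the
  maximum.
- Medians are plain sample medians (average of the middle two for even
  counts).
- Classic quantile normalization resolves ties by assigning tied values the
  mean of their positions' reference values.
- Robust z-scores scale the MAD by 1.4826 (normal consistency) by default;
  `scale_mad=False` gives the raw-MAD variant.
- OLS slopes are computed as cov/var in double precision; exact linear
  quantile–quantile relations are recovered to machine precision, which the
  tests exploit (core output equals classic quantile normalization within
  1e−9 on full-core, exactly-affine instances).

## Known limitations

- The per-feature test assumes independent replicates; it does not model
  cell-line-level random effects.
- The pooled-moderation option is a fixed-d0 shrinkage, not an estimated
  empirical-Bayes prior.
- The distance-based and two-sided core rules are reasonable
  interpretations of briefly specified ideas; their exact original
  formulations may differ in tie and boundary handling.
- Readout orientation for the positive-control reliability filter must be
  supplied; it is not inferred from the data.
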