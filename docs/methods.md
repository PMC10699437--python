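# Methods

This note documents the statistical procedures implemented in `hra`, the
choices made where conventions genuinely diverge, and what the synthetic
generator does and does not establish.

## AHP weighting and consistency

Judgment matrices are validated as positive, reciprocal
($x_{ij} x_{ji} = 1$ within a relative tolerance of 1e-3) with unit
diagonal and entries inside the 1/9–9 scale. The reciprocity tolerance is
deliberately loose: published matrices typically print reciprocal pairs
rounded to 4 d.p. (e.g. 0.9500 against 1.0526, product 0.99997), and exact
reciprocity would reject them. `JudgmentMatrix.from_upper_triangle`
rebuilds exact reciprocals when the upper triangle is authoritative; the
packaged worked-example matrix defaults to this exact form because it is
the reconstruction that reproduces the published consistency statistics to
print precision, while the rounded printed form shifts CI by ~8e-6.

Weights come from the sum-product method (column-normalise, row-average,
renormalise). $\lambda_{\max}$ is the mean of the componentwise Rayleigh
ratios $(Xw)_i / w_i$ — for the exact eigenvector this equals the
eigenvalue, and for sum-product weights of a near-consistent matrix it
agrees with the dominant eigenvalue to well under 1e-3 (property-tested). A
power-iteration eigenpair solver (tolerance 1e-12) is kept as an
independent cross-check route, never as the default.

The random-index table is Saaty's classical one (0, 0, 0.58, 0.90, 1.12,
1.24, 1.32, 1.41, 1.45, 1.49 for orders 1–10). Orders 1 and 2 are defined
consistent with $CR = 0$: a 2×2 reciprocal matrix is exactly consistent and
$RI = 0$ makes the ratio undefined. Orders above 10 require a user-supplied
RI. `build_weight_tree` refuses (rather than warns) if any matrix has
$CR \ge 0.1$, naming the offending matrix.

The packaged nine-indicator weight tree back-computes local tertiary
weights as global/secondary from the published weight table; only the
secondary judgment matrix was published, so the tertiary weights are
treated as given inputs, not AHP outputs.

## Composite scoring

Min-max normalisation is orientation-aware and refuses constant indicators
(zero denominator) by name. The extrema scope defaults to **pooled** over
the whole panel rather than per-year: per-year extrema would re-anchor the
score each year and largely flatten temporal trends, whereas pooled extrema
keep $Z$ comparable across years. Per-year scope remains available for
single-cross-section use. All nine packaged indicators are per-capita
provision quantities and default to positive orientation; the urban/rural
technician ratio is the one case where the reading is debatable, and its
orientation can be flipped in user metadata.

The regional summary reports both the mean of region means (the headline
"average of the zones", insensitive to region sizes) and the plain
all-units mean, since they differ whenever zone sizes differ (3/10/6/12 in
the packaged partition).

## Theil / generalized entropy

`ge_index` implements the standard GE family with unit weights $p_i$
(default $1/n$); the $c = 1$ (Theil T) and $c = 0$ (mean log deviation)
limits are explicit, and the $c=1$ share form
$\sum_i s_i \ln(n s_i)$ is used inside the decomposition — the two forms
agree to 1e-12 (tested). Unit weighting is equal by default because the
decomposition is over provincial units with no population weighting; a
weight vector is exposed for extensions.

The decomposition follows the standard Theil-T algebra
($T_{WR} = \sum_g S_g T_g$, $T_{BR} = \sum_g S_g \ln(S_g/(n_g/n))$ with
$S_g$ the value share of group $g$), which satisfies $T = T_{WR} + T_{BR}$
exactly — machine-precision identity is asserted on a thousand random
instances. Size-1 groups contribute zero within-inequality, which is valid,
not an error.

Nonpositive scores are a hard error by default: a pooled min-max score is
exactly 0 for the unit-year at the pooled minimum of every indicator, and
the Theil logarithm is undefined there. An explicit `shift_epsilon` flag
adds $10^{-6} \times$ mean and is recorded in pipeline warnings — never
silently. Percent changes between first and last year are computed from
full-precision values; display tables are rounded to 4 d.p. separately,
because change statistics recomputed from rounded tables do not generally
match.

## Moran's I and LISA

Global I uses the standard cross-product form over mean deviations with
both analytic variances: the normality and randomization (kurtosis-
corrected) closed forms are always computed and reported; `assumption`
selects which feeds the z-score. Permutation inference permutes the value
vector (fixed weights), vectorised over all permutations.

**Pseudo-p convention.** The directional (GeoDa-style) pseudo-p is
$(1 + \#\{I^* \text{ at least as extreme on the observed side}\})/(R+1)$,
where the side is chosen by the sign of $I - E[I]$. Because the side is
data-chosen, rejecting when this directional p falls below $\alpha$ has
size $\approx 2\alpha$ under the null. The reported `pseudo_p` is therefore
the two-sided value $\min(1, 2 p_{dir})$, and it is what significance
gating uses; the directional value is kept alongside. Empirically the
two-sided test rejects at 5.8% over 1,000 null replicates at
$\alpha = 0.05$ (inside the 3–7% calibration band asserted in the tests).

Local Moran standardises values by the $n$-divisor standard deviation, so
that under row-standardised weights $\sum_i I_i = n I$ (asserted against a
brute-force double loop). The conditional permutation for unit $i$ holds
$x_i$ fixed and permutes the other $n-1$ values using
`default_rng([seed, i])` and a stable argsort of uniform keys — the scheme
is pinned down precisely so an independent loop implementation can
reproduce it draw for draw, which the label-match test exploits. The
reference point for directionality is the analytic conditional expectation
$E[I_i] = -z_i^2 \sum_j w_{ij} / (n-1)$.

Cluster labels HH/HL/LH/LL come from the signs of the standardised value
and its lag, gated by two-sided pseudo-p $\le \alpha$ (default 0.05, 999
permutations); otherwise NS. No multiple-testing correction is applied by
default — per-unit LISA tables are conventionally reported unadjusted — but
a Benjamini–Hochberg gate is available (`fdr=True`). Isolated units keep
their place in the global statistic ($n$, $S_0$ unchanged) but get an
`undefined` local label: their lag does not exist, and silently zeroing it
would bias both statistics.

## Quadrant classification

The origin is the pair of unweighted cross-unit means at the two years.
Ties at a mean count as above-average (closed "≥" convention, flagged in
the output); the comparison uses an absolute tolerance of $10^{-9}$
(scaled by the mean's magnitude) so that a unit exactly at the mean is not
misclassified by the rounding error of the mean itself. Swapping the two
years maps II ↔ IV and fixes I and III (tested).

## Synthetic generator

Per indicator, the unit-year value is baseline + region effect + trend ×
(year − start) + SAR draw (+ optional iid measurement noise), where the SAR
draw is $(I - \rho W_{rs})^{-1} \varepsilon$ with
$\varepsilon \sim N(0, \text{noise\_sd}^2)$ redrawn each indicator-year.
The SAR innovation *is* the idiosyncratic noise — at $\rho = 0$ it is
exactly iid — so the separate measurement-noise term defaults to 0; giving
it the same sd as the innovation would halve the spatial signal share and
misstate the autocorrelation the config requests. Negative-orientation
indicators have the structural part sign-flipped around the baseline.
Values are affinely floored to strictly positive (Theil needs positivity);
shifts are recorded in the truth record with every other effect.

Defaults state a plausible world, not a tuned one: 31 units in zones of
(3, 10, 6, 12) on a planar two-block rook lattice with one bridge, nine
indicators reusing the packaged ids and grouping (so the published weight
tree applies directly), region effects (0.5, −1.0, −0.5, 1.0) in noise-sd
units ordering west > northeast > central > east, trend 0.2/yr, and
$\rho = 0.4$ — the moderate-positive-autocorrelation regime the real
provincial panel exhibits. The generator emulates structure only: it does
not reproduce real indicator magnitudes, real contiguity geography, or
non-Gaussian features of yearbook data, so a green test establishes that
the measurement chain recovers configured structure, not that it reproduces
any published real-data value.

## Numerical and degenerate-input choices

- Weight-tree sums are enforced to 1 within 1e-9; score decomposition
  identities hold to 1e-12.
- Constant values are hard errors for normalisation and for both Moran
  statistics (zero variance).
- Rounding is for display only (4 d.p., matching the conventions of
  published weight/Theil tables); every computation and change statistic
  uses full precision.
- Pipeline outputs contain no timestamps; with a fixed seed two runs are
  byte-identical (tested), and the manifest records config echo, config
  hash, versions, record counts and collected warnings.

## Known limitations

- Real-data results that depend on an undeposited panel or an unstated
  spatial-weights construction cannot be pinned; the spatial-weights matrix
  is always a user input here.
- The permutation p-value doubling is an approximation to a genuinely
  two-sided test; for markedly asymmetric permutation distributions a
  dedicated two-tail count could differ slightly.
- AHP is implemented in its classical eigen/sum-product form only; no
  geometric-mean or fuzzy variants.
- GAL parsing covers the common GeoDa dialect (single header line, id/count
  records); exotic variants are out of scope.
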