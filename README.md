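# hra — measuring regional healthcare-resource allocation

`hra` is a Python toolkit for the standard measurement chain used in
regional health-resource equity studies: derive indicator weights from
expert pairwise comparisons (AHP), build a composite provision score per
administrative unit and year, decompose score inequality into within- and
between-region parts (Theil), test whether provision clusters in space
(global/local Moran's I with LISA typing), and classify units by their
dynamics between two timepoints (quadrant analysis). It is aimed at health
economists and spatial epidemiologists who have a unit × year × indicator
panel, a region partition and a contiguity structure, and want the whole
chain reproducible from one seeded configuration.

## The measurement chain

**AHP weights.** From a positive reciprocal judgment matrix $X$ on Saaty's
1–9 scale, the sum-product method normalises each column to sum one,
averages rows and renormalises to get weights $w$. With
$\lambda_{\max} = \tfrac1n \sum_i (Xw)_i / w_i$, consistency is tested via
$CI = (\lambda_{\max} - n)/(n - 1)$ and $CR = CI/RI$; $CR < 0.1$ passes.
Secondary (group) weights times local tertiary weights give the global
weight of each indicator.

**Composite score.** Indicators are min-max normalised with orientation
($d = (x - x_{\min})/(x_{\max} - x_{\min})$ for positive indicators,
reflected for negative ones; extrema pooled over the panel by default), and
$Z = \sum_i w_i d_i$ decomposes exactly into per-group sub-scores.

**Theil decomposition.** For positive scores $y_i$ with group shares $S_g$,
$T = \sum_i s_i \ln(n s_i)$ splits exactly as $T = T_{WR} + T_{BR}$ with
$T_{WR} = \sum_g S_g T_g$ and $T_{BR} = \sum_g S_g \ln\!\big(S_g/(n_g/n)\big)$;
the full generalized-entropy family $GE(c)$ is available.

**Spatial autocorrelation.** Global Moran's
$I = \tfrac{n}{S_0}\,\sum_{ij} w_{ij} z_i z_j / \sum_i z_i^2$ with
$E[I] = -1/(n-1)$, analytic variance (normality and randomization) and
conditional-permutation pseudo-p. Local $I_i = z_i \sum_j w_{ij} z_j$ with
per-unit permutation gives HH/HL/LH/LL labels gated at a significance
level.

**Quadrant dynamics.** Units are placed against the cross-unit mean score
at two timepoints; quadrant I is above-average at both, III below at both.

## Worked example

The packaged secondary-indicator judgment matrix compares the three
provision families (facilities, personnel, beds):

```python
from hra import derive_weights, secondary_judgment_matrix

res = derive_weights(secondary_judgment_matrix())
print(res.weights.round(4), res.lambda_max, res.ci, res.cr, res.consistent)
```

prints

```
[0.3324 0.3596 0.308 ] 3.0007515039011867 0.00037575195059336153 0.0006478481906782096 True
```

i.e. personnel carries the largest weight (0.3596), the matrix is almost
perfectly consistent ($\lambda_{\max}$ barely above 3), and $CR \approx
0.0006 \ll 0.1$ passes the consistency test.

The full chain on a synthetic 31-unit, four-zone, 12-year panel:

```bash
hra pipeline --out results/pipeline --seed 42   # packaged synthetic config
```

or step by step through the numbered drivers:

```bash
python analysis/01_simulate.py    # seeded synthetic world
python analysis/02_weights.py     # AHP weights + consistency
python analysis/03_scores.py      # composite scores by unit-year and zone
python analysis/04_inequality.py  # Theil decomposition per year
python analysis/05_spatial.py     # global Moran's I and LISA clusters
python analysis/06_quadrant.py    # two-timepoint quadrant table
```

Step 05, for instance, reports a strongly positive global Moran's I every
year (pseudo-p = 0.002 at 999 permutations) and HH clusters concentrated in
the high-provision block — the pattern the generator was configured to
produce. All tables land under `results/analysis/` as CSV with a seed/
config-hash header.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged judgment matrix and nothing else, the
principal eigenvalue of the sum-product weighting and its consistency
index, and writes them as JSON.
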