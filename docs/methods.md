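# Methods

## The quantity of interest

Sexual size dimorphism is summarized per species by the Lovich–Gibbons-style
ratio index on the two reproductive castes,

    SSDi = (size of larger sex / size of smaller sex) − 1,

signed negative when males are larger. Body size is intertegular (thorax)
width in mm, an age-invariant standard proxy in bees. Two conventions are
implemented and must not be conflated:

- `queen_over_male` (default): `queen/male − 1`. Recomputation of the
  bundled 44-species table shows its printed SSDi column follows this form
  for male-biased species (e.g. 2.158/2.556 − 1 = −0.1557 → −0.155), not the
  sign-flipped larger/smaller ratio (−0.184). The default therefore
  reproduces the published numbers.
- `ratio_signed`: the literal definition, antisymmetric under sex swap.

Published-table comparisons truncate toward zero at three decimals, because
truncation (0.4258 → 0.425, 0.7775 → 0.777, −0.1557 → −0.155) reproduces the
printed column where rounding does not. Full precision is kept internally.
Recomputation caveats: 32/44 printed values match exactly under truncation,
42/44 within ±0.002; two species (*Melipona yucatanica*, *Oxytrigona
tataira*) have printed SSDi inconsistent with their own printed widths
(their printed means are consistent), evidently computed from unrounded
measurements that are not recoverable. The printed mean column mixes
truncation and round-half-up, so mean comparisons use "within one unit in
the last printed decimal place".

Categories use a configurable monomorphism band, default |SSDi| ≤ 0.06: it
covers the species the source literature describes as similar-sized (max
|SSDi| 0.058) while excluding clearly biased ones. No published threshold
exists, and no single threshold reproduces the published 23/6/12 category
counts from the table (the package reports 24/11/9 at 0.06); counts are
reported, not asserted.

## Contrasts, allometry, isometry

Trait evolution is modelled as Brownian motion on an ultrametric,
time-calibrated tree (relative depth tolerance 1e−6 by default, since dating
software rounds branch lengths). Felsenstein's pruning recursion produces
n − 1 standardized contrasts per trait on a binary n-tip tree; polytomies
must first be resolved (`resolve_polytomies`, zero-length branches, seeded).
Children are visited in a canonical order (smallest descendant tip label
first) so contrast signs are stable across traits on the same tree and
bivariate pairs stay aligned; through-origin statistics are invariant to the
joint sign flips used for plot positivization. The BM rate estimate is the
mean squared standardized contrast.

Caste allometry is estimated by major-axis regression of contrast pairs on
the log10 scale — appropriate because both variables are sizes on the same
scale and both carry error. Contrast regressions are fit through the origin
(a contrast has no intrinsic sign, so no intercept), giving df = n − 1; this
is also the only choice consistent with the published degrees of freedom
(43 contrasts → df 42; 40 contrasts → df 39 after per-pair removal of the
three taxa without worker data). The isometry test (H0: β = b0 = 1) is the
classical MA test: residual scores u = y − b0·x against axis scores
w = x + b0·y, F = r²_uw·df/(1 − r²_uw) on (1, df). It is exact under
bivariate normality with isotropic error, which holds for contrasts of two
traits with equal residual rates. α = 0.05 throughout; no multiple-testing
correction is applied across the three caste pairs. Studentized
perpendicular residuals are reported (|t| > 3 flags outliers) but never
removed. Ordinary or standardized-major-axis fits are deliberately not
offered, to avoid silently mixing line-fitting conventions.

## Ancestral reconstruction

The ML state of an internal node under BM equals the root value of the
contrasts recursion after re-rooting at that node; the implementation peels
(value, variance) summaries inward over the node's neighbours on the
undirected tree, which avoids explicit tree surgery. The test suite verifies
node-by-node equality (1e−8) with the closed-form GLS projection
(1'V⁻¹x)/(1'V⁻¹1) under the re-rooted BM covariance — an independent matrix
computation — and against R's phytools::fastAnc. Reconstruction is linear in
the data and scale-free; the contrast-based σ̂² is recorded for reference
only. Along-branch states are linear between endpoint estimates (for
interior points under BM the ML interpolation is the weighted-endpoint line,
and linearity is the deterministic, testable rule); the painted-tree export
samples each branch in short segments coloured on a diverging ramp centred
at 0, so male- vs female-biased regions of the tree are immediately visible.
No confidence intervals are drawn on node states.

## Synthetic data: what it emulates, what it does not

`simulate_yule_tree` grows a pure-birth tree conditioned on n tips (plus one
Exp(nλ) tail so E[height] = Σ_{k=2..n} 1/(kλ)); birth–death sampling and
non-ultrametric trees are out of scope. `simulate_bm` /
`simulate_correlated_bm` add independent or jointly-drawn Gaussian
increments per branch (rate matrix must be PSD; rank-deficient matrices are
handled by eigenvalue factorization).

`generate_caste_dataset` defines evolutionary allometry structurally on the
log10 scale:

    worker = r + dW,              dW ~ BM(σ²_w)
    queen  = r + a_q + b_q·dW + BM(σ²_q)
    male   = r + a_m + b_m·dW + BM(σ²_m)

Defaults are matched to the empirical dataset: 44 tips; root log10 width
0.23 (≈1.7 mm); σ²_w = 0.02 per unit time on a height-≈2.7 tree, giving tip
SDs of ≈0.2 log10 units (the empirical spread); queen offset a_q = +0.07
(SSDi ≈ +0.17, the non-*Melipona* average); and a 12-tip clade whose queen
offset is replaced by −0.06 (SSDi ≈ −0.13, the *Melipona* average). Residual
caste rates default to 5% of the shared rate (0.001): this keeps caste
co-evolution in the upper range of the empirical r² and keeps the MA target
slope within ~0.03 of the structural slope b — MA attributes residual noise
to both axes, so with noise only in the dependent caste the MA slope
slightly exceeds b (analytically ≈1.025 at b = 1 with these rates). The
slope-recovery checks (b ∈ {0.8, 1.0, 1.2} recovered within 0.05 at 200
tips × 200 replicates) operate under exactly these conditions. The clade for
the offset reversal is the non-root internal node with tip count closest to
the target (deterministic tie-break by node id).

What the generator does not emulate: measurement error and within-species
variance (one value per species, as in the empirical table), missing-data
patterns (tests knock out worker values explicitly where needed),
heterogeneous rates or selection (no OU/trend models), and non-Yule tree
shape. Passing recovery tests therefore validates the estimators under the
model they assume, not robustness to violations of it.

## Numerical and design choices

- Truncation uses a 1e−9 guard against binary-float noise (so 0.19999…996
  truncates to 0.200, not 0.199).
- Zero-length branches from polytomy resolution are legal in the recursion;
  a contrast is undefined only if both child branches are zero (error). A
  zero-length child pins the nodal value to that child.
- MA degenerate cases: an isotropic cloud (S_xy = 0, S_xx = S_yy) is an
  error; S_xy = 0 with unequal variances returns slope 0 or ∞. The isometry
  test refuses b0 at or beyond the perpendicular of the fitted axis
  (1 + b0·β̂ ≤ 0).
- Taxon matching between tree and table is case-insensitive with
  underscore/space equivalence; unmatched rows/tips are dropped with a
  logged warning (pruning, not failing, mirrors how such analyses handle
  partial overlap). Taxa missing one trait are dropped per caste pair, not
  globally — which is what makes the male~queen regression retain the
  worker-less solitary taxa.
- Reproducibility: seeds are mandatory in simulator configs, there is no
  global random state, and pipeline outputs (CSV/JSON with fixed float
  formatting and sorted keys) are byte-identical across reruns of the same
  config; the run log records a config hash, package version and all taxon
  drops.
- Validation problem sizes: oracle-equivalence checks use 100 random trees
  of ≤20 tips (GLS inverses are exact and cheap there); calibration checks
  use 100–200 tips with 100–1000 replicates, sizes at which Monte-Carlo
  error is well below the asserted bands.

## Known limitations

- The chronogram is consumed, never inferred; analyses are conditional on
  the supplied tree and its dating.
- No within-species variance or measurement-error model; species means are
  taken at face value.
- The MA isometry test assumes isotropic residual scatter on the log scale;
  strongly unequal residual rates between castes bias the MA slope away
  from the structural slope (quantified above).
- Ancestral states are point estimates; uncertainty (which grows toward the
  root) is not reported.
- The published category counts (23/6/12) are not reproducible from the
  published table under any fixed threshold; the package's counts will
  differ from them by construction.
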