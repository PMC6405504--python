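# stingless-ssd

Comparative analysis of sexual size dimorphism (SSD) in stingless bees
(Apidae: Meliponini) and their corbiculate relatives, on time-calibrated
phylogenies.

Eusocial bees split females into reproductive queens and (mostly) sterile
workers, which makes them a natural experiment for separating fecundity
selection on queens from sexual selection on males. This package implements
the macroevolutionary toolkit for that question:

- **SSD index.** For each species, `SSDi = (larger sex / smaller sex) − 1`,
  signed negative when males are larger. The bundled 44-species table of
  intertegular (thorax) widths — workers, males and queens, in mm, compiled
  from collection measurements and the taxonomic literature (per-row source
  tags) — is reproduced by the operational form `queen/male − 1`, which is the
  package default (see `docs/methods.md` for the distinction).
- **Phylogenetic independent contrasts** (PIC). Standardized contrasts
  `C_k = (x_i − x_j)/√(v_i + v_j)` computed by the post-order recursion with
  branch-length adjustment; iid `N(0, σ²)` under Brownian motion, removing
  phylogenetic non-independence.
- **Major-axis (MA) allometry and the isometry test.** MA slope
  `β̂ = [S_yy − S_xx + √((S_yy−S_xx)² + 4S_xy²)]/(2S_xy)` on contrast pairs
  (through the origin, df = n − 1), with the F test of `H0: β = b0` from the
  residual-vs-axis-score correlation. Rensch's rule corresponds to a
  male-on-female slope significantly above 1.
- **ML ancestral reconstruction** of a continuous trait under BM (re-rooted
  contrasts, equal to the GLS estimate), with linear along-branch
  interpolation and a painted-tree export on a diverging ramp centred at
  SSDi = 0.
- **Simulators** — Yule chronograms, (correlated) BM traits, and a
  three-caste generator with specified evolutionary allometric slopes and an
  optional clade-level reversal of SSD sign (the *Melipona* pattern) — so
  every stage is testable without downloads.

## Worked example

SSD indices for the bundled empirical table:

```sh
$ stingless-ssd ssdi | head -3
species,ssdi,category,species_mean_mm
Austroplebeia australis,0.0916031,female_biased,1.37
Austroplebeia cassiae,0.0583942,monomorphic,1.41
```

`ssdi` is queen/male − 1 (so *A. australis* queens are ~9.2% wider than
males), `category` applies the ±0.06 monomorphism band, and
`species_mean_mm` is the mean width of the two reproductive castes. Writing
the table with `--out` also prints the category counts, here
`{"female_biased": 24, "male_biased": 11, "monomorphic": 9}` — all twelve
*Melipona* species have negative SSDi.

The full pipeline needs a chronogram. A synthetic twin of the empirical
dataset (44 tips, a 12-tip male-biased clade) exercises every stage:

```sh
$ stingless-ssd simulate --n-tips 44 --seed 11 --out demo/sim
$ stingless-ssd run --traits demo/sim/traits.csv --tree demo/sim/tree.nwk \
      --exclude-genus shifted_clade --out demo/run
```

which reports, for the full run (43 contrasts, df = 42):

```json
"male~queen": {"slope": 1.0041, "r2": 0.8920, "F": 0.0059, "df": 42,
               "p": 0.9390, "verdict": "isometry not rejected"}
```

i.e. male and queen sizes diverged at statistically indistinguishable rates
(slope ≈ 1): no Rensch's rule, matching the generator's slope-1 truth. The
output directory collects per-pair contrast CSVs, the SSDi table,
`rensch_results.json` and a structured run log; `stingless-ssd ancestral`
additionally writes `ancestral_states.csv` and `painted_tree.svg`.

With an empirical chronogram (e.g. the time-calibrated Meliponini phylogeny
deposited as TreeBASE study 23779) the same command reproduces the published
contrast regressions; taxa lacking worker data (the two solitary Euglossini
and *Trichotrigona extranea*) are dropped per-pair, giving df = 42 for
males~queens and df = 39 for the worker pairs.

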