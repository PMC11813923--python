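# megaenv

Genotype-by-environment stability analysis for multi-environment trials
(METs), built around the workflow used for large grain-legume diversity
panels such as the 220-accession faba bean (*Vicia faba* L.) collection
evaluated in nine European location-year environments: augmented p-rep
field designs, REML variance components and BLUPs with generalized
heritability, GGE biplot mega-environment analysis, and the
WAASB/WAASBY/MTSI multi-trait selection index.  A synthetic MET
generator reproduces the statistical structure of such a study
(trial layouts, variance components, botanical-type effects, planted
mega-environment crossover) so every method can be exercised and
validated end to end.

The package is intended for quantitative geneticists and plant breeders
analyzing unbalanced multi-location trials, and for methodologists who
need a tested, scriptable implementation of these stability statistics.

## The models

**Design.** Each trial is an augmented partially replicated (p-rep)
row-by-column layout: most entries appear once, a set of checks twice
and a few standard cultivars six times.  Shared checks connect trials
into one estimable series; `check_connectivity` verifies this.

**Mixed model.** Per trait, with trial fixed and everything else random,

    y = trial + genotype + genotype:trial + row(trial) + col(trial) + e

is fitted by average-information REML (the engine handles arbitrary
crossed random effects).  Generalized heritability follows Cullis:

    H2 = 1 - vblup / (2 * sigma2_g)

where `vblup` is the mean prediction-error variance of a difference
between two genotype BLUPs — the appropriate reliability when genotypes
are unequally replicated.

**GGE biplot.** The genotype-by-environment table is environment-centered
and decomposed by SVD, `Y_ij - mu_j = sum_k lambda_k alpha_ik gamma_jk`,
with symmetric scaling (f = 0.5) by default.  The which-won-where view
takes the convex hull of genotype scores; perpendicular rays to its
edges partition environments into sectors, each won by a vertex
genotype.  Locations whose year-instances always share a winner form a
mega-environment.  The mean-vs-stability view projects genotypes on the
average-environment axis (mean performance) and its orthogonal
complement (instability).

**MTSI.** Traits are folded around an ideotype target, per-trait
stability is WAASB (weighted absolute SVD scores of the interaction
BLUP matrix), performance and stability are rescaled to 0-100 and
blended 70:30 into WAASBY, and genotypes are ranked by the Euclidean
distance to the ideotype in the factor-score space of the WAASBY matrix.
The best `round(0.15 n)` genotypes are selected.

## Worked example

```bash
python examples/simulate_and_fit.py
```

```
simulated 1252 plots across 9 trials

REML variance components for days to flowering:
             component  variance  percent
             genotypic     20.69    48.00
genotype_x_environment      8.79    20.39
        row_and_column      2.54     5.90
              residual     11.08    25.71

generalized heritability H2 = 0.883 (vblup = 4.84, var_g = 20.69)
```

The simulator drew flowering time with a genotypic variance of 16.7 and
an interaction variance of 9.91; a single 1252-plot realization recovers
them within sampling error, the row/column share stays small (~6%), and
H2 ≈ 0.88 says genotype comparisons are reliable even though 80 of 100
entries per trial are unreplicated.  `examples/gge_which_won_where.py`
continues the analysis and, under a planted southern/northern crossover,
prints the two recovered mega-environments with their winning genotypes;
`examples/mtsi_selection.py` ranks genotypes against the ideotype and
selects 15%.

There is also a thin CLI over the same library for scripted runs:

```bash
megaenv simulate --out run && megaenv fit --out run && megaenv report --out run
```

## Layout

- `src/megaenv/` — library modules: `design`, `simulate`, `reml`,
  `mixed_models`, `gge`, `mtsi`, `summaries`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, numerical choices
- `tests/` — pytest suite with closed-form and simulation oracles
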