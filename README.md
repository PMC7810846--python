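# pairvox

Quantifying vocal imitation in pair-bonded budgerigars and the
correlated neuronal activity that accompanies memory for the learned
calls.

Male budgerigars (*Melopsittacus undulatus*) copy the contact call (CC)
of their mate within weeks of pairing. `pairvox` implements the two
analysis arms such a study needs:

1. **Imitation scoring.** Calls are compared by *spectrogram
   cross-correlation*: the Pearson correlation between two short-time
   Fourier magnitude spectrograms over their overlapping frames,
   maximized over time lag — 1 for identical sonograms, 0 for no
   similarity. A male's post-pairing repertoire is scored against a
   female's pre-pairing repertoire exemplar-by-exemplar, and the
   comparison is summarized by the **Maximum Cross-correlation Value
   (MCV)**: the mean of the three highest scores over all exemplar
   pairs. Imitation shows up as within-pair MCVs exceeding extra-pair
   MCVs (Wilcoxon matched-pairs test), with supporting statistics for
   visual similarity ratings (Mann–Whitney, ANOVA + Scheffé,
   Kruskal–Wallis).

2. **IEG co-expression inference.** Immediate-early-gene (Zenk, Fos)
   cell counts from fixed 290 × 450 μm counting frames in three
   caudomedial pallium subregions (CMM, dNCM, vNCM; hippocampus as
   control) are converted to densities per mm², log-transformed, and
   pushed through the study's test battery: two-way and per-region
   one-way ANOVAs with Bonferroni post-hocs, pairwise inter-region
   Pearson correlations (with the exact small-n p-value
   p = 1 − |r| at n = 4), Bayesian simple regressions with a 95%
   credible-interval zero criterion (`BayesSimpleRegression`, a
   statsmodels-style model whose reference-prior interval provably
   equals the OLS t-interval), and scaled-profile rank-concordance
   patterns (Kendall's W).

Because raw audio and histology for such studies are rarely deposited,
both arms ship with synthetic generators — frequency-modulated tonal
calls with controllable imitation distortion, and multivariate
log-normal/Poisson count tables with group-specific inter-region
correlation — so the full chain is testable end to end, including its
type-I calibration and power at the study's n = 4. See
`docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a 12-pair colony in which each male imitates one of his mate's
call types at distortion 0.2, score every male against every female,
and test whether mates are more similar than non-mates:

```python
from pairvox import (ColonySpec, gen_colony, RunConfig,
                     compute_pair_comparisons, within_extra_summary)

colony = gen_colony(ColonySpec(n_pairs=12, imitation_distortion=0.2,
                               rng_seed=7))
cfg = RunConfig(exemplars_per_type=3, seed=7)
scores, mcv = compute_pair_comparisons(
    colony.annotations, colony.pairs,
    lambda cid: colony.waveforms[cid], cfg)
res = within_extra_summary(mcv)["test"]
print(f"within-pair MCV  {res.extras['within']['mean']:.3f}")
print(f"extra-pair MCV   {res.extras['extra']['mean']:.3f}")
print(f"Wilcoxon W+ = {res.statistic:.0f}, p = {res.p:.5f}, n = {res.n}")
```

```
within-pair MCV  0.821
extra-pair MCV   0.523
Wilcoxon W+ = 78, p = 0.00049, n = 12
```

Every male is more similar to his own mate than to the other eleven
females (all twelve signed-rank differences positive, hence W⁺ = 78,
the maximum), so imitation is detected decisively.

On the neural side, fit the credible-interval zero criterion to one
group's inter-region densities:

```python
from pairvox import (IEGSimSpec, gen_ieg_counts, density_from_counts,
                     log_transform, BayesSimpleRegression)

table, truth = gen_ieg_counts(IEGSimSpec(rng_seed=7))
dens = density_from_counts(table)
mate = dens.query("group=='MATE' and ieg=='Zenk'").pivot_table(
    index="bird_id", columns="region", values="density_per_mm2")
fit = BayesSimpleRegression(log_transform(mate["dNCM"].to_numpy()),
                            log_transform(mate["CMM"].to_numpy())).fit()
print(fit.summary())
```

```
Bayesian simple linear regression
  prior: reference    n: 4    posterior df: 2
  slope:      0.645343  [-2.00967,  3.30036] (95% credible interval)
  intercept:  2.30837
  E[sigma^2]: undefined (posterior df <= 2)
  interval includes zero: True
```

With four birds the interval is wide; this particular draw does not
exclude zero, which is exactly the small-sample behaviour the
`recovery_experiment` power analysis quantifies (at inter-region
correlation 0.95, a minority-to-majority of replicates flag all three
subregion pairs, depending on counting noise).

## Command line

```sh
pairvox simulate-calls --seed 1 --out colony/      # WAVs + CSVs + truth
pairvox similarity --annotations colony/annotations.csv \
        --pairs colony/pairs.csv --seed 1 --out report/
pairvox simulate-ieg --seed 1 --out ieg/           # counts.csv + truth
pairvox ieg --counts ieg/counts.csv --out report/
pairvox recover --grid 0,0.5,0.9,0.99 --reps 500 --out power/
```

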