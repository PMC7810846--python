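# Methods

`pairvox` implements two linked analyses of vocal imitation learning in
pair-bonded budgerigars: (1) quantification of contact-call (CC)
imitation by spectrogram cross-correlation between a male's
post-pairing call repertoire and his mate's pre-pairing repertoire, and
(2) inference of memory-specific co-activation of higher-order auditory
subregions (CMM, dNCM, vNCM; hippocampus as a non-auditory control)
from immediate-early-gene (Zenk, Fos) cell-count data. Raw recordings
and histology are not publicly deposited for this study design, so both
arms come with synthetic-data generators that reproduce the statistical
structure the analyses assume; every claim the test suite makes is
therefore a claim about the method's behaviour, calibration and power
under that generative model, not a re-derivation of the published
group-level values.

## Spectrogram cross-correlation similarity

A call is represented by its short-time Fourier magnitude spectrogram
(default FFT size 256, hop = 3 ms, Hamming window; the window family is
configurable since only the FFT size and temporal resolution are fixed
by convention). Frames start at sample zero and advance by the hop;
only complete windows are transformed. Spectrograms may be band-limited
to a frequency interval (default 1–10 kHz) before comparison.

The similarity of spectrograms *A* (T_a frames) and *B* (T_b frames) at
integer frame lag ℓ is the Pearson correlation over all cells of the
overlapping columns (all frequency bins of the overlap flattened into
one paired sample). The score is the maximum over admissible lags:

- lag search range: ±min(T_a, T_b) frames by default;
- a lag is admissible when the overlap covers at least
  `min_overlap_frac` (default 0.5) of the shorter call;
- ties on the maximum resolve to the smallest |lag| (then the smaller
  signed lag);
- a zero-variance overlap (e.g. silence against silence) yields an
  explicit *undefined* flag, never a numeric 0 — 0 is reserved for
  "no similarity";
- the score is exactly invariant to uniform amplitude scaling of either
  input (magnitudes are peak-normalized before the sums), lies in
  [−1, 1], is symmetric in its arguments (with the lag negated), and is
  1 for a spectrogram against itself.

The per-lag sums are computed via FFT-based cross-correlation of the
magnitude matrices and of their column sums/squares, so the full lag
sweep costs O(F·T log T); a plan cache (`RepertoireScorer`) reuses each
call's transforms across the many comparisons of a colony run. A brute
force per-lag `corrcoef` oracle in the tests pins the fast path to the
definition.

Linear magnitudes are correlated by default (dB is available): the
linear scale keeps the 0-anchor of the score interpretable. Files with
differing sample rates are polyphase-resampled to a configured common
rate, or refused when resampling is disabled.

### Repertoire comparison and the MCV

For each male × female comparison, up to `exemplars_per_type` exemplars
(default 5; fewer if fewer exist, sampled without replacement under the
run seed) of each call type are scored all-against-all. The **Maximum
Cross-correlation Value (MCV)** is the mean of the three highest scores
pooled over every exemplar pair of the comparison (pooling across type
pairs, not per-type maxima; a per-type reading is possible but the
pooled one matches "all of the comparisons"). Fewer than three finite
scores yield the mean of what exists, flagged degenerate. Failed
individual comparisons are recorded with their error, never dropped
silently.

Behavioural statistics operate on these quantities:

- within-pair vs extra-pair MCV (each male's mate vs his mean over
  non-mate females): Wilcoxon matched-pairs signed-rank test, zeros
  dropped before ranking, exact p at small n (scipy's policy);
  the reported statistic is W⁺, the sum of positive-difference ranks;
- within-type vs among-type scores: Mann–Whitney U;
- cross-correlation values grouped by the 1/2/3 visual similarity
  rating: one-way ANOVA with Scheffé-adjusted pairwise contrasts
  (pairwise F divided by k−1 against F(k−1, N−k) on the pooled error);
- pre/post visual scores per male: Wilcoxon matched pairs; scores
  across stimulus groups: Kruskal–Wallis with midranks.

Visual similarity scores are *inputs* (human ratings 1 = none,
2 = modest, 3 = good), reduced to one score per bird pair by the
highest-rating rule; the package never computes them.

## Synthetic calls and colonies

A call type is a template: 4–6 control points interpolated by a
monotone cubic (PCHIP) into a smooth FM contour in the 2–4 kHz
contact-call band, 0.12–0.25 s duration, two harmonics at amplitude
ratio 0.4, raised-cosine 10 ms edges, white noise at 25 dB SNR,
rendered at 22,050 Hz onto the 16-bit PCM grid (so in-memory audio
equals a WAV round trip). Exemplars of a type share the template but
receive per-call jitter (±2% frequency scale, ±4% duration).

Imitation at distortion d ∈ [0, 1] displaces each control-point
frequency by exactly d·15% of its value with a random sign, and the
duration by d·20% with a random sign; d = 0 reproduces the template
exactly, and the expected absolute relative displacement at d = 1
equals the configured maximum — a testable law.

A colony holds `n_pairs` (default 12, the study size) mated pairs; each
female has 1–2 types, each male 2 pre-pairing types, all drawn
independently (pair members therefore start dissimilar, as the study's
dissociative pairing enforced), with 3 exemplars per type as the
default problem size for replicated simulation (the study rated 5
exemplars per type; 5 remains the analysis-side default for real
annotation tables). Post-pairing, each male keeps his pre types and
gains an imitation of one randomly chosen mate type at the colony's
distortion; the ground truth records which.

**Known divergence from the published score distributions.** With
independently drawn contours, same-type exemplars score ≈ 0.89 and
different types ≈ 0.28 on average — a wider separation than the
published 0.75 / 0.54. This is deliberate. The MCV is a max-of-many
statistic: generator variants that push the cross-type *mean* toward
0.55 (shared contour archetypes) inflate the cross-type right tail,
which drives extra-pair MCVs up to within-pair levels and makes
imitation undetectable at the study size — the opposite of the real
data, where within/extra MCVs separate cleanly (0.73 vs 0.65). Matching
the detectability structure was judged more important than matching the
marginal score means; consequences: synthetic within/extra MCV means
(≈ 0.79 / 0.52 at d = 0.2) bracket the published ones, and absolute
score levels from this generator should not be read as predictions for
real audio.

## IEG densities and the inference chain

Counts come from fixed 290 × 450 μm counting frames, four per region
per bird (two per hemisphere; hemispheres are collapsed by frame
averaging). Density per mm² = (mean frame count) / 0.1305 mm², the
exact frame area. Missing frames average over those present (recorded);
a cell with no frames is an error.

Densities are log-transformed before parametric tests. The transform is
ln(x + 1) by default: zero densities occur (basal Fos in the vNCM), the
published analysis does not state its zero handling, and the +1 offset
maps 0 to 0 while preserving order; log10 and the offset are
configurable.

The chain per IEG:

1. two-way fixed-effects ANOVA (Stimulus × Brain Region) on log
   densities — balanced, fully crossed designs only, where Type-I and
   Type-III sums of squares coincide; unbalanced input is refused
   rather than silently reweighted. A split-plot (between × within
   subjects) option exists for the Stimulus × IEG layout; the published
   df (2, 33) for that analysis matches no standard layout derivable
   from 12 subjects × 2 IEGs, so the plain fixed-effects analysis is
   the default and the anomaly is simply noted.
2. one-way ANOVAs per region across stimulus groups, F on df
   (k−1, N−k); all-constant input reports F = 0, p = 1. Bonferroni
   post-hocs: pairwise t on the pooled ANOVA error term, p × (number of
   comparisons), capped at 1.
3. pairwise inter-subregion Pearson correlations per stimulus group on
   per-bird log densities, two-tailed p from
   t = r√(n−2)/√(1−r²) with df n−2. At the study's n = 4 this p equals
   1 − |r| exactly — an identity the tests hold to 1e−12, and the
   reason the printed r/p pairs can be checked mechanically. A
   zero-variance variable yields an explicit undefined flag (no r, no
   p), as happens for Fos in the vNCM under silence.
4. Bayesian simple regression per subregion pair with a 95% credible
   interval zero criterion (below).
5. scaled pattern profiles: per subregion, each bird's density as a
   percentage of that subregion's maximum bird (the maximum is exactly
   100%); birds are ranked per subregion (midranks on ties), the
   profile is *concordant* when the ranking is identical across the
   three subregions, and Kendall's W (tie-corrected) quantifies the
   agreement.
6. optionally, Spearman rank correlations of the behavioural similarity
   score against densities, with an exact permutation p for n ≤ 8
   (the score is ordinal and tied; midranks throughout).

F tail probabilities use the regularized incomplete beta; at df1 = 2
they agree with the closed form (d2/(d2 + 2F))^(d2/2) to 1e−10.

### Bayesian regression and the choice of prior

The published analysis declares a linear relationship when the 95% CI
of the regression coefficient excludes zero, but does not state its
software, prior or estimator. Two conjugate families are provided:

- **reference** (default): p(α, β, log σ) ∝ 1. The slope's marginal
  posterior is a location-scale t with n − 2 df centered on the OLS
  estimate, so the credible interval *equals* the classical OLS
  t-interval (tested to 1e−9), and includes-zero ⇔ classical two-sided
  p ≥ 0.05. This makes the criterion transparent and reproducible.
- **nig**: proper Normal–inverse-gamma shrinkage. Exposed because one
  published Fos result (Pearson p = 0.041 yet a zero-including CI) is
  inconsistent with the reference prior, implying some informative
  prior was used; neither family is asserted to be the authors'.

Zero residual variance yields a degenerate point interval with a flag.

## Synthetic IEG tables

Bird-level log densities are multivariate normal: within a stimulus
group the three pallial subregions share a common correlation ρ
(MATE 0.95, UNFAMILIAR 0, SILENCE 0 by default — coupling only in the
mate-call group), the hippocampus is independent; densities are
exponentiated (log-normal marginals: positive, right-skewed, matching
the decision to log-transform). Frame counts are Poisson with mean
density × 0.1305 (switchable off); designated cells are zero-inflated
at the bird level (default: Fos/vNCM/SILENCE with probability 0.9,
emulating near-zero basal expression). Default group log-means follow
the published *ordering* only (auditory Zenk elevated under playback
vs silence; Fos elevated only ventrally); the figure values are
graphical and are not treated as numbers.

`recovery_experiment` runs the genuine analysis chain (counts →
densities → log → Pearson + Bayesian CIs) on replicate single-group
tables over a ρ grid and reports per-pair significance rates and the
all-three-CIs-exclude-zero rate with binomial standard errors. Two
calibration facts the acceptance suite fixes at the study size
(n = 4, α = 0.05, 2000 replicates): the type-I rate per pair sits at
the nominal 5%, and detection is nondecreasing in ρ. Poisson counting
noise at the default density scale (~53 expected counts per frame)
attenuates the observed inter-region correlation from 0.99 to ≈ 0.92,
lowering the all-three rate at ρ = 0.99 from ≈ 0.87 (no frame noise) to
≈ 0.3 — a quantitative reminder that measurement noise, not only the
tiny n, limits what the published design could detect.

## Problem sizes, determinism, reporting

Replicated simulations use 12-pair colonies with 3 exemplars per type
and 2 pre-pairing male types; the acceptance test uses 100 colony
replicates and the standalone acceptance script 40 (each run's n is
recorded alongside its value). All randomness flows from named seeds
(NumPy `default_rng`); identical inputs + seed + configuration produce
byte-identical CSV/JSON reports, and input row order is irrelevant.
Human-readable summaries round to 3 decimals (half-to-even); machine
outputs are unrounded.

## Limitations

- The synthetic calls are tonal FM stacks, not vocal-tract synthesis;
  no warble song, no syllable segmentation, no time warping. Calls are
  assumed pre-cut.
- Call types are classified by the generator's ground truth or by human
  annotation; no automatic clustering.
- Absolute similarity-score levels are generator-specific (see the
  divergence note above); only the relational structure (within > extra,
  monotone decay with distortion, the 0.75 chance threshold at d = 0)
  transfers.
- The IEG arm consumes count tables; image processing and cell
  detection are upstream and out of scope. No hierarchical models
  beyond the published test battery.
- Published group-level means are not reproducible without the raw
  data; the test suite checks printed statistic/p consistency,
  analytic identities and generative-model recovery instead.
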