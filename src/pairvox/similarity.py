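"""Imitation-learning quantification from call repertoires.

A male's post-pairing call types are compared with his mate's (and, as
controls, non-mates') pre-pairing types by spectrogram cross-correlation
between randomly selected exemplars of each type.  The summary statistic
per male-female comparison is the Maximum Cross-correlation Value (MCV):
the mean of the three highest correlation values pooled over every
exemplar pair.  Behavioural statistics (within- vs extra-pair Wilcoxon,
within- vs among-type Mann-Whitney, visual-score ANOVA with Scheffe
post-hocs, pre/post Wilcoxon and Kruskal-Wallis across stimulus groups)
operate on those scores or on the 1/2/3 visual similarity ratings,
which are inputs, never computed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audio import resample_to
from .spectro import (
    Spectrogram,
    SpectroError,
    XcorrPlan,
    band_limit,
    compute_spectrogram,
    _score_plans,
)


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class SpectroConfig:
    """Analysis settings shared by every pairwise comparison."""

    fft_size: int = 256
    time_step_ms: float = 3.0
    window: str = "hamming"
    band_lo_hz: float | None = 1000.0
    band_hi_hz: float | None = 10000.0
    min_overlap_frac: float = 0.5
    max_lag_frames: int | None = None
    common_rate_hz: int | None = None
    allow_resample: bool = True
    peak_normalize: bool = True
    magnitude: str = "linear"


@dataclass(frozen=True)
class Exemplar:
    """One selected call: identity labels plus its audio."""

    call_id: str
    type_label: str
    waveform: np.ndarray
    sample_rate_hz: int


@dataclass(frozen=True)
class MCVResult:
    """Mean of the three highest cross-correlation values.

    ``degenerate`` marks the case of fewer than three available scores,
    where the mean of what exists is reported instead.
    """

    top_three: tuple
    mcv: float
    n_comparisons: int
    degenerate: bool = False


@dataclass(frozen=True)
class RankTestResult:
    test: str
    statistic: float
    p: float
    n: int
    extras: dict = field(default_factory=dict)


def select_exemplars(type_calls, k: int, rng_seed=None):
    """Sample ``k`` distinct calls of one type uniformly without
    replacement; if fewer than ``k`` exist all are used.  Deterministic
    under a fixed seed."""
    calls = list(type_calls)
    if k < 1:
        raise SimilarityError("k must be >= 1")
    if not calls:
        raise SimilarityError("cannot select exemplars from an empty type")
    if len(calls) <= k:
        return calls
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    idx = rng.choice(len(calls), size=k, replace=False)
    return [calls[i] for i in sorted(idx)]


def _prepare_spectrogram(ex: Exemplar, config: SpectroConfig) -> Spectrogram:
    w, rate = ex.waveform, ex.sample_rate_hz
    target = config.common_rate_hz or rate
    if rate != target:
        if not config.allow_resample:
            raise SpectroError(
                f"{ex.call_id}: sample rate {rate} differs from the "
                f"configured common rate {target} and resampling is disabled"
            )
        w = resample_to(w, rate, target)
        rate = target
    spec = compute_spectrogram(
        w, rate, fft_size=config.fft_size,
        time_step_s=config.time_step_ms / 1000.0,
        window=config.window, peak_normalize=config.peak_normalize,
        magnitude=config.magnitude,
    )
    if config.band_lo_hz is not None or config.band_hi_hz is not None:
        lo = config.band_lo_hz or 0.0
        hi = config.band_hi_hz or rate / 2.0
        spec = band_limit(spec, lo, min(hi, rate / 2.0))
    return spec


class RepertoireScorer:
    """Caches spectrograms and FFT plans so a call compared against many
    others is transformed once.  Plan lengths are bucketed to multiples
    of 32 frames, so calls of similar duration share cached plans; the
    scores are numerically equivalent to pairwise :func:`xcorr_score`.
    """

    def __init__(self, config: SpectroConfig = SpectroConfig()):
        self.config = config
        self._specs: dict[str, Spectrogram] = {}
        self._plans: dict[tuple, XcorrPlan] = {}

    def spectrogram(self, ex: Exemplar) -> Spectrogram:
        if ex.call_id not in self._specs:
            self._specs[ex.call_id] = _prepare_spectrogram(ex, self.config)
        return self._specs[ex.call_id]

    def _plan(self, ex: Exemplar, length: int) -> XcorrPlan:
        key = (ex.call_id, length)
        if key not in self._plans:
            self._plans[key] = XcorrPlan(self.spectrogram(ex), length)
        return self._plans[key]

    def score(self, a: Exemplar, b: Exemplar):
        sa, sb = self.spectrogram(a), self.spectrogram(b)
        need = sa.n_frames + sb.n_frames - 1
        length = -(-need // 32) * 32
        return _score_plans(self._plan(a, length), self._plan(b, length),
                            self.config.max_lag_frames,
                            self.config.min_overlap_frac)


def repertoire_scores(
    male_exemplars,
    female_exemplars,
    config: SpectroConfig = SpectroConfig(),
    scorer: RepertoireScorer | None = None,
) -> pd.DataFrame:
    """All pairwise cross-correlation scores between two repertoires.

    ``male_exemplars``/``female_exemplars`` map type label -> list of
    Exemplar.  One row is produced per (male exemplar, female exemplar)
    pair; a pair whose comparison fails is recorded with a NaN score and
    the error message, never silently dropped.  Pass a shared
    ``scorer`` to reuse spectrograms across many repertoire pairs.
    """
    if not male_exemplars or not female_exemplars:
        raise SimilarityError("both repertoires need at least one exemplar")
    if scorer is None:
        scorer = RepertoireScorer(config)

    rows = []
    for mtype, mexs in male_exemplars.items():
        for ftype, fexs in female_exemplars.items():
            for me, fe in itertools.product(mexs, fexs):
                row = dict(male_type=mtype, female_type=ftype,
                           male_call=me.call_id, female_call=fe.call_id,
                           xcorr=np.nan, best_lag=np.nan, error="")
                try:
                    sc = scorer.score(me, fe)
                    if sc.undefined:
                        row["error"] = "undefined score (zero-variance overlap)"
                    else:
                        row["xcorr"] = sc.value
                        row["best_lag"] = sc.best_lag_frames
                except SpectroError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def max_crosscorr_value(scores) -> MCVResult:
    """Mean of the three largest finite scores pooled over all comparisons."""
    vals = np.asarray(list(scores), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SimilarityError("no finite scores to summarize")
    top = np.sort(vals)[::-1][:3]
    return MCVResult(
        top_three=tuple(float(v) for v in top),
        mcv=float(top.mean()),
        n_comparisons=int(vals.size),
        degenerate=vals.size < 3,
    )


def _signed_rank_statistic(diffs: np.ndarray) -> float:
    """W+ = sum of midranks of |d| over positive differences (zeros dropped)."""
    d = diffs[diffs != 0]
    if d.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def _mean_sem(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    return {"mean": float(np.mean(x)), "sem": sem}


def within_vs_extra_pair(mcv_within, mcv_extra) -> RankTestResult:
    """Wilcoxon matched-pairs signed-rank test of each male's within-pair
    MCV against his mean extra-pair MCV."""
    w = np.asarray(mcv_within, dtype=float)
    e = np.asarray(mcv_extra, dtype=float)
    if w.shape != e.shape:
        raise SimilarityError("within and extra vectors must be paired")
    diffs = w - e
    stat = _signed_rank_statistic(diffs)
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(w, e, zero_method="wilcox",
                                 method="auto").pvalue)
    return RankTestResult(
        test="wilcoxon_signed_rank", statistic=stat, p=p, n=int(w.size),
        extras={"within": _mean_sem(w), "extra": _mean_sem(e)},
    )


def type_consistency_stats(within_type_scores, among_type_scores,
                           alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U comparing same-type with different-type scores."""
    a = np.asarray(within_type_scores, dtype=float)
    b = np.asarray(among_type_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SimilarityError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankTestResult(
            test="mann_whitney_u", statistic=a.size * b.size / 2.0, p=1.0,
            n=int(pooled.size),
            extras={"within": _mean_sem(a), "among": _mean_sem(b)},
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return RankTestResult(
        test="mann_whitney_u", statistic=float(res.statistic),
        p=float(res.pvalue), n=int(pooled.size),
        extras={"within": _mean_sem(a), "among": _mean_sem(b)},
    )


def score_group_anova(scores_by_rating: dict) -> dict:
    """One-way ANOVA of cross-correlation values across the visual-rating
    groups (1/2/3), with Scheffe-adjusted pairwise comparisons."""
    from .ieg_stats import one_way_anova  # shared ANOVA core

    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_rating.items()}
    if len(groups) < 2:
        raise SimilarityError("need at least two rating groups")
    for k, v in groups.items():
        if v.size < 2:
            raise SimilarityError(f"group {k!r} needs at least two values")
    anova = one_way_anova(groups)

    labels = sorted(groups)
    n_tot = sum(g.size for g in groups.values())
    k = len(groups)
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_err = n_tot - k
    mse = sse / df_err
    scheffe = {}
    for i, j in itertools.combinations(labels, 2):
        gi, gj = groups[i], groups[j]
        diff = gi.mean() - gj.mean()
        if mse == 0:
            p = 0.0 if diff != 0 else 1.0
            fs = math.inf if diff != 0 else 0.0
        else:
            fs = diff**2 / (mse * (1 / gi.size + 1 / gj.size)) / (k - 1)
            p = float(stats.f.sf(fs, k - 1, df_err))
        scheffe[f"{i}_vs_{j}"] = {"mean_diff": float(diff),
                                  "F": float(fs), "p": p}
    return {"anova": anova, "scheffe": scheffe,
            "group_summaries": {str(k): _mean_sem(v)
                                for k, v in groups.items()}}


def prepost_score_test(pre_scores, post_scores) -> RankTestResult:
    """Wilcoxon matched-pairs test of per-male visual similarity scores
    before vs after pairing."""
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.shape != post.shape:
        raise SimilarityError("pre and post vectors must be paired")
    diffs = post - pre
    stat = _signed_rank_statistic(diffs)
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(post, pre, zero_method="wilcox",
                                 method="auto").pvalue)
    return RankTestResult(
        test="wilcoxon_signed_rank", statistic=stat, p=p, n=int(pre.size),
        extras={"pre": _mean_sem(pre), "post": _mean_sem(post)},
    )


def kruskal_groups(scores_by_group: dict) -> RankTestResult:
    """Kruskal-Wallis H across stimulus groups, midranks for ties."""
    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_group.items()}
    if len(groups) < 2:
        raise SimilarityError("need at least two groups")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return RankTestResult(test="kruskal_wallis", statistic=0.0, p=1.0,
                              n=int(pooled.size))
    res = stats.kruskal(*groups.values())
    return RankTestResult(
        test="kruskal_wallis", statistic=float(res.statistic),
        p=float(res.pvalue), n=int(pooled.size),
        extras={str(k): _mean_sem(v) for k, v in groups.items()},
    )


def reduce_visual_scores(scores) -> int:
    """Collapse the pairwise 1/2/3 ratings of one bird pair to a single
    CC Similarity Score: the highest rating over all comparisons."""
    vals = [int(s) for s in scores if s is not None and not (
        isinstance(s, float) and math.isnan(s))]
    if not vals:
        raise SimilarityError("no visual scores to reduce")
    if any(v not in (1, 2, 3) for v in vals):
        raise SimilarityError("visual scores must be 1, 2 or 3")
    return max(vals)
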