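"""Immediate-early-gene quantification and inference chain.

Cell counts from fixed 290 x 450 um counting frames (four per region
per bird, two per hemisphere) are converted to immunoreactive-cell
densities per mm^2, log-transformed, and pushed through the study's
test battery: two-way and one-way fixed-effects ANOVAs with Bonferroni
post-hocs, pairwise inter-region Pearson correlations (with the exact
small-n p-value and an explicit undefined flag for zero-variance
variables), Bayesian simple regressions with a credible-interval zero
criterion, scaled-profile rank-concordance patterns, and Spearman tests
of behavioural scores against densities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BayesSimpleRegression

FRAME_AREA_MM2 = 0.290 * 0.450  # counting frame, exact
REGIONS = ("CMM", "dNCM", "vNCM", "HP")
SUBREGIONS = ("CMM", "dNCM", "vNCM")
GROUPS = ("MATE", "UNFAMILIAR", "SILENCE")
REGION_PAIRS = (("CMM", "dNCM"), ("CMM", "vNCM"), ("dNCM", "vNCM"))


class IEGError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float

    def as_dict(self) -> dict:
        return {"effect": self.effect, "F": self.F,
                "df1": self.df1, "df2": self.df2, "p": self.p}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-tailed p, or an undefined flag when either
    variable has zero variance (r and p are then NaN, never 0)."""

    r: float
    n: int
    p: float
    undefined: bool = False

    def as_dict(self) -> dict:
        return {"r": None if self.undefined else self.r,
                "n": self.n,
                "p": None if self.undefined else self.p,
                "undefined": self.undefined}


@dataclass(frozen=True)
class PatternProfile:
    """Scaled expression profiles and their rank concordance.

    ``percent`` holds, per region, each bird's density as a percentage
    of that region's maximum bird (the maximum maps to exactly 100%).
    ``ranks`` holds the per-region midrank of each bird (1 = highest).
    ``concordant`` is true iff the rank vector is identical across all
    regions; ``kendalls_w`` is the tie-corrected coefficient of
    concordance of the region rankings.
    """

    birds: tuple
    regions: tuple
    percent: dict
    ranks: dict
    concordant: bool
    kendalls_w: float


def density_from_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Mean frame count divided by the 0.1305 mm^2 frame area.

    One output row per bird x group x region x ieg.  Cells with fewer
    than the nominal four frames are averaged over the frames present
    (recorded in ``n_frames``); a cell with no frames is an error.
    """
    required = {"bird_id", "group", "region", "ieg", "count"}
    missing = required - set(table.columns)
    if missing:
        raise IEGError(f"count table lacks columns {sorted(missing)}")
    if (table["count"] < 0).any():
        raise IEGError("counts must be nonnegative")
    keys = ["bird_id", "group", "region", "ieg"]
    grouped = table.groupby(keys, sort=True)["count"]
    out = grouped.agg(["mean", "size"]).reset_index()
    if (out["size"] > 4).any():
        raise IEGError("more than 4 frames for a bird x region x ieg cell")
    out["density_per_mm2"] = out.pop("mean") / FRAME_AREA_MM2
    out = out.rename(columns={"size": "n_frames"})
    return out[keys + ["density_per_mm2", "n_frames"]]


def log_transform(x, base: str = "ln", offset: float = 1.0):
    """Monotone log transform applied before the parametric tests.

    Default is ln(x + 1), which maps 0 to 0 and tolerates the zero
    densities that occur (e.g. basal Fos in the vNCM); base "log10"
    is available by configuration.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise IEGError("densities must be nonnegative")
    shifted = arr + offset
    out = np.log(shifted) if base == "ln" else None
    if base == "log10":
        out = np.log10(shifted)
    elif base != "ln":
        raise IEGError(f"unknown log base {base!r}")
    return out if arr.shape else float(out)


def f_survival(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise IEGError("degrees of freedom must be >= 1")
    if F < 0:
        raise IEGError("F must be nonnegative")
    return float(stats.f.sf(F, df1, df2))


def one_way_anova(values_by_group: dict, effect: str = "group") -> AnovaResult:
    """Between-groups fixed-effects F with df (k-1, N-k).

    Total zero variance is reported as F = 0, p = 1 rather than 0/0.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise IEGError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise IEGError("each group needs at least two values")
    n_tot = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_tot - k
    if ssw == 0 and ssb == 0:
        return AnovaResult(effect, 0.0, df1, df2, 1.0)
    if ssw == 0:
        return AnovaResult(effect, float("inf"), df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(effect, float(F), df1, df2, f_survival(F, df1, df2))


def two_way_anova(values, factor_a, factor_b,
                  names: tuple = ("A", "B")) -> dict:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Requires a fully crossed, balanced design (the study's case, where
    Type-I and Type-III sums of squares coincide); unbalanced or empty
    cells raise.  Returns AnovaResults for the two main effects and the
    interaction, with dfs (a-1), (b-1), (a-1)(b-1) against N - ab.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape == fa.shape == fb.shape):
        raise IEGError("values and factors must align")
    la = sorted(set(fa.tolist()))
    lb = sorted(set(fb.tolist()))
    a, b = len(la), len(lb)
    cells = {}
    for ai, bi in itertools.product(la, lb):
        cell = y[(fa == ai) & (fb == bi)]
        if cell.size == 0:
            raise IEGError(f"empty cell ({ai}, {bi})")
        cells[(ai, bi)] = cell
    sizes = {len(c) for c in cells.values()}
    if len(sizes) != 1:
        raise IEGError("unbalanced design; cell sizes differ")
    n = sizes.pop()
    if n < 2:
        raise IEGError("need at least two replicates per cell")

    grand = y.mean()
    mean_a = {ai: y[fa == ai].mean() for ai in la}
    mean_b = {bi: y[fb == bi].mean() for bi in lb}
    ss_a = b * n * sum((mean_a[ai] - grand) ** 2 for ai in la)
    ss_b = a * n * sum((mean_b[bi] - grand) ** 2 for bi in lb)
    ss_ab = n * sum(
        (cells[(ai, bi)].mean() - mean_a[ai] - mean_b[bi] + grand) ** 2
        for ai, bi in cells
    )
    ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_err = y.size - a * b
    mse = ss_err / df_err

    def mk(effect, ss, df):
        if mse == 0:
            return AnovaResult(effect, 0.0 if ss == 0 else float("inf"),
                               df, df_err, 1.0 if ss == 0 else 0.0)
        F = (ss / df) / mse
        return AnovaResult(effect, float(F), df, df_err,
                           f_survival(F, df, df_err))

    na, nb_ = names
    return {
        na: mk(na, ss_a, df_a),
        nb_: mk(nb_, ss_b, df_b),
        f"{na}x{nb_}": mk(f"{na}x{nb_}", ss_ab, df_ab),
    }


def mixed_anova(values, between, within, subject,
                names: tuple = ("between", "within")) -> dict:
    """Split-plot (between x within subjects) ANOVA option.

    The between factor is tested against subjects-within-groups; the
    within factor and the interaction against the within-subjects
    residual.  Requires one observation per subject x within level.
    """
    y = np.asarray(values, dtype=float)
    gb = np.asarray(between)
    gw = np.asarray(within)
    su = np.asarray(subject)
    la, lb = sorted(set(gb.tolist())), sorted(set(gw.tolist()))
    subs = sorted(set(su.tolist()))
    a, b, s = len(la), len(lb), len(subs)
    if y.size != s * b:
        raise IEGError("need exactly one value per subject x within level")
    sub_group = {}
    for i, sub in enumerate(su):
        sub_group.setdefault(sub, set()).add(gb[i])
    if any(len(g) != 1 for g in sub_group.values()):
        raise IEGError("each subject must belong to one between-group")
    n_per = s / a
    if n_per != int(n_per):
        raise IEGError("between-groups must have equal subject counts")

    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    sub_means = {x: y[su == x].mean() for x in subs}
    ss_subjects = b * sum((m - grand) ** 2 for m in sub_means.values())
    mean_a = {x: y[gb == x].mean() for x in la}
    mean_b = {x: y[gw == x].mean() for x in lb}
    ss_a = b * (s / a) * sum((mean_a[x] - grand) ** 2 for x in la)
    ss_sub_within = ss_subjects - ss_a
    ss_b = s * sum((mean_b[x] - grand) ** 2 for x in lb)
    ss_ab = 0.0
    for ai, bi in itertools.product(la, lb):
        cell = y[(gb == ai) & (gw == bi)]
        ss_ab += cell.size * (cell.mean() - mean_a[ai] - mean_b[bi] + grand) ** 2
    ss_err2 = ss_total - ss_subjects - ss_b - ss_ab

    df_a, df_sub = a - 1, s - a
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err2 = (b - 1) * (s - a)

    def mk(effect, ss, df, ss_e, df_e):
        mse = ss_e / df_e
        if mse <= 0:
            return AnovaResult(effect, 0.0 if ss == 0 else float("inf"),
                               df, df_e, 1.0 if ss == 0 else 0.0)
        F = (ss / df) / mse
        return AnovaResult(effect, float(F), df, df_e,
                           f_survival(F, df, df_e))

    na, nw = names
    return {
        na: mk(na, ss_a, df_a, ss_sub_within, df_sub),
        nw: mk(nw, ss_b, df_b, ss_err2, df_err2),
        f"{na}x{nw}": mk(f"{na}x{nw}", ss_ab, df_ab, ss_err2, df_err2),
    }


def bonferroni_posthoc(values_by_group: dict, pairs=None) -> dict:
    """Pairwise two-sample t-tests on the pooled one-way error term,
    with p multiplied by the number of comparisons (capped at 1)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise IEGError("need at least two groups")
    labels = sorted(groups)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    for i, j in pairs:
        if i not in groups or j not in groups:
            raise IEGError(f"pair ({i}, {j}) references an unknown group")
    n_tot = sum(g.size for g in groups.values())
    k = len(groups)
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_err = n_tot - k
    mse = sse / df_err
    m = len(pairs)
    out = {}
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        diff = gi.mean() - gj.mean()
        if mse == 0:
            raw = 0.0 if diff != 0 else 1.0
            tval = math.inf if diff != 0 else 0.0
        else:
            se = math.sqrt(mse * (1 / gi.size + 1 / gj.size))
            tval = diff / se
            raw = 2.0 * float(stats.t.sf(abs(tval), df_err))
        out[f"{i}_vs_{j}"] = {
            "mean_diff": float(diff), "t": float(tval), "df": df_err,
            "p_raw": raw, "p_adj": min(1.0, m * raw),
        }
    return out


def pearson_corr(x, y) -> CorrelationResult:
    """Product-moment correlation with two-tailed p from the exact
    t-transform t = r sqrt(n-2)/sqrt(1-r^2), df = n-2.

    At n = 4 the two-tailed p equals 1 - |r| exactly.  If either
    variable has zero variance the result is flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise IEGError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise IEGError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), n=n, p=float("nan"),
                                 undefined=True)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=min(1.0, p))


def region_correlation_matrix(densities: pd.DataFrame,
                              value_col: str = "density_per_mm2",
                              log: bool = True,
                              log_base: str = "ln") -> dict:
    """Pearson correlations between subregion densities across birds.

    ``densities`` holds one group x IEG slice with columns bird_id,
    region, and the value column.  Every bird must be present in all
    three subregions.  Returns one CorrelationResult per pair
    (CMM-dNCM, CMM-vNCM, dNCM-vNCM), computed on log-transformed
    densities by default.
    """
    piv = densities.pivot_table(index="bird_id", columns="region",
                                values=value_col, aggfunc="mean")
    for reg in SUBREGIONS:
        if reg not in piv.columns or piv[reg].isna().any():
            raise IEGError(f"a bird is missing region {reg}")
    out = {}
    for r1, r2 in REGION_PAIRS:
        v1 = piv[r1].to_numpy()
        v2 = piv[r2].to_numpy()
        if log:
            v1 = log_transform(v1, base=log_base)
            v2 = log_transform(v2, base=log_base)
        out[f"{r1}_vs_{r2}"] = pearson_corr(v1, v2)
    return out


def region_bayes_fits(densities: pd.DataFrame,
                      value_col: str = "density_per_mm2",
                      log: bool = True, log_base: str = "ln",
                      prior: str = "reference") -> dict:
    """Bayesian simple regressions for each subregion pair, with the
    95% credible-interval zero criterion."""
    piv = densities.pivot_table(index="bird_id", columns="region",
                                values=value_col, aggfunc="mean")
    out = {}
    for r1, r2 in REGION_PAIRS:
        v1 = piv[r1].to_numpy()
        v2 = piv[r2].to_numpy()
        if log:
            v1 = log_transform(v1, base=log_base)
            v2 = log_transform(v2, base=log_base)
        key = f"{r1}_vs_{r2}"
        if np.ptp(v1) == 0:
            out[key] = None  # slope unidentified; mirrors undefined r
            continue
        out[key] = BayesSimpleRegression(v2, v1, prior=prior).fit()
    return out


def pattern_profiles(densities: pd.DataFrame,
                     value_col: str = "density_per_mm2") -> PatternProfile:
    """Scale each subregion to its maximum bird (=100%) and compare the
    birds' rank order across subregions."""
    piv = densities.pivot_table(index="bird_id", columns="region",
                                values=value_col, aggfunc="mean")
    for reg in SUBREGIONS:
        if reg not in piv.columns or piv[reg].isna().any():
            raise IEGError(f"a bird is missing region {reg}")
    if len(piv) < 2:
        raise IEGError("need at least two birds")
    birds = tuple(piv.index)
    percent, ranks = {}, {}
    rank_matrix = []
    for reg in SUBREGIONS:
        v = piv[reg].to_numpy(dtype=float)
        vmax = v.max()
        if vmax <= 0:
            raise IEGError(f"region {reg} has no positive density")
        percent[reg] = dict(zip(birds, (100.0 * v / vmax).tolist()))
        rk = stats.rankdata(-v, method="average")  # 1 = highest, midranks
        ranks[reg] = dict(zip(birds, rk.tolist()))
        rank_matrix.append(rk)
    rank_matrix = np.array(rank_matrix)  # regions x birds
    concordant = bool(np.all(rank_matrix == rank_matrix[0], axis=None))
    m, k = rank_matrix.shape
    r_sums = rank_matrix.sum(axis=0)
    s = float(((r_sums - m * (k + 1) / 2.0) ** 2).sum())
    tie_term = 0.0
    for row in rank_matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m * m * (k**3 - k) - m * tie_term
    w = 12.0 * s / denom if denom > 0 else float("nan")
    return PatternProfile(birds=birds, regions=SUBREGIONS, percent=percent,
                          ranks=ranks, concordant=concordant,
                          kendalls_w=w)


def spearman_score_vs_counts(scores, densities,
                             exact_max_n: int = 8) -> RankCorrelationResult:
    """Spearman rank correlation of behavioural similarity scores
    against IEG densities, with an exact permutation p for small n."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise IEGError("scores and densities must be paired vectors")
    if x.size < 3:
        raise IEGError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RankCorrelationResult(rho=float("nan"), n=x.size,
                                     p=float("nan"), undefined=True)
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = ry[list(perm)]
            rr = np.corrcoef(rx, rp)[0, 1]
            if abs(rr) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return RankCorrelationResult(rho=rho, n=n, p=p)


@dataclass(frozen=True)
class RankCorrelationResult:
    rho: float
    n: int
    p: float
    undefined: bool = False
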