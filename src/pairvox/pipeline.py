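"""End-to-end orchestration: configuration, the two analysis arms, and
deterministic report bundles.

``run_similarity`` chains exemplar selection -> spectrogram
cross-correlation -> MCV -> behavioural statistics for every male x
female comparison; ``run_ieg`` chains density conversion -> log
transform -> ANOVAs with post-hocs -> inter-region correlations ->
Bayesian regressions -> pattern profiles.  All randomness flows from
the seeds named in the configuration, and identical inputs + seed +
config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ieg_stats, similarity
from .audio import read_wav
from .ieg_stats import (
    REGIONS,
    SUBREGIONS,
    density_from_counts,
    log_transform,
    one_way_anova,
    bonferroni_posthoc,
    pattern_profiles,
    region_bayes_fits,
    region_correlation_matrix,
    two_way_anova,
)
from .similarity import (
    Exemplar,
    SpectroConfig,
    max_crosscorr_value,
    repertoire_scores,
    select_exemplars,
    within_vs_extra_pair,
)

log = logging.getLogger("pairvox")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class IEGConfig:
    log_base: str = "ln"
    log_offset: float = 1.0
    prior: str = "reference"
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Validated defaults for both analysis arms."""

    spectro: SpectroConfig = field(default_factory=SpectroConfig)
    exemplars_per_type: int = 5
    ieg: IEGConfig = field(default_factory=IEGConfig)
    seed: int = 0
    report_precision: int = 3

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        data = data or {}
        spectro = SpectroConfig(**data.pop("spectro", {}))
        ieg = IEGConfig(**data.pop("ieg", {}))
        return cls(spectro=spectro, ieg=ieg, **data)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# similarity arm


def _exemplar_map(annotations: pd.DataFrame, bird: str, timepoint: str,
                  audio_of, k: int, rng: np.random.Generator) -> dict:
    sub = annotations[(annotations["bird_id"] == bird)
                      & (annotations["timepoint"] == timepoint)]
    out = {}
    for type_label, grp in sub.groupby("type_label", sort=True):
        ids = list(grp["call_id"])
        chosen = select_exemplars(ids, k, rng)
        exs = []
        for cid in chosen:
            w, rate = audio_of(cid)
            exs.append(Exemplar(call_id=cid, type_label=type_label,
                                waveform=w, sample_rate_hz=rate))
        out[type_label] = exs
    return out


def compute_pair_comparisons(
    annotations: pd.DataFrame,
    pairs: pd.DataFrame,
    audio_of,
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every male's post-pairing repertoire against every female's
    pre-pairing repertoire.

    ``audio_of`` maps a call_id to (waveform, sample_rate).  Returns
    (scores, mcv): per-exemplar-pair scores and the per-(male, female)
    MCV table with the within/extra relation.
    """
    required = {"bird_id", "sex", "timepoint", "call_id", "type_label"}
    missing = required - set(annotations.columns)
    if missing:
        raise PipelineError(f"annotations lack columns {sorted(missing)}")
    if annotations.empty:
        raise PipelineError("annotations table is empty")
    rng = np.random.default_rng(config.seed)
    males = sorted(pairs["male_id"])
    females = sorted(pairs["female_id"])
    mate_of = dict(zip(pairs["male_id"], pairs["female_id"]))

    male_reps = {m: _exemplar_map(annotations, m, "post", audio_of,
                                  config.exemplars_per_type, rng)
                 for m in males}
    female_reps = {f: _exemplar_map(annotations, f, "pre", audio_of,
                                    config.exemplars_per_type, rng)
                   for f in females}

    scorer = similarity.RepertoireScorer(config.spectro)
    score_frames = []
    mcv_rows = []
    for m in males:
        for f in females:
            df = repertoire_scores(male_reps[m], female_reps[f],
                                   config.spectro, scorer=scorer)
            df.insert(0, "male_id", m)
            df.insert(1, "female_id", f)
            relation = "within_pair" if mate_of.get(m) == f else "extra_pair"
            df.insert(2, "relation", relation)
            score_frames.append(df)
            finite = df["xcorr"].dropna()
            if finite.empty:
                mcv_rows.append(dict(male_id=m, female_id=f,
                                     relation=relation, mcv=np.nan,
                                     n_comparisons=0, degenerate=True))
                continue
            res = max_crosscorr_value(finite)
            mcv_rows.append(dict(male_id=m, female_id=f, relation=relation,
                                 mcv=res.mcv, n_comparisons=res.n_comparisons,
                                 degenerate=res.degenerate))
    scores = pd.concat(score_frames, ignore_index=True)
    mcv = pd.DataFrame(mcv_rows)
    return scores, mcv


def within_extra_summary(mcv: pd.DataFrame) -> dict:
    """Per-male within-pair MCV vs mean extra-pair MCV, with the
    matched-pairs signed-rank test."""
    within = mcv[mcv["relation"] == "within_pair"].set_index("male_id")["mcv"]
    extra = (mcv[mcv["relation"] == "extra_pair"]
             .groupby("male_id")["mcv"].mean())
    males = sorted(set(within.index) & set(extra.index))
    if not males:
        raise PipelineError("no males with both within- and extra-pair MCVs")
    res = within_vs_extra_pair(within.loc[males].to_numpy(),
                               extra.loc[males].to_numpy())
    return {"test": res, "males": males,
            "within": within.loc[males].to_dict(),
            "extra": extra.loc[males].to_dict()}


def best_male_type(scores: pd.DataFrame) -> dict:
    """For each within-pair comparison, the male call type holding the
    single highest cross-correlation score (the putative imitation)."""
    out = {}
    sub = scores[(scores["relation"] == "within_pair")
                 & scores["xcorr"].notna()]
    for male, grp in sub.groupby("male_id"):
        out[male] = grp.loc[grp["xcorr"].idxmax(), "male_type"]
    return out


def run_similarity(config: RunConfig, annotations, pairs, out_dir,
                   audio_of=None) -> dict:
    """Full similarity arm: scores, MCVs, behavioural stats, report files.

    ``annotations``/``pairs`` are DataFrames or CSV paths; when
    ``audio_of`` is None, waveforms are read from each annotation row's
    ``wav_path`` (relative to the annotations CSV, when a path is given).
    """
    base = Path(".")
    if isinstance(annotations, (str, Path)):
        base = Path(annotations).parent
        annotations = pd.read_csv(annotations)
    if isinstance(pairs, (str, Path)):
        pairs = pd.read_csv(pairs)
    if annotations.empty:
        raise PipelineError("annotations table is empty")
    if audio_of is None:
        if "wav_path" not in annotations.columns:
            raise PipelineError("annotations need a wav_path column when "
                                "no in-memory audio is supplied")
        paths = dict(zip(annotations["call_id"], annotations["wav_path"]))

        def audio_of(cid):
            return read_wav(base / paths[cid])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("similarity run: %d annotation rows, %d pairs, seed %d",
             len(annotations), len(pairs), config.seed)

    scores, mcv = compute_pair_comparisons(annotations, pairs, audio_of,
                                           config)
    if (mcv["relation"] == "extra_pair").any():
        summary = within_extra_summary(mcv)
        within_extra = {
            "statistic": summary["test"].statistic,
            "p": summary["test"].p,
            "n": summary["test"].n,
            **summary["test"].extras,
        }
    else:
        within_extra = {"note": "no extra-pair comparisons (single pair)"}
    stats_payload = {
        "within_vs_extra": within_extra,
        "n_comparisons": int(len(scores)),
        "n_failed": int(scores["xcorr"].isna().sum()),
        "best_male_type": best_male_type(scores),
        "seed": config.seed,
    }

    if "visual_score" in annotations.columns:
        vis = annotations.dropna(subset=["visual_score"])
        per_bird_tp = (vis.groupby(["bird_id", "timepoint"])["visual_score"]
                       .max())
        stats_payload["visual_scores"] = {
            f"{b}|{t}": float(v) for (b, t), v in per_bird_tp.items()
        }

    scores.to_csv(out / "scores.csv", index=False, float_format="%.10g",
                  lineterminator="\n")
    mcv.to_csv(out / "mcv.csv", index=False, float_format="%.10g",
               lineterminator="\n")
    _write_json(stats_payload, out / "stats.json")
    return {"scores": scores, "mcv": mcv, "stats": stats_payload}


# ---------------------------------------------------------------------------
# IEG arm


def analyze_ieg_table(counts: pd.DataFrame, config: IEGConfig = IEGConfig(),
                      scores_by_bird: dict | None = None) -> dict:
    """The complete IEG statistics chain on a long-format count table.

    Produces, per IEG: the two-way Stimulus x Brain-Region ANOVA on
    log densities, per-region one-way ANOVAs with Bonferroni post-hocs,
    and per stimulus group the three inter-subregion Pearson
    correlations, Bayesian regression fits with the includes-zero flag,
    and the scaled pattern profile.  Row order of the input is
    irrelevant.
    """
    if "density_per_mm2" in counts.columns:
        dens = counts.copy()
        if "n_frames" not in dens.columns:
            dens["n_frames"] = 4
    else:
        dens = density_from_counts(counts)
    dens = dens.sort_values(["ieg", "group", "region", "bird_id"],
                            kind="mergesort").reset_index(drop=True)
    dens["log_density"] = log_transform(dens["density_per_mm2"].to_numpy(),
                                        base=config.log_base,
                                        offset=config.log_offset)
    report: dict = {"alpha": config.alpha, "per_ieg": {}}
    for ieg, sub in dens.groupby("ieg", sort=True):
        entry: dict = {}
        regions_present = [r for r in REGIONS
                           if r in set(sub["region"])]
        entry["two_way_anova"] = {
            k: v.as_dict() for k, v in two_way_anova(
                sub["log_density"].to_numpy(),
                sub["group"].to_numpy(), sub["region"].to_numpy(),
                names=("Stimulus", "Region"),
            ).items()
        }
        entry["one_way_by_region"] = {}
        for region in regions_present:
            rsub = sub[sub["region"] == region]
            groups = {g: grp["log_density"].to_numpy()
                      for g, grp in rsub.groupby("group", sort=True)}
            res = one_way_anova(groups, effect=f"Stimulus[{region}]")
            entry["one_way_by_region"][region] = {
                "anova": res.as_dict(),
                "bonferroni": bonferroni_posthoc(groups),
            }
        entry["per_group"] = {}
        for group, gsub in sub.groupby("group", sort=True):
            gslice = gsub[gsub["region"].isin(SUBREGIONS)]
            n_birds = gslice["bird_id"].nunique()
            gentry: dict = {"n_birds": int(n_birds)}
            if n_birds < 3:
                gentry["note"] = ("fewer than 3 birds; correlations "
                                  "skipped")
            else:
                corr = region_correlation_matrix(
                    gslice, log=True, log_base=config.log_base)
                gentry["pearson"] = {k: v.as_dict() for k, v in corr.items()}
                fits = region_bayes_fits(gslice, log=True,
                                         log_base=config.log_base,
                                         prior=config.prior)
                gentry["bayes"] = {
                    k: (None if v is None else {
                        "slope_mean": v.slope_mean,
                        "ci95_lo": v.ci95_lo, "ci95_hi": v.ci95_hi,
                        "includes_zero": v.includes_zero,
                        "prior": v.prior,
                    }) for k, v in fits.items()
                }
                try:
                    prof = pattern_profiles(gslice)
                    gentry["pattern"] = {
                        "concordant": prof.concordant,
                        "kendalls_w": prof.kendalls_w,
                        "percent": prof.percent,
                        "ranks": prof.ranks,
                    }
                except ieg_stats.IEGError as exc:
                    gentry["pattern"] = {"note": str(exc)}
            entry["per_group"][group] = gentry
        if scores_by_bird:
            spearman = {}
            for region in regions_present:
                rsub = sub[sub["region"] == region]
                for group, grp in rsub.groupby("group", sort=True):
                    birds = [b for b in grp["bird_id"]
                             if b in scores_by_bird]
                    if len(birds) < 3:
                        continue
                    gsel = grp.set_index("bird_id").loc[birds]
                    res = ieg_stats.spearman_score_vs_counts(
                        [scores_by_bird[b] for b in birds],
                        gsel["density_per_mm2"].to_numpy(),
                    )
                    spearman[f"{group}|{region}"] = {
                        "rho": None if res.undefined else res.rho,
                        "n": res.n,
                        "p": None if res.undefined else res.p,
                        "undefined": res.undefined,
                    }
            entry["spearman_score_vs_density"] = spearman
        report["per_ieg"][ieg] = entry
    return report


def _round_floats(obj, nd: int):
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, float):
        # round half to even, mirroring the printed precision convention
        return float(np.format_float_positional(
            obj, precision=nd, unique=False, fractional=True))
    return obj


def summarize_ieg_report(report: dict, nd: int = 3) -> str:
    """Human-readable digest; every number here is also present at full
    precision in the machine report."""
    lines = []
    for ieg, entry in sorted(report["per_ieg"].items()):
        lines.append(f"== {ieg} ==")
        for eff, res in entry["two_way_anova"].items():
            lines.append(
                f"  two-way {eff}: F({res['df1']},{res['df2']}) = "
                f"{res['F']:.{nd}f}, p = {res['p']:.{nd}f}")
        for region, block in entry["one_way_by_region"].items():
            res = block["anova"]
            lines.append(
                f"  one-way {region}: F({res['df1']},{res['df2']}) = "
                f"{res['F']:.{nd}f}, p = {res['p']:.{nd}f}")
        for group, gentry in entry["per_group"].items():
            if "pearson" not in gentry:
                lines.append(f"  {group}: {gentry.get('note', 'no data')}")
                continue
            for pair, c in gentry["pearson"].items():
                if c["undefined"]:
                    lines.append(f"  {group} {pair}: r undefined "
                                 "(zero-variance expression)")
                else:
                    lines.append(
                        f"  {group} {pair}: r = {c['r']:.{nd}f}, "
                        f"p = {c['p']:.{nd}f}")
            excl = [p for p, b in gentry["bayes"].items()
                    if b is not None and not b["includes_zero"]]
            lines.append(f"  {group}: slope CIs excluding zero: "
                         f"{', '.join(excl) if excl else 'none'}")
    return "\n".join(lines) + "\n"


def run_ieg(config: RunConfig, counts, out_dir,
            scores_by_bird: dict | None = None) -> dict:
    """Full IEG arm: validates the table, runs the chain, writes the
    JSON report, a tidy CSV of test results and a text summary."""
    if isinstance(counts, (str, Path)):
        counts = pd.read_csv(counts)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("ieg run: %d rows", len(counts))
    report = analyze_ieg_table(counts, config.ieg,
                               scores_by_bird=scores_by_bird)
    _write_json(report, out / "ieg_report.json")

    tidy_rows = []
    for ieg, entry in report["per_ieg"].items():
        for eff, res in entry["two_way_anova"].items():
            tidy_rows.append(dict(ieg=ieg, test="two_way_anova", unit=eff,
                                  statistic=res["F"], p=res["p"]))
        for region, block in entry["one_way_by_region"].items():
            res = block["anova"]
            tidy_rows.append(dict(ieg=ieg, test="one_way_anova", unit=region,
                                  statistic=res["F"], p=res["p"]))
        for group, gentry in entry["per_group"].items():
            for pair, c in gentry.get("pearson", {}).items():
                tidy_rows.append(dict(ieg=ieg, test="pearson",
                                      unit=f"{group}|{pair}",
                                      statistic=c["r"], p=c["p"]))
    pd.DataFrame(tidy_rows).to_csv(out / "ieg_tests.csv", index=False,
                                   float_format="%.10g", lineterminator="\n")
    (out / "ieg_summary.txt").write_text(summarize_ieg_report(report))
    return report
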