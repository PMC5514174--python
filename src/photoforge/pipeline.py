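"""End-to-end run: generate -> Delta-E -> simulate -> chance -> SDT ->
segmentation -> correlations -> covariate models -> report bundle.

Every stage draws from a seed derived deterministically from the single
root seed, so the same config produces byte-identical JSON summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, gridchance, models, observer, scenegen, sdtstats

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("photoforge")


@dataclass
class PipelineConfig:
    design: str = "exp1"
    n_scenes: int = 10
    n_manipulated_scenes: int = 6
    n_subjects: int = 200
    trials_per_subject: int = 10
    seed: int = 0
    mc_draws: int = 1_000_000
    n_boot: int = 500
    region_policy: str = "evidence"
    observer_overrides: dict = field(default_factory=dict)
    write_images: bool = False
    make_plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ReportBundle:
    config: PipelineConfig
    stimuli: scenegen.StimulusSet
    stim_table: pd.DataFrame
    trials: pd.DataFrame
    chance_mc: pd.DataFrame
    chance_empirical: pd.DataFrame | None
    accuracy: pd.DataFrame
    sdt: sdtstats.SDTResult
    subject_sdt: pd.DataFrame
    segmentation: pd.DataFrame | None
    correlations: dict
    gee: dict
    summary: dict


def _stage_seed(root: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(root, spawn_key=(k,)))


def _chance_table(
    stim_table: pd.DataFrame, grid: gridchance.Grid, draws: int, rng
) -> pd.DataFrame:
    """Monte Carlo + analytic chance per manipulation type and overall."""
    rows = []
    for label, sub in [
        *stim_table.groupby("mtype"),
        ("Overall", stim_table),
    ]:
        k = sub["n_acceptable"].astype(int).tolist()
        est = gridchance.mc_chance(k, grid.n_regions, draws=draws, rng=rng)
        rows.append(
            {
                "mtype": label,
                "mean_regions": float(np.mean(sub["n_regions"])),
                "mean_acceptable": float(np.mean(k)),
                "chance_mc": est.probability,
                "chance_analytic": est.analytic,
                "percent": est.percent,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
            }
        )
    return pd.DataFrame(rows).set_index("mtype")


def _per_image_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    manip = trials[trials["is_manipulated"]]
    acc = (
        manip.groupby(["image_id", "truth"])
        .agg(
            detect_acc=("detect_correct", "mean"),
            locate_acc=("locate_correct", "mean"),
            log_delta_e=("log_delta_e", "first"),
            n_trials=("detect_correct", "size"),
        )
        .reset_index()
    )
    return acc


def run_pipeline(config: PipelineConfig, out_dir=None) -> ReportBundle:
    """Execute the full synthetic experiment and analysis.

    Writes CSV/JSON (and optional PNG) artifacts under ``out_dir`` when
    given; always returns the in-memory bundle.
    """
    t0 = time.time()
    root = config.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-12s %+6.1fs", name, time.time() - t0)

    stage("generate")
    stimuli = scenegen.build_stimulus_set(
        config.n_scenes,
        design=config.design,
        rng=_stage_seed(root, 1),
        n_manipulated_scenes=config.n_manipulated_scenes,
    )
    if out is not None and config.write_images:
        scenegen.save_stimulus_set(stimuli, out / "stimuli")

    stage("delta_e")
    stim_table, region_sets = observer.prepare_stimulus_table(
        stimuli, policy=config.region_policy
    )

    stage("simulate")
    params = observer.ObserverParams(**config.observer_overrides)
    profiles = observer.simulate_subjects(config.n_subjects, rng=_stage_seed(root, 2))
    trials = observer.simulate_trials(
        stimuli,
        profiles,
        params,
        design=config.design,
        trials_per_subject=config.trials_per_subject,
        rng=_stage_seed(root, 3),
        stim_table=stim_table,
        region_sets=region_sets,
    )
    trials = gridchance.score_trials(trials, region_sets, stimuli.grid)

    stage("chance")
    chance_mc = _chance_table(stim_table, stimuli.grid, config.mc_draws, _stage_seed(root, 4))
    chance_empirical = None
    if config.design == "exp2":
        sets_by_image: dict[str, dict[str, gridchance.RegionSets]] = {}
        for (sid, mtype), sets in region_sets.items():
            sets_by_image.setdefault(sid, {})[mtype] = sets
        originals = trials[~trials["is_manipulated"]]
        chance_empirical = gridchance.empirical_chance(originals, sets_by_image)

    stage("sdt")
    H, F = sdtstats.hit_fa(trials)
    sdt = sdtstats.dprime_c(H, F, trials=trials, n_boot=config.n_boot, rng=_stage_seed(root, 5))
    subj_sdt = sdtstats.subject_sdt(trials)
    covars = trials.groupby("subject_id")[["gender", "belief", "interest", "frequency"]].first()
    subj_sdt = subj_sdt.merge(covars, on="subject_id")

    segmentation = None
    if config.design == "exp2":
        segmentation = sdtstats.segment_dl(trials)

    stage("accuracy")
    chance_map = chance_mc["chance_analytic"].to_dict()
    accuracy = sdtstats.accuracy_tables(trials, chance=chance_map)

    stage("correlations")
    per_image = _per_image_accuracy(trials)
    corr_detect = assoc.pearson_accuracy_vs_logdeltae(per_image, accuracy_col="detect_acc")
    corr_locate = assoc.pearson_accuracy_vs_logdeltae(per_image, accuracy_col="locate_acc")
    per_type = (
        per_image.groupby("truth")
        .agg(detect_acc=("detect_acc", "mean"), locate_acc=("locate_acc", "mean"),
             log_delta_e=("log_delta_e", "mean"))
        .reset_index()
    )
    corr_type_detect = assoc.pearson_accuracy_vs_logdeltae(per_type, accuracy_col="detect_acc")
    correlations = {
        "detect_image": corr_detect,
        "locate_image": corr_locate,
        "detect_type": corr_type_detect,  # n=5, descriptive only
    }

    stage("models")
    gee: dict[str, models.RepeatedMeasuresResults] = {}
    gee["detect"] = models.fit_repeated_binary(trials, "detect_accuracy")
    locate_preds = None
    if config.design == "exp1":
        # the detect-first design has no location response (or RT) for "no"
        # trials; the location model therefore uses the factors only
        locate_preds = ("belief", "gender", "interest", "frequency")
    gee["locate"] = models.fit_repeated_binary(trials, "locate_accuracy", predictors=locate_preds)
    if config.design == "exp2":
        gee["dl"] = models.fit_repeated_binary(trials, "dl_accuracy")
    gee["d_prime"] = models.fit_repeated_linear(subj_sdt, "d_prime")
    gee["c"] = models.fit_repeated_linear(subj_sdt, "c")

    stage("report")
    summary = {
        "design": config.design,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_pairs": len(stimuli.pairs),
        "mean_mask_regions": round(float(np.mean(stim_table["n_regions"])), 6),
        "detect_accuracy": round(float(accuracy.loc["Overall", "detect_acc"]), 6),
        "locate_accuracy": round(float(accuracy.loc["Overall", "locate_acc"]), 6),
        "hit_rate": round(sdt.H, 6),
        "false_alarm_rate": round(sdt.F, 6),
        "d_prime_aggregate": round(sdt.d_prime, 6),
        "criterion_aggregate": round(sdt.c, 6),
        "d_prime_subject_mean": round(float(subj_sdt["d_prime"].mean()), 6),
        "criterion_subject_mean": round(float(subj_sdt["c"].mean()), 6),
        "chance_overall_percent": int(chance_mc.loc["Overall", "percent"]),
        "chance_by_type_percent": {
            str(k): int(v) for k, v in chance_mc["percent"].drop("Overall").items()
        },
        "r_detect_image": round(correlations["detect_image"].r, 6),
        "r_locate_image": round(correlations["locate_image"].r, 6),
        "gee_detect_coefficients": {
            str(k): round(float(v), 6) for k, v in gee["detect"].coefficients["B"].items()
        },
    }
    if segmentation is not None:
        summary["segmentation_overall"] = {
            k: round(float(v), 6) for k, v in segmentation.loc["Overall"].items()
        }
    if chance_empirical is not None:
        summary["chance_empirical_overall_percent"] = gridchance.round_percent(
            float(chance_empirical.loc["Overall", "Overall"])
        )

    if out is not None:
        stim_table.to_csv(out / "delta_e.csv", index=False)
        trials.to_csv(out / "trials.csv", index=False)
        chance_mc.to_csv(out / "chance_mc.csv")
        if chance_empirical is not None:
            chance_empirical.to_csv(out / "chance_empirical.csv")
        accuracy.to_csv(out / "accuracy.csv")
        subj_sdt.to_csv(out / "subject_sdt.csv", index=False)
        if segmentation is not None:
            segmentation.to_csv(out / "segmentation.csv")
        per_image.to_csv(out / "per_image_accuracy.csv", index=False)
        for name, res in gee.items():
            res.coefficients.to_csv(out / f"gee_{name}.csv")
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
        if config.make_plots:
            _make_plots(out, accuracy, segmentation, per_image, chance_mc)

    stage("done")
    return ReportBundle(
        config=config,
        stimuli=stimuli,
        stim_table=stim_table,
        trials=trials,
        chance_mc=chance_mc,
        chance_empirical=chance_empirical,
        accuracy=accuracy,
        sdt=sdt,
        subject_sdt=subj_sdt,
        segmentation=segmentation,
        correlations=correlations,
        gee=gee,
        summary=summary,
    )


def _make_plots(out: Path, accuracy, segmentation, per_image, chance_mc) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    # accuracy by manipulation type, with chance markers
    by_type = accuracy.drop(index="Overall")
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(by_type))
    ax.bar(x - 0.2, by_type["detect_acc"], width=0.4, label="detect")
    ax.bar(x + 0.2, by_type["locate_acc"], width=0.4, label="locate")
    if "locate_chance" in by_type:
        ax.scatter(x + 0.2, by_type["locate_chance"], color="k", marker="_", s=300,
                   label="locate chance")
    ax.axhline(0.5, ls=":", color="grey")
    ax.set_xticks(x, by_type.index, rotation=20)
    ax.set_ylabel("proportion correct")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "accuracy_by_type.png", dpi=110)
    plt.close(fig)

    # log Delta-E vs per-image accuracy
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col, title in zip(axes, ("detect_acc", "locate_acc"), ("detect", "locate")):
        ax.scatter(per_image["log_delta_e"], per_image[col], s=18)
        ax.set_xlabel("log10 mean Delta-E")
        ax.set_title(title)
    axes[0].set_ylabel("proportion correct")
    fig.tight_layout()
    fig.savefig(fig_dir / "deltae_vs_accuracy.png", dpi=110)
    plt.close(fig)

    if segmentation is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        segmentation.drop(index="Overall").plot.bar(ax=ax)
        ax.set_ylabel("proportion of manipulated trials")
        fig.tight_layout()
        fig.savefig(fig_dir / "segmentation.png", dpi=110)
        plt.close(fig)
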