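"""Simulated observers for the detection and localization tasks.

The generative response model is logistic in the log mean Delta-E of the
stimulus: a subject answers "yes, manipulated" with probability

    P(yes | manipulated) = logistic(g0 + g1 * (log10 dE - x0) + covariates + w*e)
    P(yes | original)    = logistic(g0 + covariates + w*e)

where ``g0`` sets the false-alarm rate (response bias), ``g1`` the
sensitivity to physical image change, ``x0`` centres the signal scale and
``e`` is a per-trial attentiveness draw shared with the response-time model
(attentive trials are faster *and* more accurate, which is what gives the
RT-accuracy association downstream covariate models pick up).  Localization
succeeds (majority region chosen) with probability
``(1 - lapse) * logistic(d0 + d1 * (log10 dE - x0) + covariates)``;
otherwise — and always on original images — the response is drawn from a
region-popularity weight vector.

Two designs are supported: ``exp1`` asks for a location only after a "yes"
detection response; ``exp2`` asks on every trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colordiff import delta_e76, srgb_to_lab
from .gridchance import Grid, RegionSets, acceptable_regions
from .scenegen import MTYPE_LABELS, StimulusSet

__all__ = [
    "SubjectProfile",
    "ObserverParams",
    "DEFAULT_MIX",
    "simulate_subjects",
    "simulate_trials",
    "collapse_detection",
    "prepare_stimulus_table",
    "default_region_weights",
    "covariate_indicators",
]

# reference (coded 0) levels follow the descending category-order convention
COVARIATE_LEVELS = {
    "gender": ("male", "female"),
    "belief": ("low", "high"),
    "interest": ("not_interested", "interested"),
    "frequency": ("monthly_yearly_never", "daily_weekly"),
}

DEFAULT_MIX = {
    "gender": {"male": 0.65, "female": 0.35},
    "belief": {"low": 0.5, "high": 0.5},
    "interest": {"not_interested": 0.5, "interested": 0.5},
    "frequency": {"monthly_yearly_never": 0.5, "daily_weekly": 0.5},
}


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    gender: str
    belief: str  # low = believes 0-70% of photos manipulated, high = 71-100%
    interest: str
    frequency: str
    rt_scale: float = 1.0


@dataclass
class ObserverParams:
    """Generative parameters; defaults give roughly 60-66% detection accuracy
    on the default stimulus sets with a conservative response bias."""

    gamma0: float = -1.1  # logit-scale response bias; false-alarm rate ~0.28
    gamma1: float = 1.2  # detection sensitivity to log10 mean Delta-E
    log_de_center: float = -2.2  # signal-scale centring constant x0
    delta0: float = -0.7
    delta1: float = 0.8
    lapse: float = 0.1  # probability of a purely weight-driven localization
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"belief_high": 0.15, "interest_interested": 0.05}
    )
    locate_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"gender_female": -0.15}
    )
    region_weights: np.ndarray | None = None  # None -> centre-biased default
    p_claim_locate_original: float = 0.35
    attentiveness_weight: float = 0.4  # on the detection logit
    attentiveness_rt: float = 0.35  # on log response time
    rt_detect_mu: float = math.log(17.0)
    rt_detect_sigma: float = 0.5
    rt_locate_mu: float = math.log(7.0)
    rt_locate_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if self.region_weights is not None:
            w = np.asarray(self.region_weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("region_weights must be nonnegative and sum to 1")
            self.region_weights = w


def default_region_weights(grid: Grid, center_bias: float = 0.6) -> np.ndarray:
    """Centre-biased region popularity: guessers favour central cells."""
    r = (np.arange(grid.rows) - (grid.rows - 1) / 2) / max(grid.rows - 1, 1)
    c = (np.arange(grid.cols) - (grid.cols - 1) / 2) / max(grid.cols - 1, 1)
    dist2 = (r[:, None] ** 2 + c[None, :] ** 2).ravel()
    w = np.exp(-center_bias * dist2 / 0.25)
    return w / w.sum()


def covariate_indicators(profile: SubjectProfile) -> dict[str, int]:
    """0/1 coding of the four binary covariates against their reference level."""
    return {
        "gender_female": int(profile.gender == "female"),
        "belief_high": int(profile.belief == "high"),
        "interest_interested": int(profile.interest == "interested"),
        "frequency_daily_weekly": int(profile.frequency == "daily_weekly"),
    }


def simulate_subjects(
    n: int,
    mix: dict[str, dict[str, float]] | None = None,
    rng: np.random.Generator | None = None,
    rt_scale_sigma: float = 0.25,
) -> list[SubjectProfile]:
    """Draw ``n`` i.i.d. subject profiles from the category mix."""
    if n < 1:
        raise ValueError("need at least one subject")
    mix = {**DEFAULT_MIX, **(mix or {})}
    for name, probs in mix.items():
        levels = COVARIATE_LEVELS.get(name)
        if levels is None:
            raise ValueError(f"unknown covariate {name!r}")
        if set(probs) != set(levels):
            raise ValueError(f"{name} mix must specify exactly the levels {levels}")
        if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"{name} mix probabilities must sum to 1")
    if rng is None:
        rng = np.random.default_rng()
    out = []
    for i in range(n):
        fields = {}
        for name, levels in COVARIATE_LEVELS.items():
            p_ref = mix[name][levels[0]]
            fields[name] = levels[0] if rng.random() < p_ref else levels[1]
        out.append(
            SubjectProfile(
                subject_id=i,
                rt_scale=float(np.exp(rng.normal(0.0, rt_scale_sigma))),
                **fields,
            )
        )
    return out


def prepare_stimulus_table(
    stimset: StimulusSet, policy: str = "evidence", log_base: float = 10.0
) -> tuple[pd.DataFrame, dict[tuple[str, str], RegionSets]]:
    """Per-pair Delta-E summaries and localization region sets.

    Returns a DataFrame (scene_id, mtype, mean_delta_e, log_delta_e,
    n_regions, majority) and a ``(scene_id, mtype) -> RegionSets`` map.
    """
    rows = []
    sets: dict[tuple[str, str], RegionSets] = {}
    for p in stimset.pairs:
        summ = delta_e76(srgb_to_lab(p.original), srgb_to_lab(p.manipulated), log_base=log_base)
        rs = acceptable_regions(p.mask, stimset.grid, evidence_mask=p.evidence_mask, policy=policy)
        sets[(p.scene_id, p.mtype.label)] = rs
        rows.append(
            {
                "scene_id": p.scene_id,
                "mtype": p.mtype.label,
                "mean_delta_e": summ.mean,
                "log_delta_e": summ.log_mean,
                "n_regions": len(rs.manipulated),
                "n_acceptable": len(rs.acceptable),
                "majority": rs.majority,
            }
        )
    return pd.DataFrame(rows), sets


def collapse_detection(detect3: str) -> bool:
    """Collapse the 3-option detection answer to a yes/no judgement."""
    mapping = {"yes_can_locate": True, "yes_cannot_locate": True, "no": False}
    try:
        return mapping[detect3]
    except KeyError:
        raise ValueError(f"unknown detection response {detect3!r}") from None


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_trials(
    stimuli: StimulusSet,
    profiles: list[SubjectProfile],
    params: ObserverParams,
    design: str = "exp1",
    trials_per_subject: int = 10,
    rng: np.random.Generator | None = None,
    stim_table: pd.DataFrame | None = None,
    region_sets: dict[tuple[str, str], RegionSets] | None = None,
) -> pd.DataFrame:
    """Simulate one trial table: one row per subject x image presentation.

    Each subject sees ``trials_per_subject`` distinct scenes, half original
    and half manipulated with the manipulation types cycled so all types
    are represented.  Per-subject random streams are split off a single
    root seed by subject index, so adding subjects never reshuffles the
    trials of earlier ones.
    """
    if design not in ("exp1", "exp2"):
        raise ValueError(f"unknown design {design!r}")
    if design != stimuli.design:
        raise ValueError(f"stimulus set was built for {stimuli.design!r}, not {design!r}")
    if trials_per_subject < 2 or trials_per_subject % 2:
        raise ValueError("trials_per_subject must be even and >= 2")
    if rng is None:
        rng = np.random.default_rng()
    if stim_table is None or region_sets is None:
        stim_table, region_sets = prepare_stimulus_table(stimuli)

    grid = stimuli.grid
    weights = (
        params.region_weights
        if params.region_weights is not None
        else default_region_weights(grid)
    )
    if len(weights) != grid.n_regions:
        raise ValueError("region_weights length must equal the grid's region count")

    manip_scenes = sorted({p.scene_id for p in stimuli.pairs})
    all_scenes = sorted(stimuli.originals)
    n_manip = trials_per_subject // 2
    if n_manip > len(manip_scenes):
        raise ValueError("not enough manipulated scenes for the requested trial count")
    if trials_per_subject - n_manip > len(all_scenes) - n_manip:
        raise ValueError("not enough scenes for the requested trial count")

    by_scene: dict[str, list[str]] = {}
    for p in stimuli.pairs:
        by_scene.setdefault(p.scene_id, []).append(p.mtype.label)
    stim_lookup = stim_table.set_index(["scene_id", "mtype"])

    root = int(rng.integers(2**31))
    records = []
    for profile in profiles:
        rs = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(profile.subject_id,)))
        chosen_manip = list(rs.choice(manip_scenes, size=n_manip, replace=False))
        types = [MTYPE_LABELS[k % len(MTYPE_LABELS)] for k in range(n_manip)]
        rs.shuffle(types)
        remaining = [s for s in all_scenes if s not in chosen_manip]
        chosen_orig = list(rs.choice(remaining, size=trials_per_subject - n_manip, replace=False))

        trial_plan = [(sid, mt) for sid, mt in zip(chosen_manip, types)] + [
            (sid, None) for sid in chosen_orig
        ]
        order = rs.permutation(len(trial_plan))
        cov = covariate_indicators(profile)
        cov_det = sum(params.covariate_effects.get(k, 0.0) * v for k, v in cov.items())
        cov_loc = sum(params.locate_covariate_effects.get(k, 0.0) * v for k, v in cov.items())

        for t in order:
            sid, mtype = trial_plan[t]
            att = rs.normal()
            if mtype is None:
                truth, log_de = "original", float("nan")
                p_yes = _sigmoid(params.gamma0 + cov_det + params.attentiveness_weight * att)
                p_loc = float("nan")
            else:
                if mtype not in by_scene.get(sid, []):
                    raise ValueError(f"scene {sid} has no {mtype} variant")
                truth = mtype
                log_de = float(stim_lookup.loc[(sid, mtype), "log_delta_e"])
                signal = params.gamma1 * (log_de - params.log_de_center)
                p_yes = _sigmoid(
                    params.gamma0 + signal + cov_det + params.attentiveness_weight * att
                )
                p_loc = (1.0 - params.lapse) * _sigmoid(
                    params.delta0 + params.delta1 * (log_de - params.log_de_center) + cov_loc
                )
            detect_yes = bool(rs.random() < p_yes)

            loc_success = bool(rs.random() < p_loc) if mtype is not None else False
            if mtype is not None:
                claim_can = loc_success
            else:
                claim_can = bool(rs.random() < params.p_claim_locate_original)
            detect3 = ("yes_can_locate" if claim_can else "yes_cannot_locate") if detect_yes else "no"

            do_locate = detect_yes if design == "exp1" else True
            if do_locate:
                if loc_success:
                    region = region_sets[(sid, mtype)].majority
                else:
                    region = int(rs.choice(grid.n_regions, p=weights))
                rt_locate = profile.rt_scale * float(
                    np.exp(
                        params.rt_locate_mu
                        - params.attentiveness_rt * att
                        + params.rt_locate_sigma * rs.normal()
                    )
                )
            else:
                region, rt_locate = np.nan, np.nan
            rt_detect = profile.rt_scale * float(
                np.exp(
                    params.rt_detect_mu
                    - params.attentiveness_rt * att
                    + params.rt_detect_sigma * rs.normal()
                )
            )

            records.append(
                {
                    "subject_id": profile.subject_id,
                    "image_id": sid,
                    "truth": truth,
                    "is_manipulated": mtype is not None,
                    "detect3": detect3,
                    "detect_yes": detect_yes,
                    "locate_region": region,
                    "rt_detect": rt_detect,
                    "rt_locate": rt_locate,
                    "log_delta_e": log_de,
                    "gender": profile.gender,
                    "belief": profile.belief,
                    "interest": profile.interest,
                    "frequency": profile.frequency,
                }
            )
    return pd.DataFrame.from_records(records)
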