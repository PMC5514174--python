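"""Signal-detection estimates, accuracy tables and the DL segmentation.

Discriminability and response bias follow the equal-variance Gaussian
model: ``d' = z(H) - z(F)`` and ``c = -(z(H) + z(F)) / 2`` with ``z`` the
standard-normal quantile.  Hit/false-alarm rates of exactly 0 or 1 are
pulled in by the 1/(2N) rule before the quantile transform.  Confidence
intervals come from a percentile bootstrap over subjects.

Two aggregation routes are reported because they genuinely differ: d'/c on
the pooled (aggregate) rates, and the mean of per-subject d'/c values; the
latter is what repeated-measures covariate models operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SDTResult",
    "hit_fa",
    "correct_rate",
    "dprime_c",
    "subject_sdt",
    "segment_dl",
    "accuracy_tables",
]


@dataclass(frozen=True)
class SDTResult:
    H: float
    F: float
    d_prime: float
    c: float
    n_signal: int
    n_noise: int
    ci95_d: tuple[float, float] | None = None
    ci95_c: tuple[float, float] | None = None


def correct_rate(p_raw: float, n: int) -> float:
    """Clamp a proportion away from 0/1 by the 1/(2N) correction."""
    if n <= 0:
        raise ValueError("need at least one trial")
    if p_raw <= 0.0:
        return 1.0 / (2 * n)
    if p_raw >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p_raw


def hit_fa(trials: pd.DataFrame, correction: str = "half_count") -> tuple[float, float]:
    """Aggregate hit and false-alarm rates from a scored trial table.

    H = P(yes | manipulated), F = P(yes | original); boundary rates are
    adjusted by 1/(2N) when ``correction='half_count'`` (the only rule
    shipped; pass ``'none'`` to keep raw proportions).
    """
    signal = trials[trials["is_manipulated"]]
    noise = trials[~trials["is_manipulated"]]
    if signal.empty or noise.empty:
        raise ValueError("need both manipulated (signal) and original (noise) trials")
    H = float(signal["detect_yes"].mean())
    F = float(noise["detect_yes"].mean())
    if correction == "half_count":
        H = correct_rate(H, len(signal))
        F = correct_rate(F, len(noise))
    elif correction != "none":
        raise ValueError(f"unknown correction rule {correction!r}")
    return H, F


def _dc(H: float, F: float) -> tuple[float, float]:
    zH, zF = norm.ppf(H), norm.ppf(F)
    return float(zH - zF), float(-(zH + zF) / 2.0)


def dprime_c(
    H: float,
    F: float,
    trials: pd.DataFrame | None = None,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> SDTResult:
    """d' and criterion c from corrected rates, with optional bootstrap CIs.

    When a scored trial table is supplied the 95% CIs are percentile
    bootstrap over subjects (resampling whole subjects, recomputing the
    aggregate rates each time).
    """
    if not (0.0 < H < 1.0 and 0.0 < F < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1); correct them upstream")
    d, c = _dc(H, F)
    n_signal = n_noise = 0
    ci_d = ci_c = None
    if trials is not None:
        n_signal = int(trials["is_manipulated"].sum())
        n_noise = int((~trials["is_manipulated"]).sum())
        if rng is None:
            rng = np.random.default_rng()
        subjects = trials["subject_id"].unique()
        groups = dict(tuple(trials.groupby("subject_id")))
        ds, cs = np.empty(n_boot), np.empty(n_boot)
        for b in range(n_boot):
            sample = rng.choice(subjects, size=len(subjects), replace=True)
            boot = pd.concat([groups[s] for s in sample], ignore_index=True)
            Hb, Fb = hit_fa(boot)
            ds[b], cs[b] = _dc(Hb, Fb)
        ci_d = tuple(np.percentile(ds, [2.5, 97.5]))
        ci_c = tuple(np.percentile(cs, [2.5, 97.5]))
    return SDTResult(
        H=H, F=F, d_prime=d, c=c, n_signal=n_signal, n_noise=n_noise,
        ci95_d=ci_d, ci95_c=ci_c,
    )


def subject_sdt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject corrected H, F, d' and c (one row per subject)."""
    rows = []
    for sid, sub in trials.groupby("subject_id"):
        H, F = hit_fa(sub)
        d, c = _dc(H, F)
        rows.append({"subject_id": sid, "H": H, "F": F, "d_prime": d, "c": c})
    return pd.DataFrame(rows)


def segment_dl(trials_exp2: pd.DataFrame) -> pd.DataFrame:
    """Joint detection x localization classification of manipulated trials.

    Requires the locate-always design: every manipulated trial must carry a
    localization response.  Returns per-type (plus ``Overall``) proportions
    of DL, DnL, nDL and nDnL, each row summing to 1.
    """
    manip = trials_exp2[trials_exp2["is_manipulated"]]
    if manip["locate_region"].isna().any():
        raise ValueError("segmentation needs a localization response on every manipulated trial")
    det = manip["detect_correct"].astype(bool)
    loc = manip["locate_correct"].astype(float) > 0.5
    cells = {
        "DL": det & loc,
        "DnL": det & ~loc,
        "nDL": ~det & loc,
        "nDnL": ~det & ~loc,
    }
    frame = pd.DataFrame({k: v.astype(float) for k, v in cells.items()})
    frame["mtype"] = manip["truth"].values
    table = frame.groupby("mtype").mean()
    table.loc["Overall"] = frame[list(cells)].mean()
    return table[list(cells)]


def _subject_mean_ci(per_subject: pd.Series) -> tuple[float, float, float]:
    """Mean over subject means with a normal-approximation 95% CI."""
    vals = per_subject.dropna().to_numpy(dtype=float)
    m = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return m, m - 1.96 * se, m + 1.96 * se


def accuracy_tables(
    trials: pd.DataFrame, chance: dict[str, float] | None = None
) -> pd.DataFrame:
    """Detection and localization accuracy, overall and per manipulation type.

    Accuracies are means of per-subject means with normal-approximation
    95% CIs; ``chance`` maps manipulation-type label (and ``'Overall'``) to
    a chance-localization probability, producing accuracy-minus-chance
    columns.  Detection chance is always 0.5 (binary task).
    """
    rows = []

    def summarize(label: str, det_trials: pd.DataFrame, loc_trials: pd.DataFrame) -> None:
        det = det_trials.groupby("subject_id")["detect_correct"].mean()
        loc = loc_trials.dropna(subset=["locate_correct"]).groupby("subject_id")[
            "locate_correct"
        ].mean()
        d_m, d_lo, d_hi = _subject_mean_ci(det)
        row = {
            "condition": label,
            "detect_acc": d_m,
            "detect_lo": d_lo,
            "detect_hi": d_hi,
            "detect_minus_chance": d_m - 0.5,
        }
        if len(loc):
            l_m, l_lo, l_hi = _subject_mean_ci(loc)
            row.update({"locate_acc": l_m, "locate_lo": l_lo, "locate_hi": l_hi})
            if chance is not None and label in chance:
                row["locate_chance"] = chance[label]
                row["locate_minus_chance"] = l_m - chance[label]
        else:
            row.update({"locate_acc": np.nan, "locate_lo": np.nan, "locate_hi": np.nan})
        rows.append(row)

    manip = trials[trials["is_manipulated"]]
    summarize("Overall", trials, manip)
    for mtype, sub in manip.groupby("truth"):
        summarize(str(mtype), sub, sub)
    return pd.DataFrame(rows).set_index("condition")
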