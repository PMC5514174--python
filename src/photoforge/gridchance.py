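"""Grid partitioning, localization scoring and chance-level baselines.

The localization task overlays an ``rows x cols`` grid on the image and asks
for the single region containing the majority of the change.  A response is
scored correct under a liberal criterion: any region holding manipulated
pixels, or designated nearby "evidence" regions, counts.  Chance performance
is estimated three ways: analytically (mean acceptable-region count divided
by the number of regions), by Monte Carlo simulation of uniform guessing,
and empirically from guesses made on unmanipulated images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "RegionSets",
    "ChanceEstimate",
    "mask_regions",
    "majority_region",
    "score_localization",
    "acceptable_regions",
    "mc_chance",
    "empirical_chance",
    "round_percent",
]


@dataclass(frozen=True)
class Grid:
    """Half-open ``rows x cols`` partition of a ``width x height`` image.

    Region indices are row-major, 0-based; a boundary pixel belongs to the
    cell containing its top-left coordinate.
    """

    rows: int
    cols: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.width, self.height) <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_regions(self) -> int:
        return self.rows * self.cols

    def region_of(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(f"pixel ({x}, {y}) outside {self.width}x{self.height} image")
        return (y * self.rows // self.height) * self.cols + (x * self.cols // self.width)

    def region_map(self) -> np.ndarray:
        """(height, width) array of region indices."""
        row = np.arange(self.height)[:, None] * self.rows // self.height
        col = np.arange(self.width)[None, :] * self.cols // self.width
        return row * self.cols + col

    def neighbors(self, idx: int) -> set[int]:
        """Edge-sharing neighbour regions of ``idx``."""
        r, c = divmod(idx, self.cols)
        out = set()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                out.add(rr * self.cols + cc)
        return out


@dataclass(frozen=True)
class RegionSets:
    """Manipulated, acceptable and majority regions for one stimulus."""

    manipulated: frozenset[int]
    acceptable: frozenset[int]
    majority: int

    def __post_init__(self) -> None:
        if self.majority not in self.manipulated:
            raise ValueError("majority region must be a manipulated region")
        if not self.manipulated <= self.acceptable:
            raise ValueError("manipulated regions must be acceptable")
        if not self.acceptable:
            raise ValueError("acceptable set must be nonempty")


@dataclass(frozen=True)
class ChanceEstimate:
    """Chance probability of a correct localization with its 95% CI."""

    probability: float
    ci95: tuple[float, float]
    n_draws: int
    method: str  # analytic | monte_carlo | empirical
    analytic: float | None = None

    @property
    def percent(self) -> int:
        return round_percent(self.probability)


def round_percent(p: float) -> int:
    """Probability -> whole percent, rounding half away from zero."""
    x = 100.0 * p
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _check_mask(mask: np.ndarray, grid: Grid) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (grid.height, grid.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {grid.height}x{grid.width}"
        )
    return mask


def _region_pixel_counts(mask: np.ndarray, grid: Grid) -> np.ndarray:
    labels = grid.region_map()
    return np.bincount(labels[mask], minlength=grid.n_regions)


def mask_regions(mask: np.ndarray, grid: Grid, coverage_threshold: float = 0.0) -> frozenset[int]:
    """Regions touched by the mask.

    With the default threshold of 0 a region counts as manipulated as soon
    as any of its pixels is set; a positive threshold requires at least that
    fraction of the cell's pixels.
    """
    mask = _check_mask(mask, grid)
    counts = _region_pixel_counts(mask, grid)
    if coverage_threshold <= 0:
        hit = counts > 0
    else:
        cell_sizes = np.bincount(grid.region_map().ravel(), minlength=grid.n_regions)
        hit = counts / cell_sizes >= coverage_threshold
    return frozenset(np.flatnonzero(hit).tolist())


def majority_region(mask: np.ndarray, grid: Grid) -> int:
    """Region with the most masked pixels; ties broken by lowest index."""
    mask = _check_mask(mask, grid)
    counts = _region_pixel_counts(mask, grid)
    if counts.sum() == 0:
        raise ValueError("majority region undefined for an empty mask")
    return int(counts.argmax())  # argmax returns the first (lowest) index on ties


def acceptable_regions(
    mask: np.ndarray,
    grid: Grid,
    evidence_mask: np.ndarray | None = None,
    policy: str = "evidence",
) -> RegionSets:
    """Build the full region sets for one manipulated stimulus.

    ``policy='mask_only'`` accepts exactly the mask-covered regions.  The
    default ``'evidence'`` policy additionally accepts regions that (a)
    contain pixels of the object referenced by the manipulation (its
    ``evidence_mask`` — e.g. the shadow-casting object for a shadow change)
    and (b) share an edge with a mask-covered region.  This operationalizes
    the liberal "nearby area that could be used as evidence" criterion.
    """
    manipulated = mask_regions(mask, grid)
    if not manipulated:
        raise ValueError("cannot build region sets for an all-zero mask")
    acceptable = set(manipulated)
    if policy == "evidence" and evidence_mask is not None:
        evidence = mask_regions(evidence_mask, grid)
        adjacent = set().union(*(grid.neighbors(i) for i in manipulated))
        acceptable |= evidence & adjacent
    elif policy not in ("evidence", "mask_only"):
        raise ValueError(f"unknown acceptability policy: {policy!r}")
    return RegionSets(
        manipulated=frozenset(manipulated),
        acceptable=frozenset(acceptable),
        majority=majority_region(mask, grid),
    )


def score_localization(response_region: int, sets: RegionSets, n_regions: int) -> bool:
    """True iff the response falls in the acceptable set."""
    if not 0 <= response_region < n_regions:
        raise ValueError(f"region {response_region} outside 0..{n_regions - 1}")
    return response_region in sets.acceptable


def mc_chance(
    acceptable_counts: list[int],
    n_regions: int,
    draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> ChanceEstimate:
    """Monte Carlo chance of a correct localization under uniform guessing.

    Each draw samples an image uniformly, then one of the ``n_regions`` grid
    regions uniformly; the guess is correct when it lands in that image's
    acceptable set (``k_i`` regions).  The estimate converges to the
    analytic value ``mean(k_i) / n_regions``, which is also returned.  The
    95% CI is the normal approximation to the binomial.
    """
    k = np.asarray(acceptable_counts, dtype=int)
    if k.size == 0 or draws < 1:
        raise ValueError("need at least one image and one draw")
    if np.any(k < 1) or np.any(k > n_regions):
        raise ValueError("acceptable counts must lie in 1..n_regions")
    if rng is None:
        rng = np.random.default_rng()
    analytic = float(k.mean() / n_regions)
    imgs = rng.integers(k.size, size=draws)
    regions = rng.integers(n_regions, size=draws)
    # By symmetry of the uniform draw, correctness only depends on whether
    # the region index falls below k_i.
    hits = int((regions < k[imgs]).sum())
    p = hits / draws
    se = float(np.sqrt(max(p * (1 - p), 1e-30) / draws))
    return ChanceEstimate(
        probability=p,
        ci95=(max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se)),
        n_draws=draws,
        method="monte_carlo",
        analytic=analytic,
    )


def analytic_chance(acceptable_counts: list[int], n_regions: int) -> ChanceEstimate:
    """Exact chance under uniform guessing: mean(k_i) / n_regions."""
    k = np.asarray(acceptable_counts, dtype=int)
    if np.any(k < 1) or np.any(k > n_regions):
        raise ValueError("acceptable counts must lie in 1..n_regions")
    p = float(k.mean() / n_regions)
    return ChanceEstimate(probability=p, ci95=(p, p), n_draws=0, method="analytic", analytic=p)


def score_trials(
    trials: pd.DataFrame,
    region_sets: dict[tuple[str, str], "RegionSets"],
    grid: Grid,
) -> pd.DataFrame:
    """Add ``detect_correct`` and ``locate_correct`` columns to a trial table.

    Detection is correct when the collapsed yes/no answer matches the truth;
    localization is scored under the liberal acceptable-region criterion and
    is NaN for original images and for trials without a location response.
    """
    out = trials.copy()
    out["detect_correct"] = out["detect_yes"] == out["is_manipulated"]
    loc = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.is_manipulated or pd.isna(row.locate_region):
            continue
        sets = region_sets[(row.image_id, row.truth)]
        loc[i] = float(score_localization(int(row.locate_region), sets, grid.n_regions))
    out["locate_correct"] = loc
    return out


def empirical_chance(
    original_trials: pd.DataFrame,
    sets_by_image: dict[str, dict[str, RegionSets]],
) -> pd.DataFrame:
    """Chance levels from real guesses on unmanipulated images.

    ``original_trials`` must hold one row per localization guess on an
    original image with columns ``image_id`` and ``locate_region``.  For
    each image and manipulation type, the chance level is the fraction of
    that image's guesses landing in the type's acceptable set.  Returns a
    type x image table with an ``Overall`` row and column (row/column
    means); images without any guesses are dropped with a warning column
    left out rather than raising.
    """
    needed = {"image_id", "locate_region"}
    if not needed <= set(original_trials.columns):
        raise ValueError(f"original trials need columns {sorted(needed)}")
    trials = original_trials.dropna(subset=["locate_region"])
    mtypes = sorted({mt for per_img in sets_by_image.values() for mt in per_img})
    rows: dict[str, dict[str, float]] = {mt: {} for mt in mtypes}
    for image_id, per_type in sorted(sets_by_image.items()):
        guesses = trials.loc[trials["image_id"] == image_id, "locate_region"].astype(int)
        if guesses.empty:
            continue
        for mtype, sets in per_type.items():
            inside = guesses.isin(list(sets.acceptable))
            rows[mtype][image_id] = float(inside.mean())
    table = pd.DataFrame(rows).T
    table.index.name = "mtype"
    table["Overall"] = table.mean(axis=1)
    table.loc["Overall"] = table.mean(axis=0)
    return table
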