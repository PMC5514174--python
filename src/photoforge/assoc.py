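"""Image-level association between Delta-E and observer accuracy.

Pearson product-moment correlations of per-image accuracy against the log
mean Delta-E score, and the Fisher r-to-z comparison of two independent
correlations:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm, pearsonr

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "pearson_accuracy_vs_logdeltae",
    "compare_correlations",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class CorrelationComparison:
    z_stat: float
    p_two: float
    p_one: float
    r1: float
    n1: int
    r2: float
    n2: int


def pearson_accuracy_vs_logdeltae(
    per_image,
    accuracy_col: str = "accuracy",
    x_col: str = "log_delta_e",
) -> CorrelationResult:
    """Correlate per-image accuracy with log mean Delta-E.

    ``per_image`` is a DataFrame with one row per manipulated image.  Use a
    per-type aggregate table (n = number of manipulation types) for the
    type-level descriptive correlation; with so few points that value is
    reported but too fragile to test.
    """
    data = per_image.dropna(subset=[accuracy_col, x_col])
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 images for a correlation")
    x = data[x_col].to_numpy(dtype=float)
    y = data[accuracy_col].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = pearsonr(x, y)
    return CorrelationResult(r=float(r), n=n, p_two_tailed=float(p))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher z test for the difference of two independent correlations."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("|r| = 1 cannot be Fisher-transformed")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_two = 2.0 * float(norm.sf(abs(z)))
    p_one = float(norm.sf(abs(z)))
    return CorrelationComparison(
        z_stat=z, p_two=p_two, p_one=p_one, r1=r1, n1=n1, r2=r2, n2=n2
    )
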