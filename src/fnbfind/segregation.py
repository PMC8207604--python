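"""Chi-square goodness-of-fit test for two-class phenotypic segregation.

A single recessive mutation segregates 1 mutant : 3 wild-type-like in an F2
backcross-derived population; testing the observed counts against that
ratio is what decides between the recessive bulked-segregant design and the
F3-based non-recessive design before any sequencing happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import chi2

__all__ = ["SegregationResult", "chisq_segregation"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]  # (n_mutant, n_wildtype_like)
    expected_ratio: tuple[int, int]
    expected: tuple[float, float]
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    alpha: float
    fits_ratio: bool
    yates: bool = False

    def __str__(self) -> str:
        obs, ratio = self.observed, self.expected_ratio
        verdict = "fits" if self.fits_ratio else "does not fit"
        return (
            f"observed {obs[0]} mutant : {obs[1]} wild-type-like, "
            f"expected {self.expected[0]:g}:{self.expected[1]:g} under {ratio[0]}:{ratio[1]}\n"
            f"chi-square = {self.chi_square:.4f} (df={self.degrees_of_freedom}), "
            f"p = {self.p_value:.4f}\n"
            f"segregation {verdict} {ratio[0]}:{ratio[1]} at alpha = {self.alpha:g}"
        )


def chisq_segregation(
    n_mutant: int,
    n_wildtype_like: int,
    ratio: tuple[int, int] = (1, 3),
    alpha: float = 0.05,
    yates: bool = False,
) -> SegregationResult:
    """Goodness-of-fit of observed (mutant, wild-type-like) counts to a ratio.

    Expected counts scale the ratio to the observed total; the statistic is
    the usual sum of (observed - expected)^2 / expected with 1 degree of
    freedom, uncorrected by default (``yates=True`` applies the continuity
    correction).  ``fits_ratio`` is ``p_value >= alpha``, i.e. failure to
    reject the ratio.  Warns when any expected count is below 5, where the
    chi-square approximation degrades.
    """
    if n_mutant < 0 or n_wildtype_like < 0:
        raise ValueError("counts must be non-negative")
    total = n_mutant + n_wildtype_like
    if total == 0:
        raise ValueError("total observed count is zero")
    r1, r2 = ratio
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ratio components must be positive")
    e1 = total * r1 / (r1 + r2)
    e2 = total * r2 / (r1 + r2)
    if min(e1, e2) < 5:
        warnings.warn(
            f"expected count below 5 (expected {e1:g}, {e2:g}); "
            "chi-square approximation may be unreliable",
            stacklevel=2,
        )
    corr = 0.5 if yates else 0.0
    stat = sum(
        (max(abs(o - e) - corr, 0.0)) ** 2 / e
        for o, e in ((n_mutant, e1), (n_wildtype_like, e2))
    )
    p = float(chi2.sf(stat, df=1))
    return SegregationResult(
        observed=(n_mutant, n_wildtype_like),
        expected_ratio=(r1, r2),
        expected=(e1, e2),
        chi_square=float(stat),
        degrees_of_freedom=1,
        p_value=p,
        alpha=alpha,
        fits_ratio=p >= alpha,
        yates=yates,
    )
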