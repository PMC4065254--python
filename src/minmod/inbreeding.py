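"""Residual heterozygosity under repeated brother-sister mating.

The fraction of initially heterozygous loci still segregating after ``t``
generations of full-sib mating follows the classical linear recurrence

    H_t = H_{t-1} / 2 + H_{t-2} / 4,    H_0 = H_1 = 1,

whose decay ratio tends to (1 + sqrt(5)) / 4 ~ 0.809 per generation.
``1 - H_t`` is the standard full-sib inbreeding coefficient series. At
F10 about 14% of induced variant sites are expected to remain
heterozygous; one generation later, about 11%.
"""

from __future__ import annotations

import math

__all__ = [
    "heterozygosity_remaining",
    "heterozygosity_series",
    "generations_until",
    "ASYMPTOTIC_RATIO",
]

# Limit of H_{t+1} / H_t: the dominant eigenvalue of the recurrence.
ASYMPTOTIC_RATIO = (1.0 + math.sqrt(5.0)) / 4.0


def heterozygosity_series(t_max: int) -> list[float]:
    """H_0 .. H_{t_max} from the full-sib recurrence."""
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    series = [1.0, 1.0][: t_max + 1]
    for _ in range(2, t_max + 1):
        series.append(series[-1] / 2.0 + series[-2] / 4.0)
    return series


def heterozygosity_remaining(t: int) -> float:
    """Fraction of initially heterozygous loci still heterozygous at generation ``t``."""
    if t < 0:
        raise ValueError("generation must be non-negative")
    return heterozygosity_series(t)[t]


def generations_until(threshold: float) -> int:
    """Smallest ``t`` with H_t <= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if threshold >= 1.0:
        return 0
    h_pp, h_p = 1.0, 1.0  # H_0, H_1 (both 1: sibs of the founding pair)
    t = 2
    while True:
        h = h_p / 2.0 + h_pp / 4.0
        if h <= threshold:
            return t
        h_pp, h_p = h_p, h
        t += 1
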