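"""Assembly quality scoring, completeness estimation and identity-by-state.

The quality score compares pseudo-heterozygous SNP calls (reads from an
unassembled NLR copy piling up on a related assembled gene) with the total
mappable NLR bases:

    Q = | -10 * log10(hetsites / totalsites) |

The absolute value is retained verbatim from the score's definition even
though the ratio never exceeds 1. A monotone calibration table (quality ->
completeness, derived from assemblies of subsampled reference reads) turns
Q into a completeness estimate by piecewise-linear interpolation, clamped
at the calibration range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PERFECT = float("inf")


@dataclass
class QualityReport:
    hetsites: int
    totalsites: int
    q: float
    completeness_estimate: float | None = None


def quality_score(hetsites: int, totalsites: int) -> float:
    """Q = |-10 log10(hetsites/totalsites)|; infinite ("perfect") when no
    pseudo-heterozygous site was called."""
    if totalsites <= 0:
        raise ValueError("totalsites must be positive")
    if hetsites < 0 or hetsites > totalsites:
        raise ValueError("need 0 <= hetsites <= totalsites")
    if hetsites == 0:
        return PERFECT
    return abs(-10.0 * math.log10(hetsites / totalsites))


def completeness_ratio(covered_bases: int, total_reference_nlr_bases: int
                       ) -> float:
    """Covered NLR bases divided by the total reference NLR bases."""
    if total_reference_nlr_bases <= 0:
        raise ValueError("total reference NLR length must be positive")
    if covered_bases < 0 or covered_bases > total_reference_nlr_bases:
        raise ValueError("covered bases must lie in [0, total]")
    return covered_bases / total_reference_nlr_bases


def completeness_from_quality(q: float,
                              calibration: list[tuple[float, float]]
                              ) -> float:
    """Interpolate a completeness estimate from a (quality, completeness)
    calibration table; values outside the table clamp to its ends."""
    if not calibration or len(calibration) < 2:
        raise ValueError("calibration needs at least 2 points")
    pts = sorted(calibration)
    qs = np.array([p[0] for p in pts], dtype=float)
    cs = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(cs) < 0):
        raise ValueError("completeness must be non-decreasing in quality")
    if math.isinf(q):
        return float(cs[-1])
    return float(np.interp(q, qs, cs))


def ibs(genotypes_a, genotypes_b, missing=None) -> float:
    """Identity-by-state: the fraction of pairwise-complete sites with
    identical biallelic calls. NaN when no site is comparable."""
    a = list(genotypes_a)
    b = list(genotypes_b)
    if len(a) != len(b):
        raise ValueError("genotype vectors differ in length")
    same = 0
    total = 0
    for x, y in zip(a, b):
        if x == missing or y == missing:
            continue
        total += 1
        if x == y:
            same += 1
    if total == 0:
        return float("nan")
    return same / total
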