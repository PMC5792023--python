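"""Summary-statistic conventions used across the pipeline reports."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["SummaryStats", "summarise", "sem_from_sd", "proportion_se"]


@dataclass
class SummaryStats:
    mean: float
    sd: Optional[float]      # n-1 denominator; None when n == 1
    sem: Optional[float]
    n: int


def summarise(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD (n-1), SEM and n; SD/SEM undefined for n == 1."""
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n == 0:
        raise ValueError("cannot summarise an empty sample")
    mean = float(vals.mean())
    if n == 1:
        return SummaryStats(mean=mean, sd=None, sem=None, n=1)
    sd = float(vals.std(ddof=1))
    return SummaryStats(mean=mean, sd=sd, sem=sd / np.sqrt(n), n=n)


def sem_from_sd(sd: float, n: int) -> float:
    """SEM = SD / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sd) / np.sqrt(n)


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p (1-p) / n)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt(p * (1.0 - p) / n))
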