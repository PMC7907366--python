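"""Population statistics and two-condition comparison of aspect ratios.

Summarises per-particle aspect-ratio tables into the quantities shown
in single-molecule conformer studies (mean R, quartile box, open
fraction, tail fractions) and compares two imaging conditions with a
two-proportion z-test / Fisher exact test on open counts and a
Mann-Whitney rank test on the full R distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .afm_image import CLOSED_OPEN_THRESHOLD

__all__ = [
    "ConformationSummary",
    "summarize",
    "compare_open_fractions",
    "compare_distributions",
    "boxplot_stats",
]


@dataclass
class ConformationSummary:
    """Per-condition population statistics over labelled particles."""

    n: int
    mean_R: float
    sd_R: float
    var_R: float
    q25: float
    median: float
    q75: float
    min: float
    max: float
    n_open: int
    n_closed: int
    frac_open: float
    frac_above: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["frac_above"] = {str(k): v for k, v in self.frac_above.items()}
        return d


def _extract_ratios(data) -> np.ndarray:
    """Aspect ratios of labelled (non-excluded) records.

    Accepts a records DataFrame (``aspect_ratio``/``label`` columns), a
    sequence of ``ParticleRecord``, or a bare array of ratios.
    """
    if isinstance(data, pd.DataFrame):
        sub = data[data["label"].isin(["closed", "open"])] if "label" in data else data
        return np.asarray(sub["aspect_ratio"], dtype=float)
    if len(data) and hasattr(data[0], "aspect_ratio"):
        return np.asarray([r.aspect_ratio for r in data
                           if r.label in ("closed", "open", "")], dtype=float)
    return np.asarray(data, dtype=float)


def summarize(
    data,
    thresholds: Sequence[float] = (3.0, 5.0),
    open_threshold: float = CLOSED_OPEN_THRESHOLD,
) -> ConformationSummary:
    """Population statistics of a labelled particle set.

    ``frac_above[t]`` is the fraction with R > t (strict), reported by
    default at the open threshold 3 and the long-tail marker 5.
    Quartiles use linear interpolation.
    """
    R = _extract_ratios(data)
    if R.size == 0:
        raise ValueError("no labelled particles to summarise")
    n_open = int(np.sum(R > open_threshold))
    q25, med, q75 = np.quantile(R, [0.25, 0.5, 0.75])
    return ConformationSummary(
        n=int(R.size),
        mean_R=float(np.mean(R)),
        sd_R=float(np.std(R, ddof=1)) if R.size > 1 else 0.0,
        var_R=float(np.var(R, ddof=1)) if R.size > 1 else 0.0,
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        min=float(np.min(R)),
        max=float(np.max(R)),
        n_open=n_open,
        n_closed=int(R.size - n_open),
        frac_open=float(n_open / R.size),
        frac_above={float(t): float(np.mean(R > t)) for t in thresholds},
    )


def compare_open_fractions(
    k1: int, n1: int, k2: int, n2: int, method: str = "proportion_z"
) -> tuple[float, float]:
    """Compare two open-particle counts.

    ``proportion_z`` is the pooled two-proportion z-test;
    ``fisher`` the Fisher exact test (statistic = odds ratio).  Both
    return ``(statistic, two_sided_p)``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n")
    if method == "proportion_z":
        stat, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
        return float(stat), float(p)
    if method == "fisher":
        res = stats.fisher_exact(
            [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def compare_distributions(R1, R2) -> tuple[float, float]:
    """Mann-Whitney U on two aspect-ratio samples.

    Normal approximation with tie correction, two-sided.  Returns
    ``(U, p)`` with U counted for the first sample.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.size == 0 or R2.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(R1, R2, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def boxplot_stats(data) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, q25, median, q75, max).

    Box edges at the 25/75 % quantiles (linear interpolation), whiskers
    spanning the population minimum and maximum.
    """
    R = _extract_ratios(data)
    if R.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.quantile(R, [0.25, 0.5, 0.75])
    return (float(np.min(R)), float(q25), float(med), float(q75), float(np.max(R)))
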