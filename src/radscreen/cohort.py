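"""Distribution analysis of integral survival across and within lineages.

The screen's headline distributional observation is that integral
survival within most lineages is approximately Gaussian; the omnibus
D'Agostino-Pearson K² statistic (skewness and kurtosis Z scores combined,
chi-square with 2 df) quantifies this per lineage, with a reporting rule
flagging a lineage as Gaussian when K² < 0.65 and P > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticalPreconditionError

#: Reporting rule for calling a lineage's response Gaussian.
K2_FLAG_MAX = 0.65
P_FLAG_MIN = 0.5

NORMALITY_MIN_N = 20   # validity floor of the K² test
LINEAGE_MIN_N = 25     # lineages below this are summarised but not tested


@dataclass(frozen=True)
class NormalityResult:
    group: str
    n: int
    k2: float
    p: float
    gaussian_flag: bool


@dataclass(frozen=True)
class LineageSummary:
    lineage: str
    n: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def fold_range(self) -> float:
        """max/min spread of integral survival (inf when min is 0)."""
        return self.max / self.min if self.min > 0 else float("inf")


def dagostino_k2(
    values: Sequence[float],
    group: str = "",
    min_n: int = NORMALITY_MIN_N,
    k2_flag_max: float = K2_FLAG_MAX,
    p_flag_min: float = P_FLAG_MIN,
) -> NormalityResult:
    """D'Agostino-Pearson omnibus normality test.

    K² = Z(skewness)² + Z(kurtosis)² with p from chi-square (2 df).
    Below ``min_n`` observations the test still runs but a warning is
    issued (the moment transforms are calibrated for n >= 20).
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size == 1:
        raise StatisticalPreconditionError("constant input; normality test undefined")
    if x.size < min_n:
        warnings.warn(
            f"D'Agostino-Pearson below its validity floor (n={x.size} < {min_n})",
            stacklevel=2,
        )
    k2, p = stats.normaltest(x)
    return NormalityResult(
        group=group,
        n=int(x.size),
        k2=float(k2),
        p=float(p),
        gaussian_flag=bool(k2 < k2_flag_max and p > p_flag_min),
    )


def lineage_summaries(
    scores: Mapping[str, float],
    lineages: Mapping[str, str],
    min_n: int = LINEAGE_MIN_N,
) -> tuple[list[LineageSummary], list[NormalityResult]]:
    """Per-lineage descriptive summaries plus normality tests where n allows.

    Lineages with fewer than ``min_n`` scored lines get a summary but no
    normality test.
    """
    grouped: dict[str, list[float]] = {}
    for sample, score in scores.items():
        grouped.setdefault(lineages.get(sample, "unknown"), []).append(score)
    summaries: list[LineageSummary] = []
    normality: list[NormalityResult] = []
    for lineage in sorted(grouped):
        x = np.asarray(grouped[lineage], dtype=float)
        summaries.append(
            LineageSummary(
                lineage=lineage,
                n=int(x.size),
                mean=float(x.mean()),
                sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                min=float(x.min()),
                max=float(x.max()),
            )
        )
        if x.size >= min_n:
            normality.append(dagostino_k2(x, group=lineage))
    return summaries, normality


def lineage_table(summaries: Sequence[LineageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lineage": [s.lineage for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "min": [s.min for s in summaries],
            "max": [s.max for s in summaries],
            "fold_range": [s.fold_range for s in summaries],
        }
    )


def distribution_report(
    values: Sequence[float],
    bins: int | str = "fd",
    density_points: int = 200,
) -> dict[str, pd.DataFrame]:
    """Plot-ready distribution bundle: histogram, KDE density, normal Q-Q.

    Histogram bins follow the Freedman-Diaconis rule by default; the
    density is a Gaussian KDE evaluated on a uniform grid; Q-Q pairs are
    theoretical normal quantiles (Blom plotting positions) against the
    sorted sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatisticalPreconditionError("distribution report needs >=2 values")
    counts, edges = np.histogram(x, bins=bins)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})

    if np.unique(x).size > 1:
        kde = stats.gaussian_kde(x)
        span = x.max() - x.min()
        grid = np.linspace(x.min() - 0.5 * span, x.max() + 0.5 * span, density_points)
        dens = pd.DataFrame({"x": grid, "density": kde(grid)})
    else:
        dens = pd.DataFrame({"x": [float(x[0])], "density": [np.inf]})

    order = np.sort(x)
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    theo = stats.norm.ppf(probs, loc=x.mean(), scale=x.std(ddof=1) if x.size > 1 else 1.0)
    qq = pd.DataFrame({"theoretical": theo, "sample": order})
    return {"histogram": hist, "density": dens, "qq": qq}
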