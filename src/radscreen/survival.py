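"""Integral-survival scoring of radiation dose-response data.

A cell line's dose-response is summarised by *integral survival*: the
trapezoidal area under its survival-fraction curve plotted against
log2(dose), rescaled by 7/log2(10) so that over the standard dose panel
(1, 2, 3, 4, 5, 6, 8, 10 Gy) the score runs from 0 (fully sensitive,
no surviving signal at any dose) to 7 (fully resistant, survival equal
to mock at every dose).

Survival fractions are luminescence relative to unirradiated (mock)
wells; values are clipped to [0, 1] before integration so the 0-7 bound
is an invariant, while the raw unclipped fractions are kept for QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import StatisticalPreconditionError, ValidationError
from .io import NamedMatrix

STANDARD_DOSES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)

#: Rescale factor mapping the log2-dose trapezoid area onto the 0-7 scale.
RESCALE = 7.0 / np.log2(10.0)


@dataclass
class SurvivalCurve:
    """Per-sample survival fraction at each radiation dose (relative to mock)."""

    sample_id: str
    doses: np.ndarray
    survival: np.ndarray
    raw_survival: np.ndarray | None = None  # unclipped fractions, for QC

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.survival.shape:
            raise ValidationError("doses and survival must be 1-D of equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValidationError("doses must be strictly increasing")
        if np.any(self.doses < 1.0):
            raise ValidationError("doses must be >= 1 Gy (0 Gy is mock, not a node)")
        if np.any(self.survival < 0):
            raise ValidationError("survival fractions must be >= 0")


@dataclass
class IntegralSurvival:
    """Scalar 0-7 summary of a survival curve."""

    sample_id: str
    score: float
    n_replicate_experiments: int = 1


def integral_survival(curve: SurvivalCurve) -> IntegralSurvival:
    """Score a survival curve: trapezoid on log2(dose), times 7/log2(10).

    Survival values must already lie in [0, 1] (clip upstream); for the
    standard 8-dose panel the log2-dose range is [0, log2 10] so the
    score lies in [0, 7].
    """
    if curve.doses.size < 2:
        raise StatisticalPreconditionError("integral survival needs >=2 doses")
    if np.any(curve.survival > 1.0):
        raise ValidationError(
            "survival fractions above 1 — clip (normalize_luminescence does) "
            "before scoring"
        )
    x = np.log2(curve.doses)
    score = RESCALE * float(np.trapezoid(curve.survival, x))
    return IntegralSurvival(sample_id=curve.sample_id, score=score)


def max_attainable_score(doses: Sequence[float]) -> float:
    """Score of all-ones survival over an arbitrary panel.

    7 for the standard panel; 7*(log2 dmax - log2 dmin)/log2 10 otherwise.
    """
    d = np.asarray(doses, dtype=float)
    return RESCALE * float(np.log2(d[-1]) - np.log2(d[0]))


def mean_integral_survival(scores: Sequence[IntegralSurvival]) -> IntegralSurvival:
    """Average replicate-experiment scores for one cell line."""
    if not scores:
        raise StatisticalPreconditionError("no replicate scores to average")
    ids = {s.sample_id for s in scores}
    if len(ids) != 1:
        raise ValidationError(f"replicates from different samples: {sorted(ids)}")
    return IntegralSurvival(
        sample_id=scores[0].sample_id,
        score=float(np.mean([s.score for s in scores])),
        n_replicate_experiments=len(scores),
    )


# ---------------------------------------------------------------------------
# plate normalisation
# ---------------------------------------------------------------------------

MOCK_LABEL = "mock"


def _dose_of_row(row_id: str) -> float | None:
    """Plate row labels are 'mock' or 'd<dose>' (e.g. 'd2', 'd2.5')."""
    if row_id == MOCK_LABEL:
        return None
    if row_id.startswith("d"):
        return float(row_id[1:])
    raise ValidationError(f"unrecognised plate row label {row_id!r}")


def _density_columns(plate: NamedMatrix, density: int) -> list[int]:
    prefix = f"{density}_"
    return [i for i, c in enumerate(plate.column_ids) if c.startswith(prefix)]


def normalize_luminescence(
    plate: NamedMatrix, density: int, sample_id: str = ""
) -> SurvivalCurve:
    """Mock-normalise a luminescence plate into a survival curve.

    Plate rows are dose labels ('mock', 'd1', 'd2', ...); columns are
    '<density>_r<replicate>' wells. survival(d) = mean luminescence at
    dose d over replicates / mean mock luminescence. Fractions are
    clipped to [0, 1] for scoring; raw fractions are retained.
    """
    cols = _density_columns(plate, density)
    if not cols:
        raise ValidationError(f"plate has no wells at density {density}")
    if MOCK_LABEL not in plate.row_ids:
        raise ValidationError("plate has no mock (0 Gy) wells")
    mock = np.nanmean(plate.values[plate.row_ids.index(MOCK_LABEL)][cols])
    if not np.isfinite(mock) or mock <= 0:
        raise ValidationError("zero or missing mock signal; cannot normalise")
    doses: list[float] = []
    fractions: list[float] = []
    for i, rid in enumerate(plate.row_ids):
        dose = _dose_of_row(rid)
        if dose is None:
            continue
        doses.append(dose)
        fractions.append(float(np.nanmean(plate.values[i][cols]) / mock))
    order = np.argsort(doses)
    doses_arr = np.asarray(doses)[order]
    raw = np.asarray(fractions)[order]
    return SurvivalCurve(
        sample_id=sample_id,
        doses=doses_arr,
        survival=np.clip(raw, 0.0, 1.0),
        raw_survival=raw,
    )


def select_linear_density(
    plate: NamedMatrix,
    densities: Sequence[int],
    instrument_midrange: float = 1e5,
) -> int:
    """Pick the cell density whose mock signal sits in the assay's linear range.

    Deterministic rule: the density whose mean mock luminescence is closest
    to ``instrument_midrange``; ties break toward the lower density.
    """
    if not densities:
        raise ValidationError("no densities supplied")
    if MOCK_LABEL not in plate.row_ids:
        raise ValidationError("plate has no mock wells")
    mock_row = plate.values[plate.row_ids.index(MOCK_LABEL)]
    best: int | None = None
    best_gap = np.inf
    for density in sorted(densities):
        cols = _density_columns(plate, density)
        if not cols:
            continue
        gap = abs(float(np.nanmean(mock_row[cols])) - instrument_midrange)
        if gap < best_gap:  # strict: earlier (lower) density wins ties
            best, best_gap = density, gap
    if best is None:
        raise ValidationError("no plate wells match any supplied density")
    return best


def score_plate(
    plate: NamedMatrix,
    densities: Sequence[int],
    sample_id: str = "",
    instrument_midrange: float = 1e5,
) -> IntegralSurvival:
    """Density selection + normalisation + scoring in one step."""
    density = select_linear_density(plate, densities, instrument_midrange)
    curve = normalize_luminescence(plate, density, sample_id=sample_id)
    return integral_survival(curve)


# ---------------------------------------------------------------------------
# clonogenic survival
# ---------------------------------------------------------------------------

def clonogenic_auc(doses: Sequence[float], surviving_fractions: Sequence[float]) -> float:
    """Area under the clonogenic survival curve on the linear dose axis (Gy)."""
    d = np.asarray(doses, dtype=float)
    s = np.asarray(surviving_fractions, dtype=float)
    if d.size < 2:
        raise StatisticalPreconditionError("clonogenic AUC needs >=2 doses")
    if d.shape != s.shape or np.any(np.diff(d) <= 0):
        raise ValidationError("doses must be strictly increasing and match fractions")
    if np.any(s < 0):
        raise ValidationError("surviving fractions must be >= 0")
    return float(np.trapezoid(s, d))


def compare_platform_clonogenic(
    platform_scores: Mapping[str, float],
    clonogenic_areas: Mapping[str, float],
) -> tuple[float, float, "pd.DataFrame"]:
    """Correlate high-throughput integral survival with clonogenic AUC.

    Pairs cell lines by id; lines missing either value are excluded and
    listed in the returned table with ``paired=False``. Returns
    (pearson_r, r_squared, per-line table).
    """
    import pandas as pd

    all_ids = sorted(set(platform_scores) | set(clonogenic_areas))
    table = pd.DataFrame(
        {
            "sample_id": all_ids,
            "platform": [platform_scores.get(i, np.nan) for i in all_ids],
            "clonogenic": [clonogenic_areas.get(i, np.nan) for i in all_ids],
        }
    )
    table["paired"] = table["platform"].notna() & table["clonogenic"].notna()
    paired = table[table["paired"]]
    if len(paired) < 3:
        raise StatisticalPreconditionError(
            f"need >=3 paired lines, have {len(paired)}"
        )
    r = float(stats.pearsonr(paired["platform"], paired["clonogenic"]).statistic)
    return r, r * r, table
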