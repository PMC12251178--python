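"""Growth-curve metrics and in-vivo competitive-fitness estimation.

Maximum growth rate mu follows the 5-point sliding-window rule: over every
window of 5 consecutive background-subtracted optical-density readings, fit
ln(OD - OD_blank) against time by ordinary least squares and keep the
largest slope among windows with R^2 > 0.9. Carrying capacity is the
maximum background-subtracted OD.

The in-vivo selection coefficient comes from the competitive index: per
mouse, the slope of ln(CFU_focal / CFU_reference) over days of colonization;
the pooled estimate is the mean of per-mouse slopes with SE = SD/sqrt(n).
Division by 18 generations per gut day converts to per-generation units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_analysis import GENS_PER_DAY, round_half_away

__all__ = [
    "GrowthCurve",
    "CompetitionSeries",
    "GrowthRateEstimate",
    "SelectionEstimate",
    "max_growth_rate",
    "carrying_capacity",
    "relative_metrics",
    "selection_coefficient",
]

DEFAULT_WINDOW = 5
DEFAULT_R2_MIN = 0.9


@dataclass
class GrowthCurve:
    """One well's OD time series with its sterile-medium blank."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    blank: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be >= 0")


@dataclass
class CompetitionSeries:
    """Longitudinal CFU counts of two competing clones per mouse.

    ``data`` columns: mouse_id, day, cfu_focal, cfu_reference.
    """

    data: pd.DataFrame
    gens_per_day: int = GENS_PER_DAY

    REQUIRED = ("mouse_id", "day", "cfu_focal", "cfu_reference")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"competition table missing columns {sorted(missing)}")
        if (self.data["day"] < 0).any():
            raise ValueError("days must be >= 0")
        if (self.data[["cfu_focal", "cfu_reference"]] < 0).to_numpy().any():
            raise ValueError("CFU counts must be >= 0")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, gens_per_day: int = GENS_PER_DAY):
        return cls(pd.read_csv(path, sep="\t", comment="#"), gens_per_day=gens_per_day)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Result of the sliding-window rate fit; ``rate`` None if no window passes."""

    rate: float | None
    r_squared: float | None = None
    window_start_index: int | None = None
    window_times: tuple | None = None

    @property
    def estimated(self) -> bool:
        return self.rate is not None


def _ols_slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def max_growth_rate(
    curve: GrowthCurve,
    window: int = DEFAULT_WINDOW,
    r2_min: float = DEFAULT_R2_MIN,
) -> GrowthRateEstimate:
    """Maximum specific growth rate (per hour) by the sliding-window rule.

    Readings with OD <= blank are excluded before windows are formed (their
    logarithm is undefined); windows are ``window`` consecutive retained
    points. Among windows with R^2 strictly above ``r2_min`` the largest
    slope wins; ties break to the earliest window. Returns a no-estimate
    result when no window qualifies.
    """
    mask = curve.od > curve.blank
    t = curve.times[mask]
    y = np.log(curve.od[mask] - curve.blank)
    if len(t) < window:
        return GrowthRateEstimate(rate=None)
    best: GrowthRateEstimate | None = None
    for i in range(len(t) - window + 1):
        slope, r2 = _ols_slope_r2(t[i : i + window], y[i : i + window])
        if r2 > r2_min and (best is None or slope > best.rate):
            best = GrowthRateEstimate(
                rate=slope,
                r_squared=r2,
                window_start_index=i,
                window_times=tuple(t[i : i + window]),
            )
    return best if best is not None else GrowthRateEstimate(rate=None)


def carrying_capacity(curve: GrowthCurve) -> float:
    """Maximum background-subtracted OD, floored at zero."""
    return float(max(np.max(curve.od - curve.blank), 0.0))


def relative_metrics(
    evolved: np.ndarray | list, ancestor: np.ndarray | list
) -> np.ndarray:
    """Evolved metric values divided by the mean of their matched ancestor."""
    anc_mean = float(np.mean(ancestor))
    if anc_mean <= 0:
        raise ValueError("ancestor mean must be > 0")
    return np.asarray(evolved, dtype=float) / anc_mean


@dataclass(frozen=True)
class SelectionEstimate:
    """Per-mouse and pooled selection-coefficient estimates."""

    per_mouse: dict  # mouse_id -> (slope per day, SE of slope)
    per_day: float  # pooled mean of per-mouse slopes
    se_per_day: float  # SD of per-mouse slopes / sqrt(n)
    per_generation: float  # per_day / gens_per_day, rounded to 2 decimals
    gens_per_day: int

    @property
    def per_generation_raw(self) -> float:
        return self.per_day / self.gens_per_day


def selection_coefficient(series: CompetitionSeries) -> SelectionEstimate:
    """Selection coefficient from the slope of the log competitive index.

    Per mouse, OLS of ln(cfu_focal/cfu_reference) on day; days where either
    count is zero are dropped with a warning, and mice with fewer than two
    usable days yield no per-mouse estimate. The pooled per-day coefficient
    is the mean of per-mouse slopes (SE = SD/sqrt(n_mice)); the
    per-generation value divides by generations per day and is reported to
    two decimals.
    """
    per_mouse: dict = {}
    for mouse, sub in series.data.groupby("mouse_id", sort=True):
        usable = sub[(sub["cfu_focal"] > 0) & (sub["cfu_reference"] > 0)]
        dropped = len(sub) - len(usable)
        if dropped:
            warnings.warn(
                f"mouse {mouse}: dropped {dropped} day(s) with a zero CFU count",
                stacklevel=2,
            )
        if len(usable) < 2:
            continue
        x = usable["day"].to_numpy(dtype=float)
        y = np.log(usable["cfu_focal"].to_numpy() / usable["cfu_reference"].to_numpy())
        if len(usable) == 2:
            slope = (y[1] - y[0]) / (x[1] - x[0])
            per_mouse[mouse] = (float(slope), math.nan)
        else:
            fit = stats.linregress(x, y)
            per_mouse[mouse] = (float(fit.slope), float(fit.stderr))
    if not per_mouse:
        raise ValueError("no mouse has >= 2 usable days")
    slopes = np.array([v[0] for v in per_mouse.values()])
    per_day = float(slopes.mean())
    se = (
        float(slopes.std(ddof=1) / math.sqrt(len(slopes)))
        if len(slopes) > 1
        else math.nan
    )
    return SelectionEstimate(
        per_mouse=per_mouse,
        per_day=per_day,
        se_per_day=se,
        per_generation=round_half_away(per_day / series.gens_per_day, 2),
        gens_per_day=series.gens_per_day,
    )
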