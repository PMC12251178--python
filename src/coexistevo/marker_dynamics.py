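"""Longitudinal analysis of fluorescent-marker CFU trajectories.

Each strain carries two neutral fluorescent markers (strain A: CFP and YFP;
strain B1: mCherry and sfGFP) and is tracked by plating feces over ~3 months
of gut colonization. Plating has a detection limit (~300 CFU/g), so a zero
count means "below the limit of detection (LOD)", not proven absence; the
within-strain frequency of a below-LOD marker is reported as the upper bound
LOD / (LOD + other marker's CFU).

Polymorphism at the marker locus is called lost when the same single marker
stays below LOD on the last k sampled days (default k=2); maintained
otherwise. A strain absent from day 7 onward is called not-colonized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sweep import fisher_exact_2x2

__all__ = [
    "MARKER_STRAIN",
    "STRAIN_MARKERS",
    "MarkerTrajectory",
    "PolymorphismCall",
    "within_strain_frequencies",
    "classify_polymorphism",
    "polymorphism_proportion_test",
    "mean_log10_load",
]

MARKER_STRAIN = {"CFP": "A", "YFP": "A", "mCherry": "B1", "sfGFP": "B1"}
STRAIN_MARKERS = {"A": ("CFP", "YFP"), "B1": ("mCherry", "sfGFP")}

DEFAULT_DETECTION_LIMIT = 300.0
DEFAULT_COLONIZATION_DAY = 7


@dataclass
class MarkerTrajectory:
    """Long-format CFU table: one row per (mouse, day, marker).

    ``data`` columns: mouse_id, day, marker, cfu_per_g.
    """

    data: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    marker_strain: dict = field(default_factory=lambda: dict(MARKER_STRAIN))

    REQUIRED = ("mouse_id", "day", "marker", "cfu_per_g")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {sorted(missing)}")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be > 0")
        if (self.data["day"] < 0).any():
            raise ValueError("days must be non-negative")
        if (self.data["cfu_per_g"] < 0).any():
            raise ValueError("CFU values must be >= 0")
        self.data = self.data.sort_values(["mouse_id", "day", "marker"]).reset_index(
            drop=True
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, detection_limit: float = DEFAULT_DETECTION_LIMIT):
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(data=df, detection_limit=detection_limit)


@dataclass(frozen=True)
class PolymorphismCall:
    """Per (mouse, strain) verdict on neutral-marker polymorphism."""

    mouse_id: object
    strain: str
    status: str  # maintained | lost | strain_not_colonized
    day_of_loss: object = None
    fixed_marker: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("maintained", "lost", "strain_not_colonized"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "lost" and self.fixed_marker is None:
            raise ValueError("lost calls must name the fixed marker")
        if self.status == "strain_not_colonized" and (
            self.day_of_loss is not None or self.fixed_marker is not None
        ):
            raise ValueError("strain_not_colonized carries no loss fields")


def within_strain_frequencies(traj: MarkerTrajectory) -> pd.DataFrame:
    """Marker frequencies within each strain per (mouse, day).

    Returns a long table with columns mouse_id, day, strain, marker,
    cfu_per_g, frequency, below_lod, strain_absent. A below-LOD marker's
    frequency is the upper bound LOD/(LOD + other CFU); when both markers
    of a strain are below LOD the strain is flagged absent and frequencies
    are NaN.
    """
    lod = traj.detection_limit
    rows = []
    for (mouse, day), day_df in traj.data.groupby(["mouse_id", "day"], sort=True):
        by_marker = dict(zip(day_df["marker"], day_df["cfu_per_g"]))
        for strain, (m1, m2) in STRAIN_MARKERS.items():
            if m1 not in by_marker or m2 not in by_marker:
                continue  # strain not measured that day
            c1, c2 = float(by_marker[m1]), float(by_marker[m2])
            below = (c1 < lod, c2 < lod)
            absent = below[0] and below[1]
            for marker, cfu, other, b in ((m1, c1, c2, below[0]), (m2, c2, c1, below[1])):
                if absent:
                    freq = math.nan
                elif b:
                    freq = lod / (lod + other)
                else:
                    freq = cfu / (c1 + c2)
                rows.append(
                    {
                        "mouse_id": mouse,
                        "day": day,
                        "strain": strain,
                        "marker": marker,
                        "cfu_per_g": cfu,
                        "frequency": freq,
                        "below_lod": b,
                        "strain_absent": absent,
                    }
                )
    return pd.DataFrame(rows)


def classify_polymorphism(
    traj: MarkerTrajectory,
    k: int = 2,
    colonization_day: int = DEFAULT_COLONIZATION_DAY,
) -> list[PolymorphismCall]:
    """Call marker polymorphism maintained/lost per (mouse, strain).

    Lost: the same single marker is below LOD on each of the last ``k``
    sampled days; ``day_of_loss`` is the first day of that terminal run and
    ``fixed_marker`` the surviving one. Not-colonized: the strain is absent
    (both markers below LOD) on every sampled day from ``colonization_day``
    onward. Maintained otherwise.
    """
    freqs = within_strain_frequencies(traj)
    calls = []
    for (mouse, strain), sub in freqs.groupby(["mouse_id", "strain"], sort=True):
        days = sorted(sub["day"].unique())
        if len(days) < k:
            raise ValueError(
                f"mouse {mouse} strain {strain}: need >= {k} sampled days, "
                f"got {len(days)}"
            )
        per_day = {
            d: g.set_index("marker") for d, g in sub.groupby("day", sort=True)
        }
        late_days = [d for d in days if d >= colonization_day]
        if late_days and all(
            per_day[d]["strain_absent"].all() for d in late_days
        ):
            calls.append(
                PolymorphismCall(mouse_id=mouse, strain=strain, status="strain_not_colonized")
            )
            continue
        markers = STRAIN_MARKERS[strain]
        last_k = days[-k:]
        below_markers = [
            m
            for m in markers
            if all(
                bool(per_day[d].loc[m, "below_lod"])
                and not bool(per_day[d].loc[m, "strain_absent"])
                for d in last_k
            )
        ]
        lost_marker = below_markers[0] if len(below_markers) == 1 else None
        if lost_marker is not None:
            other = markers[0] if lost_marker == markers[1] else markers[1]
            # first day of the terminal run of below-LOD observations
            day_of_loss = last_k[0]
            for d in reversed(days):
                row = per_day[d].loc[lost_marker]
                if bool(row["below_lod"]) and not bool(row["strain_absent"]):
                    day_of_loss = d
                else:
                    break
            calls.append(
                PolymorphismCall(
                    mouse_id=mouse,
                    strain=strain,
                    status="lost",
                    day_of_loss=day_of_loss,
                    fixed_marker=other,
                )
            )
        else:
            calls.append(
                PolymorphismCall(mouse_id=mouse, strain=strain, status="maintained")
            )
    return calls


def polymorphism_proportion_test(
    calls_A: list[PolymorphismCall], calls_B1: list[PolymorphismCall]
) -> float:
    """Exact test that marker-polymorphism maintenance is strain independent.

    Builds the 2x2 maintained/lost table across strains (not-colonized mice
    excluded) and returns the two-sided Fisher exact p-value.
    """
    if not calls_A or not calls_B1:
        raise ValueError("need at least one call per strain")

    def tally(calls):
        kept = [c for c in calls if c.status != "strain_not_colonized"]
        maintained = sum(c.status == "maintained" for c in kept)
        return maintained, len(kept) - maintained

    ma, la = tally(calls_A)
    mb, lb = tally(calls_B1)
    return fisher_exact_2x2(ma, la, mb, lb)


def mean_log10_load(
    traj: MarkerTrajectory, strain: str, coexistence_only: bool = True
) -> tuple[float, float]:
    """Mean and SE of log10 total CFU/g of ``strain`` across mice.

    Per mouse, log10 of the strain's total load (sum of its two markers) is
    averaged over eligible days; the returned mean and standard error are
    taken across mice. With ``coexistence_only`` (default) a day is eligible
    only when both strains are at or above the detection limit, matching the
    "under coexistence" framing of load summaries.
    """
    if strain not in STRAIN_MARKERS:
        raise ValueError(f"unknown strain {strain!r}")
    lod = traj.detection_limit
    per_mouse = []
    for mouse, sub in traj.data.groupby("mouse_id", sort=True):
        logs = []
        for day, day_df in sub.groupby("day", sort=True):
            by_marker = dict(zip(day_df["marker"], day_df["cfu_per_g"]))
            totals = {
                s: sum(float(by_marker.get(m, 0.0)) for m in ms)
                for s, ms in STRAIN_MARKERS.items()
            }
            if totals[strain] < lod:
                continue
            if coexistence_only and any(t < lod for t in totals.values()):
                continue
            logs.append(math.log10(totals[strain]))
        if logs:
            per_mouse.append(float(np.mean(logs)))
    if not per_mouse:
        raise ValueError(f"no eligible observations for strain {strain}")
    mean = float(np.mean(per_mouse))
    if len(per_mouse) == 1:
        return mean, math.nan
    se = float(np.std(per_mouse, ddof=1) / math.sqrt(len(per_mouse)))
    return mean, se
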