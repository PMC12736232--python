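"""Viability normalization, response-zone classification and depth tracking.

Luminescence is normalized per cell line and assay day to the mean of
the same-day dark (untreated) control.  Each condition's replicate-mean
percent viability is then classified into one of three response zones:

* Effect (Go): viability below 50% of control;
* Consider: 50% to 70% inclusive (boundaries fall here because the
  neighbouring zones are defined by strict inequalities);
* NoEffect (NoGo): viability above 70%.

For each cell line x tissue x day the zone calls along the tested
thickness grid yield a depth profile: the deepest grid thickness still
in the Effect zone and the shallowest grid thickness in the NoEffect
zone.  Both depths can be censored by the finite grid; censoring is kept
as the first-class markers ">max" and "none" rather than numbers.
Profiles are functions on the tested grid only — untested thicknesses
are never interpolated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import TREATED, ViabilityRecord

GO_THRESHOLD = 50.0
NOGO_THRESHOLD = 70.0

#: Censoring markers (serialized verbatim).
CENSORED_DEEP = ">max"  # Effect zone extends beyond the deepest tested plate
CENSORED_NONE = "none"  # zone never reached within the tested grid


class Zone(enum.Enum):
    EFFECT = "Effect"
    CONSIDER = "Consider"
    NO_EFFECT = "NoEffect"


class NormalizationError(ValueError):
    """A (cell line, day) stratum lacks the dark-control denominator."""


class IncompleteProfileError(ValueError):
    """A depth profile is missing zone calls for part of its grid."""


def classify_zone(mean_pct: float) -> Zone:
    """Assign a replicate-mean percent viability to a response zone."""
    if mean_pct < 0:
        raise ValueError(f"viability cannot be negative, got {mean_pct}")
    if mean_pct < GO_THRESHOLD:
        return Zone.EFFECT
    if mean_pct <= NOGO_THRESHOLD:
        return Zone.CONSIDER
    return Zone.NO_EFFECT


@dataclass(frozen=True)
class NormalizedViability:
    """Replicate summary of one condition as percent of dark control."""

    cell_line: str
    condition: str
    tissue: str | None
    thickness_mm: float | None
    day: float
    mean_pct: float
    sd_pct: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be non-negative")

    @property
    def zone(self) -> Zone:
        return classify_zone(self.mean_pct)


def records_to_frame(records: Iterable[ViabilityRecord]) -> pd.DataFrame:
    """Tabulate viability records (one row per replicate reading)."""
    return pd.DataFrame(
        {
            "cell_line": r.cell_line,
            "condition": r.condition,
            "tissue": r.tissue,
            "thickness_mm": r.thickness_mm,
            "day": r.day,
            "replicate": r.replicate,
            "luminescence": r.luminescence,
        }
        for r in records
    )


def normalize_viability(records: Iterable[ViabilityRecord]) -> list[NormalizedViability]:
    """Normalize every arm to the same-day dark control, per cell line.

    mean_pct is 100 x mean(arm luminescence) / mean(dark-control
    luminescence); sd_pct is the replicate standard deviation (ddof=1)
    of the arm on the same percent scale.  Light-only and ALA-only
    controls are normalized and reported like any other arm but never
    used as the denominator.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to normalize")

    dark = (
        df[df["condition"] == "dark_control"]
        .groupby(["cell_line", "day"])["luminescence"]
        .mean()
    )

    out: list[NormalizedViability] = []
    keys = ["cell_line", "condition", "tissue", "thickness_mm", "day"]
    for (cell_line, condition, tissue, thickness, day), grp in df.groupby(
        keys, dropna=False, sort=True
    ):
        try:
            denom = dark.loc[(cell_line, day)]
        except KeyError:
            raise NormalizationError(
                f"no dark control for cell line {cell_line!r} on day {day}"
            ) from None
        lum = grp["luminescence"].to_numpy()
        mean_pct = 100.0 * lum.mean() / denom
        sd_pct = 100.0 * lum.std(ddof=1) / denom if len(lum) > 1 else 0.0
        out.append(NormalizedViability(
            cell_line=cell_line, condition=condition,
            tissue=None if pd.isna(tissue) else tissue,
            thickness_mm=None if pd.isna(thickness) else float(thickness),
            day=float(day), mean_pct=float(mean_pct), sd_pct=float(sd_pct),
            n=len(lum),
        ))
    return out


@dataclass(frozen=True)
class DepthZoneProfile:
    """Zone calls along the thickness grid for one cell line, tissue, day.

    ``deepest_effect_mm`` is the maximum grid thickness in the Effect
    zone, the marker ``">max"`` if even the deepest tested plate is
    Effect (the true depth exceeds the grid), or ``None`` if no grid
    point is Effect.  ``no_effect_onset_mm`` is the minimum grid
    thickness in the NoEffect zone, or the marker ``"none"`` if the
    NoEffect zone is never reached within the grid.
    """

    cell_line: str
    tissue: str
    day: float
    zone_by_thickness: tuple[tuple[float, Zone], ...]
    deepest_effect_mm: float | str | None
    no_effect_onset_mm: float | str

    def deepest_effect_numeric(self) -> float:
        """Deepest Effect depth on a totally ordered scale for comparisons:
        censored-beyond-grid maps to +inf, no-Effect-anywhere to -inf."""
        if self.deepest_effect_mm == CENSORED_DEEP:
            return math.inf
        if self.deepest_effect_mm is None:
            return -math.inf
        return float(self.deepest_effect_mm)


def depth_profile(
    normalized: Sequence[NormalizedViability], grid: Sequence[float]
) -> DepthZoneProfile:
    """Build the depth-zone profile of one cell line x tissue x day.

    ``normalized`` must contain exactly the treated arms of a single
    stratum; every thickness in ``grid`` needs a zone call.
    """
    strata = {(nv.cell_line, nv.tissue, nv.day) for nv in normalized}
    if len(strata) != 1:
        raise ValueError(f"profile requires a single cell_line x tissue x day, got {strata}")
    cell_line, tissue, day = next(iter(strata))

    by_thickness = {nv.thickness_mm: nv for nv in normalized}
    missing = [d for d in grid if d not in by_thickness]
    if missing:
        raise IncompleteProfileError(
            f"missing zone calls at thicknesses {missing} for "
            f"{cell_line}/{tissue}/day {day}"
        )

    grid = sorted(grid)
    zones = tuple((float(d), by_thickness[d].zone) for d in grid)

    effect_depths = [d for d, z in zones if z is Zone.EFFECT]
    if not effect_depths:
        deepest: float | str | None = None
    elif max(effect_depths) == grid[-1]:
        deepest = CENSORED_DEEP
    else:
        deepest = max(effect_depths)

    noeffect_depths = [d for d, z in zones if z is Zone.NO_EFFECT]
    onset: float | str = min(noeffect_depths) if noeffect_depths else CENSORED_NONE

    return DepthZoneProfile(
        cell_line=cell_line, tissue=tissue, day=day,
        zone_by_thickness=zones,
        deepest_effect_mm=deepest, no_effect_onset_mm=onset,
    )


def profiles_from_normalized(
    normalized: Sequence[NormalizedViability],
    grids: Mapping[str, Sequence[float]],
    include_zero: bool = False,
) -> list[DepthZoneProfile]:
    """Depth profiles for every cell line x tissue x day in a table.

    The 0 mm direct-irradiation arm is not a phantom depth; by default
    it is excluded from the profile grid.
    """
    treated = [nv for nv in normalized if nv.condition == TREATED]
    out: list[DepthZoneProfile] = []
    strata = sorted({(nv.cell_line, nv.tissue, nv.day) for nv in treated})
    for cell_line, tissue, day in strata:
        grid = [d for d in grids[tissue] if include_zero or d > 0]
        subset = [
            nv for nv in treated
            if (nv.cell_line, nv.tissue, nv.day) == (cell_line, tissue, day)
            and nv.thickness_mm in grid
        ]
        out.append(depth_profile(subset, grid))
    return out


def track_shifts(profiles: Sequence[DepthZoneProfile]) -> pd.DataFrame:
    """Day-indexed table of zone depths for one cell line x tissue.

    Columns: ``deepest_effect_mm``, ``no_effect_onset_mm`` (censoring
    markers kept verbatim) and ``anomalous_deepening`` flagging any
    day-over-day increase of the deepest Effect depth (a delayed
    response — reported, not rejected).
    """
    if not profiles:
        raise ValueError("no profiles to track")
    strata = {(p.cell_line, p.tissue) for p in profiles}
    if len(strata) != 1:
        raise ValueError(f"shift tracking requires a single cell_line x tissue, got {strata}")
    days = [p.day for p in profiles]
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate assay days in profiles: {sorted(days)}")

    ordered = sorted(profiles, key=lambda p: p.day)
    numeric = [p.deepest_effect_numeric() for p in ordered]
    anomalous = [False] + [b > a for a, b in zip(numeric, numeric[1:])]
    return pd.DataFrame(
        {
            "deepest_effect_mm": [p.deepest_effect_mm for p in ordered],
            "no_effect_onset_mm": [p.no_effect_onset_mm for p in ordered],
            "anomalous_deepening": anomalous,
        },
        index=pd.Index([p.day for p in ordered], name="day"),
    )
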