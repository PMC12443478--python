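"""Lane densitometry: percent-of-total for a target band and relative
total protein per cell.

Starts from band-intensity tables (one row per band per lane, as produced
by gel-imaging software), never from gel images.  Lanes are assumed to be
loaded with protein extracted from a fixed number of OD units of cells, so
lane totals are comparable across strains once divided by the OD units
loaded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "LaneQuant",
    "percent_of_total",
    "relative_total_protein",
    "read_lanes_tsv",
]


@dataclass(frozen=True)
class LaneQuant:
    """Quantified bands for one gel lane.

    bands is an ordered list of (band_id, intensity) with intensities in
    arbitrary units >= 0; target_band_id names the overexpressed protein's
    band when present.
    """

    lane_id: str
    bands: tuple[tuple[str, float], ...]
    target_band_id: str | None = None
    strain: str = ""
    condition: str = ""
    replicate: int = 0
    od_units_loaded: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bands = tuple((str(b), float(i)) for b, i in self.bands)
        object.__setattr__(self, "bands", bands)
        if any(i < 0 for _, i in bands):
            raise ValidationError(f"lane {self.lane_id}: negative band intensity")
        if self.od_units_loaded <= 0:
            raise ValidationError(f"lane {self.lane_id}: od_units_loaded must be > 0")
        if self.target_band_id is not None and self.target_band_id not in {
            b for b, _ in bands
        }:
            raise ValidationError(
                f"lane {self.lane_id}: target band {self.target_band_id!r} not present"
            )

    @property
    def total(self) -> float:
        return float(sum(i for _, i in self.bands))

    @property
    def target_intensity(self) -> float:
        if self.target_band_id is None:
            return 0.0
        return float(
            sum(i for b, i in self.bands if b == self.target_band_id)
        )


def percent_of_total(lane: LaneQuant) -> float:
    """Target band intensity as a percent of the summed lane intensity."""
    if lane.target_band_id is None:
        raise ValidationError(f"lane {lane.lane_id}: no target band set")
    total = lane.total
    if total <= 0:
        raise ValidationError(f"lane {lane.lane_id}: zero total intensity")
    return 100.0 * lane.target_intensity / total


def relative_total_protein(
    lanes: list[LaneQuant],
    control_lanes: list[LaneQuant],
    exclude_target: bool = False,
) -> tuple[float, float]:
    """Total protein per OD unit as a percent of the control group.

    Lane totals are divided by od_units_loaded before averaging.  With
    ``exclude_target`` the target band is removed from the sample totals
    first, giving the "other proteins" quantity.  When the two groups have
    equal replicate counts the ratio is computed per replicate pairing (by
    list position) and the per-replicate SD is reported; otherwise the
    ratio of group means is returned with SD propagated from the sample
    side only.

    Returns (mean_percent, sd_percent).
    """
    if not lanes or not control_lanes:
        raise ValidationError("both lane groups must be nonempty")

    def per_od(lane: LaneQuant, exclude: bool) -> float:
        total = lane.total - (lane.target_intensity if exclude else 0.0)
        return total / lane.od_units_loaded

    sample_totals = np.array([per_od(ln, exclude_target) for ln in lanes])
    control_totals = np.array([per_od(ln, False) for ln in control_lanes])
    if np.any(control_totals <= 0):
        raise ValidationError("control lane with non-positive total intensity")

    if len(sample_totals) == len(control_totals):
        ratios = 100.0 * sample_totals / control_totals
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
        return float(np.mean(ratios)), sd
    mean_ratio = 100.0 * float(np.mean(sample_totals)) / float(np.mean(control_totals))
    sd = (
        100.0 * float(np.std(sample_totals, ddof=1)) / float(np.mean(control_totals))
        if sample_totals.size > 1
        else 0.0
    )
    return mean_ratio, sd


def read_lanes_tsv(path) -> list[LaneQuant]:
    """Read a band table TSV: lane_id, band_id, intensity, strain, condition,
    replicate, od_units, is_target (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"lane_id", "band_id", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"lanes TSV missing columns: {sorted(missing)}")
    lanes = []
    for lane_id, grp in df.groupby("lane_id", sort=True):
        bands = tuple(zip(grp["band_id"].astype(str), grp["intensity"].astype(float)))
        target = None
        if "is_target" in grp.columns:
            hits = grp.loc[grp["is_target"].astype(bool), "band_id"].astype(str)
            if len(hits) > 1:
                raise ValidationError(f"lane {lane_id}: multiple target bands flagged")
            if len(hits) == 1:
                target = hits.iloc[0]
        first = grp.iloc[0]
        lanes.append(
            LaneQuant(
                lane_id=str(lane_id),
                bands=bands,
                target_band_id=target,
                strain=str(first.get("strain", "")),
                condition=str(first.get("condition", "")),
                replicate=int(first.get("replicate", 0)),
                od_units_loaded=float(first.get("od_units", 1.0)),
            )
        )
    return lanes
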