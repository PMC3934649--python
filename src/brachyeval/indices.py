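"""Dose regions and implant quality indices.

High-dose-rate interstitial implants have steep dose gradients, so a single
target dose number says little about plan quality.  Instead the target DVH
is carved into four dose bands relative to the reference (prescription)
dose Dref — below Dref, [1·Dref, 1.5·Dref), [1.5·Dref, 2·Dref) and
≥ 2·Dref — and normal tissue into two (below / at-or-above Dref).  Five
classical indices summarize the result:

* CI  (coverage index)            = TV_Dref / TV
* EI  (external volume index)     = NTV_Dref / TV
* DHI (relative dose homogeneity) = (TV_Dref − TV_1.5Dref) / TV_Dref
* ODI (overdose volume index)     = TV_2.0Dref / TV_Dref
* DNR (dose nonuniformity ratio)  = TV_1.5Dref / TV_Dref

where TV_x is the target volume receiving at least dose x and NTV_Dref the
normal-tissue volume receiving at least Dref.  An ideal implant has
CI = 1, EI = 0, DHI = 1, ODI = 0, DNR = 0.

Every band is closed below and open above; a DVH bin straddling a band edge
is split pro-rata by dose-width overlap, consistent with the linear
interpolation used for threshold volumes, so region totals and
threshold-volume differences agree to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dvh import (
    DifferentialDVH,
    differential_to_cumulative,
    total_volume,
    volume_at_or_above,
)

__all__ = [
    "ThresholdVolumes",
    "QualityIndices",
    "RegionPartition",
    "threshold_volumes",
    "quality_indices",
    "partition_regions",
    "N_TARGET_REGIONS",
    "N_NORMAL_REGIONS",
]

N_TARGET_REGIONS = 4
N_NORMAL_REGIONS = 2

_REL = 1e-9


@dataclass(frozen=True)
class ThresholdVolumes:
    """The six volumes (cm³) the quality indices are built from."""

    TV: float
    TV_Dref: float
    TV_1p5Dref: float
    TV_2p0Dref: float
    NTV_Dref: float
    V_normal: float
    Dref: float

    def __post_init__(self) -> None:
        if self.Dref <= 0:
            raise ValueError(f"reference dose must be > 0, got {self.Dref}")
        tol = _REL * max(self.TV, 1.0)
        seq = (self.TV, self.TV_Dref, self.TV_1p5Dref, self.TV_2p0Dref)
        if any(a < b - tol for a, b in zip(seq, seq[1:])) or seq[-1] < -tol:
            raise ValueError(f"threshold volumes must be nested and ≥ 0: {seq}")
        if self.NTV_Dref < -tol or self.V_normal < self.NTV_Dref - tol:
            raise ValueError(
                f"normal-tissue volumes inconsistent: total {self.V_normal}, "
                f"≥Dref {self.NTV_Dref}"
            )


@dataclass(frozen=True)
class QualityIndices:
    CI: float
    EI: float
    DHI: float
    ODI: float
    DNR: float

    def as_dict(self) -> dict[str, float]:
        return {
            "CI": self.CI,
            "EI": self.EI,
            "DHI": self.DHI,
            "ODI": self.ODI,
            "DNR": self.DNR,
        }


@dataclass(frozen=True)
class RegionPartition:
    """Per-region (dose cGy, subvolume cm³) pairs for one structure.

    ``regions`` has 4 entries for a target, 2 for normal tissue; each entry
    lists the subvolume fragments whose doses fall in that band.  Fragments
    from bins straddling a band edge carry the midpoint dose of the
    overlapping sub-interval.
    """

    regions: list[list[tuple[float, float]]]
    role_label: Literal["target", "normal"]
    Dref: float

    def region_volumes(self) -> list[float]:
        return [float(sum(v for _, v in reg)) for reg in self.regions]

    def total_volume(self) -> float:
        return float(sum(self.region_volumes()))


def _band_edges(Dref: float, role: str) -> list[tuple[float, float]]:
    if role == "target":
        return [
            (0.0, Dref),
            (Dref, 1.5 * Dref),
            (1.5 * Dref, 2.0 * Dref),
            (2.0 * Dref, np.inf),
        ]
    if role == "normal":
        return [(0.0, Dref), (Dref, np.inf)]
    raise ValueError(f"unknown role {role!r}: expected 'target' or 'normal'")


def threshold_volumes(
    target: DifferentialDVH, normal: DifferentialDVH, Dref: float
) -> ThresholdVolumes:
    """Evaluate the six index volumes at Dref, 1.5·Dref and 2·Dref."""
    if Dref <= 0:
        raise ValueError(f"reference dose must be > 0, got {Dref}")
    ct = differential_to_cumulative(target)
    cn = differential_to_cumulative(normal)
    return ThresholdVolumes(
        TV=total_volume(target),
        TV_Dref=volume_at_or_above(ct, Dref),
        TV_1p5Dref=volume_at_or_above(ct, 1.5 * Dref),
        TV_2p0Dref=volume_at_or_above(ct, 2.0 * Dref),
        NTV_Dref=volume_at_or_above(cn, Dref),
        V_normal=total_volume(normal),
        Dref=Dref,
    )


def quality_indices(tv: ThresholdVolumes) -> QualityIndices:
    """Compute CI, EI, DHI, ODI, DNR from threshold volumes.

    DHI is evaluated as 1 − DNR, which equals
    (TV_Dref − TV_1.5Dref)/TV_Dref exactly and keeps the DHI + DNR = 1
    identity exact in floating point.
    """
    if tv.TV <= 0:
        raise ValueError("empty target: TV must be > 0")
    CI = tv.TV_Dref / tv.TV
    EI = tv.NTV_Dref / tv.TV
    if tv.TV_Dref <= 0:
        raise ValueError(
            "no target volume at or above the reference dose: DHI, ODI and "
            "DNR are undefined (CI and EI are still reportable)"
        )
    DNR = tv.TV_1p5Dref / tv.TV_Dref
    ODI = tv.TV_2p0Dref / tv.TV_Dref
    DHI = 1.0 - DNR
    return QualityIndices(CI=CI, EI=EI, DHI=DHI, ODI=ODI, DNR=DNR)


def partition_regions(
    dvh: DifferentialDVH, Dref: float, role: Literal["target", "normal"]
) -> RegionPartition:
    """Assign each DVH bin's volume to its dose region.

    Bands are closed below, open above ("equal to or greater than" the
    band's lower dose).  A bin overlapping several bands is split pro-rata
    by dose-width; each fragment carries the midpoint dose of its
    sub-interval, matching the within-bin uniform-dose assumption of the
    cumulative-curve interpolation.
    """
    if Dref <= 0:
        raise ValueError(f"reference dose must be > 0, got {Dref}")
    bands = _band_edges(Dref, role)
    regions: list[list[tuple[float, float]]] = [[] for _ in bands]
    lows = dvh.bin_lower_edges
    highs = dvh.bin_upper_edges
    dens = dvh.volume_density
    for lo, hi, rho in zip(lows, highs, dens):
        if rho == 0.0:
            continue
        for r, (blo, bhi) in enumerate(bands):
            olo = max(lo, blo)
            ohi = min(hi, bhi)
            if ohi <= olo:
                continue
            width = ohi - olo
            regions[r].append(((olo + ohi) / 2.0, rho * width))
    return RegionPartition(regions=regions, role_label=role, Dref=Dref)
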