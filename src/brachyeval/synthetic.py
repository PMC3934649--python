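"""Synthetic implants, DVHs and outcome cohorts.

Interstitial implants produce characteristic dose distributions: extreme
hot spots in the millimetres around each needle, a prescription isodose
wrapping the target, and a cold tail into surrounding tissue.  This module
generates such distributions from first principles so every evaluator
component can be tested — and its voxel ground truth inspected — without
clinical data:

* an *ideal implant* DVH whose entire target volume sits in
  [Dref, 1.5·Dref) (the configuration whose quality indices are exactly
  CI=1, DHI=1, ODI=DNR=0);
* a 2-D multi-needle implant simulator using a bare inverse-square
  line-source kernel (deliberately not full clinical dosimetry — no radial
  dose function or anisotropy), returning target/normal DVHs *and* the
  underlying voxel doses as ground truth;
* randomized smooth DVHs for property tests;
* synthetic patient cohorts linking NTCP estimates to CTCAE grades through
  a configurable monotone link, for exercising the outcome-correlation
  path.

Everything is driven by :class:`numpy.random.Generator` seeds and is
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
from shapely.geometry import MultiPoint, Point

from .dvh import DifferentialDVH, total_volume
from .outcomes import OutcomeRecord
from .radiobiology import EvaluationResult, PlanParams, evaluate_plan

__all__ = [
    "ImplantSpec",
    "ImplantSimulation",
    "generate_ideal_implant_dvh",
    "generate_cold_normal_dvh",
    "generate_implant_dvh",
    "random_dvh",
    "generate_outcome_cohort",
    "threshold_link",
]


# ---------------------------------------------------------------------------
# ideal implant

def generate_ideal_implant_dvh(
    TV: float, Dref: float, n_bins: int = 10, label: str = "target"
) -> DifferentialDVH:
    """Target DVH of an ideal implant: all volume in [Dref, 1.5·Dref).

    The dose bins span [1.05, 1.45]·Dref so that every bin edge — not just
    every bin center — lies strictly inside the homogeneity band, and the
    quality indices evaluate to their ideal values CI=1, DHI=1, ODI=DNR=0
    exactly.
    """
    if TV <= 0:
        raise ValueError(f"target volume must be > 0, got {TV}")
    if Dref <= 0:
        raise ValueError(f"reference dose must be > 0, got {Dref}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be ≥ 1, got {n_bins}")
    lo, hi = 1.05 * Dref, 1.45 * Dref
    width = (hi - lo) / n_bins
    centers = lo + width * (np.arange(n_bins) + 0.5)
    density = np.full(n_bins, TV / (n_bins * width))
    return DifferentialDVH(
        structure_label=label,
        dose_bin_centers=centers,
        volume_density=density,
        bin_width=width,
    )


def generate_cold_normal_dvh(
    volume: float, Dref: float, n_bins: int = 10, label: str = "normal"
) -> DifferentialDVH:
    """Normal-tissue DVH lying entirely below the reference dose.

    Pairs with :func:`generate_ideal_implant_dvh` to complete the ideal
    plan (EI = 0).  Dose spans [0.1, 0.8]·Dref with a linearly falling
    density, the cold tail a distant organ-at-risk shows.
    """
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    lo, hi = 0.1 * Dref, 0.8 * Dref
    width = (hi - lo) / n_bins
    centers = lo + width * (np.arange(n_bins) + 0.5)
    shape = np.linspace(2.0, 0.5, n_bins)
    density = shape / (shape.sum() * width) * volume
    return DifferentialDVH(
        structure_label=label,
        dose_bin_centers=centers,
        volume_density=density,
        bin_width=width,
    )


# ---------------------------------------------------------------------------
# inverse-square implant simulator

@dataclass(frozen=True)
class ImplantSpec:
    """Geometry and discretization of a simulated parallel-needle implant.

    Needles are parallel line sources seen in the axial plane as 2-D
    points (cm).  Dose at a voxel is the sum over needles of an
    inverse-square falloff normalized so one unit-strength needle delivers
    the reference dose at 1 cm, capped at the half-voxel radius so hot
    spots stay finite.  The target is the convex hull of the needles
    padded by ``margin``; everything else on the grid is normal tissue.
    """

    needle_positions: Sequence[tuple[float, float]]
    reference_dose: float
    grid_extent: float = 8.0
    voxel_size: float = 0.1
    margin: float = 0.5
    slice_thickness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.needle_positions) < 1:
            raise ValueError("need at least one needle")
        if self.voxel_size <= 0 or self.grid_extent <= 0:
            raise ValueError("voxel_size and grid_extent must be > 0")
        if self.reference_dose <= 0:
            raise ValueError("reference_dose must be > 0")
        pts = np.asarray(self.needle_positions, dtype=float)
        if len(pts) > 1 and np.allclose(pts, pts[0], atol=1e-12):
            raise ValueError("degenerate geometry: all needles coincident")


@dataclass(frozen=True)
class ImplantSimulation:
    """Simulator output: binned DVHs plus the voxel-dose ground truth."""

    target_dvh: DifferentialDVH
    normal_dvh: DifferentialDVH
    target_voxel_doses: np.ndarray
    normal_voxel_doses: np.ndarray
    voxel_volume: float


def _bin_doses(
    doses: np.ndarray, voxel_volume: float, bin_width: float, label: str
) -> DifferentialDVH:
    # edges at integer multiples of bin_width so that Dref, 1.5·Dref and
    # 2·Dref (with bin_width = Dref/20) are exact bin edges
    n_bins = max(int(np.ceil(doses.max() / bin_width)), 1)
    counts, _ = np.histogram(doses, bins=n_bins, range=(0.0, n_bins * bin_width))
    centers = bin_width * (np.arange(n_bins) + 0.5)
    density = counts * voxel_volume / bin_width
    return DifferentialDVH(
        structure_label=label,
        dose_bin_centers=centers,
        volume_density=density,
        bin_width=bin_width,
    )


def generate_implant_dvh(spec: ImplantSpec) -> ImplantSimulation:
    """Simulate a multi-needle implant and bin its voxel doses into DVHs.

    The per-needle strength is jittered ±10% by the spec's seed, emulating
    dwell-weight variation between plans.  Bin width is Dref/20, aligning
    the quality-index thresholds with bin edges so DVH-derived threshold
    volumes agree with direct voxel counting.
    """
    rng = np.random.default_rng(spec.seed)
    needles = np.asarray(spec.needle_positions, dtype=float)
    strengths = spec.reference_dose * rng.uniform(0.9, 1.1, size=len(needles))

    half = spec.grid_extent / 2.0
    coords = np.arange(-half + spec.voxel_size / 2.0, half, spec.voxel_size)
    xx, yy = np.meshgrid(coords, coords)
    dose = np.zeros_like(xx)
    r_min = spec.voxel_size / 2.0
    for (nx, ny), s in zip(needles, strengths):
        r2 = (xx - nx) ** 2 + (yy - ny) ** 2
        np.maximum(r2, r_min**2, out=r2)  # ceiling at the half-voxel radius
        dose += s / r2

    hull = MultiPoint([tuple(p) for p in needles]).convex_hull.buffer(spec.margin)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    in_target = np.fromiter(
        (hull.covers(Point(x, y)) for x, y in flat), dtype=bool, count=len(flat)
    )
    doses_flat = dose.ravel()
    target_doses = doses_flat[in_target]
    normal_doses = doses_flat[~in_target]
    if target_doses.size == 0:
        raise ValueError("target mask is empty: enlarge margin or grid")

    voxel_volume = spec.voxel_size**2 * spec.slice_thickness
    bin_width = spec.reference_dose / 20.0
    return ImplantSimulation(
        target_dvh=_bin_doses(target_doses, voxel_volume, bin_width, "target"),
        normal_dvh=_bin_doses(normal_doses, voxel_volume, bin_width, "normal"),
        target_voxel_doses=target_doses,
        normal_voxel_doses=normal_doses,
        voxel_volume=voxel_volume,
    )


# ---------------------------------------------------------------------------
# randomized DVHs for property tests

def random_dvh(
    rng: np.random.Generator,
    n_bins: int = 20,
    dose_max: float = 1200.0,
    volume_scale: float = 50.0,
    label: str = "random",
) -> DifferentialDVH:
    """A smooth random DVH: gamma-shaped density with multiplicative noise.

    Emulates the generic single-mode implant DVH (rise, peak, hot tail)
    with total volume of order ``volume_scale`` cm³.
    """
    width = dose_max / n_bins
    centers = width * (np.arange(n_bins) + 0.5)
    peak = rng.uniform(0.2, 0.7) * dose_max
    shape = (centers / peak) ** 2 * np.exp(-2.0 * centers / peak)
    shape *= rng.uniform(0.5, 1.5, size=n_bins)
    total = rng.uniform(0.5, 1.5) * volume_scale
    density = shape / (shape.sum() * width) * total
    return DifferentialDVH(
        structure_label=label,
        dose_bin_centers=centers,
        volume_density=density,
        bin_width=width,
    )


# ---------------------------------------------------------------------------
# outcome cohorts

LinkFn = Callable[[float], Sequence[float]]


def threshold_link(
    thresholds: Sequence[float] = (0.2, 0.4, 0.6, 0.8), noise: float = 0.0
) -> LinkFn:
    """Monotone link from NTCP to CTCAE grade probabilities.

    With ``noise = 0`` the categorical distribution is one-hot at the
    grade given by how many thresholds the NTCP exceeds (a noiseless,
    monotone staircase); ``noise > 0`` spreads probability onto
    neighbouring grades.
    """
    th = np.asarray(thresholds, dtype=float)
    if th.size != 4 or np.any(np.diff(th) <= 0):
        raise ValueError("need 4 strictly increasing thresholds")

    def link(ntcp_value: float) -> np.ndarray:
        grade = int(np.sum(ntcp_value >= th))  # 0..4
        probs = np.full(5, noise / 4.0)
        probs[grade] = 1.0 - noise
        return probs

    return link


def _cohort_plan_params(Dref: float) -> PlanParams:
    # cervix-implant-flavoured defaults: α=0.3 Gy⁻¹, α/β=10 Gy for tumour
    # response scale; sign-corrected NTCP so grades track a probability
    return PlanParams(
        Dref=Dref,
        alpha=0.3,
        alpha_beta=10.0,
        rho=1e6,
        n_fractions=4,
        G=1.0,
        dose_scope="per_fraction",
        N0=50.0,
        k=1.5,
        V0=50.0,
        ntcp_variant="sign_corrected",
    )


def generate_outcome_cohort(
    n_patients: int,
    link: Union[LinkFn, Literal["rank"]] = "rank",
    seed: int = 0,
    Dref: float = 400.0,
    endpoint_label: str = "acute rectal toxicity",
) -> list[tuple[EvaluationResult, OutcomeRecord]]:
    """Simulate a patient cohort: plan evaluation plus a scored outcome.

    Each patient gets a randomly scaled synthetic plan (target plus one
    organ-at-risk DVH), is evaluated through the full pipeline, and a
    CTCAE grade is drawn from ``link(NTCP)``.  ``link="rank"`` is the
    noiseless strictly monotone special case: grades follow the rank of
    the patient's NTCP within the cohort (distinct grades whenever
    n_patients ≤ 5).  Fixed seed → identical cohort.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    params = _cohort_plan_params(Dref)

    evaluations: list[EvaluationResult] = []
    for _ in range(n_patients):
        scale = rng.uniform(0.75, 1.35)  # plan-to-plan dose variation
        base_t = random_dvh(rng, n_bins=24, dose_max=3.0 * Dref * scale,
                            volume_scale=40.0, label="target")
        base_n = random_dvh(rng, n_bins=24, dose_max=1.8 * Dref * scale,
                            volume_scale=80.0, label="rectum")
        evaluations.append(evaluate_plan(base_t, {"rectum": base_n}, params))

    ntcps = np.array([ev.ntcp_per_organ["rectum"] for ev in evaluations])
    if link == "rank":
        order = np.argsort(np.argsort(ntcps, kind="stable"), kind="stable")
        grades = 1 + (order * 5) // n_patients
    else:
        grades = np.array(
            [1 + rng.choice(5, p=np.asarray(link(v)) / np.sum(link(v)))
             for v in ntcps]
        )

    cohort: list[tuple[EvaluationResult, OutcomeRecord]] = []
    for i, (ev, g) in enumerate(zip(evaluations, grades), start=1):
        rec = OutcomeRecord(
            patient_id=f"P{i:03d}",
            ctcae_grade=int(g),
            endpoint_label=endpoint_label,
        )
        cohort.append((ev, rec))
    return cohort
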