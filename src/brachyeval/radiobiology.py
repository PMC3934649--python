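"""Linear-quadratic BED, region BEEUD, and Poisson TCP/NTCP models.

The dose response of a fractionated treatment is summarized by the
biologically effective dose

    BED = D · (1 + G·d/(α/β)),

with total dose D, dose per fraction d, incomplete-repair factor G (1 under
full interfraction repair) and the tissue's α/β ratio.  For a uniformly
irradiated target of volume V and clonogen density ρ, Poisson statistics on
the surviving-clonogen number give

    TCP = exp[−ρ·V·exp(−α·BED)].

Interstitial implants are anything but uniform, so the target is split
into four dose regions (see :mod:`brachyeval.indices`) and each region's
heterogeneous dose is condensed into a biologically effective equivalent
uniform dose (BEEUD): the uniform BED that yields the same voxel-wise
Poisson TCP as the region's actual dose distribution,

    BEEUD_r = −(1/α) · ln[ Σ_i (v_i/V_r) · exp(−α·BED_i) ].

With the quality indices supplying the region weights, the implant TCP is

    TCP = exp[−ρ·TV_Dref·( ((1−CI)/CI)·e^(−α·BEEUD1) + DHI·e^(−α·BEEUD2)
                           + (DNR−ODI)·e^(−α·BEEUD3) + ODI·e^(−α·BEEUD4) )],

which reproduces the voxel-wise TCP exactly under this BEEUD definition —
a property the test suite exercises as its cornerstone invariant.

Normal-tissue complication probability is modelled on the two normal-tissue
regions with tissue-specific adjustable parameters N0, k and a reference
volume V0.  The literal published form (``as_printed``) grows *above* 1 for
typical inputs because its dose exponents are positive; a ``sign_corrected``
variant with the outer coefficient and both dose exponents negated restores
a probability in (0, 1].  Both are exposed; out-of-range values warn, never
clamp.

All doses entering α or α/β arithmetic are in Gy; DVH tables arrive in cGy
and are converted by the evaluation pipeline (:func:`evaluate_plan`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .dvh import DifferentialDVH
from .indices import (
    QualityIndices,
    RegionPartition,
    ThresholdVolumes,
    partition_regions,
    quality_indices,
    threshold_volumes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CGY_PER_GY",
    "FractionationParams",
    "TCPParams",
    "NTCPParams",
    "NTCPResult",
    "EvaluationResult",
    "PlanParams",
    "bed",
    "bed_from_axis",
    "beeud_region",
    "tcp",
    "tcp_uniform",
    "ntcp",
    "voxelwise_tcp_oracle",
    "evaluate_plan",
    "load_parameter_file",
]

CGY_PER_GY = 100.0

DoseScope = Literal["per_fraction", "total"]
NTCPVariant = Literal["as_printed", "sign_corrected"]


@dataclass(frozen=True)
class FractionationParams:
    """LQ-model fractionation context.

    ``dose_scope`` states what the DVH dose axis means: ``per_fraction``
    (default) reads each dose as a single-fraction dose d with total course
    dose n·d; ``total`` reads it as the whole-course dose D with
    d = D / n_fractions.
    """

    alpha: float
    alpha_beta: float
    n_fractions: int = 1
    G: float = 1.0
    dose_scope: DoseScope = "per_fraction"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0 Gy⁻¹, got {self.alpha}")
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha/beta must be > 0 Gy, got {self.alpha_beta}")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be ≥ 1, got {self.n_fractions}")
        if not 0.0 <= self.G <= 1.0:
            raise ValueError(f"G must be in [0, 1], got {self.G}")
        if self.dose_scope not in ("per_fraction", "total"):
            raise ValueError(f"unknown dose_scope {self.dose_scope!r}")


class NTCPResult(NamedTuple):
    value: float
    warnings: tuple[str, ...]


@dataclass(frozen=True)
class TCPParams:
    """Everything the region-weighted TCP formula needs besides α."""

    rho: float
    TV_Dref: float
    qi: QualityIndices
    beeud: Sequence[Optional[float]]  # 4 entries, Gy; None for empty regions

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"clonogen density must be ≥ 0, got {self.rho}")
        if self.TV_Dref < 0:
            raise ValueError(f"TV_Dref must be ≥ 0, got {self.TV_Dref}")
        if len(self.beeud) != 4:
            raise ValueError("need 4 per-region BEEUD entries (None if empty)")


@dataclass(frozen=True)
class NTCPParams:
    N0: float
    k: float
    V0: float
    TV: float
    V_normal: float
    EI: float
    beeud_n: Sequence[Optional[float]]  # 2 entries, Gy; None for empty regions
    variant: NTCPVariant = "as_printed"

    def __post_init__(self) -> None:
        if self.N0 < 0:
            raise ValueError(f"N0 must be ≥ 0, got {self.N0}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.V0 <= 0:
            raise ValueError(f"V0 must be > 0, got {self.V0}")
        if len(self.beeud_n) != 2:
            raise ValueError("need 2 normal-tissue BEEUD entries (None if empty)")
        if self.variant not in ("as_printed", "sign_corrected"):
            raise ValueError(f"unknown NTCP variant {self.variant!r}")


@dataclass(frozen=True)
class EvaluationResult:
    """A full plan evaluation: TCP, per-organ NTCP, BEEUDs and indices."""

    tcp: float
    ntcp_per_organ: dict[str, float]
    beeud_report: dict[str, list[Optional[float]]]
    qi: dict[str, QualityIndices]
    warnings: tuple[str, ...]


# ---------------------------------------------------------------------------
# BED / BEEUD

def bed(
    total_dose: Optional[float],
    dose_per_fraction: Optional[float],
    fx: FractionationParams,
) -> float:
    """BED = D·(1 + G·d/(α/β)) in Gy.

    Either dose may be omitted and is derived via n_fractions; when both
    are given they must be consistent (D = n·d) to 1e-9 relative.
    """
    if total_dose is None and dose_per_fraction is None:
        raise ValueError("need total_dose and/or dose_per_fraction")
    if total_dose is None:
        total_dose = fx.n_fractions * dose_per_fraction  # type: ignore[operator]
    if dose_per_fraction is None:
        dose_per_fraction = total_dose / fx.n_fractions
    if total_dose < 0 or dose_per_fraction < 0:
        raise ValueError("doses must be ≥ 0")
    if abs(total_dose - fx.n_fractions * dose_per_fraction) > 1e-9 * max(
        total_dose, 1.0
    ):
        raise ValueError(
            f"inconsistent doses: D={total_dose} Gy but n·d="
            f"{fx.n_fractions * dose_per_fraction} Gy"
        )
    return total_dose * (1.0 + fx.G * dose_per_fraction / fx.alpha_beta)


def bed_from_axis(doses_gy: np.ndarray, fx: FractionationParams) -> np.ndarray:
    """Vectorized BED for a DVH dose axis, honouring ``dose_scope``."""
    d = np.asarray(doses_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be ≥ 0")
    if fx.dose_scope == "per_fraction":
        total = fx.n_fractions * d
        per_fx = d
    else:
        total = d
        per_fx = d / fx.n_fractions
    return total * (1.0 + fx.G * per_fx / fx.alpha_beta)


def beeud_region(
    subvolumes: Sequence[tuple[float, float]],
    fx: FractionationParams,
    alpha: float,
) -> float:
    """Biologically effective equivalent uniform dose of one region (Gy).

    ``subvolumes`` is a list of (dose Gy — interpreted per dose_scope,
    volume cm³) pairs with positive total volume.  Returns the uniform BED
    giving the same voxel-wise Poisson TCP:
    −(1/α)·ln[Σ (v_i/V_r)·exp(−α·BED_i)].  Lies between the region's
    minimum and maximum BED; cold subvolumes dominate.
    """
    if len(subvolumes) == 0:
        raise ValueError(
            "empty region: callers must treat empty regions as zero-weight "
            "terms, never compute their BEEUD"
        )
    doses = np.array([d for d, _ in subvolumes], dtype=float)
    vols = np.array([v for _, v in subvolumes], dtype=float)
    if np.any(vols < 0):
        raise ValueError("subvolumes must be ≥ 0")
    vtot = vols.sum()
    if vtot <= 0:
        raise ValueError("region must have positive total volume")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0 Gy⁻¹, got {alpha}")
    beds = bed_from_axis(doses, fx)
    log_mean_survival = logsumexp(-alpha * beds, b=vols / vtot)
    return float(-log_mean_survival / alpha)


# ---------------------------------------------------------------------------
# TCP

def tcp_uniform(rho: float, V: float, alpha: float, bed_t: float) -> float:
    """Poisson TCP for a uniformly irradiated target: exp[−ρV·e^(−α·BED)]."""
    if rho < 0 or V < 0 or bed_t < 0:
        raise ValueError("rho, V and BED must be ≥ 0")
    return float(math.exp(-rho * V * math.exp(-alpha * bed_t)))


def tcp(params: TCPParams, alpha: float) -> float:
    """Region-weighted implant TCP.

    Empty regions (weight 0) contribute nothing regardless of their
    (undefined) BEEUD.  Requires CI > 0 whenever the below-reference region
    holds volume, since its weight (1−CI)/CI would diverge.
    """
    qi = params.qi
    if qi.CI == 0.0:
        raise ValueError("no target coverage: CI = 0 with a non-empty cold region")
    weights = (
        (1.0 - qi.CI) / qi.CI,
        qi.DHI,
        qi.DNR - qi.ODI,
        qi.ODI,
    )
    if weights[2] < 0:
        raise ValueError(f"DNR < ODI is impossible for valid indices: {qi}")
    acc = 0.0
    for r, (w, b) in enumerate(zip(weights, params.beeud), start=1):
        if w == 0.0:
            continue
        if b is None:
            raise ValueError(f"region {r} has weight {w} but no BEEUD")
        acc += w * math.exp(-alpha * b)
    return float(math.exp(-params.rho * params.TV_Dref * acc))


def voxelwise_tcp_oracle(
    subvolume_doses: Sequence[tuple[float, float]],
    rho: float,
    fx: FractionationParams,
    alpha: float,
) -> float:
    """Direct Poisson TCP over (dose Gy, volume cm³) subvolumes.

    Bypasses regions, indices and BEEUD entirely:
    exp[−ρ·Σ v_i·exp(−α·BED_i)].  Serves as the independent ground truth
    the region-weighted :func:`tcp` must reproduce.
    """
    if rho < 0:
        raise ValueError("rho must be ≥ 0")
    if len(subvolume_doses) == 0:
        return 1.0
    doses = np.array([d for d, _ in subvolume_doses], dtype=float)
    vols = np.array([v for _, v in subvolume_doses], dtype=float)
    if np.any(vols < 0):
        raise ValueError("volumes must be ≥ 0")
    beds = bed_from_axis(doses, fx)
    return float(np.exp(-rho * np.sum(vols * np.exp(-alpha * beds))))


# ---------------------------------------------------------------------------
# NTCP

def ntcp(params: NTCPParams, alpha: float) -> NTCPResult:
    """Two-region normal-tissue complication probability, NTCP = NTCPF^k.

    ``as_printed`` evaluates the published form literally,
    NTCPF = exp[N0^(−1/k)·(TV/V0)·((V_n/TV − EI)·e^{(α/k)·BEEUDn1}
    + (EI/V0)·e^{(α/k)·BEEUDn2})]; its value exceeds 1 whenever the
    argument is positive, in which case a warning is attached.
    ``sign_corrected`` negates the outer coefficient and both dose
    exponents, giving a proper probability in (0, 1] that rises to 1 as
    the region BEEUDs grow.
    """
    warnings: list[str] = []
    sign = 1.0 if params.variant == "as_printed" else -1.0
    if params.N0 == 0.0:
        if params.variant == "as_printed":
            raise ValueError("N0 = 0: N0^(-1/k) undefined for the as-printed form")
        coef = math.inf
    else:
        coef = params.N0 ** (-1.0 / params.k)
    # region weights: (V_normal/TV − EI) is region-n1 volume over TV;
    # the extra 1/V0 on the EI term is kept as published
    w1 = params.V_normal / params.TV - params.EI if params.TV > 0 else 0.0
    w2 = params.EI / params.V0
    acc = 0.0
    for r, (w, b) in enumerate(zip((w1, w2), params.beeud_n), start=1):
        if w == 0.0:
            continue
        if b is None:
            raise ValueError(f"normal region {r} has weight {w} but no BEEUD")
        with np.errstate(over="ignore"):
            acc += w * float(np.exp(sign * (alpha / params.k) * b))
    if acc == 0.0:
        value = 1.0  # exp(0)^k, the literal zero-volume behaviour
    else:
        arg = sign * params.k * coef * (params.TV / params.V0) * acc
        with np.errstate(over="ignore"):
            value = float(np.exp(arg))
    if not 0.0 <= value <= 1.0:
        msg = (
            f"{params.variant} NTCP = {value:.6g} lies outside [0, 1]; "
            "the published form is not a bounded probability"
        )
        warnings.append(msg)
        logger.warning(msg)
    return NTCPResult(value=float(value), warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# whole-plan evaluation

@dataclass(frozen=True)
class PlanParams:
    """Flat parameter set for a full evaluation (the prompt values).

    Doses Dref in cGy (the DVH unit); α in Gy⁻¹, α/β in Gy; ρ in cm⁻³;
    N0, k dimensionless; V0 in cm³.
    """

    Dref: float
    alpha: float
    alpha_beta: float
    rho: float
    n_fractions: int = 1
    G: float = 1.0
    dose_scope: DoseScope = "per_fraction"
    N0: float = 1.0
    k: float = 1.0
    V0: float = 100.0
    ntcp_variant: NTCPVariant = "as_printed"

    def fractionation(self) -> FractionationParams:
        return FractionationParams(
            alpha=self.alpha,
            alpha_beta=self.alpha_beta,
            n_fractions=self.n_fractions,
            G=self.G,
            dose_scope=self.dose_scope,
        )


def _region_beeuds(
    part: RegionPartition, fx: FractionationParams, alpha: float
) -> list[Optional[float]]:
    out: list[Optional[float]] = []
    for reg in part.regions:
        if not reg or sum(v for _, v in reg) <= 0:
            out.append(None)
        else:
            gy = [(d / CGY_PER_GY, v) for d, v in reg]
            out.append(beeud_region(gy, fx, alpha))
    return out


def evaluate_plan(
    target: DifferentialDVH,
    normals: dict[str, DifferentialDVH],
    params: PlanParams,
) -> EvaluationResult:
    """Run the full DVH → regions → BEEUD → TCP/NTCP pipeline.

    Each organ-at-risk in ``normals`` is evaluated independently (its own
    EI, region BEEUDs and NTCP); the target indices CI/DHI/ODI/DNR are
    organ-independent.
    """
    if not normals:
        raise ValueError("need at least one organ-at-risk DVH")
    fx = params.fractionation()
    warnings: list[str] = []

    target_part = partition_regions(target, params.Dref, "target")
    target_beeud = _region_beeuds(target_part, fx, params.alpha)
    logger.info(
        "target %s: total %.3f cm³, region volumes %s",
        target.structure_label,
        target_part.total_volume(),
        [f"{v:.3f}" for v in target_part.region_volumes()],
    )

    qi_map: dict[str, QualityIndices] = {}
    ntcp_map: dict[str, float] = {}
    beeud_report: dict[str, list[Optional[float]]] = {"target": target_beeud}
    tcp_value: Optional[float] = None

    for organ, ndvh in normals.items():
        tv = threshold_volumes(target, ndvh, params.Dref)
        qi = quality_indices(tv)
        qi_map[organ] = qi
        if tcp_value is None:
            tcp_value = tcp(
                TCPParams(
                    rho=params.rho, TV_Dref=tv.TV_Dref, qi=qi, beeud=target_beeud
                ),
                params.alpha,
            )
        npart = partition_regions(ndvh, params.Dref, "normal")
        nbeeud = _region_beeuds(npart, fx, params.alpha)
        beeud_report[organ] = nbeeud
        logger.info(
            "organ %s: total %.3f cm³, region volumes %s",
            organ,
            npart.total_volume(),
            [f"{v:.3f}" for v in npart.region_volumes()],
        )
        res = ntcp(
            NTCPParams(
                N0=params.N0,
                k=params.k,
                V0=params.V0,
                TV=tv.TV,
                V_normal=tv.V_normal,
                EI=qi.EI,
                beeud_n=nbeeud,
                variant=params.ntcp_variant,
            ),
            params.alpha,
        )
        ntcp_map[organ] = res.value
        warnings.extend(f"{organ}: {w}" for w in res.warnings)

    assert tcp_value is not None
    return EvaluationResult(
        tcp=tcp_value,
        ntcp_per_organ=ntcp_map,
        beeud_report=beeud_report,
        qi=qi_map,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# parameter files

_FLOAT_KEYS = {
    "Dref", "alpha", "alpha_beta", "rho", "G", "N0", "k", "V0",
}
_INT_KEYS = {"n_fractions"}
_STR_KEYS = {"dose_scope", "ntcp_variant"}


def load_parameter_file(path: str) -> PlanParams:
    """Read a flat ``key = value`` parameter file into :class:`PlanParams`.

    Recognized keys: Dref (cGy), alpha (Gy⁻¹), alpha_beta (Gy), rho (cm⁻³),
    n_fractions, G, N0, k, V0 (cm³), dose_scope, ntcp_variant.  Lines
    starting with ``#`` and blank lines are ignored.
    """
    values: dict[str, object] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}")
                key, val = parts
            key = key.strip()
            val = val.strip()
            if key in _FLOAT_KEYS:
                values[key] = float(val)
            elif key in _INT_KEYS:
                values[key] = int(val)
            elif key in _STR_KEYS:
                values[key] = val
            else:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
    missing = {"Dref", "alpha", "alpha_beta", "rho"} - values.keys()
    if missing:
        raise ValueError(f"{path}: missing required parameters {sorted(missing)}")
    return PlanParams(**values)  # type: ignore[arg-type]
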