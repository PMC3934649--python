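"""Differential and cumulative dose-volume histograms (DVHs).

A differential DVH tabulates, for each dose bin, the structure volume per
unit dose (cm³/cGy) deposited at that dose.  Treatment planning systems for
interstitial brachytherapy export these as plain two-column tables (dose in
cGy against volume density); this module reads that dialect, validates it,
converts it to the cumulative form, and answers "how much volume receives at
least dose D" queries — the primitive every implant quality index is built
on.

Conventions
-----------
* Tabulated doses are bin *centers*; the bin volume is density × bin width.
* Doses are kept in cGy throughout this module (the export format's unit);
  conversion to Gy happens only where linear-quadratic arithmetic needs it.
* Threshold-volume queries interpolate linearly on the cumulative curve,
  which is exact at grid nodes and equivalent to assuming dose is uniformly
  distributed within each bin.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DVHValidationError",
    "DifferentialDVH",
    "CumulativeDVH",
    "read_differential_dvh",
    "total_volume",
    "differential_to_cumulative",
    "volume_at_or_above",
    "write_differential_tsv",
    "write_cumulative_tsv",
]

#: relative tolerance for the uniform-bin-spacing check
_SPACING_RTOL = 1e-9


class DVHValidationError(ValueError):
    """Raised when a DVH table violates the format's structural invariants."""


@dataclass(frozen=True)
class DifferentialDVH:
    """One structure's dose-binned volume-density curve.

    Parameters
    ----------
    structure_label
        Name of the delineated structure (e.g. ``"CTV"``, ``"rectum"``).
    dose_bin_centers
        Strictly increasing, uniformly spaced bin-center doses in cGy.
    volume_density
        Volume per unit dose in cm³/cGy, one value per bin, all ≥ 0.
    bin_width
        Dose width of each bin in cGy; must equal the grid spacing.
    """

    structure_label: str
    dose_bin_centers: np.ndarray
    volume_density: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.dose_bin_centers, dtype=float)
        density = np.asarray(self.volume_density, dtype=float)
        object.__setattr__(self, "dose_bin_centers", centers)
        object.__setattr__(self, "volume_density", density)
        object.__setattr__(self, "bin_width", float(self.bin_width))

        if centers.ndim != 1 or density.ndim != 1:
            raise DVHValidationError("dose and density must be 1-D sequences")
        if centers.size < 1:
            raise DVHValidationError("a DVH needs at least one bin")
        if centers.size != density.size:
            raise DVHValidationError(
                f"{centers.size} doses but {density.size} densities"
            )
        if self.bin_width <= 0:
            raise DVHValidationError(f"bin_width must be > 0, got {self.bin_width}")
        if np.any(density < 0):
            bad = int(np.flatnonzero(density < 0)[0])
            raise DVHValidationError(
                f"negative volume density {density[bad]} at row {bad + 1} "
                f"(dose {centers[bad]} cGy)"
            )
        if centers.size > 1:
            steps = np.diff(centers)
            if np.any(steps <= 0):
                bad = int(np.flatnonzero(steps <= 0)[0])
                raise DVHValidationError(
                    "dose column must be strictly increasing; rows "
                    f"{bad + 1} and {bad + 2} have doses {centers[bad]} and "
                    f"{centers[bad + 1]} cGy"
                )
            ref = steps[0]
            off = np.flatnonzero(np.abs(steps - ref) > _SPACING_RTOL * abs(ref))
            if off.size:
                bad = int(off[0])
                raise DVHValidationError(
                    "non-uniform dose spacing: rows "
                    f"{bad + 1}–{bad + 2} step {steps[bad]} cGy vs expected "
                    f"{ref} cGy"
                )
            if abs(self.bin_width - ref) > _SPACING_RTOL * abs(ref):
                raise DVHValidationError(
                    f"bin_width {self.bin_width} does not match grid spacing {ref}"
                )
        if centers[0] - self.bin_width / 2.0 < -_SPACING_RTOL * self.bin_width:
            raise DVHValidationError(
                f"first bin (center {centers[0]} cGy, width {self.bin_width} cGy) "
                "extends below zero dose"
            )

    @property
    def n_bins(self) -> int:
        return int(self.dose_bin_centers.size)

    @property
    def bin_lower_edges(self) -> np.ndarray:
        return self.dose_bin_centers - self.bin_width / 2.0

    @property
    def bin_upper_edges(self) -> np.ndarray:
        return self.dose_bin_centers + self.bin_width / 2.0

    @property
    def bin_volumes(self) -> np.ndarray:
        """Absolute volume per bin in cm³ (density × bin width)."""
        return self.volume_density * self.bin_width


@dataclass(frozen=True)
class CumulativeDVH:
    """Volume receiving at least each grid dose.

    ``dose_grid`` holds the lower edges of the differential bins plus a
    terminal node at the last bin's upper edge (where the curve reaches 0),
    so that linear interpolation is defined across every bin.
    """

    structure_label: str
    dose_grid: np.ndarray
    volume_at_or_above: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.dose_grid, dtype=float)
        vols = np.asarray(self.volume_at_or_above, dtype=float)
        object.__setattr__(self, "dose_grid", grid)
        object.__setattr__(self, "volume_at_or_above", vols)
        if grid.size != vols.size or grid.size < 1:
            raise DVHValidationError("cumulative grid and volumes must match, ≥ 1")
        if np.any(np.diff(vols) > 0):
            raise DVHValidationError("cumulative volume must be non-increasing")
        if vols[-1] < 0:
            raise DVHValidationError("cumulative volumes must be ≥ 0")

    @property
    def total_volume(self) -> float:
        return float(self.volume_at_or_above[0])


# ---------------------------------------------------------------------------
# parsing

def _split_row(line: str) -> list[str]:
    # delimiter auto-detection order: tab, comma, whitespace
    if "\t" in line:
        parts = line.split("\t")
    elif "," in line:
        parts = line.split(",")
    else:
        parts = line.split()
    return [p.strip() for p in parts if p.strip()]


def read_differential_dvh(
    source: Union[str, IO[str]],
    structure_label: str,
    *,
    bin_width: float | None = None,
) -> DifferentialDVH:
    """Read a two-column differential DVH table.

    ``source`` is a file path or an open text stream whose body is
    ``dose  volume-per-dose`` rows (tab-, comma- or whitespace-delimited,
    auto-detected).  Leading header lines that do not parse as numbers are
    skipped.  The bin width is inferred from consecutive doses; a single-row
    table needs the explicit ``bin_width`` override because spacing cannot
    be inferred.
    """
    if hasattr(source, "read"):
        stream: IO[str] = source  # type: ignore[assignment]
        name = getattr(source, "name", "<stream>")
    else:
        stream = open(source, "r", encoding="utf-8")
        name = str(source)
    try:
        doses: list[float] = []
        densities: list[float] = []
        in_body = False
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = _split_row(line)
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if in_body:
                    raise DVHValidationError(
                        f"{name}: non-numeric row {lineno} after data began: {line!r}"
                    )
                logger.info("%s: skipping header line %d: %r", name, lineno, line)
                continue
            if len(values) < 2:
                if in_body:
                    raise DVHValidationError(
                        f"{name}: row {lineno} has {len(values)} column(s), need 2"
                    )
                logger.info("%s: skipping header line %d: %r", name, lineno, line)
                continue
            in_body = True
            doses.append(values[0])
            densities.append(values[1])
    finally:
        if stream is not source:
            stream.close()

    if len(doses) < 1:
        raise DVHValidationError(f"{name}: no numeric rows found")
    if len(doses) == 1:
        if bin_width is None:
            raise DVHValidationError(
                f"{name}: single-row table; bin width cannot be inferred — "
                "pass an explicit bin_width"
            )
        width = float(bin_width)
    else:
        width = float(doses[1] - doses[0]) if bin_width is None else float(bin_width)

    return DifferentialDVH(
        structure_label=structure_label,
        dose_bin_centers=np.array(doses, dtype=float),
        volume_density=np.array(densities, dtype=float),
        bin_width=width,
    )


# ---------------------------------------------------------------------------
# transforms and queries

def total_volume(dvh: DifferentialDVH) -> float:
    """Total structure volume in cm³: bin_width × Σ volume_density."""
    if dvh.volume_density.size == 0:
        return 0.0
    # sequential (cumsum) summation so this equals the cumulative curve's
    # first entry bit-for-bit
    return float(dvh.bin_width * np.cumsum(dvh.volume_density[::-1])[-1])


def differential_to_cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Convert to the cumulative (volume-at-or-above) form.

    Grid point j (a bin lower edge) carries the summed volume of bins j..n;
    a terminal node at the last upper edge carries 0.
    """
    suffix = np.cumsum(dvh.volume_density[::-1])[::-1] * dvh.bin_width
    grid = np.append(dvh.bin_lower_edges, dvh.bin_upper_edges[-1])
    vols = np.append(suffix, 0.0)
    return CumulativeDVH(
        structure_label=dvh.structure_label,
        dose_grid=grid,
        volume_at_or_above=vols,
    )


def volume_at_or_above(cdvh: CumulativeDVH, threshold: float) -> float:
    """Volume (cm³) receiving at least ``threshold`` cGy.

    Linear interpolation between grid points; a threshold below the first
    grid dose returns the total volume, one above the last returns 0.
    """
    if threshold < 0:
        raise ValueError(f"dose threshold must be ≥ 0, got {threshold}")
    return float(
        np.interp(
            threshold,
            cdvh.dose_grid,
            cdvh.volume_at_or_above,
            left=cdvh.volume_at_or_above[0],
            right=cdvh.volume_at_or_above[-1],
        )
    )


# ---------------------------------------------------------------------------
# writers

def write_differential_tsv(dvh: DifferentialDVH, path: str) -> None:
    """Write the reader's own dialect: header + tab-separated dose/density."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Dose (cGy)\tVolume/dose (cm3/cGy)\n")
        # repr round-trips doubles exactly, keeping the uniform-spacing
        # validation happy on re-read
        for d, v in zip(dvh.dose_bin_centers, dvh.volume_density):
            fh.write(f"{float(d)!r}\t{float(v)!r}\n")


def write_cumulative_tsv(cdvh: CumulativeDVH, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Dose (cGy)\tVolume >= dose (cm3)\n")
        for d, v in zip(cdvh.dose_grid, cdvh.volume_at_or_above):
            fh.write(f"{d:.6f}\t{v:.9f}\n")
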