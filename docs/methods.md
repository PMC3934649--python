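# Methods

## Scope and data model

`brachyeval` evaluates interstitial brachytherapy plans purely from
differential DVHs: one two-column table (dose, volume-per-dose) per
structure, the format planning systems export after conversion to a
spreadsheet-readable form. It does not read native planning-system binaries
or DICOM-RT, and it performs no dose calculation or optimization — the DVH
is the interface.

Tabulated doses are treated as **bin centers** with uniform spacing; the
bin volume is density × bin width. The alternative left-edge reading would
shift every threshold volume by at most half a bin; the center convention
was chosen because the density column (cm³/cGy) implies a symmetric binning
of a continuous dose distribution. A single-row table cannot reveal its bin
width, so the reader demands an explicit override there. Doses stay in cGy
(the export unit) everywhere except inside the radiobiology layer, which
converts to Gy before any α or α/β arithmetic.

Cumulative curves store volume-at-or-above on the bin lower edges plus a
terminal node (last upper edge, volume 0). Threshold-volume queries
interpolate linearly on that curve. This is exactly equivalent to assuming
dose is uniformly distributed *within* each bin, which is also how bins
straddling a region boundary are split (pro-rata by dose-width overlap,
fragment dose = sub-interval midpoint). The two choices being consistent is
what makes region totals equal threshold-volume differences to rounding —
an invariant the suite checks on hundreds of random DVHs.

Region bands are closed below and open above ("a dose equal to or greater
than" the band's lower limit): target r1 < Dref ≤ r2 < 1.5·Dref ≤ r3 <
2·Dref ≤ r4; normal tissue n1 < Dref ≤ n2. DHI is computed as 1 − DNR so
the DHI + DNR = 1 identity holds exactly in floating point. EI is
normalized by the *target* volume, as the index is defined, so it can
exceed 1 for a large organ-at-risk. Multiple organs-at-risk are evaluated
independently; no composite normal-tissue DVH is formed.

## BEEUD definition

The region BEEUD is defined as the uniform BED giving the same voxel-wise
Poisson TCP as the region's actual dose distribution:
BEEUD_r = −(1/α)·ln[Σ (v_i/V_r)·e^(−α·BED_i)] (computed via a weighted
log-sum-exp for numerical stability). This is the unique definition under
which the region-weighted TCP formula reproduces the direct voxel-wise
Poisson TCP identically — each quality-index weight times TV_Dref equals a
region volume, and V_r·e^(−α·BEEUD_r) recovers the region's summed
survival. The suite verifies this equivalence to 1e-9 relative over 500
random DVH/parameter draws; it is the package's cornerstone correctness
argument, since it ties the convenient index-based formula to first
principles. By Jensen's inequality BEEUD never exceeds the volume-weighted
mean BED: cold spots dominate.

## Dose scope and fractionation

Whether an exported DVH axis is single-fraction or whole-course dose is
plan-system dependent, so it is an explicit flag. `per_fraction` (default)
reads axis value d as the fraction dose, total D = n·d, BED =
n·d·(1 + G·d/(α/β)); `total` reads the axis as D with d = D/n. G defaults
to 1 (full sublethal-damage repair between fractions) and is clamped to
[0, 1]; G = 0 reduces BED to physical dose.

## NTCP variants

The two-region NTCP form is implemented twice. `as_printed` evaluates the
published expression literally — positive dose exponents and outer
coefficient, including the extra 1/V0 on the EI term — and therefore grows
above 1 whenever its argument is positive; any value outside [0, 1] is
returned with an attached warning (and logged), never silently clamped.
`sign_corrected` negates the outer coefficient and both dose exponents,
yielding a proper probability in (0, 1] that increases monotonically with
the normal-tissue BEEUDs and saturates at 1. The dimensionally ambiguous
volume ratio in the first term is read as V_normal/TV, so that term's
weight times TV is exactly the volume of the normal-tissue region below the
reference dose, mirroring the TCP construction. `as_printed` is the default
for fidelity; analyses that need a bounded probability (e.g. the synthetic
cohort link) use `sign_corrected`. N0 = 0 is rejected for `as_printed`
(N0^(−1/k) undefined); the sign-corrected limit 0 is allowed.

Empty regions never have a BEEUD computed; their index weight is exactly 0
and they contribute nothing. Probabilities are stored unrounded; display
formatting is 4 decimals.

## Outcome scoring and correlation

CTCAE grades 1–5 map to scores 0.00, 0.25, 0.50, 0.75, 1.00 — exactly
(grade − 1)/4. Because the coding is ordinal, association with TCP/NTCP
estimates uses the Spearman rank correlation with mid-ranks for ties
(scipy's implementation; the tests check it against an independent
rank-then-Pearson computation). Fewer than 3 pairs or a constant column
make the coefficient undefined; the report flags this rather than returning
zero. NTCP pairs with toxicity scores, TCP with tumour-control scores.

## Synthetic data

The generator exists so every pipeline stage is testable without clinical
data, and its outputs mimic the structural features the evaluator assumes —
not clinical dosimetry.

* **Ideal implant**: a flat DVH spanning [1.05, 1.45]·Dref, so every bin
  *edge* lies inside the homogeneity band and the indices are exactly
  (CI, EI, DHI, ODI, DNR) = (1, 0, 1, 0, 0). The companion cold organ DVH
  spans [0.1, 0.8]·Dref with a linearly falling density.
* **Implant simulator**: parallel needles as 2-D points on a voxel grid
  (default 0.1 cm voxels, 1 cm slice thickness), dose = Σ strength/r² with
  the singularity capped at the half-voxel radius, per-needle strength
  jittered ±10 % by the seed. The target is the needles' convex hull padded
  by a margin; the rest of the grid is normal tissue. Bin width is Dref/20,
  placing Dref, 1.5·Dref and 2·Dref exactly on bin edges so DVH threshold
  volumes agree with direct voxel counting. This is deliberately *not*
  clinical source dosimetry (no radial dose function, no anisotropy, no
  TG-43 formalism): it reproduces the four-region high-gradient structure
  — extreme hot spots at needles, a prescribed shell, a cold rim — which is
  all the evaluator consumes. Passing tests therefore validate the
  evaluation mathematics, not any particular source model.
* **Outcome cohorts**: each synthetic patient gets a randomly scaled smooth
  (gamma-shaped) target and rectum DVH, is evaluated through the full
  pipeline with cervix-flavoured defaults (α = 0.3 Gy⁻¹, α/β = 10 Gy,
  ρ = 10⁶ cm⁻³, 4 fractions, sign-corrected NTCP with N0 = 50, k = 1.5,
  V0 = 50 cm³), and a CTCAE grade is drawn from a monotone NTCP→grade link.
  The noiseless `"rank"` link assigns grades by NTCP rank — strictly
  monotone and tie-free for cohorts of ≤ 5, where the Spearman coefficient
  is exactly +1; larger noiseless cohorts necessarily tie grades, which is
  a property of mapping a continuum onto 5 grades, not of the estimator.
  Everything is driven by `numpy.random.Generator` seeds;
  fixed seed ⇒ byte-identical fixtures.

What the synthetic data does **not** emulate: inter-fraction anatomy
changes, delineation uncertainty, true clonogen-density maps, source
anisotropy, and clinically calibrated N0/k/V0 values. Conclusions about
real plans require the user's own parameter choices.

## Numerical choices and degenerate inputs

* Uniform-spacing validation at 1e-9 relative; violations name the rows.
* DVH text written by the package uses `repr` floats, so files round-trip
  bit-exactly through the parser.
* Total volume is accumulated with the same sequential summation as the
  cumulative curve, making `total_volume == volume_at_or_above(·, 0)` an
  exact identity.
* log-sum-exp inside BEEUD avoids underflow for strongly hot regions; TCP
  values that underflow to 0 do so consistently in both the region formula
  and the voxel oracle.
* CI = 0 with a non-empty cold region, empty targets, zero TV_Dref (DHI,
  ODI, DNR undefined), k = 0, and coincident simulator needles are all
  rejected with explicit messages rather than producing NaNs.
* Problem sizes in the test suite (hundreds of random DVHs of ≤ 40 bins, a
  6400-voxel simulator grid, 5–10-patient cohorts) were chosen as the
  smallest scales at which every invariant is non-trivially exercised.

## Command-line interface

The CLI is a thin batch layer over the library: `indices`, `evaluate`,
`simulate`, `score`. The interactive prompt style of the original MATLAB
workflow is replaced by flags and a flat `key = value` parameter file for
scriptability; `evaluate` also accepts the full prompt-value set directly
(`--ci --dhi --odi --dnr --tv-dref --beeud …`), bypassing DVH input
entirely and matching the DVH route bit-for-bit when fed the same values.
Outputs are never overwritten without `--force`; each pipeline stage logs
its input/output volumes at `-v` so conservation failures are diagnosable.
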