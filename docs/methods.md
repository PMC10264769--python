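# Methods notes

This note records the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices made where the standard methods leave the
algorithm open.

## Anatomy-derived indices

**Hydraulically weighted diameter.** `D_h = (Σ D⁴ / N)^{1/4}` is the L4
power mean of equivalent circular lumen diameters, so it always equals
or exceeds the arithmetic mean and is dominated by the widest vessels,
mirroring their share of laminar flow.  Elliptical lumina are reduced to
an equivalent circular diameter area-preservingly, `d = √(d_long ·
d_short)`.

**Theoretical conductivity.** `K_th = (π ρ / 128 η) · VF · D_h⁴` with
VF converted to m⁻² and D_h to m internally.  Defaults are water at
20 °C: ρ = 998.2 kg m⁻³ and η = 1.002 × 10⁻⁹ MPa·s (equivalently
1.002 × 10⁻³ Pa·s; the MPa·s unit keeps K_th in kg m⁻¹ MPa⁻¹ s⁻¹).
Both constants are overridable through `PhysicalConstants`.  When D_h
and VF come from the same vessel set, this formula is algebraically
identical to summing Hagen–Poiseuille conductances vessel by vessel;
the test suite asserts that identity to 1e-9 relative.

**Pit traits.** Shape ratios are computed per pit and then averaged
(mean of ratios).  The alternative, the ratio of mean diameters, is
exposed via `ratio_mode="mean_diameter"` since published datasets are
often ambiguous about which was used; the two differ only at second
order in the diameter spread.  Pit density pools counts over walls
(Σn / Σarea), weighting by observed wall area rather than averaging
per-wall densities, so sparsely sampled walls do not dominate.  The
wall-coverage fraction `D_p · A_pit` quantifies proximity to the
geometric packing limit, defined here as full coverage (`= 1`); it is a
descriptive index, not a biophysical bound on achievable packing (discs
cannot tile a plane, so real maxima are below 1).

**Stomatal counting.** Densities use the standard unbiased counting
rule: objects touching (within `border_tol`) the top or left frame edge
are included, those touching the bottom or right edge are excluded, and
corner cases resolve in favor of inclusion.  Coordinates follow image
convention (origin top-left, y downward).

## Minimum diffusive conductance

`g_min = WL · P_atm / VPD`.  The water-loss slope is fitted by OLS on
the mass-time series; the default window is the full series (≈10
weighings), matching how bench-drying data are usually reduced for
astomatous or promptly-closing organs.  An `auto` mode scans all
contiguous windows of ≥5 points and keeps the one maximizing r²
(ties to longer, then later windows) for samples with an initial fast
phase from incomplete stomatal closure.  VPD is computed per weighing
from T and RH via the Buck equation and averaged over the fit window;
weighing-resolution aggregation matters when room conditions drift.
The projected area is single-sided and is not doubled.  The molar mass
of water is fixed at 18.015 g mol⁻¹.  Area- and mass-normalized
conductances satisfy `g_min_area · area = g_min_mass · dry_mass`
exactly by construction.

## Pressure–volume analysis

All quantities are on a dry-mass basis, because a wilted flower's
surface area cannot be measured reliably.

- **Saturated mass** defaults to the maximum observed mass.  The
  optional plateau correction fits the initial linear region of mass vs
  Ψ (dropping up to 3 leading points when that improves linearity) and
  extrapolates to Ψ = 0; it both corrects oversaturation plateaus and
  mild undersaturation of the first weighing.
- **Breakpoint.** The turgor loss point is the split of the series (≥3
  points per segment) that maximizes r² of the post-segment line of
  −1/Ψ against cumulative water deficit, ties resolved toward the more
  hydrated split.  The search is exhaustive; a brute-force oracle test
  pins this behavior so future optimizations cannot drift.  A curve
  whose whole series is already linear (r² ≥ 0.9995) is treated as
  purely osmotic: breakpoint flagged at the first point, no turgor
  phase.
- **Parameters.** Ψ_sft = −1/intercept of the post-TLP line at zero
  deficit; Ψ_tlp is the fitted line evaluated at the breakpoint
  deficit, which guarantees Ψ_tlp ≤ Ψ_sft whenever the fitted slope is
  admissible.  C_T is the slope of water content (mol per kg dry mass)
  against Ψ over the **pre**-TLP segment — capacitance at full turgor —
  because that is the regime in which capacitance buffers diurnal water
  potential fluctuation; the post-TLP slope is reported as a
  diagnostic, and an apoplastic-fraction and elastic-modulus estimate
  are exposed in `diagnostics` without being headline outputs.

Known limitation: maximizing post-segment r² can, at high noise, favor
a short driest-points segment and inflate the extrapolated Ψ_sft error;
the recovery grid (below) shows the median error remains well inside
0.05 MPa at 0.02 MPa noise, but individual fits in the tail can be off
by ~0.2 MPa.  Inspect `r2_post` and `tlp_index` on real curves.

## Phylogenetic independent contrasts

Felsenstein's pruning recursion: contrast `(x_i − x_j)/√(v_i + v_j)`
at each internal node, ancestral value the variance-weighted mean, and
branch-length inflation `v_i·v_j/(v_i + v_j)`.  Polytomies are resolved
arbitrarily with zero-length branches (warned), keeping the contrast
count at n − 1.  Contrast association uses regression through the
origin — the only choice invariant to the arbitrary sign of each
contrast — with the slope t-test on (#contrasts − 1) degrees of
freedom, which makes the test exactly calibrated under Brownian motion
(verified empirically: type-I error 0.049–0.061 at nominal 0.05 across
seeds, 1000 replicates).  A with-intercept mode exists for sensitivity
analysis only.  Correctness is established against an independent
matrix-GLS implementation (subtree covariance matrices inverted
directly) on a panel of trees up to 6 tips, to 1e-10.

## Comparative statistics

- Paired t-tests pair by species (flower − leaf), two-sided.  The
  degenerate all-zero-difference case returns t = 0, p = 1; constant
  nonzero differences raise, since t is genuinely undefined there.
- ANOVA + LSD: pairwise t-tests on the pooled within-group mean square
  (N − k df), run only when the omnibus test is significant (protected
  LSD — the variant that letter displays in trait tables almost always
  reflect); an unprotected switch exists.  Letters come from the
  insert-and-absorb compact-letter-display algorithm, ordered by
  descending group mean.
- SMA: slope sign(r)·sd_y/sd_x, line through the bivariate mean,
  p-value from the Pearson correlation test.  Identities |slope| =
  sd_y/sd_x, reciprocity under x↔y, and SMA = OLS/|r| are tested on
  random data.
- PCA is an eigendecomposition of the correlation matrix (centered and
  scaled data) by default; a covariance-mode is available via
  `scale=False`.  Rows with missing values in the selected traits are
  dropped and logged (relevant for astomatous petals, which have no
  stomatal traits).  Signs are fixed so each component's dominant trait
  loads positively.  All components are retained, so variance fractions
  sum to 1 and retaining all scores reconstructs the standardized data
  exactly.
- Trait-space occupancy is intersection-over-union of the two organs'
  convex hulls in PC1–PC2; collinear (zero-area) groups are flagged.

Missing values use pairwise-complete deletion for bivariate statistics
and complete-case deletion for PCA.  No multiple-testing correction is
applied across the many trait-pair regressions; the tables report raw
two-sided p-values at α = 0.05.

## Synthetic study generator

The generator emulates a 10-species, two-organ (flower/leaf) study with
a 23-trait panel (per-organ thickness occupies a single column, so the
flower and leaf thickness of a 24-symbol panel appear as one trait).

- **Tree**: pure-birth (Yule) process, ultrametric, strictly positive
  branch lengths, tips `sp01..spNN`.
- **Traits**: log-scale Brownian motion on the tree (depth-normalized;
  default tip sd 0.25), shared between organs, with cross-trait
  correlations overlaid through a Cholesky factor of a user-specified
  correlation matrix; organ identity contributes a fixed log offset
  (the flower/leaf trait centers) plus an independent organ-specific
  deviation (sd 0.12) and measurement noise (sd 0.05).  Positive traits
  are lognormal; water potentials are negated lognormal magnitudes.
  Two flower rows lose their stomatal traits to emulate astomatous
  petals.  Trait centers are illustrative magnitudes for subtropical
  angiosperms (e.g. flower g_min ≈ 3× leaf, flower C_T and SWC several
  times leaf values, slightly smaller flower pits at higher density) —
  they set the study conditions and are not fitted to any dataset.
- **Drying curves**: linear mass decline at `WL = g·area·VPD/P_atm`,
  10 weighings at 10-min intervals, 10⁻⁴ g Gaussian weighing noise,
  constant 25 °C / 50% RH.
- **PV curves**: osmotic component Ψ_s = Ψ_sft/R_s (van't Hoff
  dilution); turgor declines from −Ψ_sft at saturation to zero at
  R_tlp = 1 + Ψ_sft/ε with shape exponent k (default linear, k = 1);
  default ε = 5·|Ψ_sft| puts R_tlp at 0.8.  12 points sampled evenly in
  symplastic water content from 0.99 down past the TLP; 0.02 MPa noise
  on Ψ.  The apoplastic fraction (default 0.2) holds water that does
  not dilute the symplast.

What passing recovery tests therefore shows: the estimators are
consistent and approximately unbiased **under these generating
models** — linear drying, van't Hoff osmotics, no plate/boundary-layer
effects, no temperature drift, no rehydration artifacts.  Real curves
violate these in ways the generators do not emulate (oversaturation
plateaus are the one artifact explicitly modeled, via the plateau
correction), so recovery rates here bound performance from above.

## Problem sizes

Chosen so the whole suite and the acceptance script each run in a few
seconds to minutes on one core: PV recovery over a 4×4×3 grid of
(Ψ_sft, SWC, apoplastic fraction) with 3 replicates (144 fits); g_min
recovery over 500 seeded curves; contrast-test calibration with 1000
Brownian replicates on a 10-tip tree; the end-to-end organ-contrast
recovery over 20–50 full synthetic studies (each: 20 drying fits, 20 PV
fits, full statistics).  These sizes give Monte-Carlo standard errors
comfortably below the tolerances being asserted.

## Pipeline conventions

Reports serialize floats at 6 significant digits with sorted keys, so a
rerun with the same configuration and seed is byte-identical
(timestamps live only in `log.txt`).  Stage failures (e.g. contrasts
requested for a trait with missing species) are collected in a failure
manifest rather than aborting the run; a species mismatch between tree
and table is a hard error listing the offending names.  Significance is
two-sided at α = 0.05 throughout, configurable.
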