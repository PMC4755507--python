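# Methods

## The measurement and its model

A kinome peptide array carries ~1000 spotted kinase-substrate peptides;
incubation with a cell lysate and labeled ATP deposits signal on each
spot in proportion to the activity of the upstream kinase(s) that
phosphorylate that peptide. The experimental design profiled here is a
full factorial: two cell types (Treg, Teff) × four stimulation time
points (0, 5, 15, 60 min) × three technical replicates, one slide per
(cell type, time) condition carrying all three replicate sub-grids, so
24 observations per substrate.

After quantification and normalization, each substrate's log2 net
intensities are modeled by ordinary least squares with treatment-coded
categorical covariates:

    y_ijk = μ + τ_j + γ·1[cell = Treg] + ρ_k + ε,   ε ~ N(0, σ²)

with reference levels time 0, Teff and replicate 1. Time is categorical,
not linear in minutes: activity trajectories over 0–60 min are
non-monotone, so a linear trend term would be misspecified. The
technical replicate enters as a fixed categorical covariate; no
random-effects or GLS variance structure is fitted, because none is
identified by the assay and with n = 24 balanced observations OLS with a
fixed replicate effect is the transparent choice.

The cell-type coefficient γ is the quantity of interest: substrates are
ranked by its two-sided p-value. Per substrate we additionally test the
full model against a nested null by ANOVA; the default null drops only
the cell-type term (so for this single-degree contrast F = t² exactly —
asserted in the tests), and an intercept-only null is available via
`null_model="intercept"`.

### Multiple testing

Benjamini–Hochberg step-up q-values (q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (m/j)·p₍ⱼ₎, capped
at 1) are computed separately within each parameter family — cell type
(the coefficient p), time and replicate (the family's partial-F p, since
those families span several coefficients) — with m = number of retained
substrates. The nested-ANOVA p is Bonferroni-corrected with the same m.
Both procedures are implemented directly (they are part of the package's
contract, with hand-checked examples) and cross-checked against
statsmodels' `multipletests` in the test suite.

## Quantification pipeline

**Alignment.** A single rigid integer (dx, dy) offset for the whole
grid, found by maximizing the Pearson correlation between the image
values under the shifted spot disks and the expected Gaussian spot
profile over a square search window (default ±10 px). Ties break to the
smallest Euclidean offset, then row-major order; a maximum on the window
boundary raises a warning (the true offset may be out of range). No
per-spot deformation search: the sub-grids are printed rigidly.

**Spot statistics.** Raw = mean pixel value in the disk of the nominal
radius; background = *median* of an annulus at 1.5–2.5× the radius
(median resists bleed-over from neighbors); net = raw − background, and
log2(net) exists only for net > 0 — nonpositive nets become missing
values rather than being floored, which feeds the imputation rule
naturally.

**Quality control.** The spot is segmented above local background at
half its peak height; a spot is flagged `irregular_shape` when the
region's eccentricity exceeds 0.8 (a 3:1 ellipse has eccentricity 0.943)
or its area deviates more than 50% from the nominal segmented disk area,
and `displaced` when the segmented centroid lies more than half a radius
from the expected center. `saturated` (any disk pixel at the bit-depth
maximum) and `nonpositive_net` complete the flag set. The assay itself
states no numeric criteria for "irregular", so these thresholds are
configurable conventions (`IrregularityThresholds`). Control spots
(identical peptide printed on every slide) are compared across slides;
a slide whose control mean deviates from the across-slide median by
more than a strict tolerance (default 1.0 log2) is flagged.

## Normalization, imputation, exclusion

Order of operations: QC-drop → per-slide median centering → imputation/
exclusion. Centering uses only observed values (even-count medians are
the mean of the middle two), so imputed values can never influence a
slide median; the slide median spans all three replicate sub-grids
because they share a slide. Within each (substrate, cell type, time)
replicate triple, exactly one missing value is imputed with the mean of
the two present (this preserves the condition mean exactly — a tested
invariant); more than one missing excludes the substrate from the whole
analysis. The default scope (`exclusion_scope="condition"`) applies the
"more than one missing" count per condition triple, the strictest
reading consistent with allowing at most one imputed replicate per
model cell; `"global_count"` instead counts missing values across the
substrate's whole row. Both are implemented because the rule's original
scope is ambiguous.

## The synthetic generator

`SimulationDesign` defaults *are* the study conditions: 1024 substrates,
2 cell types × 4 time points × 3 technical replicates, and a planted
effect on a 10% minority of substrates with magnitude 1.0 log2 and
random sign. Values follow the additive model above with noise_sd 0.3;
baselines are N(10, 1) log2 counts, time offsets N(0, 0.3) and replicate
offsets N(0, 0.1) — the assay defines no variance structure, so these
are documented conventions chosen to look like a real scan (net spot
intensities in the hundreds-to-thousands of counts over a ~500-count
background). Missingness is MCAR at rate 0.09 per value: under the
condition-scope exclusion rule P(exclude) = 1 − (1 − p₂)⁸ with
p₂ = 3m²(1−m) + m³, which at m = 0.09 retains ≈ 851 of 1024 substrates —
the scale of a real run of this assay — and sits mid-range of the 4–12%
per-slide unreliable-spot rates such scans show.

Rendering exponentiates log2 values to linear scale and draws each spot
as an isotropic Gaussian-profile disk (σ = radius/2, truncated at 2×
radius) on a sloped background, with the *disk-mean* amplitude — the
statistic quantification recovers — as the input value (the peak is
scaled by the kernel's pixel disk-mean, whose continuous closed form
(2σ²/r²)(1 − e^(−r²/2σ²)) is verified against the pixel grid in tests).
Irregular spots are drawn independently with probability
`irregular_fraction` (default 0.08, mid-range of 4–12%) and rendered
either elongated (volume-preserving 3:1 anisotropic scaling) or
displaced by 0.75–1.0 radii — exactly the two failure modes the QC stage
tests. A planted rigid grid offset and per-spot truth are returned for
round-trip tests.

What the generator does **not** emulate: scanner PSF and radioactive
exposure physics, spatially correlated background beyond a linear
gradient, intensity-dependent variance, non-MCAR missingness, and
biological kinetics beyond additive time offsets. Passing tests
therefore demonstrate correctness of the pipeline's rules and
calibration of its inference under its own model assumptions — not
robustness to every artifact of real scans.

## Numerical and interface choices

- Pixel coordinates are 0-based (x, y) = (column, row); grid offsets are
  integers.
- Degenerate Welch t-tests are resolved explicitly: two zero-variance
  groups with equal means give (t = 0, p = 1); with unequal means the
  result is flagged degenerate (p = 0 with a warning).
- Rank-deficient designs raise an error naming the collinear covariate.
- `fit_linear_model` (statsmodels OLS, handles missing rows) and
  `fit_many` (vectorized normal equations over a complete matrix) are
  asserted equal to each other and to an independent normal-equations
  oracle at 1e-8.
- All randomness flows from a single seed; figures embed no timestamps,
  so every artifact is bit-reproducible.
- Problem sizes in the routine test battery: calibration uses 1000 null
  substrates; FDR/recovery uses 200 experiments × 500 substrates; the
  image round trip uses one 32×32-spot block; the end-to-end determinism
  check renders 12×12-spot blocks. These sizes give Monte-Carlo errors
  small enough for the stated bounds while keeping the suite quick.

## Known limitations

- Mean-imputation of a missing replicate re-uses the other two
  replicates' information without reducing the residual degrees of
  freedom, so p-values on substrates with imputed values are slightly
  anticonservative; at the default 9% missingness this inflates the
  realized FDP modestly above the nominal level. The calibration
  guarantees in the test suite hold for complete data.
- BH controls FDR under independence/PRDS across substrates; substrates
  sharing an upstream kinase are positively correlated in real data.
- A single rigid grid offset cannot absorb slide warping; warped grids
  would surface as elevated `displaced` flag rates.
- The between-slide control check validates levels only, not variance.
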