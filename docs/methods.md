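# Methods

`psdgold` quantifies the spatial organisation of immunogold-labeled receptors
(AMPA-type GluR1–4 and the NMDA-receptor subunit GluN1) at postsynaptic
densities (PSDs) reconstructed from freeze-fracture replica immunolabeling
(FRIL) electron microscopy. A PSD enters the analysis as a closed polygonal
contour traced around the intramembrane-particle cluster (coordinates in nm,
optional hole rings for annular PSDs) together with the coordinates, bead
size and receptor label of every colloidal gold grain. This note documents
the model and procedure, the tunable parameters, the synthetic-data
generator, numerical choices, and known limitations.

## Pipeline

1. **Classification.** Grains are partitioned into synaptic (inside the outer
   contour and outside every hole, even-odd rule; boundary points count as
   inside, since the outermost intramembrane particles define the traced
   border) and extra-synaptic grains. Only synaptic grains are quantified.
2. **Geometry.** Region area (shoelace of the outer ring minus holes,
   reported in µm²), area centroid ("center of gravity"), and the maximum
   Feret (caliper) diameter over outer-contour vertices. The Feret search is
   restricted to convex-hull vertices (both endpoints of any diameter lie on
   the hull) and ties resolve to the lexicographically smallest vertex-index
   pair for determinism.
3. **Pose normalization.** Each PSD is translated so its centroid sits at the
   origin and rotated so the maximum-Feret pair is horizontal. The rotation
   is fixed to [0, π) and no reflection is applied, so each PSD retains a
   180° ambiguity; population averaging accepts this, as no left/right
   convention exists for a fractured membrane face. (Centering on the
   centroid and putting the Feret *segment* on the x-axis are generally
   incompatible; the package centers the centroid and makes the Feret pair
   horizontal.)
4. **Density maps.** A Cartesian grid (default 25 nm cells, configurable —
   e.g. 20 nm) with a node pinned at the origin is laid over the
   pose-normalized PSD. Cells are half-open, `[x0, x0+s) × [y0, y0+s)`, so a
   grain on a shared edge belongs to the cell with larger coordinates. Grain
   counts and the exact cell∩region area (polygon clipping) are accumulated;
   population maps sum counts and coverage over PSDs and report the quotient
   (grains/nm²), which corrects the average for PSD size and shape.
5. **Radial profiles.** Distances of synaptic grains to the centroid are
   binned in half-open 20 nm annular segments extending to the farthest
   contour point; each segment's count is normalized by the area of the
   annulus∩region intersection. For ring/horseshoe PSDs whose centroid falls
   in a hole the inner segments have near-zero area; segments under 1 nm² are
   masked from normalized output to avoid division blow-ups.
6. **Null models.** Simulated placements keep the real outline and observed
   grain count and redraw positions: `equal` (uniform over the region),
   `center_gaussian` (acceptance ∝ exp(−d_c²/2σ²), d_c = distance to
   centroid) and `border_gaussian` (acceptance ∝ exp(−d_b²/2σ²), d_b =
   distance to the nearest point of the outer contour). Each simulation is
   iterated (default 100×) and per-iteration radial profiles are averaged,
   pairing every measured PSD with its simulated references.
7. **Statistics.** Group summaries (mean, sample SD, median, IQR, extremes,
   adjusted Fisher–Pearson skewness, variance, CV); Mann–Whitney U
   (exact enumeration with midranks when both n ≤ 8, tie-corrected normal
   approximation otherwise); Kruskal–Wallis H with post-hoc pairwise U tests
   reported raw and Bonferroni-adjusted (no adjustment is canonical for this
   design, so both are emitted); OLS grain count on area with R² = squared
   Pearson correlation; per-animal AMPA/GluN1 ratios (mean of per-animal
   means ± SD); and the measured-vs-simulated profile comparison below.
   Group grain densities per µm² are means of per-PSD densities, not pooled
   count over pooled area, matching how per-group SDs of that quantity are
   reported.

## Measured-vs-simulated comparison

The comparison of a measured radial-profile population against each simulated
placement model is a Dunnett-style family of control-vs-treatment tests with
an exact Monte-Carlo null. Under the hypothesis that grains follow placement
model *c*, the measured profile of each PSD and the model's simulation
iterations are iid draws; the pool of k+1 profiles per PSD (measured + k
iterations) is therefore exchangeable. The statistic compares a tested
profile set against the mean of the remaining pool: values are jointly
rank-transformed over the PSD × bin table, rank differences are averaged over
PSDs within each radial bin, and the absolute per-bin deviations are averaged
— a shape-sensitive discrepancy in which a center excess and a border deficit
do not cancel. Holding out each iteration in turn as pseudo-measured data
yields the exact null distribution; the one-sided exceedance p-value has
resolution 1/(k+1), e.g. 1/101 at the default 100 iterations.

A two-way rank transform ANOVA F statistic over condition × bin (computed on
iteration-averaged condition profiles) is reported descriptively. Familywise
Bonferroni-adjusted p-values over the simulated conditions are emitted
alongside the exact per-comparison p-values; note that at 100 iterations the
adjusted p cannot fall below 3/101, so decisions at α = 0.05 should use the
per-comparison p. A naive alternative — rank-permuting condition labels
within each PSD over the table of measured and iteration-averaged profiles —
is badly anticonservative (a single noisy profile is not rank-exchangeable
with a smooth average of 100 draws; empirically ≈ 80% false rejection at
nominal 5%), which is why the hold-one-out construction is the package's
authoritative test. Its measured type-I error is ≤ nominal by construction
(measured ≈ 0.02–0.07 at α = 0.05 over 200 null replicates).

Missing cells (radial bins beyond a small PSD's extent, masked near-zero
segments) are excluded cell-wise; each PSD contributes the bins it has.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid cell size | 25 nm | density-map binning (20 nm supported) |
| radial bin width | 20 nm | annular segment width |
| σ fraction | 1/3 | Gaussian null scale, σ = sigma_frac·√(area/π) |
| iterations | 100 | simulated placements per PSD per model |
| circle approximation | 720-gon | annulus clipping, rel. error < 10⁻⁴ |
| segment mask | 1 nm² | minimum area for a normalized radial value |

σ is not fixed by the underlying study; scaling it to the PSD's effective
radius gives every PSD comparable peakedness regardless of size. The
border-Gaussian uses distance-to-outer-contour, which realizes a peak at the
border for arbitrary, non-convex outlines.

## Synthetic-data generator

The generator emulates the reference study's populations so the pipeline is
testable without raw EM data (none are deposited): per (layer, target)
lognormal PSD areas moment-matched to the published mean/SD (lognormal:
positive and right-skewed; the true family is unknown — only moments,
skewness and extremes are printed); morphology proportions
macular/perforated/horseshoe/ring = 0.80/0.10/0.05/0.05 with class-specific
contour synthesis (smooth radial-harmonic outlines, holes for
perforated/ring, a 60–120° sector removed from an annulus for horseshoe);
grain counts `count ~ Poisson(density · area · f_animal · e^ε)` with a
per-(animal, receptor) lognormal factor (default SD 10%, keeping the
per-animal ratio analysis non-degenerate) and a per-PSD lognormal noise term;
and grain placement from any of the three null models (uniform by default,
matching the study's conclusion that measured patterns are uniform).

The total log-noise variance is solved by bisection on the closed-form
count–area R² of this model. Poisson counting noise alone caps the achievable
R² at d²·Var(A) / (d·E[A] + d²·Var(A)); for several published groups the
printed R² exceeds that cap given the printed density and area moments (partly
a rounding artifact of one-significant-digit area SDs, partly suggesting
sub-Poisson counting in the real data). The generator then uses zero extra
noise and records the effective R² in the ground-truth table; recovery is
assessed against the achievable value.

What the generator does **not** emulate: antibody-linkage displacement of
gold beads (~20–30 nm between epitope and bead), spatial clustering /
nanodomains, double-label steric interference, observer variability in
contour tracing, and any correlation between morphology class and grain
statistics. Passing tests therefore validate the pipeline's arithmetic and
statistical calibration on populations with the study's first- and
second-order structure, not the biological realism of any placement model.

## Numerical choices and problem sizes

Annulus areas use cumulative differences of region∩disc(720-gon) clippings;
coverage uses exact cell clipping with fast paths for fully-inside/outside
cells. Rejection sampling draws from the axis-aligned bounding box with
adaptive batch sizing and a 10⁶-attempts-per-point budget. All randomness
flows through seeded `numpy` generators; a simulation call draws all
iterations from one stream and partitions them (statistically identical to
per-iteration substreams, far fewer rejection batches).

Calibration experiments in the test suite and reproduction script use:
geometry oracles on 100 random contours (10⁵ Monte-Carlo points each);
conservation on 300 synthetic PSDs; flatness on 200 uniform PSDs (4 SD
binomial bands); type-I calibration over 200 small null studies (25 PSDs, 60
iterations); discrimination over 51 replicates of 100 PSDs × ~25 grains ×
100 iterations. These sizes keep a full run in minutes on one CPU while
leaving the statistical conclusions unambiguous.

## Known limitations

* The published group tables cannot be reproduced from raw data (not
  deposited); the package instead verifies internal arithmetic consistency of
  the published statistics and full pipeline behaviour on synthetic data.
* The exact construction of the border-peaked Gaussian in the original
  analysis is ambiguous ("related to the distance of a marker to the
  center"); distance-to-contour was chosen, and a per-direction
  boundary-radius construction would be a straightforward extension.
* Extra-synaptic grains are strictly excluded; no re-inclusion margin near
  the contour is applied.
* Averaged density maps inherit the 180° pose ambiguity per PSD.
* The 25 nm default grid and the 20 nm alternative are both supported because
  both appear in the reference analysis; neither is endorsed.
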