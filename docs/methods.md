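# Methods

This note documents the models behind each pipeline, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a user auditing results will want to know.

## Micropillar traction forces

**Model.** Each pillar is an independent linear spring: the traction force
at a pillar is its spring constant times the measured tip deflection. The
ideal Euler–Bernoulli bending stiffness of a cylindrical cantilever is
k_bend = (3/64)πED⁴/H³. Because the pillar is anchored in the same
elastomer it is made of, the base shears and tilts under load; the
multiplicative correction (in aspect ratio r = H/D and Poisson ratio v)

    corr = (16/3)r³ / [(16/3)r³ + ((7+6v)/3)r + 8·T_tilt(v)·r²],
    T_tilt(v) = a(1+v)/(2π²(1−v)) + 1 − 1/(4(1−v)),

collects the bending, shear and base-tilt compliances of the anchored
pillar. The constant `a` in T_tilt is a dimensionless fitted constant from
the substrate-warping analysis of micropillar mechanics, not the pillar
radius (a length there would break dimensional consistency); it is exposed
as `tilt_constant` with default 1.3. The effective substrate modulus a
cell senses is E_eff = 9k/(4π·radius). For the default geometry
(D = 0.5 µm, H = 1.3 µm, pitch 1 µm) and material (E = 2.0 MPa, v = 0.5,
typical of 10:1 Sylgard-184 PDMS; both configurable since cure conditions
vary) this gives k_bend ≈ 8.4 mN/m, corr ≈ 0.67, k ≈ 5.6 mN/m,
E_eff ≈ 16 kPa. At v = 1 the tilt term is singular; the `Material`
validator restricts v to [0, 0.5].

**Displacement measurement.** Pillar tops are localized by an
intensity-weighted centre of mass in a window of half the pitch,
recentred for three passes after subtracting the window-border median;
noiseless accuracy is below 0.1 nm, and the accuracy under the default
imaging noise (~8 nm per axis) dominates the error budget. The ideal
lattice is fitted only to reference pillars outside the cell: orientation
from the circular mean of nearest-neighbour directions (folded mod 90°),
then alternating integer node assignment and linear least squares for
origin and basis. The fit is rigid-motion equivariant and refuses to
proceed when fewer than 6 references are available or the residual exceeds
pitch/4 (the perfect-grid assumption is then wrong). Each centroid is
assigned to its nearest node; centroids farther than pitch/2 from every
node are flagged unassigned and excluded.

**Noise gating.** The noise floor is the 95th percentile (linear
interpolation between order statistics) of the reference-pillar
displacement magnitudes. By construction about 5% of truly undisplaced
pillars exceed this gate, which is the accepted operating point of a
one-sided 95% specificity gate; the suite checks that bound on
zero-displacement control scenes. Sub-noise pillars carry zero force.
"Traction stress" is ambiguous between raw force and force per area, so
the edge-band summary reports both the force statistics and the mean force
divided by the pillar cross-section.

**Edge band.** Traction concentrates where adhesions form, at the cell
periphery, so the summary selects pillars inside the cell whose
distance-transform value is at most 10 µm (configurable).

## Focal-adhesion imaging

The cell is masked on the membrane channel at 100 AU above background.
Background is estimated as the histogram mode (robust when most of a TIRF
field is background); a median-based estimate can be substituted via the
`background_level` argument. The largest connected component is kept and
holes filled. Vinculin foci are 8-connected components above 10000 AU
(raw intensities — the pipeline applies no background subtraction before
thresholding) restricted to the cell mask, with pixel-count area of at
least 0.5 µm²; 8-connectivity matches common imaging-suite defaults and
avoids splitting diagonal foci. Per-focus edge distance is the minimum of
the Euclidean distance transform of the cell mask over the focus's pixels.

The turnover index links foci in consecutive frames one-to-one by maximal
pixel overlap (Hungarian assignment on the overlap matrix, only non-zero
overlaps count) and reports 1 − 2m/(n_t + n_{t+1}) per frame pair. This
per-frame overlap fraction is this package's operational definition of
turnover — 0 for fully persistent adhesion maps, 1 for complete exchange —
chosen because it needs no per-adhesion lifetime bookkeeping; per-lifetime
variants in the literature are not reproduced here. The index is symmetric
under frame exchange and invariant to label permutation, and the
one-to-one matching guarantees m ≤ min(n_t, n_{t+1}).

## Migration and invasion tracks

Metrics per track: accumulated distance (sum of step lengths), net
displacement (last minus first), lateral/vertical components (x/y of the
net vector; the chemoattractant gradient axis is +y by convention,
configurable), straightness = net/accumulated, speed =
accumulated/elapsed time, and parallel FMI = vertical/accumulated.
"Total track length" in the straightness denominator is read as
accumulated path length, which makes the quantity unitless in [0, 1].
The FMI is signed (toward-gradient positive); an absolute variant is
available via `signed_fmi=False`. Stationary tracks return straightness =
FMI = 0 rather than NaN so cohort summaries stay computable. Speed uses
first-to-last elapsed time without gap interpolation; a mean
instantaneous-step variant is available (`speed_mode="per_step"`).
Filters: 3D invasion discards tracks with fewer than 3 timepoints; 2D
migration keeps tracks with ≥ 5 timepoints starting before frame 5; the
proximity exclusion drops any cell with a neighbour strictly closer than
35 µm at the selection frame. Group summaries use sample SD (n−1).

## Colocalization

Thresholded Manders split coefficients use each channel's own
above-threshold pixels as denominator (the convention of the common
ImageJ plugins); the whole-image denominator is available via
`denominator="total"`. Pearson's r defaults to excluding only zero-zero
pixels, matching the usual "above threshold (zero-zero pixels)" reading;
restriction to the above-threshold union is available via
`mode="above_union"`. The Costes procedure fits an orthogonal regression
and walks thresholds down from the brightest value until the
below-both-thresholds pixel set is uncorrelated (r ≤ 0); perfectly
correlated pairs return the minimal thresholds. The round-structure
prefilter keeps components with circularity 4πA/P² ≥ 0.8 (cutoff and area
bounds exposed, since "round-shaped" has no canonical number). Perimeter
is the weighted contour-length estimator of `skimage.regionprops`, which
scores digitized disks near 1; a naive crack-length (city-block) perimeter
would score a disk near π²/16 ≈ 0.62 and reject it, contradicting the
intended behaviour. All statistics are 2D; "percent volume" is percent of
qualifying pixels in a single plane.

## Proteomics and assay arithmetic

The differential filter log2-transforms abundances, takes group means on
the log2 scale (so the reported fold change is the geometric-mean ratio),
applies per-protein Welch t-tests and Benjamini–Hochberg adjustment
(via `statsmodels`), and flags proteins with fold change ≥ 2 or ≤ 0.5 and
adjusted p ≤ 0.05. The test and the FDR procedure are the standard
label-free-proteomics defaults and are deliberately swappable; proteins
with zero variance in both groups get NaN p-values and are excluded from
the number of tests. Presence/absence comparisons go through
`venn_partition`, not the fold-change test. 2^−ΔΔCt normalizes the target
Ct against the arithmetic mean of the ACTB/GAPDH/B2M Cts per sample
(equivalent to a geometric mean on the expression scale) and against a
calibrator group; a per-sample additive Ct offset cancels exactly. The
bead-capture and densitometry fold changes are the stated ratios of
normalized signals.

## Synthetic data: what it emulates, what it does not

Pillar scenes render one analytic isotropic Gaussian per lattice node
(σ = 0.15 µm at 0.1 µm/pixel) plus additive Gaussian intensity noise
clipped at zero. Gaussian spots and uniform-disk foci were chosen because
their closed-form centroids make localization oracles exact. The default
intensity noise (sd 70 AU at spot amplitude 1000) was calibrated so that
the measured reference-pillar noise floor is ≈ 20 nm, the floor typical of
this kind of experiment; the imaging-noise magnitude itself is not a
published quantity, so it is an exposed parameter. Contractile scenes
impose centripetal displacements of 30–150 nm (uniform magnitude) on every
pillar under a disk-shaped cell — above the noise floor, as gated tractions
are in practice — and leave all reference pillars undisplaced.

Walk cohorts follow x_{t+1} = x_t + persistence·(x_t − x_{t−1}) + drift +
noise with 10-minute frames over 12 hours (72 steps), step noise 0.5 µm
per axis and drift toward +y. The omics generator plants log2 shifts on a
log-normal baseline with replicate sd 0.25 (~18% CV), four replicates per
group, 500 proteins.

None of the generators model realistic optics (no PSF beyond Gaussian
blur, no camera gain or Poisson statistics), pillar crosstalk, adhesion
maturation dynamics, track gaps/collisions, or missing values and batch
effects in proteomics. Passing tests therefore demonstrate that the
estimators are correct and well-calibrated under their stated models —
not that they are robust to every artefact of real microscopes or mass
spectrometers.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use 20 traction scenes of
400×400 pixels plus 5 undisplaced controls, cohorts of 300–500 tracks,
400×400 colocalization pairs, and 200-seed null proteomes of 200 proteins
— sizes at which every Monte-Carlo check has comfortable margin while the
whole suite runs in well under a minute per pipeline. Every stochastic
step draws from a `numpy` Generator seeded from the scene or the script's
`--seed`; repeat runs are bit-identical.

## Known limitations

- The grid fit assumes a square lattice; hexagonal arrays are not
  supported.
- Pillar tracking across time-lapse frames is out of scope (displacements
  are computed per frame).
- The turnover index is a per-frame overlap fraction, not a per-adhesion
  lifetime statistic.
- Costes thresholds on nearly-independent channels stop at the first
  zero-crossing of the below-threshold correlation, which fluctuates for
  finite images; expect seed-to-seed variation of the returned thresholds
  there.
- The colocalization statistics are single-plane; z-stacks must be
  reduced or analysed slice-wise by the caller.
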