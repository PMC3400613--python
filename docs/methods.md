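# Methods

`mitocohort` re-creates, on fully synthetic data with known ground truth, the
quantitative core of a cross-sectional immunology study design: single-cell
mitochondrial network morphometry from confocal slices, flow-cytometric
parameterization of ROS production and inner-membrane potential (ΔΨm), and a
multivariate group-comparison layer.  This note records the models, the
defaults and why they were chosen, and what the synthetic benchmarks do and do
not demonstrate.

## Synthetic network ground truth

A mitochondrial network is a vector graph (node coordinates, edge list) drawn
inside a circular cell.  Each requested fragment is grown as a
curvature-limited self-avoiding random walk (unit steps, heading drift
N(0, 0.08 rad), specular reflection off the cell boundary); side branches
leave interior nodes perpendicular to the local strand.  Self-avoidance works
on a stamped occupancy grid with two zones:

* a hard *contact* zone (2·tube_radius + 1 px, euclidean) that no strand may
  enter, so rasterized tubes never touch;
* a soft *clearance* zone (2·tube_radius + 4 px) that only a walk's own recent
  trail and the vicinity of its branch origin may enter, chosen so strands of
  distinct fragments stay resolvable after a ~1 px point-spread function.

Fragment separation is verified against the final rasterization (connected
components of the dilated polyline mask must equal the graph's component
count); a violating layout is regenerated deterministically from a derived
seed.  Volume density is calibrated during growth against the incrementally
maintained raster, so the achieved raster area is within one percentage point
of the target; the achieved value is stored next to the target.

Design choices worth knowing about:

* **Per-fragment growth instead of one tree split by edge deletion.**  Cutting
  gaps out of a single tree could not guarantee raster-level separation of the
  resulting pieces (dilated tubes bridge small gaps), whereas separate walks
  under the contact rule make the rasterized fragment count exact by
  construction.  Fragment count and branching remain independently
  controllable.
* **Branch scheduling.**  The number of branch nodes is drawn as
  Poisson(branch_density × expected length) and realized by repeated spawning;
  a branch that jams before a resolvable length (12 steps) is rolled back via
  a checkpoint so the stored truth never contains sub-resolution stubs, and
  another origin is tried.  Realized counts are unbiased at moderate density.
* **Rescue branches.**  A single self-avoiding path cannot fill more than
  roughly 10–15 % of the disk before jamming; when leaf extensions are
  exhausted the generator branches from an interior node to keep growing.
  Such rescue branch points are counted faithfully in the stored truth, which
  is why high-density / zero-branching configurations carry a small positive
  true branching.
* **Corner rounding.**  When the walk deflects sharply around an obstacle the
  previous node is pulled to the chord midpoint; hard corners in the
  rasterized tube otherwise thin into spurious ≥3-neighbour skeleton pixels
  whose rate scales with crowding, biasing the branching parameter upward at
  high density.
* **Tube radius defaults to 2 px** (5 px wide tubes).  At 1 px the number of
  skeleton pixels produced per true junction was too erratic for branching to
  be recoverable; 5 px wide tubes at the working magnification (~0.05 µm/px,
  organelle diameter a few hundred nm imaged through the PSF) are also the
  more realistic appearance.

## Image rendering

Constant fluorophore density inside the tubes (level 220), dim cytoplasm (60),
background (10), Gaussian PSF (default σ = 1 px), additive Gaussian read noise
(default SD 3) and optional Poisson shot noise; the nuclear channel is a
blurred filled disk.  With the PSF and noise switched off, thresholding
recovers the tube raster exactly, which anchors the exactness tests.  No Airy
optics, no 3-D stacks, no depth attenuation: the generator probes the
*algorithm*, not the microscope.

## Morphometry

Per cell: (1) cell outline = largest connected component above
(border-frame background mean + 3 SD), holes filled; (2) network = Otsu
threshold inside the cell mask, finished by a radius-1 morphological opening
(removes sub-tube-width necks and specks; a clean tube raster passes through
unchanged, by the opening identity on dilated sets); (3) skeletonization and
8-neighbour pixel taxonomy (0 isolated / 1 end / 2 through / ≥3 branch);
(4) the three stereological parameters

* volume density `Vv% = 100 · |network| / |cell|`,
* fragmentation = skeleton components / skeleton pixels (isolated pixels count
  as fragments and as length, so the ratio stays in (0, 1]),
* branching = branch pixels / skeleton pixels.

Thinning is hybrid: masks that are already one pixel wide (no fully set 2×2
block) pass through untouched — this preserves closed-form fixtures and makes
the operation idempotent — while thicker masks are reduced with the
medial-axis transform (fixed tie-break order), whose junction pixel counts
proved markedly more reproducible than iterative Zhang–Suen-type thinning on
tube-like masks.  Endpoint twigs of ≤3 px hanging off a junction are pruned as
thinning artifacts; free chain ends are never pruned.  Lengths are pixel
counts, not Euclidean polyline lengths, matching how per-pixel taxonomies are
tallied; µm calibration is carried in the data model but the reported ratios
are unit-free (fragmentation and branching are per pixel of skeleton).

Known limitation: skeleton branch pixels per true junction average ≈3 with
per-junction scatter, so branching is recovered as a monotone (rank-faithful)
readout rather than an absolute count.  The recovery benchmark therefore
reports Spearman correlations over a 3×3×3 grid of generated networks
(Vv 5–30 %, 1–10 fragments, branch density 0–0.03 /px; two networks per grid
point, per-point means; cell radius 120 px, 300×300 px images, PSF σ = 1,
noise SD 3), where all three parameters recover at ρ ≥ 0.9.

## Cytometry event model and analysis

One simulated tube holds lymphocytes and CD14+ monocytes, with FSC/SSC/CD14
drawn from well-separated lognormal clusters.  Fluorescence lives on the log10
scale (Gaussian components in decades = lognormal intensities, matching
decade-scaled cytometer axes):

* green = two-component ROS mixture per cell type.  Control defaults put the
  lymphocyte components at 1.00/1.28 decades (≈1.9× apart, 55.4 % high) and
  the monocyte components at 1.20/2.15 decades (≈9× apart, 75.8 % high).
* red = green × ratio, with the log10 red/green ratio following the ΔΨm
  mixture: lymphocytes −0.35/+0.50 decades (14.7 % low-potential), monocytes a
  single component at +0.45.  Under CCCP the ratio mixture collapses (means
  drop, the low fraction rises to 85 %); under PMA all green intensities are
  multiplied by the subject's stimulation factor (control defaults 2.0
  lymphocytes, 4.0 monocytes).

Analysis standardizes the operator's manual marker placement as BIC-selected
1- vs 2-component Gaussian mixtures on log10 intensity (EM with deterministic
quantile initialization, tol 1e-6), bimodal only when the means differ by more
than 0.15 decades and both weights exceed 1 %.  The reported high fraction is
the fitted mixture weight — the model-based fraction of high-ROS events, which
stays unbiased when components overlap, unlike the fraction of events above
any single threshold (biased by ≈4 points for the lymphocyte defaults).
Component MFIs are arithmetic means of linear intensities over the
equal-posterior hard assignment, matching the cytometer convention; at large n
they agree with the lognormal closed form exp(µ + σ²/2).

The ΔΨm quadrant marker is calibrated per subject on the CCCP tube — the
collapsed component's mean + 2 SD on the log ratio — and applied unchanged to
the basal tube; a sanity check refuses calibration when the "CCCP" tube is not
left-shifted against basal.  Monocytes show a single potential population and
are never split.  Gating: monocytes are events above the valley of the
smoothed log10 CD14 histogram (a fixed fallback boundary is used when no two
peaks at least half a decade apart exist); lymphocytes are CD14-negative
events inside a configurable FSC/SSC rectangle.

The per-subject functional vector is the 8-dimensional lymphocyte set
(a, b, c_high, c_low, c_low%, d_high, d_low, d_low%) — basal high-ROS MFI,
PMA/basal MFI ratio, basal potential of the high/low subpopulations, the
low-potential percentage, basal/CCCP potential ratios and the CCCP/basal ratio
of low-potential percentages — and the 4-dimensional monocyte set (a, b, c, d)
without subpopulation splits.

## Cohort simulation

Default design: Control 49, untreated 49, and three first-line treatment arms
of 27 subjects (the 81 treated subjects split evenly, the exact split being
unreported); 15 000 lymphocyte and 3 000 monocyte events per tube; three
imaged subjects per group (the ones with minimal, median-rank and maximal
basal high-ROS lymphocyte MFI) with 30 cells per cell type.  Group-level
subpopulation fractions are set directly to the cohort-reported percentages;
MFI-scale group effects are unreported and were chosen once to reproduce the
qualitative picture — infection shifts lymphocyte parameters strongly
(+0.20 decades basal ROS, PMA reserve 2.0 → 1.55, low-potential ratio
−0.10 decades), therapy partially rescues them, monocytes respond slightly to
therapy and not to infection, and the 3-NRTI arm is the most heterogeneous
(subject SD ×1.6).  Between-subject spread defaults to 0.08 decades on
log-scale means and 0.05 absolute on fractions.

Viral load is lognormal (log10 µ = 4.2, σ = 0.8 in the untreated group;
µ = 1.2, σ = 0.4 in treated groups) with a 40 copies/ml detection floor;
below-floor values are kept but flagged censored, and correlations exclude
them.  Selected traits couple to log10 viral load through a single-factor
Gaussian copula, z_trait = r·z_VL + √(1−r²)·ε, with r set to the target
correlations (0.355 lymphocyte ROS, −0.417 lymphocyte potential, 0.457
low-potential percentage, −0.455 monocyte potential).  Because the traits are
lognormal in the latent, the realized Pearson r is attenuated by ~1–3 %; this
is documented rather than corrected, and the recovered means sit within 0.012
of the targets.

## Discriminant analysis and statistics

Canonical axes solve H v = λ E v (between vs pooled-within SSCP) through a
dense symmetric generalized eigensolver; axes are scaled to unit pooled
within-group variance, eigenvalues clipped at zero and sorted, variance
fractions are eigenvalue shares.  A singular within matrix gets a logged
1e-8·trace ridge (or a hard error when the fallback is disabled).  Wilks'
Λ = det(E)/det(E+H) is tested with Rao's F approximation and Roy's greatest
root with its conservative upper-bound F (both match `statsmodels` MANOVA to
numerical precision); pairwise two-group Wilks tests are Bonferroni-multiplied
over all g(g−1)/2 pairs.  The 95 % confidence circle around a group mean has
radius √(χ²₂(0.95)/n_g) in canonical units — the χ² construction for the
standard error of a bivariate mean with unit within-group variance; the
circle's defining formula was an open choice and this interpretation makes the
radius scale as n^(−1/2).

Units of analysis: functional vectors are one per subject; morphological
records are one per cell, grouped by cohort group (cells pooled over the
representative subjects, the default; per-subject aggregation is a caller-side
groupby away).

Univariate layer: Pearson correlations with two-sided t tests (log10 viral
load, censored values excluded and counted); ANOVA or Kruskal–Wallis omnibus
tests with Bonferroni-adjusted pairwise versions (a pair is flagged iff raw
p < 0.05/n_pairs); box summaries whose whisker limits are the observed values
nearest to and inside the Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR).
Quartiles interpolate linearly (type 7) by default with a type-6 option for
spreadsheet parity.  The representative-subject selector returns the minimal,
median-rank and maximal subject per group, ties resolved to the lower subject
id; "medium" is interpreted as the median rank.

## Numerical and degenerate-input behaviour

Mixture fits are deterministic (fixed initialization, single start); constant
images raise a segmentation error; an empty network mask flags the cell and
`batch_morphometry` reports every exclusion with its reason instead of
dropping rows; zero-intensity events are excluded from ratios with a count;
group tests require ≥2 groups with ≥2 observations; confidence circles are
undefined (flagged) for singleton groups.

## Problem sizes of the shipped benchmarks

The recovery benchmarks run at sizes chosen for stable statistics: 27-point
grid × 2 networks for morphometry; 50 simulated tubes (6 000 lymphocyte /
2 500 monocyte events) for the fraction recovery; 200 subject-level cohort
draws of 44 untreated subjects for the correlations; 50 replicate two-group
cohorts (12 + 12 subjects, 2 500/1 200 events) for the differential-response
rate.  The full five-group pipeline in `analysis/01_run_cohort_pipeline.py`
runs at the complete design (179 subjects, 15 000/3 000 events, 30 images per
imaged subject and cell type).

## What passing these benchmarks does and does not show

The generator shares the pipeline's geometric and distributional vocabulary
by construction: tubes are uniform-intensity and the cell is a disk, mixtures
really are lognormal, group effects are additive on the log scale.  Passing
therefore demonstrates internal correctness — the algorithms recover what was
put in, at realistic noise — not robustness to the full phenomenology of real
confocal slices (uneven staining, out-of-focus haze, touching cells) or real
cytometry (spillover, autofluorescence tails, acquisition drift).  Those
belong to instrument-specific validation, which this package does not claim.
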