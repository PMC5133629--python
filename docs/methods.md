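# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Synthetic time-lapse generator

**Acquisition schedule.** Imaging timestamps are built from contiguous
constant-interval phases; the default design is three phases — 10 min
intervals from 0–6 h, 15 min from 6–96 h, 1 h from 96–504 h — giving 805
frames per field of view over 21 days. Timestamps are computed with exact
rational arithmetic (`fractions.Fraction`) and converted to float once, so
phase boundaries are hit exactly and repeated runs enumerate identical
grids; intervals must divide their phase length, and gapped or overlapping
phases are rejected.

**Cell populations.** Each condition is a `ConditionParams` set:

| parameter | units | default | role |
|---|---|---|---|
| `mean_orientation_deg` (μ) | deg, [0, 180) | 90 | axial mean orientation |
| `orientation_concentration` (κ) | – | 0 | von Mises concentration; 0 = uniform |
| `area_plateau_um2` | µm² | 2200 | long-time mean spread area |
| `area_timescale_h` (τ) | h | 8 | spreading time constant |
| `aspect_ratio_plateau` | – | 2.5 | long-time major/minor ratio |
| `initial_radius_um` | µm | 15 | unattached round-cell radius |
| `n_cells_per_fov` | – | 6 | labelled cells per field of view |
| `area_cv` | – | 0.15 | lognormal per-cell size heterogeneity |

Orientations are axial (θ ≡ θ + 180°), drawn by sampling a von Mises variate
on the doubled angle 2θ with location 2μ and concentration κ, then halving —
the standard generative model for axial data; no generative model is implied
by the phenomenology being emulated, so this is a declared design choice.
Spreading follows a saturating exponential: area rises from πr₀² to the
plateau and aspect ratio from 1 to its plateau, both as 1 − e^(−t/τ). Only
the qualitative trend (fast rise, then plateau) is empirically motivated;
the exponential form is the simplest monotone saturating choice. The four
bundled study conditions encode the reported contrast: aligned substrates
get the largest, most elongated (AR 4.0), strongly 90°-oriented cells;
random substrates the smallest and roundest (AR 1.8, κ = 0); flat and
flat-osteo sit between with no orientation preference.

**Placement and rendering.** Cell centres are rejection-sampled with a
minimum spacing of twice the largest attainable semi-major axis, so two
cells can at most touch — emulating the dilution of labelled cells that
keeps objects separable; an impossible density raises an error rather than
silently overlapping. Each cell is rendered as a filled ellipse, blurred by
a Gaussian PSF (σ = 1 px), on a constant background (100 counts) with
signal-dependent Gaussian noise of standard deviation
`photon_noise_scale · sqrt(signal)` — a Gaussian approximation to shot
noise. Defaults give foreground SNR ≈ 30. The noise-free label mask and an
analytic shape table (ellipse area πab, Ramanujan perimeter, axes,
orientation) are emitted alongside every frame.

**What the generator does not emulate:** cell texture and internal actin
structure, motility, division, death, photobleaching, focus drift, uneven
illumination, and touching or overlapping cells. Passing tests therefore
demonstrate correctness of the measurement pipeline on well-separated
elliptical objects, not robustness to the full messiness of real
micrographs; in particular, segmentation accuracy on real data with
overlapping cells will be worse than the synthetic IoU suite suggests.

**Conventions.** Pixels are indexed 0-based with origin top-left; the
default pixel size is 1 µm/px so pixel and micrometre units coincide unless
configured. Orientation is measured counter-clockwise *in display sense*
(i.e. towards decreasing row index) from the +x (column) axis, range
[0°, 180°). Frames are written as 16-bit single-channel TIFFs, masks as
16-bit label TIFFs, with metadata in a manifest CSV (UTF-8, comma
separator, '.' decimal).

## Segmentation

Gaussian smoothing (σ = 1 px) → global threshold → hole filling → removal of
objects below `min_area_px` (default 50 px) → optional border clearing →
connected-component labelling (8-connectivity default, recorded in the
mask). Otsu's method is the default threshold; a fixed threshold is
available for determinism experiments. A constant image under Otsu returns
an empty mask with a warning flag instead of raising. There is no
declumping or watershed: the acquisition design keeps labelled cells sparse,
so touching-cell separation is out of scope and merged objects simply appear
as large objects.

Validation against a reference mask matches objects greedily by decreasing
pixel overlap (one-to-one) and scores intersection-over-union; the result is
invariant to label renumbering. On the synthetic suite (non-overlapping
cells, SNR ≥ 5) automated masks recover every object with mean IoU ≥ 0.8 —
the repository's stand-in for a manual-vs-automated agreement study.

## Shape metrics

**Circularity** is the form factor 4πA/P², clamped at 1 (discretization can
push small round objects slightly above 1; the raw value is stored
alongside). The clamp threshold is exact: only the estimator below makes the
metric meaningful, since a naive pixel-edge perimeter overestimates a
circle's boundary by ~27% and caps circularity near 0.63.

**Perimeter** is estimated from the sub-pixel 0.5-level iso-contour of the
padded binary object; the closed polygon's vertices are smoothed with a
5-vertex circular moving average before summing segment lengths. The
smoothing removes the staircase bias of the marching-squares contour:
rasterized circles of radius 25–100 px evaluate to circularity 0.993–1.005,
converging to 1 with radius, while a 20 px square's perimeter stays within
5% of its true 80 px. Objects too small to smooth fall back to the raw
contour.

**Axes and orientation** default to the moment-equivalent ellipse (the
ellipse with the same normalized second central moments as the pixel set) —
the convention of standard morphometry software, and the measure most
comparable to published per-object axis lengths. A minimal-area enclosing
ellipse (Khachiyan's algorithm on the convex hull of pixel corners) is
available as `ellipse_method="enclosing"` for the stricter geometric reading
of "smallest enclosing ellipse"; on convex rasters the two agree within 5%,
and the method used is recorded in every record. Degenerate (collinear)
objects get a 1 px minor-axis floor and a flag.

## FFT alignment

Each frame is mean-subtracted and Hann-windowed (without the window, frame
edges imprint a strong axis-aligned cross on the spectrum), and the centred
2-D power spectrum is computed. The DC bin is excluded and power is summed
over frequencies in a radial band from 4 cycles/frame to half-Nyquist
(0.25 cycles/px) — low frequencies carry field-level illumination structure,
the highest frequencies mostly noise; the band is configurable. Each
frequency pixel is assigned to one of 180 1° bins by its real-space feature
angle: the spectral direction (atan2 on the frequency coordinates in display
convention) plus 90°, mod 180°, since elongated features concentrate
spectral power perpendicular to their axis. Spectra from the fields of view
of one condition/timepoint are summed bin-wise and normalized to unit total;
rows of combined spectra over the schedule form the time–angle surface, with
missing timepoints flagged as NaN rows.

**Flatness.** The max/median bin ratio flags dominant orientations, but raw
1° bins are speckle-dominated for sparse fields of discrete objects: Monte
Carlo runs of uniform-orientation and round-cell renders reach raw ratios of
9 even though the populations are isotropic. `spectrum_flatness` therefore
smooths the spectrum with a 5° circular moving average first; calibration on
those isotropic renders gives ratios ≤ 2.8, while aligned populations (κ = 8)
exceed 6.5. The declared isotropy bound `FLATNESS_THRESHOLD = 3.0` sits
between the two.

## Divergence statistics

Per-object records are pooled across replicates and fields of view at each
timestamp (no nested model — pooling is the declared design). For a
condition pair and metric, each timepoint's two samples are compared with a
two-group one-way ANOVA F (df 1, nₐ+n_b−2), which equals the squared
pooled-variance t statistic; the label "F-test" is ambiguous between this
and a variance-ratio test, so a two-sided variance-ratio mode
(`mode="variance"`, df nₐ−1, n_b−1) is also provided and the mode is
recorded in every result. The divergence time is the first timestamp with
p < α (default α = 0.05) persisting for k consecutive timepoints (default
k = 1, matching sub-hour reported resolutions; k > 3 guards against isolated
false positives). No multiple-testing correction is applied across the ~800
timepoints by default, matching the apparent original procedure; with ~800
tests at α = 0.05 a null pair still diverges eventually with high
probability, so divergence times near the end of a long schedule should be
read with that in mind. Degenerate inputs are explicit: zero within-group
variance with equal means gives (F = 0, p = 1), with unequal means (p = 0,
flagged); timepoints with fewer than two objects in either condition yield
NaN p-values, which break persistence runs. Mean-ratio trajectories report
mean(A)/mean(B) per timepoint and the median |log ratio| as a summary
distance from unity, with zero-denominator timepoints flagged NaN.

Calibration properties verified by the test suite: type-I error 0.05 ± 0.02
under the null (1000 simulated timepoints, n = 50 per group); a 1-SD mean
shift injected at hour 12 (n = 200 per timepoint) is recovered within two
1 h grid steps in the median over 50 seeds; identically generated condition
pairs report "never" in ≥ 95% of seeds at α = 0.05, k = 3.

## Comparative CT

ΔCT per replicate is CT_target minus the arithmetic mean of the housekeeping
CTs (equivalent to the geometric mean of housekeeping expression — the
combination rule for multiple housekeepers is a declared choice). ΔΔCT
calibrates each condition's mean ΔCT against the calibrator condition; fold
change is 2^(−ΔΔCT) with no efficiency correction, reported as log₂ or
log₁₀. Statistical comparison is the unpaired two-sample pooled-variance
Student's t-test on the per-replicate ΔCT samples, never on fold changes. A
reference-cDNA calibrator is handled as just another condition column.

## Pipeline and problem sizes

`run_pipeline` executes simulate → segment → measure → align → diverge
(→ ddct when a CT table is supplied), writing every artifact with a run log
(seed, config hash, version, stage timings, output SHA-256 digests). The
bundled demo design compresses the 504 h schedule to 48 h (2 h cadence to
6 h, then 6 h steps) at 512×512 px with four cells per field of view; the
test suite runs this demo at 2 replicates × 2 fields of view, a size chosen
to keep a full determinism round-trip (two complete runs) in tens of
seconds while still exercising all four conditions and every stage.
Determinism is exact: per-series seeds are derived from the root seed with
`numpy.random.SeedSequence` spawn keys, so outputs are byte-identical for a
given config and seed and independent of iteration order.

## Limitations

- Shape metrics assume one cell per labelled object; merged cells bias area
  and axis statistics upwards.
- The FFT spectrum measures *population*-level feature orientation; it does
  not resolve per-cell orientation (that comes from the moment ellipse) and
  its angular resolution degrades for nearly round objects.
- The divergence procedure is a first-rejection rule, not a changepoint
  model; its reported hour inherits the acquisition grid's resolution and
  the F-test's sensitivity at the local sample size.
- Synthetic imagery is idealized (see generator section); quantitative
  transfer of IoU or divergence-recovery numbers to real micrographs is not
  implied.
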