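# topocell

Quantitative analysis of how substrate nanotopography shapes stem-cell
morphology in long-term fluorescent time-lapse experiments. The package is
aimed at cell-biology and biomaterials labs that image sparse, fluorescently
labelled cells (e.g. adipose-derived stem cells on flat glass, randomly
deposited, or aligned nanofibre substrates) over days to weeks and want
reproducible, scriptable answers to three questions:

1. **How does cell shape evolve per condition?** Per-object morphometrics —
   area *A*, perimeter *P*, circularity 4π*A*/*P*² (1 for a circle, → 0 with
   elongation), and the major/minor axes and orientation of the
   moment-equivalent ellipse — pooled across replicates and fields of view
   into per-condition time series.
2. **When do two conditions become different?** For each condition pair and
   metric, a per-timepoint two-group F-test (ANOVA form, F = t²) gives a
   p-value series; the *divergence time* is the first acquisition timestamp
   with p < α (optionally persisting for k consecutive timepoints), or
   "never".
3. **Is the population globally aligned?** The 2-D FFT power spectrum is
   summed into 1° orientation bins over [0°, 180°); combined across fields
   of view and normalized, a peak at angle θ marks features elongated at θ
   in real space. Stacked over the schedule this yields a time–angle
   alignment surface; a smoothed max/median flatness statistic separates
   aligned from isotropic populations.

A fourth stage computes relative gene expression from qPCR CT tables by the
comparative-CT method: ΔCT = CT_target − CT_housekeeping,
ΔΔCT = ΔCT_sample − ΔCT_calibrator, fold change 2^(−ΔΔCT), with unpaired
two-sample Student's t-tests on ΔCT values.

Because such experiments rarely ship with public raw images, the package
includes a first-class synthetic generator that emulates the acquisition
design — four conditions, duplicate substrates, four fields of view, a
three-phase cadence (every 10 min for 0–6 h, every 15 min for 6–96 h, hourly
for 96–504 h) — with cells that start round and spread into elongated
ellipses whose orientations follow an axial von Mises distribution. Every
frame comes with a ground-truth label mask and an analytic shape table, so
the whole pipeline is testable end to end.

## Worked example

Simulate a 6 h spreading experiment for a `random` (isotropic, small cells)
and an `aligned` (κ = 8 at 90°, elongated cells) condition, segment and
measure every frame, and ask when the two conditions diverge:

```python
import pandas as pd
from topocell import (ConditionParams, FrameGeometry, make_schedule,
                      simulate_experiment, segment_frame, measure_objects,
                      angular_power_sum, combine_and_normalize,
                      divergence_table)
from topocell.alignment import spectrum_flatness

conditions = [
    ConditionParams("random", orientation_concentration=0.0,
                    area_plateau_um2=1500.0, aspect_ratio_plateau=1.8,
                    n_cells_per_fov=4),
    ConditionParams("aligned", mean_orientation_deg=90.0,
                    orientation_concentration=8.0, area_plateau_um2=2600.0,
                    aspect_ratio_plateau=4.0, n_cells_per_fov=4),
]
schedule = make_schedule([(0, 6, 0.75)])        # 45 min cadence, 0-6 h
sim = simulate_experiment(conditions, schedule, n_replicates=2, n_fovs=2,
                          rng_seed=0, geometry=FrameGeometry(512, 512))

tables, spectra = [], {}
for frame in sim.frames:
    mask = segment_frame(frame)
    tables.append(measure_objects(mask, frame.pixel_size_um, metadata={
        "condition": frame.condition, "replicate": frame.replicate,
        "fov_id": frame.fov_id, "timestamp_h": frame.timestamp_h}))
    spectra.setdefault((frame.condition, frame.timestamp_h), []).append(
        angular_power_sum(frame, condition=frame.condition,
                          timestamp_h=frame.timestamp_h))
shapes = pd.concat(tables, ignore_index=True)

print(shapes[shapes.timestamp_h == 6.0].groupby("condition")[
    ["area_um2", "circularity", "major_axis_um"]].mean().round(2))
for cond in ("random", "aligned"):
    spec = combine_and_normalize(spectra[(cond, 6.0)])
    print(f"{cond}: FFT peak {spec.peak_angle_deg:.0f} deg, "
          f"flatness {spectrum_flatness(spec):.1f}")
table, _ = divergence_table(shapes, pairs=[("random", "aligned")])
print(table)
```

This prints:

```
           area_um2  circularity  major_axis_um
condition
aligned     1738.25         0.73          75.34
random      1197.38         0.95          46.40
random: FFT peak 45 deg, flatness 1.8
aligned: FFT peak 90 deg, flatness 3.6
             random/aligned
metric
area                   1.50
circularity            0.75
major_axis             0.75
minor_axis             1.50
```

Six hours in, aligned-substrate cells are larger, less circular and longer;
their orientation spectrum peaks at 90° and is far from flat (flatness 3.6 vs
1.8 — an isotropic field's argmax is just speckle), and every shape metric
has already diverged between the conditions within 0.75–1.5 h of seeding.

## Command line

Each stage is also a subcommand of the `topocell` CLI:

```sh
topocell simulate --out sim/                      # built-in demo design
topocell segment  --manifest sim/manifest.csv --out masks/
topocell measure  --manifest sim/manifest.csv --masks masks/ --out shapes.csv
topocell align    --manifest sim/manifest.csv --out spectra.csv
topocell diverge  --shapes shapes.csv --pairs flat:aligned --out table1.csv
topocell ddct     --ct ct.csv --housekeeping 18S --calibrator flat --out expr.csv
topocell run      --out demo/                     # whole pipeline, one seed
```

`topocell run` is deterministic: the same config and seed produce
byte-identical CSV outputs, and every run writes a log with the seed, config
hash and per-stage timings.

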