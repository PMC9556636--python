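# mwacool

Three-dimensional analysis of vascular cooling ("heat-sink") effects on
hepatic microwave ablation (MWA), for researchers quantifying how a
perfused vessel near the antenna deforms and shrinks an ablation zone in
standardized ex vivo experiments.

A large vessel beside an MWA antenna extracts heat and indents the
clinically relevant white zone (WZ), risking incomplete tumour ablation.
This package implements the full serial-section analysis of that effect:

- **Planimetry** — per 2 mm cross section: WZ area `A_i`, maximum
  ablation radius `r_max` from the antenna point, clipping to the
  vessel-containing half (only that half enters the quantitative
  analysis), boundary radius at the vessel azimuth, and the fraction of
  the vessel disc still enclosed by the WZ.
- **Volumetry** — the truncated-cone (frustum) reconstruction
  `V = Σ (A_i + A_{i+1})/2 · d` over consecutive slices; an *idealized*
  uncooled ablation built from per-slice `½π r_max²` half-discs; the
  **cooling volume** (idealized − actual) and **cooling portion**
  (cooling volume as % of ablation volume).
- **Classification** — the semi-quantitative Type 0–III cooling scale
  (none / minor / moderate with vessel partly enclosed / major with
  vessel outside the ablation), operationalized with thresholds on the
  indentation ratio `ι = 1 − r(θ_vessel)/r_max` and the vessel enclosure
  fraction, plus cooling-type profiles against the 3D vessel-to-ablation-
  centre distance `ρ = √(d² + z²)`.
- **Energy balance** — coolant-absorbed energy `ΔQ = m·c_aqua·ΔT` and
  its fraction of the applied microwave energy.
- **Statistics** — *exact* (full-enumeration, midrank-tied) two-sided
  Mann–Whitney U for the small per-series samples, Kruskal–Wallis,
  Bonferroni-banded verdicts (significant at p ≤ 0.05/6 ≈ 0.008, trend
  up to 0.05), and LOESS smoothing of type profiles.
- **Synthetic phantom** — an ellipsoidal WZ (nominal 3.6 × 3.2 cm) with
  a vessel-side notch whose depth grows with flow rate and peaks when
  the vessel sits near the ablation border (ρ* = 7.5 mm), with analytic
  ground-truth volumes for parameter-recovery testing. The default
  factorial study is 3 antenna–vessel distances (2.5/5.0/10.0 mm) ×
  7 flow rates (0–500 ml/min) × 6 replicates = 126 runs at 100 W, 5 min,
  2 mm sections.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
import mwacool as mw

# one synthetic ablation: vessel 5 mm from the antenna, 100 ml/min
params = mw.PhantomParams(av_distance_mm=5.0, flow_ml_min=100.0, seed=7)
slices, truth = mw.generate_stack(params)

measurements = []
for s in slices:
    m = mw.measure_slice(s)
    m.av_distance_mm = params.av_distance_mm
    mw.classify_slice(m)
    measurements.append(m)

report = mw.stack_report(measurements, spacing_mm=2.0)
print(f"ablation volume : {report.ablation_volume_ml:.2f} ml")
print(f"cooling volume  : {report.cooling_volume_ml:.2f} ml "
      f"(analytic truth {truth.cooling_volume_ml:.2f} ml)")
print(f"cooling portion : {mw.round_half_up(report.cooling_portion_pct)}%")
print(f"slice types     : {[m.cooling_type for m in measurements]}")
```

prints

```
ablation volume : 6.58 ml
cooling volume  : 3.71 ml (analytic truth 2.98 ml)
cooling portion : 56%
slice types     : [1, 1, 1, 1, 2, 2, 2, 2, 1, 2, 2, 2, 2, 1, 1, 1, 1]
```

The ablation volume is the vessel-half WZ volume; the cooling volume is
the deficit against the idealized `r_max` ablation. The analytic truth
refers to the noise-free boundary: contour-tracing noise biases the
measured `r_max` upward and inflates the measured cooling volume — the
same mechanism that produces a nonzero apparent cooling volume even
without perfusion (set `boundary_noise_sd_mm=0` to recover the truth to
within a fraction of a percent). The per-slice grades show moderate
cooling (Type II) where the vessel passes near the ablation border and
minor cooling towards the poles.

The same analysis is available from a shell:

```sh
mwacool simulate --seed 1 --out slices.csv
mwacool volumes  --in slices.csv --out reports.csv
mwacool measure  --in slices.csv --out measurements.csv
mwacool profile  --in measurements.csv --out profile.csv --loess
mwacool report   --seed 1 --out study/     # full study, all tables
```

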