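# Methods

## The measurement problem

A large hepatic vessel running beside a microwave ablation antenna acts
as a heat sink: it extracts energy locally, indenting the white zone
(WZ, the irreversibly destroyed region) towards the vessel and — when
the effect reaches the ablation centre — shrinking the total ablation
volume. Because the deformation is directional, a per-slice 3D analysis
is required: single mid-plane sections miss most of it.

The package analyses a stack of serial cross sections cut every 2 mm
orthogonally to the antenna. In each section the WZ contour, the antenna
point and the vessel centre are known (traced, calibrated coordinates in
mm). The antenna point is the in-plane origin; the vessel lies on the +x
axis at the antenna–vessel distance `d`.

## Planimetry and volumetry

Per slice `i` we compute the WZ area `A_i` (shoelace, via shapely), the
maximum ablation radius `r_max` from the antenna point (attained at a
contour vertex), and the section clipped to the closed half-plane
through the antenna point perpendicular to the antenna→vessel axis,
keeping the vessel side. Only this half enters the quantitative
analysis: it isolates the cooling effect around the vessel, and the
contralateral half serves as the implicit uncooled reference through
`r_max`.

Volumes are reconstructed with the truncated-cone (trapezoidal) rule

    V = Σ_i (A_i + A_{i+1})/2 · d_2mm ,

converted mm³ → ml. The *idealized* ablation replaces each half-section
by the half-disc `½π r_max²`; the per-slice cooling area is the
difference (non-negative by construction, since the measured half lies
inside the antenna-centred `r_max` half-disc), the cooling volume is the
frustum difference `V_ideal − V_abl` (computed exactly as that
difference, so additivity holds bit-for-bit), and the cooling portion is
`100 · V_cool / V_abl`, tabulated to the nearest integer percent. The
portion is normalized by the ablation volume, not the idealized volume:
back-computation against the published median pairs fixes that
convention uniquely.

Accuracy of the frustum rule at the 2 mm spacing: on an analytic
half-ellipsoid with semi-axes a = 18 mm (axial), b = 16 mm sampled over
its full extent the error is −0.31% with second-order convergence in the
spacing. For generated stacks, whose last recorded slice stops short of
the ellipsoid pole, the missing end caps add a ~−1.8% deficit relative
to the continuous volume; cooling volumes are unaffected (the notch
vanishes well before the poles), which is why cooling-volume recovery is
accurate to ~0.1% while half-volume recovery carries the ~2% cap bias.

## Cooling classification

Each slice is graded on the ordinal Type 0–III scale: 0 none, I minor
indentation, II strong indentation with the vessel still partly enclosed
by the WZ, III strong indentation with the vessel outside the WZ. The
pictorial scheme is operationalized with two config-exposed thresholds
on the indentation ratio `ι = 1 − r(θ_vessel)/r_max`:

- `ι < τ_minor` → Type 0 (default τ_minor = 0.05);
- `τ_minor ≤ ι < τ_moderate` → Type I (default τ_moderate = 0.20);
- `ι ≥ τ_moderate`: Type III if the vessel-disc enclosure fraction
  `f = area(WZ ∩ vessel disc)/area(disc)` is 0, Type II if `0 < f < 1`,
  and Type I if `f = 1` (the deformation has not reached the vessel).

The thresholds are an operationalization choice — the original grading
was visual and no numeric values exist to recover — so a sensitivity
test verifies that scaling both thresholds by ±50% moves no noise-free
phantom slice by more than one type. Profiles aggregate grades against
the 3D vessel-to-ablation-centre distance `ρ = √(d² + z²)` (the vessel
runs parallel to the antenna, so its distance to the centre point grows
with the axial offset `z`), binned at 1 mm by default.

## Energy balance

For the perfused series with measurable coolant warming (≥ 100 ml/min),
`ΔQ = m · c_aqua · ΔT` with `m = flow · duration · density`,
`c_aqua = 4.186 kJ/(kg·K)` and density 1.0 g/ml (both config-exposed),
and the absorbed fraction is `100 · ΔQ / (P · t)`. At 100 W for 5 min
(30 kJ applied), a median ΔT of 0.6 K at 100 ml/min gives 4.19%, and
ΔT = 0.55 K at 500 ml/min gives 19.2%.

## Statistics

Two-group comparisons use a two-sided Mann–Whitney U test computed
*exactly* at the study's sample sizes (n = 6 per cell): pooled values
are midranked, and the null distribution of U is enumerated over all
C(n+m, n) group assignments by subset-sum dynamic programming on the
doubled (integer) midranks; the two-sided p sums both tails of the
symmetric distribution. A brute-force enumeration oracle confirms
equality for all n, m ≤ 7 including heavy ties. For min(n, m) > 8 the
tie-corrected normal approximation (scipy) is used. More than two groups
use Kruskal–Wallis (tie-corrected, chi-square reference); two identical
constant groups return H = 0, p = 1 rather than an error.

Multiplicity follows the study protocol: each perfused flow rate is
compared against the unperfused series within one distance (6
comparisons), so the Bonferroni significance level is 0.05/6 ≈ 0.008;
p-values in (0.008, 0.05] are reported as a trend. The divisor is
config-exposed — 6 is the only divisor consistent with the published
0.008 level, but the protocol does not state the family explicitly.

LOESS smoothing of type profiles uses tricube weights on the span-
nearest neighbours with local degree 1 (default) or 2, evaluated on an
explicit grid (default 100 points, span 0.5 — none of these are fixed by
the protocol). Windows that would be rank-deficient because boundary
points carry zero weight receive a vestigial 1e-9 weight; a still-
degenerate window raises an error naming the grid point.

## The synthetic phantom

No measured contours are deposited, so the pipeline is exercised on a
generative stand-in with analytic ground truth. The noise-free WZ
boundary in the section at axial offset `z` is star-shaped about the
antenna:

    r(θ, z) = r0(z) · [1 − κ(z) · exp(−Δθ² / 2σθ²)],
    r0(z)   = b √(1 − (z/a)²),
    κ(z)    = κ0 · L(Q; Q50(ρ)) · exp(−(ρ − ρ*)² / 2σρ²),
    Q50(ρ)  = Qc · e^(−ρ/ρc),   L(Q; Q50) = 1 / (1 + (Q50/Q)^s),  L(0) = 0,

with `ρ(z) = √(d² + z²)`. The three κ factors encode, respectively, the
saturated notch depth, a logistic flow response in log-flow whose
midpoint `Q50` falls exponentially with distance from the energy-dense
ablation centre, and a Gaussian peak of vulnerability where the vessel
approaches the ablation border.

Defaults and why (lengths mm, flows ml/min):

| parameter | default | meaning |
|---|---|---|
| a, b | 18, 16 | nominal uncooled ablation 3.6 × 3.2 cm |
| ρ*, σρ | 7.5, 3.0 | border-proximity peak of the cooling effect |
| Qc, ρc | 20, 4.0 | central flow demand and its decay length |
| κ0 | 0.73 | saturated fractional radial loss |
| s | 2.0 | logistic steepness in log-flow |
| σθ | 0.5 rad | azimuthal notch width |
| boundary noise | 0.2 | i.i.d. radial vertex noise (tracing error) |
| size jitter | 2% | per-replicate Gaussian factor on both semi-axes |
| min slice radius | 6.0 | smallest recordable cross-section radius |
| vertices | 256 | contour resolution (512 in recovery tests) |

κ0 and s were calibrated analytically against the qualitative behaviour
the generator must emulate: cooling appears peripherally from ≥ 2
ml/min, requires ≥ 10 ml/min at the ablation centre when d = 2.5 mm,
and the pooled mean-type profile peaks near ρ* = 7.5 mm. The size
jitter supplies the replicate-to-replicate spread real ablations show
(vertex noise alone is far too small, and without it any deterministic
volume difference — however tiny — becomes "significant" at n = 6). The
minimum recordable radius drops end-cap sections smaller than about the
vessel diameter, whose landmarks drown in tracing noise. Slices are
placed at multiples of the 2 mm spacing within |z| < a and the ±20 mm
sectioning span; the red zone is carried as the WZ dilated by 3 mm but
excluded from all volumes.

Ground truth (half-ablation volume, cooling volume, per-slice cooling
areas and types) integrates the closed-form boundary at 0.1 mm axial and
~2000-point angular resolution — far finer than the pipeline's 2 mm /
per-vertex sampling and independent of the polygon code under test.

Coolant temperature rises are drawn from a normal (mean 0.6 K, sd 0.1 K,
truncated at 0) for flows ≥ 100 ml/min — the only series where ΔT was
measurable; the sd is a free choice, as no per-series spread is
recorded.

What the phantom does *not* model: biophysical heat transfer (no bioheat
equation or FEM), diffuse parenchymal cooling, correlated tracing error,
rater disagreement in grading, repeat/exclusion bookkeeping of failed
ablations, and the real study's absolute volume scale. Passing tests
therefore demonstrate that the *analysis* is correct and recovers known
geometric truth, and that it reproduces the qualitative structure of the
real findings (border peak, central flow demand, volume loss only at
maximal flow next to the antenna) — not that the phantom's absolute
cooling magnitudes match ex vivo tissue.

## Numerical choices and degenerate inputs

- Areas, clipping, ray casting and disc overlap go through shapely;
  enclosure fractions within 1e-9 of 0 or 1 count as exactly 0 or 1.
- Folded (non-star-shaped) measured contours: the azimuthal radius takes
  the nearest boundary crossing and warns; no crossing at all is an
  error naming the azimuth.
- Negative per-slice cooling areas can only arise from floating-point
  noise and are clamped at 0 (warned above 1e-6 relative).
- A clip that leaves multiple pieces keeps the largest and warns; an
  empty clip, an origin outside the polygon, fewer than 2 slices,
  non-uniform spacing (> 0.01 mm), or a zero ablation volume in the
  cooling portion are hard errors.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-run seeds are spawned children, so
  run order never changes results.

## Problem sizes

The full synthetic study (126 runs, ~2100 slices at 256 vertices) runs
in ~10 s; the noise-free recovery battery (9 phantoms at 512 vertices
with high-resolution truth) in ~1 s. These sizes keep the whole test
suite and the acceptance script fast while leaving every comparison
well-powered for its tolerance.

## Known limitations

- `r_max` is measured from the antenna point, not a shape centroid; the
  original software's convention is unrecorded, so this is a documented,
  overridable choice (the idealized ablation is antenna-centred by
  construction).
- The vertex-noise bias on `r_max` (a maximum over noisy vertices)
  inflates measured cooling volumes by a flow-independent offset; the
  real analysis shares this property (nonzero cooling volume at 0
  ml/min), but the phantom's offset magnitude is set by the noise sd,
  not by tissue.
- Published real-data medians and p-values are not reproducible from
  synthetic data; only direction-level patterns are asserted.
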