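# Methods

This note documents the models, algorithms and numerical choices behind
`sarcolattice`, what its synthetic data do and do not emulate, and the known
limits of each read-out.

## Imaging model and channel scheme

All image analysis assumes the two-channel scheme of label-free multiphoton
muscle imaging: channel 1 is forward-scattered SHG and contains the periodic
myosin-II band signal of sarcomeres plus extracellular fibrillar collagen;
channel 2 is the backward-collected autofluorescence (>460 nm) of the muscle
cell body and is dark on collagen-only pixels. Stacks are
(slices × rows × cols) with an isotropic lateral pixel size (µm/px, carried in
TIFF resolution tags) and an independent z-step. Calibration is applied
exactly once at analysis time; all areas are reported in µm² and densities per
100 µm², independent of pixel size. Channel order on disk is resolved by an
explicit `channel_map` and never guessed, because the two channels play
asymmetric roles.

## Collagen quantification

Fibrosis is quantified as collagen area per muscle area on cross-sections:

1. **Muscle mask** — median filter (3 px), Otsu threshold on the
   autofluorescence channel, hole filling, removal of objects < 5 µm².
2. **Collagen mask** — median filter and Otsu on the SHG channel, then
   *set-difference* with the muscle mask, then removal of objects < 5 µm².
3. **Fraction** — 100 · Σ collagen / Σ muscle over slices.

Set-difference (mask subtraction) was chosen over raw intensity subtraction
because intensity subtraction is detector-gain dependent, whereas automatic
per-channel thresholds make the fraction invariant to uniform intensity
rescaling (verified by test). The 5 µm² small-object floor suppresses shot
noise without deleting resolvable collagen streaks; it, the median size and
the threshold method are configurable (`CollagenConfig`). Consequences of the
floor: collagen deposits smaller than ~5 µm² are by construction invisible to
the measure. A uniform-intensity frame has no Otsu separation and raises a
degenerate-threshold error rather than returning an arbitrary mask.

## Fiber morphometry: CAS

**Pre-masking.** Single-fiber SHG frames are first multiplied by the cell mask
derived from the autofluorescence channel (median + Otsu + hole filling), so
extracellular collagen — which also emits SHG and would contaminate both
orientation statistics and defect detection — never enters the analysis.

**Local orientation.** Gaussian-derivative structure tensor: derivatives at
scale σ_g, products smoothed at scale σ_i, axial angle = ½·atan2(2J_rc,
J_cc − J_rr) (the orientation of dominant intensity variation, i.e. the
myofibril long axis), energy = λ₁ − λ₂. Pixels with energy below 10 % of the
slice's 95th energy percentile are invalid (flat regions carry no
orientation); the comparison is strict, so a perfectly flat slice has no
valid pixels.

**Scales.** σ_g = 0.15 × spacing and σ_i = 0.3 × spacing (≈1.5 px and 3 px at
the default 2 µm spacing / 0.2 µm px). Larger, more conventional scales
(σ_g ≈ spacing/4, σ_i ≈ spacing) were evaluated against the analytic oracle
below and rejected: they average orientations across myofibril boundaries,
which biases CAS upward by up to ~0.02 at 20° jitter because mixing
oppositely-signed deviations produces near-axis angles. At the chosen scales
the worst oracle error is ≈0.011 (20° jitter), noise-free and at SNR 5 alike.
A coherence-gated validity cut was also evaluated and rejected: it removes
pixels preferentially from strongly misaligned strips and biases the sample
of valid pixels itself.

**Axis and CAS.** The main fiber axis comes from the second central moments of
the cell mask; when the mask is nearly isotropic (major/minor axis ratio
< 1.2) it falls back to the energy-weighted axial circular mean of the
orientation field, and the method used is recorded. CAS is the *unweighted*
mean of cos(Δθ) over valid pixels, Δθ folded into [−90°, 90°), so CAS ∈ [0, 1]
and a 90° deviation contributes exactly zero. Energy weighting is available
behind a flag (`energy_weighted_cas`) but off by default — the plain mean is
the simplest reading of the statistic. Before CAS the valid mask is eroded by
0.5 × spacing: tensor responses within one integration scale of the mask edge
mix band and background orientations and would bias the mean upward.

**3D handling.** Stacks are analysed per slice and pooled: stack CAS is the
valid-pixel-count-weighted mean of slice CAS; counts and areas are summed for
VD. Full 3D tensor analysis was not used because z-sampling is strongly
anisotropic in this kind of data.

## Fiber morphometry: vernier density

A vernier is a half-period axial register shift between neighbouring
myofibrils; in the band image it appears as a Y where one band forks. The
detector works in the phase domain rather than on a skeleton:

1. Convolve the masked slice with a complex Gabor filter tuned to the
   sarcomere frequency along the fiber axis (envelope σ = 0.6 × spacing).
2. Demodulate by the carrier e^{−2πi s/λ} (s = axial coordinate). The
   argument of the resulting phasor is the local register offset: ~0 in
   in-register lattice, ~π across a shifted domain.
3. Mark domain-wall pixels where the phasor anti-aligns across a straddle of
   1.2 × (Gabor σ) perpendicular to the fiber axis, gated on striation
   amplitude (>10 % of the in-mask 95th percentile) so flat or noise-only
   regions cannot flip.
4. Each connected wall segment ends either at the fiber edge (the offset
   simply runs out of the fiber — not an event) or at a dislocation core.
   Events are the axial extremes of wall segments that lie inside the mask
   eroded by 0.8 × spacing; extremes within one spacing merge, so a single
   physical junction is never double-counted.

A skeleton-branch-point detector (binarise bands, skeletonise, count ≥3-
neighbour pixels) was implemented first and abandoned: at a half-period
dislocation the binarised bands as often connect diagonally across the seam
or terminate without forking, so branch points recover only a fraction of
true events even noise-free. The phase detector recovers 12/12 injected
events noise-free and ≥11/12 at SNR 5 with zero false positives on ordered
fibers. On strongly jittered fibers (≈20° between strips) occasional extra
events appear at strip boundaries where misaligned lattices genuinely pass
through anti-alignment; these are real register mismatches of the rendered
lattice, and they move VD in the same direction as true dystrophic
remodeling.

VD = 100 · (# events) / (analysed fiber area in µm²). The analysed area is
the cell-mask area, which for the synthetic scenes sits a few percent below
the geometric fiber area (soft mask edges under noise) — the dominant term in
the small VD biases seen in tests. Detection is wholly deterministic; all
randomness lives in the generator.

## Passive mechanics

Stress is force/PCSA (1 mN/cm² = 0.01 kPa). Per annotated strain step the
*dynamic* stress is the maximum within 0.5 s of onset and the *elastic*
stress is the mean over the final 10 % of the hold; both windows are
configurable and robust to sampling rate. Each component is fitted by least
squares with σ = aε² + bε, origin-constrained because passive stress is zero
at reference length (an `intercept` escape hatch exists for
offset-contaminated recordings; the constant does not enter the tangent).
Stiffness is the tangent 2a·0.10 + b at 10 % stretch — an interior point of
the 5–12.5 % protocol — in kPa per unit strain, with a per-percent column as a
convenience. The fit requires ≥3 distinct strains in (0, 0.2]; exact
quadratic data are recovered to machine precision (tested at 1e−9 relative).

## Active mechanics

PCSA = m / (L₀ · L_f/L₀ · ρ) with ρ = 1.06 g/cm³; L_f/L₀ is 0.45 for EDL and
1.0 for diaphragm strips. Specific tension is the trace's peak force divided
by PCSA, in kPa. These are pure unit arithmetic and are tested to 1e−12.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Striated fibers.** A rotated rectangular fiber (default ≈0.85/0.45 of the
  frame; 25 × 16 µm in the 400 µm² test scenes) split into myofibril strips
  of width 5 µm running along the axis. Band intensity is a raised cosine
  (amplitude 1.0) along each strip's own axis; each strip's angle is the
  fiber axis plus a N(0, σ_jitter) deviation drawn per strip and slice. The
  per-pixel injected angle field is stored, and the ground-truth CAS is its
  brute-force mean cosine — the oracle the estimator is judged against
  (consistency asserted to 1e−12). Default geometry 0.2 µm/px, 2.0 µm
  spacing, 512² frames (tests use 160–256² for runtime).
* **Verniers** are rendered as half-period phase dislocations at strip
  boundaries: beyond the event's axial position the outer strip's band phase
  gains π over a transition of λ/16, producing exactly one Y-junction per
  event. Auto-placement distributes events round-robin over interior strip
  boundaries with ≥2 spacings separation. Offsets on one boundary accumulate,
  so consecutive events alternate shifted/in-register domains, as real
  vernier pairs do.
* **Cross-sections.** A wavy-boundary elliptical muscle body (bright in both
  channels, mild axial texture in SHG) plus extracellular collagen laid as
  thick random-walk streaks (radius 2–3 px) outside the muscle mask until the
  pixel budget matches the requested fraction within 0.5 percentage points;
  the realized fraction is recorded. Streaks below ~10 µm² are not laid —
  deposits that small are not resolvable as fibrillar streaks at this
  magnification — and small budget remainders thicken an existing streak
  instead.
* **Noise** is Gaussian read noise (SNR = amplitude/σ; tests use σ = 0.2,
  i.e. SNR 5) plus optional Poisson photon noise; images are clipped at 0.
* **Traces.** Stress-relaxation steps jump to σ_dyn = a_d ε² + b_d ε and decay
  exponentially (τ) to σ_el = aε² + bε; dynamic coefficients default to twice
  the elastic ones, a typical dynamic/elastic ratio for passive muscle, and
  are overridable. Twitches are alpha-functions whose sampled maximum equals
  the requested peak exactly; tetani ramp linearly to an exact plateau with an
  optional non-negative sin² stimulation ripple.

Everything is driven by a single integer seed through `numpy`'s Generator;
identical (scene, seed) pairs are bit-identical.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: optical point-spread and polarization physics of
SHG, depth-dependent attenuation and scattering, fixation artifacts, fiber
curvature and branching, myonuclei and mitochondrial autofluorescence
structure, partial-volume effects at oblique fiber orientations, and the
heavy-tailed inter-animal variability of real dystrophic tissue. Results on
real stacks should be validated against manual counts on a subset.

## Statistics and pipeline

Group contrasts use Welch's unequal-variance t (two-sided,
Welch–Satterthwaite df; asserted against the closed form to 1e−9). Units of
analysis mirror the measurements: cryosections for collagen, single fibers
for CAS/VD, muscles/strips for mechanics; no multiple-testing correction is
applied by default (single contrast per muscle). The `run_pipeline` driver
derives per-sample seeds arithmetically from the study seed, isolates
per-sample failures, and writes no timestamps into result files, so a rerun
with the same config is byte-identical.

## Numerical details and edge cases

* Axial angles are stored mod 180°; folding into [−90°, 90°) precedes every
  cosine, so CAS is bounded in [0, 1] by construction and a deviation of
  exactly 90° contributes zero (no special-casing).
* Degenerate inputs fail loudly: empty cell masks, all-zero or uniform
  channels, missing pixel-size calibration (a TIFF resolution of exactly
  1 px/unit — the writer default for uncalibrated files — counts as missing),
  non-monotone trace time, overlapping or non-increasing strain steps,
  sub-2 px sarcomere spacing (aliased lattice).
* The Monte-Carlo stiffness check simulates whole experiments (noisy sampled
  traces through extraction and fitting) rather than perturbing the four
  stress points directly: the elastic plateau is an average over the hold
  tail, and that averaging is part of the measurement. Perturbing the bare
  points at the same noise level has an analytic success probability of only
  ≈0.88 for a ±5 % band, i.e. it tests the noise model, not the estimator.
* Problem sizes in tests (160–256 px frames, 3–5 seeds per condition, 10
  fibers per group in the replication check) were chosen as the smallest
  scenes that keep ≥8 myofibril strips and ≥10 band periods in view, which is
  where the estimators' asymptotics hold.

## Known limitations

* CAS carries a small upward bias (≤0.011 in validation) from residual
  orientation mixing at strip boundaries; it grows with angular disorder.
* VD recall degrades on strongly disordered fibers because register walls
  between misaligned strips blur; in the dystrophic-like regime VD remains a
  monotone, direction-preserving read-out rather than an unbiased count.
* The collagen measure is blind to deposits below the small-object floor and
  to non-fibrillar collagen that yields no SHG signal.
* The stiffness tangent is only meaningful inside the strain range actually
  sampled; extrapolation beyond 12.5 % strain is not supported.
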