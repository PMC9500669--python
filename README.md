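# sarcolattice

Label-free structure–function analysis of skeletal muscle from two-channel
second-harmonic-generation (SHG) microscopy and force transducer recordings.

In dystrophic muscle (e.g. dystrophin-deficient mouse models of Duchenne
muscular dystrophy), weakness has two candidate structural substrates:
**extracellular fibrosis** (collagen replacing contractile tissue) and
**intracellular remodeling of the myofibrillar lattice** (myofibrils losing
their parallel, in-register arrangement). SHG microscopy sees both without any
staining — myosin-II and fibrillar collagen are the two strong intrinsic SHG
emitters — so a single imaging modality can quantify them side by side and
relate them to passive and active mechanics. `sarcolattice` implements that
pipeline for researchers working with muscle multiphoton data:

* **Collagen content** of muscle cross-sections. The forward-scattered SHG
  channel contains myosin *and* collagen; the backward autofluorescence
  channel (>460 nm) marks the muscle cell body only. Both channels are
  auto-thresholded (Otsu) and collagen is the SHG mask set-minus the muscle
  mask; fibrosis is reported as collagen area per muscle area (%).
* **Sarcomere-lattice morphometry** of single fibers, after removing
  extracellular collagen with the autofluorescence-derived cell mask:
  - **CAS** (cosine angle sum): mean over striation-carrying pixels of
    cos(θ<sub>local</sub> − θ<sub>axis</sub>), where θ<sub>local</sub> is the
    local lattice orientation from a Gaussian structure tensor and
    θ<sub>axis</sub> the main fiber axis. CAS = 1 for a perfectly parallel
    lattice; angular disorder pulls it down.
  - **VD** (vernier density): Y-shaped lattice shifts between neighbouring
    myofibrils — half-period register dislocations — detected by complex
    Gabor demodulation of the striation pattern, counted per 100 µm² of
    analysed fiber area.
* **Passive mechanics** from stress-relaxation protocols: per strain step the
  stress decomposes into a *dynamic* peak and an *elastic* plateau; each
  component is fitted with an origin-constrained quadratic σ = aε² + bε and
  stiffness is the tangent dσ/dε at 10 % stretch (kPa per unit strain).
* **Active mechanics**: specific tension = peak twitch/tetanus force per
  physiological cross-sectional area, PCSA = m / (L₀ · L_f/L₀ · ρ) with
  ρ = 1.06 g/cm³ (L_f/L₀ = 0.45 for EDL, 1.0 for diaphragm strips).

Because raw stacks and traces from such studies are typically not deposited,
the package ships a first-class synthetic-data module (`sarcolattice.synth`)
that renders striated fibers, collagen-bearing cross-sections and force traces
with exact ground truth. Every analysis stage is validated against it.

## Worked example

```python
import sarcolattice as sl
from sarcolattice.synth import auto_vernier_events
from dataclasses import fields

# a 400 um^2 fiber with 12 injected Y-junction verniers at SNR 5
scene = sl.FiberScene(shape=(1, 160, 160), fiber_axis_angle_deg=15.0,
                      fiber_length_um=25.0, fiber_width_um=16.0,
                      noise_gaussian_sd=0.2)
events = auto_vernier_events(scene, 12, seed=100)
scene = sl.FiberScene(**{**{f.name: getattr(scene, f.name) for f in fields(scene)},
                         "vernier_events": events})
stack, truth = sl.generate_striated_fiber(scene, seed=1)
fm = sl.analyze_fiber_stack(stack, spacing_um=2.0)
print(f"true CAS    {truth.true_cas:.3f}   measured CAS {fm.cas:.3f}")
print(f"true VD     {100*truth.true_vernier_count/truth.true_fiber_area_um2:.2f}"
      f"   measured VD  {fm.vd_per_100um2:.2f}  (#/100 um^2)")

sec, sec_truth = sl.generate_cross_section(21.4, seed=1, shape=(1, 256, 256),
                                           noise_gaussian_sd=0.2)
res = sl.collagen_fraction(sec)
print(f"collagen: generated {sec_truth.true_collagen_fraction_pct:.2f}%"
      f"  measured {res.collagen_fraction_pct:.2f}%")

trace, _ = sl.generate_stress_relaxation(100.0, 20.0, tau_s=1.0,
                                         noise_sd_kpa=0.05, seed=1)
sr = sl.analyze_stress_relaxation(trace)
print(f"elastic stiffness {sr.elastic_stiffness_kpa:.2f} kPa/strain (truth 40.00)")
```

prints

```
true CAS    1.000   measured CAS 0.999
true VD     3.00   measured VD  3.12  (#/100 um^2)
collagen: generated 21.04%  measured 21.57%
elastic stiffness 40.15 kPa/strain (truth 40.00)
```

The defect-free lattice reads CAS ≈ 1; the 12 injected verniers on ~400 µm²
give VD ≈ 3 per 100 µm² (the measured value differs by the cell-mask area and
one spurious/missed event at this noise level); the generated ~21 % collagen
fraction is recovered within half a percentage point; and the tangent of the
quadratic fit at 10 % stretch recovers the generating stiffness.

## Command line

```bash
sarcolattice synth fiber --seed 1 --n-verniers 12 --noise-sd 0.2 --out fiber.tif
sarcolattice fiber --in fiber.tif --pixel-size 0.2 --spacing 2.0 --out fiber.csv
sarcolattice synth section --fraction 21.4 --out section.tif
sarcolattice section --in section.tif --out section.csv
sarcolattice mech --trace trace.csv --geometry geom.yaml --out mech.csv
sarcolattice run --config study.yaml --out-dir results/
```

`sarcolattice run` drives a whole two-group study (fibers, sections, traces
per group), writes long-format result CSVs and Welch-t group comparisons, and
isolates per-sample failures so one corrupt input does not sink the run.

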