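# puffoct

Analysis pipeline for **multi-spot air-puff OCT corneal elastography**: from
depth-encoded nine-channel M-scan images to anterior-surface displacement
profiles, transient deformation parameters, and the **asymmetry vector**
that localizes focal biomechanical imbalance such as a keratoconus cone.

## The problem and the method

An air puff indents the cornea for a few tens of milliseconds. A swept-source
OCT system probes the deformation simultaneously at nine spots — one central
(SC) and eight peripheral (S1…S8) on a 1.1 mm ring at 45° spacing — by giving
each beam its own path-length offset ΔLᵢ, so each spot occupies a private
depth window of a single A-scan stream (space-division multiplexing with
depth encoding, 10 µs per sample at a 100 kHz sweep rate).

From each spot's displacement-vs-time profile *d(t)* the package extracts
nine descriptors: displacement amplitudes DA₁ (first indentation peak), DA₂
(intervening minimum), DA₃ (second peak of a dual-indentation response),
their latencies t_DA₁–t_DA₃ from deformation onset, the symmetric mean
(DA₁+DA₃)/2, the ratio DA₁/DA₃, and the area under the displacement curve.

The asymmetry statistic pairs opposite peripheral spots on the four
meridians. Each pair (a, b) yields a meridional vector

    m_ab = |v_a − v_b| · û(toward the higher-valued spot)

and the **asymmetry vector** is the planar sum **A** = Σ m_ab. Its magnitude
quantifies, and its azimuth localizes, the biomechanical imbalance: softer
(e.g. ectatic) regions deform more, so **A** points at them. The statistic is
linear in the per-spot values, invariant to common offsets, and equivariant
under 45° label rotation.

Supporting modules provide: a synthetic-acquisition generator with known
ground truth (the only way to test the pipeline quantitatively — no public
air-puff OCT datasets exist), worst-case temporal down-sampling error
analysis, repeatability statistics (circular SD of azimuths, normalized
magnitude SD), the instrument's optical design arithmetic (dₛ = f₁·tan α
spot geometry, k-clock depth budget, axial sag, Gaussian depth of focus,
laser-safety margins), and polar-plot/heat-ring reporting.

## Worked example

```python
import puffoct as po

# a keratoconus-like eye: 50% excess compliance centred at 270 deg (S7)
model = po.CornealComplianceModel(cone_excess=0.5, cone_azimuth_deg=270.0)
truth = po.simulate_displacement(model, po.StimulusProfile())
mscan = po.render_mscan(truth)                       # 9-channel M-scan image
profiles = po.profiles_from_mscan(mscan)             # surface tracking
params = po.extract_all(profiles)                    # the nine descriptors
values = {s: params[s].da1_um for s in truth.layout.peripheral_labels}
vec = po.AsymmetryVector.from_values(values, truth.layout)
print(f"S7 DA1 {params['S7'].da1_um:.1f} um, S3 DA1 {params['S3'].da1_um:.1f} um")
print(f"asymmetry vector: {vec.magnitude:.1f} um at {vec.azimuth_deg:.1f} deg")
```

prints

```
S7 DA1 438.8 um, S3 DA1 292.5 um
asymmetry vector: 189.8 um at 270.0 deg
```

The spot over the soft cone (S7) deforms ~146 µm more than its opposite
(S3); the neighbouring meridians contribute smaller differences in the same
direction, giving a 189.8 µm vector that points at the cone azimuth (270°)
exactly, because the cone sits on a spot meridian.

The same pipeline is scriptable from the shell:

```bash
puffoct run --seed 11 --out run1        # simulate -> track -> extract -> report
puffoct optics                          # instrument design report table
puffoct downsample run1/profiles.csv --dt-us 250
```

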