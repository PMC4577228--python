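# mlcedge

Rounded leaf-end effects of a multileaf collimator (MLC) on penumbra width
and radiation field offset: analytic leaf-position algorithms, a
primary-fluence ray tracer, and beam-profile edge analysis.

## The problem

A single-focused MLC moves its tungsten leaves linearly, so the leaf tip is
machined as a circular arc (radius R, typically 4-25 cm) to approximate beam
divergence at every field position.  The arc partially transmits the beam,
which separates three edge definitions on the scoring plane for a leaf at
nominal position x_N:

* **nominal position** N — projection of the mechanical tip E, where
  x_E = x_N · SCD/SAD;
* **geometric position / light-field edge** G — projection of the source ray
  grazing the leaf outline (arc tangency, clamped to the tip corners when the
  tangency leaves the leaf slab);
* **physical position / radiation-field edge** P — where the relative
  fluence is 50%.  Analytically, P is the intercept of the secant ray whose
  in-leaf chord equals one half-value layer L = −ln(0.5)/μ.

The differences LPO = G − N (leaf position offset), RFO = P − G (radiation
field offset) and PNO = P − N = LPO + RFO are the calibration constants a
treatment-planning system needs; getting them wrong shifts every field edge
by tenths of a millimetre, which matters for stereotactic and IMRT delivery.

`mlcedge` implements:

* **geometry** — the 2-D leaf cross-section (arc + flat faces) and exact
  analytic ray-path lengths through it;
* **analytic** — the tangent construction for G and the half-value-layer
  secant construction for P (arc-arc system with proximal/distal-flat
  fallbacks), with offset bookkeeping in mm;
* **fluence** — relative primary energy fluence on the scoring plane for an
  extended Gaussian focal spot (FWHM 0.5-3 mm), ray-traced by exponential
  attenuation exp(−μ·path) through the studied leaf and its opposing
  partner; deterministic kink-aware Gauss-Legendre quadrature or Monte
  Carlo source sampling;
* **profiles** — profile normalisation, n-peak Gaussian edge fitting
  f(x) = Σ aᵢ·exp(−((x−bᵢ)/cᵢ)²), the 50% field edge and the 20-80%
  penumbra width;
* **bounds** — why the half-value rule systematically *underestimates* the
  radiation field offset for an extended source (chord-sagitta bound and the
  three-part source inequality);
* **experiments** — sweeps over radius × source size × nominal position, and
  synthetic fixtures with closed-form ground truth.

Default machine constants: SAD 100 cm, SCD 46 cm (leaf middle plane),
leaf height 8 cm, μ = 0.96 cm⁻¹ (1.5 MeV primary photons in tungsten),
maximum half field 20 cm.

## Worked example

Analytic positions for the 15 cm leaf end at nominal position 10 cm:

```sh
$ mlcedge analytic --radius 15 --nominal 10
{
 "x_nominal_cm": 10.0,
 "x_mechanical_cm": 4.6,
 "x_geometric_cm": 9.842434719383773,
 "x_physical_cm": 9.851632196888808,
 "lpo_mm": -1.575652806162271,
 "rfo_mm": 0.09197477505034968,
 "pno_mm": -1.4836780311119213
}
```

The light-field edge sits 1.58 mm short of the nominal position (the arc tip
projects inside the field), and the radiation-field edge is a further
0.09 mm into the shadow.  Simulating the same edge with a 1 mm FWHM focal
spot and analysing the profile:

```sh
$ mlcedge simulate --radius 15 --nominal 10 --fwhm 1 -o profile.csv
wrote 601 samples to profile.csv
$ mlcedge analyze profile.csv
{
 "field_edge_cm": 9.8649524211914,
 "penumbra_width_mm": 1.0346964454239327,
 "rmse": 0.005057385637810518,
 "n_peaks": 3,
 ...
}
```

The simulated 50% edge (9.865 cm) lies about 0.14 mm beyond the analytic
physical edge: with an extended source, the unattenuated rays from the
field-side half of the focal spot outweigh what the shadow-side half loses,
so the half-value-layer rule underestimates the offset.  In library form:

```python
from mlcedge import TreatmentGeometry, leaf_positions, compute_offsets

geom = TreatmentGeometry()
offsets = compute_offsets(leaf_positions(geom, nominal_x=10.0, radius=15.0))
print(offsets.rfo)   # 0.0920 mm
```

Key quantities the package reproduces (Table-style geometry above):

* mean analytic RFO for R = 15 cm over nominal positions −20…20 cm:
  **0.095 mm**, essentially flat across the field;
* mean ray-traced RFO for R = 15 cm with a 1 mm FWHM source: **0.237 mm**,
  a near-constant ~0.14 mm above the analytic curve;
* simulated PNO at the extreme configuration R = 25 cm, nominal −20 cm:
  **−10.18 mm** (corner-dominated edge);
* penumbra width grows monotonically with source size, and R = 15 cm
  minimises the penumbra-width sum across the field.

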