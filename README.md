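# vippgeom

Geometric analysis toolkit for Vipp1/ESCRT-III polymer lattices: helical
filaments, their diffraction signatures, and the planar sheets, spirals and
rings the same protein forms on membranes.

Vipp1 (an ESCRT-III superfamily protein of cyanobacteria and chloroplasts)
polymerises into helical filaments, dome-shaped rings and — on supported
lipid bilayers — planar spirals and crystalline sheets.  All of these share
one lattice: ESCRT-III-like protofilaments of side-by-side hairpins spaced
~54 Å apart, packed laterally ~32.5 Å apart.  This package implements the
geometry connecting those polymer forms:

- **`core_lattice`** — helical symmetry (rise Å / twist °) to k-start strand
  families: azimuthal step, handedness, strand pitch, inter-strand axial
  spacing, and the nearest-neighbour lattice vectors at a given radius
  (whose start numbers are, up to sign, the dominant Bessel orders n).
- **`diffraction`** — the helical selection rule
  `Z = (n·twist/360 + m)/rise`, layer-line prediction, simulated power
  spectra of projected lattices, and the grid search inverting indexed
  layer lines back to candidate (rise, twist) pairs.
- **`unroll`** — cylindrical projection: map a helical lattice (points or a
  3D density raster) at radius r onto the plane via (x, y) = (r·φ, z), and
  measure the line-family spacings of the resulting 2D lattice.
- **`planar_model`** — spiral-form fitting (Archimedean r = a + bθ vs
  exponential r = a·e^{bθ}, AIC selection), the curvature-limit model (the
  inter-ridge spacing can only compress to ~41 Å or stretch to ~61 Å, so a
  13.4 nm-wide planar filament cannot curl below a ~103 nm centerline
  diameter — tighter rings must tilt out of plane), C_N ring geometry and
  protofilament counting.
- **`afm_synth`** — synthetic AFM height images (TIFF + JSON sidecar) of
  sheets, spiral fields, ring fields, filaments and growth time series,
  with defaults set to the measured statistics and a ground-truth table per
  rendered object.
- **`afm_measure`** — the matching measurement pipeline: FFT ridge
  periodicity, object detection/classification, minimal-enclosing-circle
  diameters, skeleton-based widths, height offsets, central-ring
  protrusion, and per-interval growth velocities.
- **`io` / `cli`** — MRC and TIFF+sidecar readers/writers, configuration,
  and the `vippgeom` umbrella command.

## Worked example

The refined Vipp1Δα6 L3 filament has rise 2.159 Å and twist 85.495°, a
24.4 nm outer diameter and a 12.7 nm lumen (mid-wall radius 92.75 Å):

```python
>>> from vippgeom import presets, near_axial_family, principal_vectors, start_family
>>> sym = presets.VIPP1_DA6_L3
>>> near_axial_family(sym, 25)
21
>>> principal_vectors(sym, sym.mid_wall_radius_A, 25)
(4, 17)
>>> start_family(sym, 4).axial_spacing_A
43.13207547169815
```

The 21-start family runs nearly parallel to the filament axis (step
−4.6°); the two nearest-neighbour lattice directions are the left-handed
4-start (the protofilament-stacking direction, inter-strand spacing
43.1 Å — the surface ridges) and the right-handed 17-start (the
ESCRT-III-like protofilaments themselves).  The same numbers from the
command line:

```sh
$ vippgeom lattice --rise 2.159 --twist 85.495 --r-lumen 63.5 --r-outer 122 --kmax 25
k,step_deg,handedness,strand_pitch_A,axial_spacing_A,near_axial,principal,spacing_at_midwall_A
...
4,-18.02,left,172.53,43.13,False,True,30.42
...
```

The curvature-limit model, with the measured spacing bounds:

```sh
$ vippgeom curvature-model
{
 "s0_A": 54.0, "s_min_A": 41.0, "s_max_A": 61.0, "width_A": 134.0,
 "min_planar_diameter_nm": 103.37142857142858,
 "requires_tilt_at_37nm": true
}
```

A strictly planar filament bottoms out at a ~103 nm centerline diameter;
the ~37 nm rings observed in spiral centres therefore require the filament
to tilt out of the membrane plane.

Synthetic AFM round trip:

```python
>>> from vippgeom.afm_synth import synth_spiral_field
>>> from vippgeom.afm_measure import detect_objects, object_morphometrics
>>> img, truth = synth_spiral_field(n_spirals=100, seed=1)
>>> report = object_morphometrics(detect_objects(img), img)
>>> spirals = report.per_object[report.per_object.kind == "spiral"]
>>> round(spirals.diameter_nm.mean(), 1), round(truth.diameter_nm.mean(), 1)
(87.5, 87.5)
```

## Acceptance script

`scripts/acceptance.py` recomputes the toolkit's headline quantities from
scratch — the near-axial and principal start families of the three refined
lattices, the 4-start pitch, and the synthetic-AFM recoveries (ridge
period, spiral diameter, filament width, growth rate, protofilament
count) — by running the generators and measurement pipeline end to end:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Limitations

The synthetic AFM generator does not model tip convolution, scanner drift
or tapping-mode physics, and vendor AFM file formats are out of scope; see
`docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
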