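# chemmorph

Headless 2D chemical drawing with morphing animations: a scene model of
atoms, bonds and annotations; MDL MOL V2000 import/export with structure
insertion and attachment; and a morphing engine that interpolates two
depictions — shape and colour, with cross-dissolve for unmatched content —
into animation frames for visualising molecular vibrations and reaction
mechanisms, rendered to SVG, PNG or animated GIF.

It is aimed at chemistry educators and tool builders who want reproducible
structure animations from scripts or pipelines rather than an interactive
editor: every command is deterministic (same inputs, byte-identical
outputs).

## The model in brief

A `Drawing` holds up to 100000 atoms (a hard capacity), bonds
(single/double/triple/aromatic, wedge and hash stereo), annotations and an
optional background raster. Morphing a source drawing *S* into a target *T*
over *N* frames evaluates, at each t_k = k/(N−1):

- **paired atoms** move linearly, p(t) = (1−t)·p₀ + t·p₁, with RGB channels
  blended as round((1−t)·c₀ + t·c₁);
- **unmatched content** cross-dissolves: source-only elements fade out with
  opacity 1−t while target-only elements fade in with opacity t (or shrink
  toward their centroid in `--fade-mode shrink`);
- the pairing itself (`auto_correspond`) groups atoms by element and matches
  greedily by nearest position, with deterministic tie-breaks and an explicit
  override available.

Region warping for annotations and backgrounds uses the two classical
constructions: **three-point (affine) mapping** over triangular sections,
and **four-point (projective) mapping** over square areas, solved by the
unit-squares method — the homography is factored through maps between the
unit square and each quadrilateral, with an exact affine shortcut when the
quad is a parallelogram.

Structure attachment follows the leftmost-atom convention: the guest
structure's atom with the smallest x-coordinate is the coupling atom, placed
1.5 scene units to the right of the chosen host atom and joined by a single
bond. Molfile export never truncates: files beyond the V2000 record limit of
999 atoms/999 bonds are written in full with a machine-readable
`CompatibilityWarning` per breached limit.

## Worked example

Animate the scissoring vibration of water and decode the result:

```sh
chemmorph fixture water water.json
chemmorph vibrate water.json --preset scissoring --amplitude 0.15 \
    --out vib --frames 5 --gif vib.gif
python -c "from PIL import Image; print(Image.open('vib.gif').n_frames)"
```

This writes nine SVG frames (`frame_0000.svg` … `frame_0008.svg`) and prints

```
9
```

— two 5-frame steps (equilibrium → opened by 0.15 rad → equilibrium) share
their junction frame, so the sequence totals 5 + 5 − 1 = 9 frames. The same
pipeline is available from Python:

```python
from chemmorph import fixtures, vibration_preset, run_sequence

seq = vibration_preset(fixtures.water(), "scissoring", 0.15, n_frames=5)
frames = run_sequence(seq)       # 9 drawings
```

A two-step reaction sequence (the SN2 substitution fixtures `sn2_pre` /
`sn2_post`) works the same way through `chemmorph sequence steps.json --out
frames --gif sn2.gif`.

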