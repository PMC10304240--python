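# mitolens

Optical simulation of the **lens mitochondrion** — the giant (~2 µm)
mitochondrion that sits in the light path of tree-shrew cone
photoreceptors, packed with a *cubic membrane*: twelve lipid bilayers
folded along a gyroid surface that splits the organelle into two
interpenetrating labyrinth compartments. Because the membrane spacing
(~400 nm) is comparable to visible wavelengths, the organelle is a
candidate micro-optic: a weak ball lens, a mild waveguide, and an
imperfect UV-rejecting interference filter. `mitolens` lets you
quantify all three from first principles.

The package is aimed at computational biophysicists and photonics
researchers who want a tractable (minutes, one core) alternative to
full-wave FDTD for sphere-confined membrane assemblies.

## Model

* **Geometry.** A sphere of radius R = 1 µm clipped around the gyroid
  level set `g = sin u cos v + sin v cos w + sin w cos u` with lattice
  constant a = 400 nm; compartments labelled by the sign of g
  (n_A = 1.33 cytosolic, n_B up to 1.48). The twelve bilayers are
  collapsed onto the g = 0 mid-surface for collision detection.
* **Wall optics.** Each crossing of the mid-surface applies the exact
  thin-film response of the 25-medium wall (12 lipid films n = 1.70 /
  1.8 nm alternating with 11 cytosolic gaps n = 1.38 / 10 nm) via 2×2
  characteristic matrices per polarization,

      M = [[cos δ, i sin δ/γ], [iγ sin δ, cos δ]],  γ_s = n cos θ, γ_p = n/cos θ,

  with energy-exact R + T = 1 and full TIR handling.
* **Transport.** Polarized Monte Carlo ray packets with photon
  splitting (Russian roulette, deterministic branch pursuit with
  discard threshold ε, or a 3-ray diffraction fan), complex s/p
  amplitudes, accumulated phase, and an exact energy ledger.
* **Near field.** Exit packets become intensity maps on image planes
  via an angular-spectrum wave propagator or a Huygens surface-patch
  integrator; observables include focus position vs wavelength,
  disk-flux spectra vs free propagation, rotation-robustness sweeps,
  and waveguide diagnostics.
* **Equivalent bilayer.** An optimizer finds the four-parameter closed
  bilayer [na, da][nb, db][na, da] whose polarized reflectance best
  matches the full wall over 400–800 nm × 0–90°.

## Worked example

```python
import numpy as np
from mitolens import build_mitochondrion, reference_wall, find_focus
from mitolens.transport import SourceGrid, trace

model = build_mitochondrion(wall_stack=reference_wall())   # defaults: R=1 um, n_B=1.48
records, ledger = trace(model, SourceGrid(spacing=10.0, wavelength=600.0),
                        epsilon=1e-5)
print(f"forward {100*ledger.exited_forward/ledger.input:.1f}%, "
      f"back {100*ledger.exited_backward/ledger.input:.1f}%, "
      f"discarded {100*ledger.discarded/ledger.input:.4f}%")
res = find_focus(model, 600.0, plane_range_um=(0.5, 6.0), step_um=0.1,
                 spacing=10.0, records=records)
print(f"focus {res.focus_um:.1f} um behind the rear pole, centred={res.centered}")
```

prints (exactly reproducible — strategy ii is deterministic):

```
forward 96.1%, back 3.9%, discarded 0.0049%
focus 2.2 um behind the rear pole, centred=True
```

i.e. the membrane assembly transmits ~95 % of 600 nm light forward and
concentrates its coherent component ~2.2 µm behind the organelle —
in front of where the equivalent homogeneous ball lens would focus,
because interference between the split wavefronts, not refraction
alone, sets the focal position. The `examples/` directory has one
short script per capability (reflectance spectra, bilayer fit, focus
scan, UV filter, rotation robustness, waveguiding).

A thin CLI wraps the same calls:

```bash
mitolens fixtures --list
mitolens fit-bilayer --out fit.json
mitolens simulate --config run.yaml --seed 1
```

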