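# needlefem

Adaptive cohesive-zone finite-element simulation of steerable
bevel-tip needle insertion into soft elastic substrates.

Percutaneous needle steering — in particular with programmable
bevel-tip needles (PBNs), whose curvature is set by the axial offset
`c` between interlocked segment pairs — depends on a tight coupling
between needle bending, frictional tool–tissue interaction and
fracture of the substrate.  `needlefem` models a 2D plane-strain
insertion where the penetration path is **not prescribed**: the cut
grows by adaptive insertion of cohesive interface elements, with the
timing of growth set by a crack-tip-opening-displacement (CTOD)
criterion and the direction by the minimum-strain-energy-density
(MSED) criterion, followed by remeshing of the tip region.  It is a
research tool for steering-mechanics studies on gelatine-phantom-like
substrates.

## Model in brief

- Substrate (gelatine phantom, `E = 14.8 kPa`, `nu = 0.475`) and
  needle (`E = 117–940 kPa`) meshed with plane-strain triangles;
  geometric nonlinearity via a compressible neo-Hookean realisation of
  the linear-elastic input.
- Bilinear cohesive law on the crack path, calibrated from the
  fracture energy and the needle geometry:
  `G_c = ½ σ_max δ_c = 1.1 J/m²`, `δ_max = 2 ρ_tip`, `δ_c < b`.
- Propagation when the crack-face opening at
  `L̄ = ρ_tip / tan α` behind the equivalent crack tip reaches
  `δ_max`; kinking toward the minimum of the strain energy density
  sampled on a radial element ring around the tip.
- Frictional contact (Coulomb, `f = 0.3`) between the needle outline
  and the cavity walls; rigid frictionless trocar guides above the
  surface.
- Outer loop per the adaptive algorithm: replay from `D_e = 0`, drive
  to criticality, kink, insert one cohesive element, remesh, repeat;
  results are read from the final iteration.

See `docs/methods.md` for the full account, including all numerical
choices and the limitations of the shipped problem sizes.

## Worked example

A desk-scale insertion of the symmetric (zero-offset) needle into an
80 × 60 mm gelatine block:

```python
import numpy as np
from needlefem.driver import run_insertion, energy_balance
from needlefem.fixtures import make_preset

cfg = make_preset("micro-symmetric")      # b = 8 mm, 2a = 20 deg,
                                          # rho_tip = 0.5 mm, f = 0.3
hist = run_insertion(cfg, progress=True)
W, U_S, U_f, U_G, rel = energy_balance(hist)
print("final depth D_e =", hist.D_e[-1] * 1e3, "mm")
print("max insertion force =", round(hist.force.max(), 1), "N/m")
print("energy residual =", round(100 * rel, 2), "%")
print("crack straightness:", abs(hist.crack_path[:, 0]).max(), "m")
```

which prints (four crack-propagation events, ~3 minutes on one core):

```
iteration 0: D_e = 2.625 mm, crack = 2.500 mm, theta_c = 0.0
iteration 1: D_e = 3.475 mm, crack = 2.750 mm, theta_c = 0.0
iteration 2: D_e = 5.075 mm, crack = 3.000 mm, theta_c = 0.0
iteration 3: D_e = 8.000 mm, crack = 3.250 mm, theta_c = None
final depth D_e = 8.0 mm
max insertion force = 37.2 N/m
energy residual = 5.39 %
crack straightness: 3.061616997868383e-20 m
```

Every kink angle is zero and the established cut lies on the insertion
axis to round-off — the straight-path validation of the zero-offset
needle.  The insertion force per unit out-of-plane depth rises to a
few tens of N/m, and the external work is balanced by stored and
frictional energy to within a few per cent (the residual reflects the
contact-engagement transient; see `docs/methods.md`).

The same machinery runs the PBN presets (`micro-pbn`, `pbn-c32`, ...),
writes VTK/CSV/JSON outputs through the CLI, and post-processes tip
trajectories with the hyper-accurate circle fit:

```sh
needlefem fixtures micro-symmetric --out configs
needlefem run configs/micro-symmetric.yaml --out runs/demo
needlefem postprocess runs/demo/history.csv runs/demo/crack_path.csv --offset-mm 6
```

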