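# ompermeate

Inference of membrane permeability, partitioning, and whole-cell flux
for small aromatic solutes crossing a glycosylated (LPS-bearing)
gram-negative outer membrane, from biased reaction-coordinate sampling
data.

Gram-negative bacteria that catabolize lignin-derived aromatics must
take those compounds up across two membranes. The outer membrane's
lipopolysaccharide leaflet adds a hydrophilic glycan barrier whose
effect on passive uptake is naturally quantified by simulation:
replica-exchange umbrella sampling (REUS) along the membrane normal ξ
yields a free-energy profile G(ξ) and a diffusivity profile D(ξ), which
the inhomogeneous solubility-diffusion model converts into a
permeability coefficient

    Pm = [ ∫ exp(β ΔG(ξ)) / D(ξ) dξ ]⁻¹        (cm/s; β = 1/k_BT)

This package implements the full inference chain downstream of the
molecular-dynamics engine, plus a synthetic Langevin/replica-exchange
generator with known ground truth so every stage is testable without
MD:

- **synthetic** — overdamped Langevin dynamics (Itô, position-dependent
  D with the spurious-drift term) on analytic landscapes; REUS with
  Metropolis neighbour swaps; toy membrane traces and C–H bond-vector
  fixtures.
- **free_energy** — binned WHAM with a periodic-coordinate option,
  solution zero point, symmetrization for charged species, and a
  Dirichlet-posterior (Bayesian-bootstrap) uncertainty band.
- **diffusivity** — D(ξ) = var(ξ)/τ per umbrella window, with τ from an
  exponential fit to the autocorrelation function inside the 1 ps
  intervals between exchanges; Einstein-relation estimates from
  equilibrium traces (20 ps displacement lag, position-binned).
- **permeability** — spline fitting, the solubility-diffusion integral,
  partition coefficients logP = (G_aq − G_mem)/(RT ln 10), the regional
  decomposition log Pm = logP + log[(Pm_u⁻¹ + Pm_c⁻¹ + Pm_g⁻¹)⁻¹],
  O-antigen thickness extrapolation, and multi-segment profile
  stitching.
- **transport** — serial two-membrane permeability
  Pm_t = Pm_o·Pm_i/(Pm_o + Pm_i), steady-state flux
  J = Pm_t·A·Δc, and rate-limiting-membrane classification.
- **observables** — crossing-event detection with hysteresis,
  periodic-boundary unwrapping, acyl-tail order parameters
  −S_CD = −⟨3cos²θ_CH − 1⟩/2.

## Worked example

Decompose the permeability of a synthetic outer-membrane-like landscape
(asymmetric free energy, aqueous D plateau of 80 Å²/ns with
interfacial dips) and predict the whole-cell flux:

```python
import numpy as np
import ompermeate as om
from ompermeate.permeability import spline_fit, decompose_permeability
from ompermeate.transport import (TransportSystem, serial_permeability,
                                  steady_state_flux)

ls = om.outer_membrane_like_landscape()
grid = np.linspace(-35, 65, 401)
g = spline_fit(om.Profile(grid=grid, values=ls.free_energy(grid)))
d = spline_fit(om.Profile(grid=grid, values=ls.diffusivity(grid),
                          kind="diffusivity"))
bd = decompose_permeability(g, d, solution_range=(45.0, 65.0))

pm_om = 10**bd.logPm
pm_t = serial_permeability(pm_om, 10.0)          # inner membrane: 10 cm/s
j = steady_state_flux(TransportSystem(Pm_o=pm_om, Pm_i=10.0,
                                      area=1.25, c_out=1.0), Pm_t=pm_t)
```

This prints:

```
logP     = 2.11
log Pm   = -0.13   (u=-0.49, c=-2.23, g=0.41)
boundaries: u=-8.0 A, g=20.8 A
Pm_t = 0.70 cm/s; J = 8.7 fmol/s (5.25e+09 molecules/s)
```

Reading: the compound partitions into the membrane (logP = 2.11, i.e.
~130-fold enrichment), total permeability is 10^−0.13 ≈ 0.7 cm/s and is
limited by the core-crossing component (Pm_c, the smallest of the three
regional permeabilities). In series with a 10 cm/s inner membrane the
envelope passes ~9 fmol/s (5×10⁹ molecules/s) per cell under a 1 mM
gradient — far above typical aromatic catabolic capacity, so passive
uptake would not be rate limiting in this example.

The same chain runs from the shell over plain-text window files:

```sh
ompermeate simulate reus --out windows/ --seed 1 --n-windows 40 --n-steps 20000
ompermeate wham --windows 'windows/window_*.dat' --out g.csv
ompermeate diffusivity --windows 'windows/window_*.dat' --out d.csv
ompermeate permeability decompose --free-energy g.csv --diffusivity d.csv --out breakdown.json
ompermeate transport flux --pm-o 2 --pm-i 10 --c-out 1
```

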