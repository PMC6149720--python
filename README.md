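# sandlam

Reduction and analysis of small-angle neutron diffraction (SAND) data from
aligned, vapor-hydrated lipid multilayers — from indexed Bragg peak
intensities, through contrast-variation phasing, to neutron
scattering-length-density (NSLD) profiles and the bilayer structural
parameters, with companion observables for coarse-grained bilayer
trajectories. It is aimed at membrane biophysicists reducing lamellar
diffraction data (e.g. phosphatidylcholine bilayers doped with n-alcohols)
and at anyone needing a fully testable forward model of that reduction.

## What it computes

For a centrosymmetric lamellar stack with repeat distance *D*, the NSLD
profile is reconstructed from the signed structure factors *F‌ₕ* by Fourier
synthesis,

    ρ(z) = F₀ᵃᵇˢ/D + (1/k)·(2/D)·Σₕ Fₕ·cos(2πhz/D),

where ±|Fₕ| = ±(Iₕ/(L_f·A_c·F_c))^½ comes from the integrated peak
intensity Iₕ corrected by the Lorentz factor L_f = 1/sin 2θₕ, the slab
absorption factor A_c = [sin θ/(2μt)]·[1 − exp(−2μt/sin θ)] and the flux
correction F_c = erf(l·sin θ/(8σ)). Signs are fixed by contrast variation:
Fₕ is affine in the water scattering density ρ_w, measured at several
D₂O/H₂O ratios. The water distribution w(z) follows from profile
differences between contrasts; an error-function fit to its flanks puts
the Gibbs dividing surface at ±D_B/2, giving the bilayer thickness D_B,
the water layer D_W = D − D_B, the head-to-head distance D_HH (profile
maxima at the water-nulling ~8% D₂O contrast), the area per unit cell
A = 2(V_l + x·V_a)/D_B and the interlamellar water count. The trajectory
module computes P2 = ½(3⟨cos²θ⟩ − 1) bond order parameters, leaflet-folded
number-density profiles with central-90% spans, the phosphate-to-phosphate
thickness D_PP, and the lateral 2D radial distribution function.

A forward model (`sandlam.synthetic`) generates ground-truth bilayer
profiles, theoretical structure factors, noisy indexed peak tables and
labelled coordinate frames, so every stage of the chain is verified by
round-trip parameter recovery.

## Worked example

```python
import numpy as np
from sandlam import synthetic, pipeline
from sandlam.models import BilayerModel, ContrastSpec, InstrumentConfig, VolumetricInputs

model = BilayerModel()                      # D = 55 Å, headgroups ±18.2 Å, interface ±19.5 Å
contrasts = [ContrastSpec.from_d2o_fraction(f) for f in (0.08, 0.20, 0.50)]
instrument = InstrumentConfig()             # λ = 4.5707 Å
table = synthetic.simulate_peak_table(model, contrasts, hmax=6,
                                      instrument=instrument, noise_scale=0.0, seed=1)
f0abs = {c.d2o_fraction: synthetic.true_f0abs(model, c) for c in contrasts}
res = pipeline.reduce_contrast_series(table, instrument, f0abs, VolumetricInputs())
s = res.structure
print(f"D = {s.D:.2f}  D_B = {s.D_B:.2f}  D_HH = {s.D_HH:.2f}  "
      f"D_W = {s.D_W:.2f}  A = {s.A:.2f}  n_W = {s.n_waters:.1f}")
```

prints

```
D = 55.00  D_B = 39.03  D_HH = 36.81  D_W = 15.97  A = 72.36  n_W = 19.3
```

i.e. the lattice constant is recovered exactly from the Bragg angles, the
Gibbs-surface bilayer thickness lands within 0.03 Å of the generator's
2×19.5 Å ground truth, the head-to-head distance reflects the headgroup
maxima of the water-nulled profile, and area/water count follow from the
volumetric identity A·D_B = 2(V_l + 0.3·V_a).

The same stages are available from the shell:

```sh
sandlam simulate config.yaml -o simdir/
sandlam reduce simdir/peaks.tsv -o lattice.json
sandlam phase simdir/peaks.tsv phase.yaml -o sf.json
sandlam profile sf.json -o profiles/
sandlam params profiles/summary.json -o results.csv
sandlam order frames.gro --bonds C1A-C2A --rdf-label PO4 -o order/
```

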