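# saxsdic

Scanning-SAXS nanomechanical imaging for fibrous connective tissue, with
diffraction-contrast digital image correlation (DIC).

Fibrotic and other collagen-rich tissues are heterogeneous at the micron
scale, so a single small-angle X-ray scattering (SAXS) pattern is not
representative: microfocus *scanning* SAXS rasters a micron-sized beam over
the specimen and fits nanoscale structure at every point. Under load, the
deformation is also heterogeneous — to measure fibril-level strain you must
compare the *same tissue volume* before and after stretching, which cannot
be done by assuming uniform deformation. This package closes that loop by
running subset-based DIC on the collagen peak-intensity maps themselves
(the "diffraction contrast"), tracking each scan point into the deformed
scan.

## What it computes

For each scan point, from the radial profile I(q) and azimuthal profile
I(χ):

* the collagen **D-period** from a Gaussian + exponential-background fit of
  the 5th meridional order, D = 10π/q₀₅ (axial width w_q, background-
  corrected peak intensity I_c = A·σ√2π);
* the **interfibrillar spacing** D_IFC = 4π/q₂ from the broad 2nd-order
  equatorial peak, with intensity I_ifc;
* the **mean fibril angle** χ₀ (mod 180°) and angular width w_χ from a
  paired-lobe azimuthal fit with wrap-around correction;
* the **total SAXS intensity** I_total = ∫I(q) dq.

Between two load states, after DIC matching of scan points:

* **fibril strain** ε_F = (D_def − D_ref)/D_ref and the ratio ε_F/ε_T to
  the applied tissue strain;
* **reorientation** of χ₀ toward the loading axis on the 180°-periodic
  circle, and width changes Δw_χ, Δw_q;
* distribution summaries (histogram + Gaussian KDE) and per-row line
  profiles of all of the above.

A forward simulator (`saxsdic.synth`) generates Pilatus-like frames —
meridional collagen orders with step-density Fourier amplitudes
cₙ = sin(πnf)/(πn), a broad IFC ring, exponential background, Poisson
noise, beamstop mask — plus warped scan pairs with known point
correspondence, so the entire pipeline is testable without beamline data.

## Worked example

```python
import numpy as np
import saxsdic as sx
from saxsdic.geometry import RADIAL_Q, Profile1D

q = np.linspace(0.4005, 0.5195, 120)                       # nm^-1
intensity = 12.0 * np.exp(-0.5 * ((q - 0.4812) / 0.003) ** 2) \
    + 30.0 * np.exp(-q * 6.0)
profile = Profile1D(RADIAL_Q, q, intensity, np.full(q.size, 200, dtype=int))

col = sx.fit_collagen(profile)
print(f"q05 = {col.fit.center:.4f} nm^-1 -> D = {col.D:.2f} nm")
```

prints

```
q05 = 0.4812 nm^-1 -> D = 65.29 nm
```

i.e. the fitted 5th-order position 0.4812 nm⁻¹ corresponds to a collagen
axial period of 65.29 nm — a typical hydrated-tissue value (wet tendon is
~67 nm; lower values indicate reduced fibril pre-strain or tilted
intrafibrillar packing). The `examples/` directory walks through the other
capabilities one at a time; `examples/05_load_step.py` runs the full
two-scan pipeline on synthetic tissue and prints, among others,

```
median fibril strain eps_F = 0.00147 (imposed 0.0015; tissue strain 0.20)
eps_F / eps_T = 7.35e-03 - fibrils carry far less strain than the bulk tissue
```

showing the method recovering an imposed nanoscale strain through the
complete frames → fits → maps → DIC → matching chain, and the hallmark of
soft hydrated tissue: fibrils carry only ~10⁻² of the macroscopic strain
(interfibrillar shear and reorientation absorb the rest).

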