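# coloptics

Optical analysis of structurally coloured bacterial colonies.

*Flavobacterium* IR1 colonies pack their rod-shaped cells into a 2D
hexagonal photonic crystal (cross-section lattice constant d ≈ 395 nm,
cell index 1.38 in a 1.34 matrix) and owe their iridescent green
appearance to it. Because the index contrast is tiny and the packing
polycrystalline, electron microscopy gives scattered estimates of the
lattice constant — but the colony's own optics does better. This
package implements that programme for researchers in biophotonics and
microbial self-organization:

* **Inverse analysis of angle-resolved scattering**: lattice constant
  from diffraction spots via the grating equation
  θ_m = arcsin(mλ/d − sin θ_i); average refractive index from the
  specular dispersion λ_s = λ_p cos(arcsin(sin θ_in/n_avg)); domain-tilt
  streaks extracted and corrected for incidence so that measurements at
  different angles overlay.
* **Forward models** that explain every spectral feature: 1D
  effective-medium transfer matrices, a 2D plane-wave-expansion band
  solver with mode-symmetry classification (partial gaps between
  plane-wave-excitable modes at ≈ 471, 309 and 336 nm), and a 2D TM
  FDTD solver for ordered and disordered hard-disk packings.
* **Structure generation and metrology**: hexagonal packings, disorder
  controlled through target structure factors (radial broadening σ_k,
  azimuthal broadening σ_Φ) by simulated annealing, S(q), image
  autocorrelation and line-profile lattice estimators.
* **A synthetic-data generator** (goniometer maps and EM-like
  cross-section images) with known ground truth, so every inverse step
  is tested closed-loop.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Recover the day-2 lattice constant from three synthetic goniometer maps
(incidences 0°, −45°, −60°) with 0.5° angular noise, and the average
index from a noisy specular trace:

```python
import numpy as np
from coloptics.synthdata import ColonyModel, TiltDistribution, \
    synth_goniometer_map, synth_specular_trace
from coloptics.goniometry import fit_grating, fit_specular

model = ColonyModel(d=395.0, tilt=TiltDistribution(0, 0, 0), seed=0)
maps = [synth_goniometer_map(model, t, angle_jitter_deg=0.5)
        for t in (0.0, -45.0, -60.0)]
fit = fit_grating(maps)
print(f"d = {fit.d_hat:.1f} +- {fit.d_se:.1f} nm, orders {fit.orders_used}")

trace = synth_specular_trace(ColonyModel(d=395.0, lambda_p=480.0, seed=0),
                             noise_sigma_nm=3.0, n_avg=1.4)
sfit = fit_specular(trace)
print(f"lambda_p = {sfit.lambda_p_hat:.1f} nm, n_avg = {sfit.n_avg_hat:.3f}")
```

```
d = 394.8 +- 0.4 nm, orders [-2, -1, 1]
lambda_p = 480.6 nm, n_avg = 1.393
```

The fit uses six diffraction spots across the three maps (orders −2, −1
and +1) and lands within a nanometre of the generator truth; the index
comes back within 0.01 of the ground-truth 1.4. Averaged over 10 noise
seeds the recovery errors are ≈ 0.2 nm and ≈ 0.01 (see
`analysis/01_goniometry_inversion.py`).

The photonic-crystal side in two lines of shell:

```sh
coloptics bands --d 395 --diam 395 --n-in 1.38 --n-out 1.34 \
    --pol TM --window 430:520 -o gaps.json
```

which reports the visible TM partial gap of the touching-disk lattice at
471.6 nm with 0.66 nm width — the origin of the colony's specular
reflection — and `coloptics fdtd --structure ens.tsv -o spec.tsv` gives
the angle-integrated reflectance of any packing.

## Analysis pipeline

The numbered scripts under `analysis/` run the full study and write
their tables to `results/`:

| script | what it does |
| --- | --- |
| `01_goniometry_inversion.py` | d (day 1/2), n_avg and streak-overlay recovery from synthetic maps |
| `02_lattice_metrology.py` | autocorrelation / line-profile / S(q) estimators on an EM-like image |
| `03_multilayer_tmm.py` | 41-period effective-medium stack: Bragg peaks, angle sweep, tilted stacks |
| `04_band_structure.py` | TM bands with symmetry labels; partial gaps on both legs |
| `05_fdtd_perfect_lattice.py` | perfect-lattice reflectance for both crystal orientations |
| `06_disorder_study.py` | 7-realization FDTD sweep over σ_k and σ_Φ disorder (minutes) |

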