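# Methods

This package models the optics of structurally coloured *Flavobacterium*
IR1 colonies. In cross-section the cells pack into a 2D hexagonal
photonic crystal of low index contrast (cells n_bac = 1.38 in a matrix
n_env = 1.34, nearest-neighbour distance d ≈ 395 nm on day 2 and
≈ 425 nm on day 1 of growth), organized as polycrystalline domains that
mostly lie flat but carry a broad spread of tilts. The package has two
halves: inverse analysis of angle-resolved scattering, and forward
electromagnetic models of the lattice.

## Angle conventions and lattice orientation

All goniometer angles are measured from the sample normal; the source
sits on the negative side, so the grating equation is used as
θ_m = arcsin(mλ/d − sin θ_i) with θ_i ≤ 0, and specular reflection is
θ_out = −θ_in. For the crystal, the close-packed rows are parallel to
the colony surface: the stacking normal (the direction probed at normal
incidence, row period Λ = √3 d/2 ≈ 342 nm, lateral period d) is labelled
"KG incidence" in the real-space/FDTD modules. In reciprocal space this
stacking normal is the conventional Γ–M direction of the triangular
lattice, and the band-structure module uses the conventional labels:
Γ–K (to the zone corner, 4π/3d) carries the visible 471 nm and near-UV
309 nm gaps, Γ–M the 336 nm gap. The two labelling schemes coexist in
the literature on this system; we keep the incidence label for
real-space geometry and the conventional reciprocal labels for bands.

## Synthetic goniometer (forward model)

Each crystalline domain tilted by α sees an effective incidence
θ_g = θ_in − α. The internally refracted beam (Snell with the
volume-averaged index n_avg) scatters elastically where the Laue
condition |k + G| = |k| is met for a reciprocal vector G of the
row-oriented lattice, giving the resonant vacuum wavelength

  λ(G, θ_g) = −4π n_avg (G_x cos θ_2 + G_y sin θ_2)/|G|²,
  sin θ_2 = −sin θ_g / n_avg.

The lateral order n_2 of G sets the exit angle through the grating
equation in the domain frame, and the outgoing direction is rotated back
by +α. This single rule generates every feature class of the
measurements: the G = (−p, 0) family is the specular cosine law
λ_s = λ_p cos(arcsin(sin θ/n_avg)) with λ_p = n_avg Λ · 2/2 ≈ 471 nm
(p = 2) and the weak 314 nm line (p = 3); laterally periodic G give the
diffraction spots — at normal incidence the first-order spot lands at
(58°, ≈ 335 nm) and the trapped ≈ 471 nm first order that only exits at
oblique incidence; and sweeping the tilt density strings the spots into
the diagonal streaks crossing the specular line. Spots are deposited as
Gaussian kernels (1.5° × 5 nm, an instrument-like smoothing), orders
weighted 1/(n_1²+n_2²) with a configurable specular boost, intensity
noise is additive Gaussian clipped at zero, and the ±5° blind region
around the source arm is masked as missing.

The default tilt density is a Gaussian core of halfwidth 10° (σ = 5°,
the flat-lying domains) plus 10% uniform mass over ±90° (fully
re-oriented domains). The ±90° tail range is a deliberate choice: the
corrected streak loci depend only on θ_g, so streaks recorded at
different incidences overlay exactly wherever all maps have tilt
coverage, and a tail narrower than ≈ ±85° would leave the −60° map
without coverage in the extraction window.

Limitations: the generator is kinematic (no multiple scattering, no
absolute intensities — the measurement itself is not quantitative in
intensity), domains are treated independently, and conical (out-of-plane)
diffraction is not modelled.

## Inverse analysis

* **Peak detection** finds local maxima above both 5× the map's median
  absolute deviation and 5% of the map maximum (flat-domain spots are
  ~100× brighter than streak ridges), excluding the blind region, a ±3°
  specular band, and maxima adjacent to masked cells (shoulders of
  truncated features). Sub-grid positions come from a separable 3-point
  log-parabola, which is exact for Gaussian spots — noiseless synthetic
  maps invert to machine accuracy.
* **Lattice-constant fit**: each peak is assigned an order m ∈ {±1, ±2}
  by consensus of the closed-form d = mλ/(sin θ_m + sin θ_i) values;
  ties from the (m, d) → (2m, 2d) degeneracy resolve to the minimal
  period. The final d̂ minimizes summed squared angle residuals
  (Levenberg–Marquardt), with a 1σ error from the linearized fit.
* **Index fit**: λ̂_p is read from a local quadratic through the specular
  ridge around 0°, then n̂_avg is a 1D least-squares fit of the cosine
  law. A ridge flatter than 0.25 nm over its span returns an
  infinite-index lower-bound flag (degenerate n → ∞ limit).
* **Streak correction** extracts, per detector angle in the corrected
  window θ_out − θ_in ∈ [45°, 56°], the intensity-weighted centroid
  wavelength in the 330–348 nm window. The window selects the region
  where only symmetry-equivalent branches of the first-order streak are
  present in all three standard incidences; overlay quality is an RMS
  angular misalignment obtained by converting wavelength offsets through
  the local ridge slope.

## Structure generation

`make_hexagonal` fills a centred band of the box with the oriented
lattice at exactly N = round(ff · A_box/(πa²/4)) disks (ff = 0.6 with
diameter 375 nm and d = 395 nm reproduces 136 disks in a 5×5 μm box), so
ordered and disordered ensembles hold the same particle number. For
laterally periodic boxes the lateral period is snapped to the box height
(choose commensurate boxes to avoid strain).

Disorder targets are six first-shell Bragg peaks broadened radially by
σ_k·|q₁| and azimuthally by σ_Φ, each convolved with the finite-size
width 2π/L of the box (≈ 6% of |q₁| at the 2.5 μm desk scale) — without
this convolution the zero-disorder target is unrealizable and the
annealer destroys the lattice chasing it. σ_k or σ_Φ below the
finite-size floor are therefore indistinguishable from order at desk
scale. `generate_disordered` anneals single-particle Gaussian moves
(step a/10, hard-disk rejection, geometric cooling, incremental ρ(q)
updates) against the weighted squared mismatch with a free amplitude
scale; isotropic targets are preceded by a hard-disk melt.
`jitter_lattice` is the fast alternative for small positional disorder;
its first-shell peak suppression follows exp(−q₁²σ²) (Debye–Waller)
within 15%, and it raises once redraws exceed the particle count (> 50%
rejection).

## Structure-factor metrology

S(q) of point sets is the direct sum |Σ exp(iq·r)|²/N on a Cartesian
grid (separable phase factors); images use the normalized power spectrum
of the mean-subtracted (Otsu-binarized if needed) indicator. The
lattice constant from the image autocorrelation is the mean radius of
the first shell of off-centre ACF peaks (sub-pixel by local centroid);
oblique shell peaks are re-collected with a threshold relative to the
strongest peak because pixelation damps them, and a > 5% spread of shell
radii raises the anisotropy flag. Line-profile spacing segments the
profile into above-threshold runs (robust to the plateau tops of disks)
and reports the direction used — in a hexagonal lattice the answer is
d along the rows but √3 d/2 across them, which is one reason line-plot
and autocorrelation estimates of micrographs disagree.

## Transfer matrix (1D effective medium)

One stacking period is discretized into 8 slabs whose permittivity is
the chord-length area fraction of the disk rows, volume-averaged with
the matrix (thickness-weighted RMS index 1.3766 for touching disks).
The standard characteristic-matrix recursion (admittance form, complex
kz for evanescent layers) gives R and T per wavelength, angle and
polarization; energy closes to ~1e−14 for lossless stacks. The default
41-period Γ–K stack peaks at the m = 2 and m = 3 Bragg wavelengths
2n̄Λ/m ≈ 470 and 314 nm, and its angle sweep follows the specular cosine
law within 1 nm. Tilted stacks are evaluated at the effective incidence
θ − tilt with grazing cases marked missing.

## Plane-wave expansion (2D bands)

TM bands solve |k+G|² E = (ω/c)² ε(G−G′) E as a Hermitian definite
generalized eigenproblem; TE uses the inverse-permittivity curl form.
The G basis is a circular shell |G| ≤ cutoff·2π/d (closed under the leg
mirrors; cutoff 9 ≈ 440 plane waves), and disk permittivity enters
through the analytic 2J₁(GR)/GR factor. Mode parity under the mirror
containing the leg is the normalized overlap ⟨v, σv⟩, with degenerate
subspaces symmetrized first; |overlap| < 0.9 is flagged "mixed" and
conservatively treated as excitable. Gaps are wavelength intervals not
covered by any excitable band segment (a segment blocks if either
endpoint is excitable, which bridges label swaps inside near-degenerate
pairs); gaps narrower than 0.05 nm are not reported. Because folded
bands from other parts of the leg can sweep through a stop band of this
nearly-free-photon crystal ("mode banding"), a gap read at an
anticrossing is evaluated in a k-neighbourhood of its zone point — the
near-UV Γ–K gap uses the outer 20% of the leg around the K corner.
Computed TM gaps for touching disks: 471.6 nm (width 0.66 nm) and
308.8 nm (0.46 nm) on Γ–K, 335.7 nm (1.2 nm) on Γ–M; positions are
stable to well under 1 nm between cutoffs 9 and 15, and TE gaps sit
within 0.5 nm of the TM ones.

## FDTD (2D, TM)

A Yee-grid TM solver (Ez, Hx, Hy) with split-field PML along the
propagation axis and periodic lateral boundaries; a soft current line
launches a differentiated-Gaussian pulse spanning 300–700 nm, and
monitor-line fields are Fourier-transformed on the fly. Reflected
fields are isolated by subtracting a cached structure-free reference
run; total reflectance is backward flux over incident flux, and a
lateral Fourier split (flux-weighted by Re kx per order) divides it into
specular and diffracted channels. The background is n_env everywhere —
the air–colony interface is deliberately absent, so spectra isolate the
lattice response. Disk permittivity is anti-aliased by 4×4 subsampling
of boundary cells. The hot loop is compiled with numba.

Problem sizes: the production geometry keeps the full 5 μm slab depth
(≈ 11 rows, where the specular Bragg orders are clearly developed) but
reduces the lateral period to 6 cells of d (2.37 μm) at a 10 nm grid and
300 fs of simulated time; the disorder study further reduces depth to
2.5 μm with 7 annealed realizations per disorder level. Peak positions
shift < 3 nm between 10 and 5 nm grids and are insensitive to halving
the box.

At the KG ("normal incidence") orientation the perfect lattice gives
strong peaks at 470 and 336 nm and a weak specular peak at 312 nm; the
336 nm peak is carried by first-order diffraction and the 470/312 nm
features appear in the zero-order channel, while the 30°-rotated (MG)
orientation scatters into a multi-peak visible spectrum. One caveat:
because the embedding matrix extends to the monitors, the ≈ 471 nm
first-order wave — which would be totally internally reflected at a real
air interface — propagates and dominates the total 470 nm peak; the
specular channel still peaks there, but with the air interface absent
its share of the flux is small.

Energy accounting closes to within 2% for ordered structures. Strongly
disordered samples scatter into near-grazing waves whose lateral
residence time far exceeds any affordable run time, so a few percent of
the pulse energy is still in flight at shutdown; the disorder sweep
therefore accepts up to 10% imbalance while single-structure runs keep
the 2% abort threshold.

## What the synthetic data do and do not show

All quantitative claims are closed-loop: parameters recovered from data
generated by the package's own forward models (grating fit exact on
noiseless maps; d̂ within ±5 nm at 0.5° angular noise over 10 seeds;
n̂_avg within ±0.05 at 3 nm wavelength noise; streak overlay < 2° RMS
with a sign-flipped negative control). Passing these shows the inverse
machinery is unbiased under the stated noise, not that real colonies
meet the model assumptions: real micrographs carry dehydration
shrinkage, sectioning obliquity and charging artefacts (the reason
published EM-based lattice constants scatter far more than goniometric
ones), and real goniometer data include conical diffraction and
intensity effects that the kinematic generator omits.
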