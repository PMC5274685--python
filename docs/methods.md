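# Methods

This note records the models, estimators, numerical choices and known
limitations behind `cartiqus`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## 1. Acoustic parameters

A scanned cartilage site is characterized by four scalars, each an
average over the m A-lines of the scan (m = 100 by default, a 10 × 10
raster over a 0.3 mm × 0.3 mm region of interest):

- **URI** (ultrasound roughness index, µm) — the population standard
  deviation `sqrt((1/m) Σ (d_i − d̄)²)` of the per-line
  transducer-to-surface distances `d_i`. The population (1/m)
  normalization is used deliberately, not the 1/(m−1) sample form.
- **RC1** (%) — mean surface-echo peak-to-peak amplitude over the
  perfect-reflector amplitude, ×100.
- **RC2** (%) — the same for the cartilage–subchondral bone interface
  echo. No correction is applied for transmission through the surface
  or attenuation in cartilage, so RC2 understates the physical
  interface reflectivity by design; consequently RC2 is *coupled to
  thickness* (thinner cartilage attenuates less, raising RC2).
- **h** (mm) — `(1/m) Σ c_cartilage · TOF_i / 2` with
  `c_cartilage = 1675 m/s` by default (a standard average sound speed
  for articular cartilage; configurable).

In each average, m is the number of lines with a *valid* detection of
that echo; invalid lines are excluded and the average renormalized
(surface and interface counts may differ). URI is an SD and therefore
needs at least two valid lines.

## 2. RF forward model (synthetic scans)

The transducer emits a Gabor pulse
`g(t) = A exp(−t²/2σ_t²) cos(2π f₀ t)` with f₀ = 50 MHz and σ_t set so
the −6 dB spectral width equals the fractional bandwidth (0.5) times
f₀. Each line carries two specular echoes:

- surface echo at delay `2 d_i / c_medium`, amplitude `r_s · A_ref`;
- interface echo delayed a further `2 h_i / c_cartilage`, amplitude
  `r_i (1 − r_s²) · A_ref · 10^(−2 α h_i f₀ / 20)` — the `(1 − r_s²)`
  term is the two-way transmission loss through the surface, and the
  attenuation α (dB·cm⁻¹·MHz⁻¹) is applied at f₀ only (narrowband
  approximation, appropriate because the downstream parameters are
  peak-to-peak amplitudes, not spectra).

`d_i ~ N(standoff, σ_rough)` and `h_i ~ N(h̄, σ_h)` are independent per
line; nonpositive draws are redrawn and counted. White Gaussian noise
is added with SD expressed as a fraction of the reference peak-to-peak
amplitude. Identical spec + seed ⇒ bit-identical output. Echo pairs
closer than one pulse length set an `overlap_warning` flag.

Defaults (all configurable) and why:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 400 MHz | matches the 8×-oversampling digitizer class used with 50 MHz transducers |
| saline sound speed | 1520 m/s | room-temperature saline |
| standoff | 10 mm | typical ~1 cm transducer positioning |
| surface roughness σ | 8 µm | healthy cartilage surface, literature range ~5–20 µm |
| thickness | 0.25 / 0.30 mm (two sites) | rat tibial plateau cartilage scale |
| r_surface | 0.05 | intact cartilage surface reflection of a few percent |
| r_interface | 0.25 | strong osteochondral impedance step |
| attenuation | 1.0 dB·cm⁻¹·MHz⁻¹ | ≈50 dB/cm at 50 MHz, literature range for cartilage |
| noise SD | 0.002 × A_ref | ≈54 dB below the perfect reflector; an averaged laboratory acquisition |

What the generator does **not** emulate: diffuse speckle from
sub-resolution scatterers, beam diffraction and focusing, curved
plateau geometry, frequency-dependent attenuation within the pulse
band, and electronic nonlinearity. Passing tests therefore demonstrate
correctness of the estimators under a specular two-interface model,
not robustness to every property of tissue data.

## 3. Echo detection

Every line and the reference trace are conditioned identically, by
default with a **matched filter** (correlation with the unit-energy
reference pulse) — the optimal detector for specular echoes in white
noise, zero-phase because the pulse is symmetric. A Butterworth
band-pass or no conditioning are available.

- Candidate echoes are local maxima of the Hilbert envelope exceeding
  `max(6 × noise floor, 1% of the reference envelope peak)`, the noise
  floor being the RMS envelope of the leading 15% of the line (valid
  while the standoff keeps echoes out of that segment). The factor 6
  is chosen so that the Rayleigh tail over the several thousand
  pre-surface samples contributes a negligible false-detection rate; a
  false surface detection displaces `d_i` by millimetres and corrupts
  URI catastrophically, whereas a dropped line merely renormalizes m.
- The **surface** echo is the first candidate; the **interface** echo
  is the largest candidate in the window (surface + one pulse length,
  surface + max TOF]. The dead time prevents the surface tail being
  read as the interface. Pulse length = reference envelope full width
  at 1/10 maximum.
- Echo times are refined to sub-sample precision by parabolic
  interpolation of the envelope peak; `d_i = c_medium t_surf / 2`,
  `TOF_i = t_int − t_surf`.
- Amplitudes are reported in peak-to-peak units. The default estimator
  reads the interpolated envelope peak and scales by the reference's
  peak-to-peak/envelope-peak ratio — exact for specular echoes (scaled
  copies of the pulse) and insensitive to the upward selection bias
  that a raw max-minus-min readout suffers in noise (measured: ~1.2%
  relative bias on RC1 at default noise for raw peak-to-peak vs
  <0.3% mean for the envelope-scaled form). Raw peak-to-peak within
  ±1 pulse length (on 8× band-limited upsampled samples) remains
  available as `amplitude_method="rf_peak_to_peak"`.
- Lines failing detection are flagged and excluded; more than 50%
  surface failures is a hard error.

Detections are per-line independent; no lateral continuity constraint
is imposed.

Measured performance at default conditions (m = 100, default noise;
see `scripts/acceptance.py`): URI within the SD sampling error of the
configured roughness, RC1 within 1% relative of `r_s × 100`, h within
one sample-period equivalent (≈2.1 µm) of the true mean thickness.

## 4. Trabecular morphometry

Binary isotropic volumes (12 µm voxels by default), full-volume VOI
unless a mask is supplied.

- **BV/TV** — foreground voxel count over VOI voxel count (exact).
- **Tb.Th / Tb.Sp** — volume-weighted mean local thickness of the bone
  / marrow phase, maximal-inscribed-sphere definition: the Euclidean
  distance transform gives candidate sphere radii; spheres are painted
  in decreasing radius order so each voxel keeps the diameter of the
  largest sphere containing it. Radii are taken as (EDT − ½) voxel so
  a slab of t voxels reads exactly t; radii are binned to ¼ voxel to
  bound the number of passes (error ≤ ⅛ voxel). Because sphere
  centres live on voxel centres, structures whose medial axis falls
  between voxels can read up to ~1 voxel thin — the usual resolution
  of this family of algorithms.
- **Tb.N** — model-independent inverse mean spacing
  `1/(Tb.Th + Tb.Sp)` by default; the plate-model form `(BV/TV)/Tb.Th`
  is available. Vendor "direct" Tb.N variants differ in detail.
- **Conn.D** — first Betti number per unit total volume. The Euler
  characteristic is computed exactly on the closed cubical complex
  (χ = V − E + F − C by vectorized cell counting), which corresponds
  to **26-connected foreground / 6-connected background** — stated
  because χ depends on the convention. β₁ = β₀ + β₂ − χ with β₀ from
  26-connected labeling and β₂ from enclosed background components.
  If the foreground is disconnected the largest component is used and
  a warning issued.
- **SMI** — `6·V·S′/S²` with plate ≈ 0, rod ≈ 3, sphere ≈ 4. S and V
  are the area and enclosed volume of the zero-level isosurface of the
  signed distance field (half-voxel-corrected EDT, Gaussian-smoothed
  by 1 voxel to suppress faceting, which otherwise inflates S by
  ~10%). S′ = dS/dr under a uniform surface offset equals twice the
  integrated mean curvature and is evaluated discretely as
  Σ (edge length × signed dihedral angle) over mesh edges; offset
  level sets of the discrete EDT were measured to move ≠ ½ voxel per
  ½-voxel level and are not used. Measured on digital phantoms:
  sphere 3.99, long cylinder 3.07 (end caps raise the ideal 3), wide
  thin plate 0.19 (edge rims raise the ideal 0). Foreground touching
  all six faces has no bounded surface and is rejected.

Phantom generators provide the ground truth: parallel plates (BV/TV =
t/p exact when the axial extent is a whole number of periods; plates
centred in the period so volume faces fall mid-gap and the in-plane
mirror symmetry of the EDT is respected), cubic rod lattices (painted
edge by edge; the independent-loop count of the kept rod graph is
recorded, giving a graph-theoretic oracle for Conn.D), solid blocks,
and tori (β₁ = 1). Rod lattices drop a seeded 5% of rods by default so
every synthetic specimen has its own connectivity — without this all
specimens in a cohort would share one Conn.D value, which no real
cohort shows.

## 5. Statistics

Group comparison uses the Mann–Whitney U test, U from rank sums with
midranks for ties. For pooled sizes n₁+n₂ ≤ 16 the two-sided p-value
is computed by full enumeration of all C(n₁+n₂, n₁) assignments of the
observed pooled values — exact under ties because the permutation
distribution conditions on the observed values; 7 vs 7 enumerates
3432 assignments. Two-sided p = 2 × min(lower tail, upper tail),
capped at 1. Larger samples use the tie-corrected normal approximation
with continuity correction. A constant pooled sample yields p = 1 and
is flagged `degenerate`. Significance is declared at p ≤ α (default
0.05) with **no multiplicity correction**, matching the single-test
reporting convention of small-animal studies. The discrete 7-vs-7 test
attains size 0.0379 at nominal 0.05 (`attained_size`).

## 6. Study pipeline and cohort design

`run_study` synthesizes a two-group cohort (default 7 + 7), scans two
cartilage sites per specimen (medial- and lateral-plateau-like
parameterizations) plus one trabecular volume, extracts all parameters
and compares groups. The treated group's latent truths are multiplied
by per-site effect multipliers; between-animal variability is applied
as truncated-Normal CVs (roughness 15%, reflectivities 10%, thickness
5%, rod radius 5%, cell size 3%). The shipped demo effects — surface
roughness ×3 / ×2.5, surface reflectivity ×0.6 at the first site only,
thickness ×0.75, bone ×1.0 — are synthetic defaults chosen to mirror
the qualitative early-estrogen-deficiency pattern (cartilage changes
detectable, bone not yet); they are not estimates of any measured
cohort. Every output table carries the seed and a config hash.

The type-I-error simulation samples the cohort's latent parameter
layer directly (1000 null cohorts) rather than synthesizing RF for
14,000 specimens: under the null the measurement stage adds
identically distributed noise to both groups, so group exchangeability
— the only property the rank test uses — is already decided at the
latent layer.

## 7. Problem sizes and determinism

Default scans are 100 lines × ~5600 samples (~25 ms to simulate,
~70 ms to detect); trabecular volumes are 64³ voxels (~1.5 s for the
full panel); the full demo study runs in ~25 s and the acceptance
script in ~30 s on one CPU. All randomness flows from
`numpy.random.default_rng` / `SeedSequence` seeds carried in the
specs; reruns with the same seed are bit-identical.

## 8. Known limitations

- The specular forward model omits speckle; detection thresholds may
  need retuning for RF with tissue backscatter.
- Thickness estimates assume a single constant sound speed in
  cartilage; dispersion and refraction are ignored.
- Local thickness carries the usual ≤1 voxel medial-axis quantization.
- SMI is the classic differential form, which modern literature
  criticizes for concave surfaces; it is provided because it remains
  the conventional panel member.
- The exact test enumerates up to pooled n = 16; beyond that the
  normal approximation is used (labelled in the output).
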