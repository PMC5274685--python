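# cartiqus

Quantitative pulse-echo ultrasound assessment of articular cartilage,
micro-CT-style trabecular bone morphometry, and exact two-group rank
statistics — exercised end to end on synthetic phantoms with known
ground truth.

Early estrogen deficiency (the menopause model produced by
ovariectomy, "OVX") degrades articular cartilage before measurable
cancellous bone loss appears. Detecting that early window requires
quantitative readouts on both tissues: high-frequency (50 MHz)
pulse-echo ultrasound of the cartilage surface and thickness, and
trabecular morphometry of the underlying cancellous bone. This package
implements both analysis chains for researchers who want a tested,
seedable reference implementation — and, because raw RF scans of such
studies are rarely shared, ships physics-based generators so every
stage is verifiable against known truth.

## The quantities

From the m RF A-lines of one scanned site (m = 100 over a
0.3 mm × 0.3 mm region by default), with `d_i` the
transducer-to-surface distance, `A_i`/`A_j` the surface/interface echo
peak-to-peak amplitudes, `A_ref` a perfect-reflector amplitude and
`TOF_i` the surface-to-interface time-of-flight:

    URI = sqrt( (1/m) Σ (d_i − d̄)² )            surface roughness, µm
    RC1 = (1/m) Σ A_i / A_ref × 100%            surface reflection
    RC2 = (1/m) Σ A_j / A_ref × 100%            interface reflection
    h   = (1/m) Σ c_cartilage · TOF_i / 2       thickness, mm  (c = 1675 m/s)

From a binary trabecular volume (12 µm isotropic voxels): BV/TV, Tb.N,
Tb.Th, Tb.Sp, Conn.D (first Betti number per volume, 26/6
connectivity) and SMI (plate ≈ 0, rod ≈ 3, sphere ≈ 4). Group
comparisons use the Mann–Whitney U test with the two-sided p-value
computed by full enumeration of all C(n₁+n₂, n₁) group assignments
(3432 at 7 vs 7), exact even under ties.

See `docs/methods.md` for models, estimators and numerical choices.

## Worked example

```python
from cartiqus import (TransducerSpec, CartilagePhantomSpec, simulate_reference,
                      simulate_rf_scan, detect_echoes, compute_acoustic_params)

transducer = TransducerSpec()                      # 50 MHz, 400 MHz sampling
reference = simulate_reference(transducer)         # perfect-reflector A-line
phantom = CartilagePhantomSpec(seed=7)             # 100-line scan, defaults
scan, truth = simulate_rf_scan(phantom, transducer)

features = detect_echoes(scan, reference)
params = compute_acoustic_params(features)
print(f"URI = {params.uri_um:.2f} um   (true SD of d_i: {truth.true_uri_um:.2f} um)")
print(f"RC1 = {params.rc1_pct:.2f} %    (r_surface x 100: {truth.true_rc1_pct:.2f} %)")
print(f"RC2 = {params.rc2_pct:.2f} %   (true interface ratio: {truth.true_rc2_pct:.2f} %)")
print(f"h   = {params.h_mm:.4f} mm (true mean thickness: {truth.true_h_mm:.4f} mm)")
```

prints

```
URI = 6.98 um   (true SD of d_i: 7.00 um)
RC1 = 5.02 %    (r_surface x 100: 5.00 %)
RC2 = 18.73 %   (true interface ratio: 18.72 %)
h   = 0.2491 mm (true mean thickness: 0.2491 mm)
```

i.e. the detector recovers this scan's realized surface roughness,
reflectivities and thickness essentially exactly at the default noise
level. Note RC2 (18.7%) sits well below the configured interface
reflectivity (25%): by definition it is uncorrected for transmission
loss and cartilage attenuation.

The full study design — a sham and an OVX-like group of 7 specimens
each, two cartilage sites plus one trabecular volume per specimen,
every parameter compared by the exact test — runs as

```python
from cartiqus import default_study_config, run_study
report = run_study(default_study_config(seed=0))
print(report.comparisons[["parameter", "p_value", "significant"]])
```

With the shipped defaults (cartilage effects on, bone effects off) the
comparison table flags URI and thickness at both sites and RC1 at the
first site as significant (p ≤ 0.05, exact), and none of the six bone
parameters — the qualitative signature of early estrogen deficiency.

A CLI mirrors the stages:

```sh
cartiqus simulate  --config cohort.yaml --out data/ --seed 1
cartiqus acoustic  --in data/sham_01_mtp.h5 --out params.json
cartiqus morpho    --in data/sham_01_trabecular.tif
cartiqus compare   --table parameters_wide.csv --alpha 0.05
cartiqus run-study --out study_out/ --seed 1 --figures
```

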