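# zshim

Adaptive slice-specific z-shimming and model-based R2\* mapping for 2D
spoiled multi-echo gradient-echo (mGRE) MRI.

## The problem

R2\* (= 1/T2\*) mapping from 2D mGRE data is biased wherever a macroscopic
through-slice field gradient `Gz` (air/tissue interfaces, sinuses, temporal
lobes) dephases the magnetization within the slice: the measured decay

    S(TE_i) = S0 · exp(−R2*·TE_i) · F_zshim(TE_i)

is modulated by the dephasing function

    F_zshim(TE_i) = ∫ M_xy(z) · e^{ i γ (Gz + Ḡ_c,i) z TE_i } dz  ⁄  ∫ M_xy(z) dz ,

where `M_xy(z)` is the Bloch-simulated slice profile and `Ḡ_c,i` the mean
compensation (z-shim) gradient accumulated by echo i.  A fitted
mono-exponential overestimates R2\* roughly in proportion to |Gz|; a z-shim
gradient train can rephase the signal, but a single global shim value only
helps where it happens to match −Gz.

This package implements, for methods researchers and simulation studies:

* **Shim-pattern design** — inter-echo moment trains for three schemes:
  none, global alternating pairs, and a slice-specific pattern that splits
  the per-slice extrema `(g⁺ₙ, g⁻ₙ)` into fractions 1/3, 2/3, 3/3 (or
  1/5 … 5/5 when one extremum is zero), rewinding the net moment after
  each block.  Moments and mean gradients interconvert exactly via
  `Σ_{k≤i} m_c,k = Ḡ_c,i·TE_i`.
* **Prescan processing** — a fast 3-echo phase scan is unwrapped, converted
  to a field map, masked, differentiated through-slice, smoothed, quantized
  to 10 µT/m bins, and reduced to per-slice compensation extrema.
* **Slice-profile and dephasing modelling** — hard-pulse Bloch simulation
  of shaped RF pulses with B1+ scaling, spoiled-GRE steady state, and the
  λ = Gslice/(Gz+Gslice) thickness rescaling; F tabulated over Gz for fast
  voxelwise lookup.
* **Forward simulation** — digital phantoms with ground-truth S0/R2\*/B0
  maps, per-shot respiration-like field fluctuations, a navigator echo and
  Rician noise.
* **Reconstruction** — navigator phase correction and voxelwise nonlinear
  magnitude fitting of (S0, R2\*), with a mono-exponential baseline and
  region summaries (median, IQR).
* **Sensitivity analysis** — relative R2\* error when B1+, λ and TR/T1 are
  included in or omitted from the fitting model.

## Worked example

Simulate a homogeneous agar-like phantom (true R2\* = 6.4 1/s) whose
through-slice gradient ramps from ≈ −200 to +150 µT/m across 26 slices,
drive the adaptive shim from a synthetic prescan, and fit R2\* with the
dephasing model:

```python
import zshim

params = zshim.phantom_params()          # 20-echo, 4 mm slices, alpha 60
phantom = zshim.make_phantom("uniform-agar", seed=1)

# 1) prescan -> per-slice compensation gradients
pres = zshim.simulate_prescan(phantom, zshim.prescan_echo_times())
gz_map, selections = zshim.process_prescan(
    pres.magnitude, pres.phase, pres.echo_times, phantom.voxel_size,
    erosion_radius_px=1,
)
s = selections[20]
print(f"slice 20: g_plus = {s.g_plus*1e6:.0f} uT/m, g_minus = {s.g_minus*1e6:.0f} uT/m")

# 2) slice-specific shim patterns and forward simulation
patterns = [zshim.build_adaptive_pattern(params, s) for s in selections]
series = zshim.simulate_mgre(phantom, params, patterns, noise_sd=0.0)

# 3) model-based R2* fit via the dephasing table
gslice = zshim.slice_select_gradient(params)
profile = zshim.simulate_profile(
    zshim.sinc_hanning_pulse(), params.flip_angle_deg, 1.0, gslice,
    slice_thickness=params.slice_thickness,
)
tables = [zshim.build_table(profile, p, gslice) for p in patterns]
fit = zshim.fit_r2star_model(series, phantom.gz_map(), tables)

print(zshim.summarize_regions(fit, phantom.labels).to_string(index=False))
```

Output:

```
slice 20: g_plus = 0 uT/m, g_minus = -85 uT/m
 region  n_voxels   median      iqr
      1      4888 6.313803 0.062756
```

Slice 20 sits where the field gradient is ≈ +80 µT/m, so the prescan
selects only a negative compensation extremum (−85 µT/m, the quantized
opposite of the slice's gradient) and the pattern falls back to five
fractions of it.  The fitted phantom-wide median R2\* of 6.31 1/s recovers
the ground truth of 6.4 1/s to within 1.4 % across the whole ±200 µT/m
gradient range — a mono-exponential fit of the same no-shim data
(`zshim.fit_r2star_mono`) instead reads 40–100 1/s in the strongly
dephased slices.

The same pipelines are scriptable from the shell:

```sh
zshim simulate  --config run.yml --out run/
zshim prescan   --magnitude mag.nii.gz --phase ph.nii.gz --te 2.7,4.8,6.9 --out pre/
zshim pattern   --scheme adaptive --selections pre/selections.csv --out pat/
zshim fit       --config fit.yml --out maps/
zshim sensitivity --out sens/
```

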