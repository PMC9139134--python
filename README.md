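# focidens

Quantification of radiation-induced DNA damage from γH2AX immunofluorescence
images, and evaluation metrics for nanoparticle-enhanced radiotherapy plans.

`focidens` is for radiobiology and medical-physics groups who irradiate
cells at graded doses (with and without a radiosensitizer such as gold
nanoparticles), image γH2AX foci in two-channel fluorescence micrographs,
and need a reproducible number for the biological enhancement. It provides:

- **Nuclei segmentation** from the DAPI channel: Otsu binarization,
  adaptive median denoising, hole filling, opening by reconstruction with a
  minimal nucleus radius (default 25 px), and an iterated morphological
  closing. Touching nuclei deliberately stay merged: the unit of analysis is
  the *object of quantification* (nucleus or small group), not the single
  cell.
- **Foci detection** in the γH2AX channel: adaptive median filter, white
  top-hat with maximal focus radius `r_f`, H-maxima transform at the Otsu
  level `h` of the filtered signal, and an intensity gate `T_e` on the
  original pixel values. The statistic is the **foci density** — foci count
  divided by object area (foci·px⁻¹) — which is robust to nucleus size and
  cell-splitting artifacts.
- **Dose-response analysis**: per-image Tukey-fence outlier screening,
  mean ± SEM per condition, ordinary least squares of density on dose, and
  the **radiosensitization factor**

  &nbsp;&nbsp;&nbsp;&nbsp;RSF = gradient(treated) / gradient(control),

  the ratio of the two fitted slopes (e.g. gradients ≈ 3.25 vs ≈ 2.23 give
  RSF ≈ 1.46).
- **Plan-evaluation metrics** on voxel dose grids: the dose enhancement
  factor DEF = D_with/D_without (voxelwise, mean ± SD over the target) and
  the conformity number CN_p = (V_p/V)·(V_p/T_p) at p % of the prescription
  dose.
- A **seeded synthetic-data generator** producing two-channel fixtures with
  exact ground truth (nucleus geometry, planted foci, dose-linear densities)
  and toy dose grids, so the whole pipeline is testable without any
  microscope data.

## Worked example

Generate a two-arm synthetic experiment with a planted slope ratio of 1.46
and push it through the full pipeline:

```python
from focidens import (FociParams, analyze_dose_response, generate_dose_series,)

pairs_c, _ = generate_dose_series(5e-4, 2e-4, objects_per_dose=200,
                                  seed=20301, group="control")
pairs_t, _ = generate_dose_series(5e-4 * 1.46, 2e-4, objects_per_dose=200,
                                  seed=20502, group="treated")
params = {"control": FociParams(r_f=13, t_e=0.55),
          "treated": FociParams(r_f=13, t_e=0.55)}
result = analyze_dose_response(pairs_c + pairs_t, foci_params_by_group=params)
for group, fit in result.fits.items():
    print(f"{group}: slope={fit.slope:.3e} R2={fit.r_squared:.4f}")
print(f"radiosensitization factor: {result.factor:.3f}")
```

Output (fixed seeds):

```
control: slope=4.880e-04 R2=0.9998
treated: slope=7.355e-04 R2=0.9992
radiosensitization factor: 1.507
```

The fitted gradients recover the planted 5.0·10⁻⁴ and 7.3·10⁻⁴
foci·px⁻¹·Gy⁻¹ within ~2.5 %, both fits are essentially perfectly linear
over the {0, 0.25, 0.5, 1, 2} Gy design, and the recovered factor 1.507
matches the planted 1.46 within ~3 % (sampling noise at 200 objects per
condition; other seeds land in a similar band, e.g. 1.475 from
`scripts/acceptance.py --seed 1`).

On real data, the same analysis starts from TIFFs via the CLI:

```bash
focidens quantify --config run.yaml --out results/
focidens optimize --config run.yaml          # grid-search r_f, T_e per group
focidens dosemetrics --dose-with w.nii --dose-without wo.nii \
                     --mask btv.nii --rx 70 --percent 100 --percent 90
focidens synth scene --seed 7 --out fixtures/
```

`run.yaml` lists the images with dose/group metadata, the channel indices
and per-group `r_f`/`T_e` (see `focidens.cli` docstring for the schema).
`quantify` writes per-object, per-condition and per-fit CSVs, a parameter
sidecar JSON, the factor, and a dose-response plot.

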