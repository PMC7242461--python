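# utemri

Synthetic multi-echo MRI simulation and R2*/R2 relaxometry for
iron-oxide (SPIO) cell-tracking studies in joints.

## The problem

Mesenchymal stem cells injected into a joint can be tracked on MRI by
labelling them with superparamagnetic iron-oxide nanoparticles, which
accelerate local transverse relaxation (raise R2 and R2*). The catch is
that bone and concentrated SPIO deposits decay so fast that standard
Cartesian multi-echo gradient-echo acquisitions — whose first echo
arrives several milliseconds after excitation — see nothing there, and a
focal SPIO depot "blooms" into a signal void far larger than the depot
itself. Ultrashort-echo-time (UTE) acquisitions with center-out k-space
trajectories sample the k-space center ~0.03 ms after excitation and
retain that signal.

`utemri` packages the complete quantitative chain of such a study as
testable code operating on synthetic data: digital joint phantoms with
the five standard regions of interest (synovial joint space, fat pad,
tibial bone, dorsal muscle, defect region), a forward signal model with
SPIO relaxivity, dipole-field blooming and Rician noise, three
acquisition protocols (five-echo UTE, six-echo Cartesian mGE, four-echo
FSE), k-space sampling/gridding for the center-out vs Cartesian
contrast, voxelwise relaxometry, and ROI-level group statistics.

## The model

Per voxel the magnitude signal follows (bi-)exponential decay

    S(TE) = S0 [ f e^(-R_fast TE) + (1-f) e^(-R_slow TE) ],

with `f = 0` for mono-exponential tissue. In gradient-echo mode
`R_slow = R2* + r·c` (relaxivity `r`, SPIO concentration `c`) and the
signal is further attenuated by intravoxel dephasing in the dipole field
of the depot's susceptibility; in spin-echo mode the rate is R2.

Quantification mirrors standard practice:

* **Log-linear fit** — ordinary least squares of `ln S` on TE gives the
  rate map `R = -slope` (s^-1), with voxels below a signal floor
  excluded, as in regions of heavy blooming.
* **Echo ratios** — fractional signal loss between echo pairs,
  `R_ij = (S_i - S_j)/S_i`, zero for no loss, approaching 1 at complete
  loss (`R12`, `R15`, `R25` over the five UTE echoes).
* **Two-point rate** — `-ln(1 - R_ij)/ΔTE`, exact for mono-exponential
  decay.
* **Echo subtraction** — `S(TE_i) - S(TE_j)` highlights fast-decaying
  tissue (bone, SPIOs) as hyperintense.
* **Group comparison** — each replicate phantom ("animal") contributes
  one ROI mean; groups are compared with a two-sided Welch t-test at
  α = 0.15.

## Worked example

```python
from utemri import (PhantomConfig, generate_phantom, simulate_series,
                    CONES_UTE, MonoExponentialModel, roi_summary,
                    replicate_study)

phantom = generate_phantom(PhantomConfig(spio_group=True), seed=0)
series = simulate_series(phantom, CONES_UTE, noise_sigma=2.0, seed=1)
results = MonoExponentialModel(series).fit()
print(results.summary())
```

```
Mono-exponential log-linear fit
  mode:            r2star
  echoes (ms):     0.03, 4, 8.1, 12.1, 16.1
  signal floor:    6
  valid voxels:    9647 / 16384 (58.9%)
  rate median:     64.84 s^-1
  rate IQR:        [36.54, 273.74] s^-1
  negative rates:  7
  median R^2:      0.9943
```

The fitted map summarised over the phantom's ROIs recovers each
tissue's configured rate (joint space 64 s^-1 here, the SPIO-injected
group value; bone ≈ 300 s^-1 is recovered with larger spread because
its signal crosses the noise floor by the later echoes):

```python
print(roi_summary(results.rate_map, phantom).to_string(index=False))
```

```
          roi  n_voxels       mean        sd
defect_region       161  49.961478  3.263840
dorsal_muscle      3220  34.934106  2.715535
      fat_pad       822  39.767184  2.561111
  joint_space       960  63.923752  3.168087
  tibial_bone      4474 277.672576 39.224473
```

A two-group replicate study (seven synthetic joints per group,
joint-space R2* drawn around 64 s^-1 for the SPIO group and 70 s^-1 for
controls with between-replicate SDs of 6 and 7 s^-1):

```python
study = replicate_study(n_per_group=7, noise_sigma=2.0, seed=1)
print(study.comparisons.to_string(index=False))
```

```
        roi       metric group_a group_b         t        p  significant
joint_space r2star_cones    spio control -2.354918 0.036387         True
```

`t < 0` means the SPIO group's joint-space rate is lower; whether the
difference clears α = 0.15 depends on the draw — at this spread and
sample size the comparison is under-powered, which is the point of
simulating it.

The same pipeline is scriptable from a shell:

```bash
utemri simulate --config run.yaml --out out/
utemri fit out/series.nii.gz --out out/
utemri ratios out/series.nii.gz --out out/
utemri reproduce --seed 3 --n-per-group 7 --out study/
```

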