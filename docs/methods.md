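# Methods

## Scope and intent

`utemri` reproduces, on synthetic data, the quantitative analysis chain
of an SPIO cell-tracking MRI study in a large-animal joint model:
multi-echo signal simulation, R2*/R2 relaxation mapping, echo-ratio
statistics, echo-subtraction imaging, k-space trajectory contrast, and
ROI-level group comparison. No scanner data are consumed; the phantom
generator defines the study conditions, and everything downstream is
exercised against it.

## Phantom

The phantom is a single sagittal slice (2D by default, thin-3D
optional) of simple parametric shapes: a dorsal muscle slab, an
elliptical fat pad, a thin synovial joint-space band, a tibial bone
slab, and an 8 mm-diameter disc carved into the bone surface for the
osteochondral defect. These are the five ROIs the analysis summarises.
Geometry is a pure function of the configuration; the seed only
perturbs an optional smoothed proton-density texture, so labelled
volumes are identical across seeds. Coordinates are (row, column[,
slice]), 0-based, voxel centers at integer positions; the default voxel
is 0.5625 mm (a 180 mm field of view at a 320 matrix).

Tissue parameters (signal-unit proton density; R2*, R2 in s^-1;
optional fast pool; SPIO concentration; susceptibility in ppm) are free
parameters with documented defaults. Two are anchored to the study
being emulated: the joint-space R2* is 64 s^-1 in the SPIO-injected
group and 70 s^-1 in controls. Bone is given R2* = 300 s^-1 — a design
choice, not a measured value — so that it is effectively invisible at a
7 ms first echo but retains ~99% of its signal at 0.03 ms. Every tissue
satisfies R2 ≤ R2*, since R2* includes the reversible dephasing
contribution R2'. ROI placement is parametric and makes no claim to
match the original study's manually drawn ROIs.

The focal SPIO depot is a disc of elevated concentration (1.0 unit) and
susceptibility (10 ppm) centered in the fat pad, emulating a
supra-patellar injection of labelled cells.

## Forward model

Per voxel, `S(TE) = PD [f e^(-R_fast TE) + (1-f) e^(-R_slow TE)]`. The
optional fast pool represents multi-component decay (cartilage-like
tissue); the default tissues are mono-exponential, matching what a
log-linear fit assumes. T1/steady-state weighting is folded into PD: no
T1 correction is modelled, and because all echoes of a protocol share
one excitation, any T1 scaling cancels in every ratio and fit.

SPIO enters twice:

* inside the depot, an additive relaxivity `R_slow = R2* + r·c` with
  `r = 1000 s^-1` per concentration unit in gradient-echo mode
  (200 s^-1 in spin-echo mode). The default makes the depot signal at
  the 7 ms Cartesian first echo ≈ `90·e^(-7.3) ≈ 0.06` signal units,
  far below any realistic noise floor — i.e. non-fittable, the regime
  in which relaxivity is not reported clinically. No calibration to
  real iron mass is claimed; relaxivity is a free parameter.
* outside the depot, blooming: the susceptibility map is convolved
  spectrally with the unit dipole kernel `1/3 - k_par²/|k|²` (zero at
  k = 0, grid zero-padded 2x per axis against wrap-around). In 2D a
  fixed in-plane axis (axis 0) stands for the B0 axis, making the
  result the field of out-of-plane line sources. The k = 0 zeroing is a
  gauge choice fixing the domain-mean field to zero; comparisons to the
  real-space summation oracle align this gauge before differencing.
  The residual disagreement (wrap-around plus discretisation) is ≤ 5%
  of the local dipole magnitude beyond three source radii on a 64²
  grid. Intravoxel dephasing is then computed per echo as the magnitude
  of the mean phasor over linearly interpolated subvoxel samples
  (default 4 per axis); for a linear intravoxel gradient this
  reproduces the analytic |sinc| attenuation to <1% at 16 subsamples.

Noise is Rician — the magnitude of the complex signal plus independent
Gaussian noise in both channels — so dark voxels are
Rayleigh-distributed with mean σ√(π/2). All randomness flows through a
single `numpy` generator seeded per call.

Spin-echo (`r2` mode) simulations use R2 and ignore the static dipole
field, since spin echoes refocus static dephasing.

## Protocols

Three presets parameterise the simulations: a five-echo UTE protocol
(TE = 0.03, 4.0, 8.1, 12.1, 16.1 ms; TR 23 ms; flip 15°), a six-echo
Cartesian multi-echo gradient echo (TE = 7.0, 12.8, 18.5, 24.3, 30.1,
35.8 ms; TR 40.7 ms; flip 20°), and a four-echo FSE series for R2
(TE = 2.8, 31.7, 63.8, 112 ms; TR 1920 ms). Echo times are
authoritative; sequence internals (composite-pulse preparations,
susceptibility-weighted reconstruction filters) are out of scope.

## Acquisition layer

An optional k-space layer demonstrates why the trajectory family
matters. A 2D center-out radial trajectory stands in for 3D interleaved
cones: the property under test — sampling the k-space center at
TE ≈ 0 preserves short-T2* signal — is generic to center-out
trajectories, and no cones waveform mathematics is claimed. Sampling is
an exact DFT of the object with decay evaluated at each sample's
acquisition time (samples grouped by unique time); Cartesian samples
all share the echo time, radial sample times grow linearly with |k|
over a configurable readout (default 1 ms). Reconstruction is adjoint
gridding: analytic annulus-area density compensation for radial (unit
cell areas for Cartesian), width-4 Kaiser-Bessel interpolation onto a
2x oversampled grid (Beatty shape parameter), inverse FFT, numeric
deapodization. Center-out readouts oversample the center, so the
radial default uses two radial samples per Cartesian Δk; at that
density the reconstructor matches direct FFT inversion to ≤ 2%
relative RMSE on non-decaying objects (0.6% measured radially, <0.1%
Cartesian at 64²).

## Relaxometry

Rate maps come from unweighted ordinary least squares of `ln S(TE)` on
TE — the paper-standard "linear least-squares" estimator — per voxel
over the echoes whose signal exceeds a floor (default 3x the noise σ,
or 1e-12 for noiseless data). Voxels with fewer than two usable echoes
are flagged invalid rather than raising, mirroring the exclusion of
non-fittable blooming regions; an all-invalid image is a valid result.
Negative fitted rates are retained but visible in diagnostics —
clipping would bias ROI means under noise. A flat log-signal is a
perfect fit of rate 0 and reported with R² = 1. Echo times are ms at
every interface; the ms→s conversion lives in one place and all rates
are s^-1.

The two-point estimate is `-ln(1 - R_ij)/ΔTE`. The verbal description
this implements ("the negative logarithm of the ratio, minus one") is
ambiguous as prose; the adopted reading is the only one that inverts
mono-exponential decay exactly, and it is unit-tested against the
forward model and against the full log-linear fit (agreement to
machine precision on noiseless data). The R2 fit uses all four FSE
echoes by default.

Echo ratios satisfy, on noiseless mono-exponential data, the exact
identity `1 - R15 = (1 - R12)(1 - R25)` and the bounds `0 ≤ R < 1`;
both are enforced in tests at 1e-10 or better.

## Statistics

The replicate unit is one phantom instance (one synthetic "joint");
voxels within an ROI are never treated as independent samples. ROI
summaries report mean and population SD over valid voxels, with
zero-valid ROIs omitted rather than zeroed. Group comparison is a
two-sided Welch t-test by default (Student and paired variants are a
switch), at α = 0.15 with no multiple-testing correction — a faithful
reproduction of the emulated screening analysis, not a recommendation.
Welch p-values are cross-checked against the exhaustive permutation
distribution of the t statistic (n ≤ 6 per group, 924 splits),
agreeing within 0.05 on normal data.

`replicate_study` draws each replicate's joint-space R2* from
N(group mean, between-replicate SD) — defaults 64 ± 6 s^-1 (SPIO) vs
70 ± 7 s^-1 (control) — simulates, fits, and compares. Replicate
phantoms carry no depot: the group difference is expressed through the
joint-space rate itself. The replicate R2 is scaled as 0.65·R2* so the
FSE metric carries the same group structure. Default study size in the
acceptance script is 7 per group with noise σ = 2 (first-echo SNR 50 in
the joint space) on 64² phantoms; at these settings a single run's
p-value scatters around ~0.05–0.15 across seeds, i.e. the design is
marginally powered for a 6 s^-1 difference — the study-scale conclusion
this package is built to let one probe.

## What the generator does and does not emulate

Emulated: compartmental mono-/bi-exponential decay with realistic joint
rates, echo-time structure of the three protocols, SPIO relaxivity and
blooming geometry, Rician magnitude statistics, between-animal spread.
Not emulated: anatomical geometry, partial-volume mixtures at tissue
boundaries, B0/B1 inhomogeneity beyond the depot's dipole field, fat
chemical shift, motion, coil sensitivity, scanner reconstruction
filters. Passing tests therefore demonstrate correctness of the
estimators and the internal consistency of the model — not performance
on in-vivo data.

## Numerical choices and problem sizes

Default phantom 128² (tests mostly 64²); dipole oracle and gridding
oracle at 64²; noise-robustness check at 20 replicates; permutation
oracle exhaustive at 6+6. These sizes keep the full suite under a
minute on one core while leaving every comparison's tolerance
meaningful. Ties and degenerate inputs: identical groups define
t = 0, p = 1; zero-variance groups with different means give ±inf and
p = 0 (passed through); empty k-space sample sets, sub-32 grids,
non-increasing echo times, and sidecar/volume mismatches raise named
errors.

## Known limitations

* The 2D line-dipole geometry scales blooming differently from a 3D
  point dipole (field falls as 1/r² rather than 1/r³); void-area
  comparisons are therefore qualitative, ordered contrasts, not
  quantitative artefact-size predictions.
* The log-linear estimator is biased for bi-exponential tissue; the
  bi-exponential phantom option exists precisely to demonstrate that
  the fitted mono-exponential rate falls strictly between the
  component rates.
* Echo-ratio maps under noise can leave [0, 1); such voxels are masked
  in the two-point estimate rather than clipped.
* The acquisition layer reconstructs single echoes; it does not
  simulate interleave ordering, partial Fourier, or parallel-imaging
  acceleration.
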