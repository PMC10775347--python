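# Methods

`vistamrf` implements a complete desk-scale model of 3D ViSTa-MRF:
myelin-water, T1, T2 and proton-density mapping from a single
double-inversion-prepared MR fingerprinting acquisition, reconstructed with
a temporal-subspace / locally-low-rank solver.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Sequence and signal model (EPG)

One acquisition group consists of eight ViSTa preparation blocks followed
by a 500-time-point FISP-MRF block (660 readouts per group).  Each ViSTa
block applies two ideal inversions (TI1 = 560 ms between inversions,
TI2 = 220 ms from the second inversion to the first readout), acquires 20
spoiled gradient-echo readouts (TR/TE = 12/1.8 ms), and ends with an ideal
90° saturation plus a TD = 380 ms recovery — except the last block, where
saturation and TD are omitted so the signal runs smoothly into the MRF
block.  The MRF block inserts a 1 s rest and an inversion before its 200th
readout.  Groups are separated by another saturation + TD.

The double inversion nulls long-T1 magnetization at the first readout of
each block (the *ViSTa signal*): with the default timings, magnetization
with T1 ≳ 500 ms arrives at the readout with |Mz| below ~1% of equilibrium
while the myelin-water pool (T1/T2 = 120/20 ms) retains ~70%.

Signals are computed with the extended-phase-graph formalism:

* constant-phase RF (FISP convention) — with ideal inversions this keeps
  every configuration state real, so the engine evolves the real
  (F+, F−, Z) representation;
* one configuration shift per TR (ideal gradient spoiling), states
  truncated at 40 dephasing orders;
* inversions are ideal Z → −Z with a crusher; saturations zero all states;
  B1+ scales excitation angles only (preparation pulses are adiabatic and
  B1-insensitive);
* readout value = F0 after the pulse, decayed by exp(−TE/T2); units are
  chosen so a 90° tip of fully recovered Mz at unit proton density gives 1.

The engine is validated against a closed-form inversion-recovery limit
(<1e−6) and against an independent 2000-isochromat Bloch integration
(<1% relative on FISP subsequences; suppression ratios agree on the full
sequence).  Because the inter-group saturation erases all magnetization
history, the group-to-group steady state is exact after a single settle
group; the default `n_settle_groups = 3` is therefore conservative (a test
asserts bitwise equality of settle-1 and settle-3 simulations).

Not modeled: finite pulse durations and slice profiles, fat chemical
shift, magnetization transfer and inter-compartment exchange (single-pool
voxel compartments; see “Known limitations”).

### Timing model

Scan durations are quoted from the nominal 19 s group duration
(48 groups → 15.2 min, 16 groups → 5 min (≈304 s)).  The sum of the
explicitly modeled intervals is ~18.0 s per group; the ~1 s remainder is
pulse/spoiler time that the ideal-pulse model does not represent —
`SequenceProtocol.group_duration_modeled_ms` documents this gap.  The
standard (non-MRF) 2D ViSTa reference needs 48 interleaves × (TI1 + TI2 +
TD) = 55.68 s ≈ 56 s per fully-sampled slice.

## Flip-angle optimization (CRLB)

The flip-angle train is scored by the Cramér–Rao bound of (PD, T1, T2)
under i.i.d. Gaussian noise: J = ∂s/∂(pd, t1, t2) (exact in pd, central
differences with relative step 1e−3 in T1/T2), I = JᵀJ/σ², and

    cost = Σ_tissues w_i [ √CRLB(T1)/T1 + √CRLB(T2)/T2 ]

over myelin water (120/20), WM (750/60) and GM (1300/75) with equal
weights.  PD is carried as a nuisance parameter in the Fisher matrix.  The
optimizer is a projected gradient descent on a knot grid (one knot per 10
excitations, linear interpolation), with box bounds [1°, 90°] and a
smoothness limit of 5°/excitation; backtracking accepts only decreasing
steps, so the cost trace is monotone.  From a constant 35° start the
shipped train reduces the cost to 0.68× and begins at 30.3° — consistent
with the design intuition that continuous readouts favor a much smaller
first angle than the 90° single-shot excitation.

## Sampling: variable-density spiral + TGAS

One spiral-out arm is acquired per TR.  The arm is designed by numerical
integration of an Archimedean spiral with a Nyquist-pitch core (inner 5%
of k-space radius) ramping linearly to an outer pitch factor, under
gradient-amplitude and slew constraints (speed budget split between
centripetal and tangential acceleration, 0.9 safety).  If no pitch factor
is given, the smallest factor that reaches k_max within the readout window
is found by bisection.  The paper-scale gradient sets (40 mT/m, 100 T/m/s
at 1 mm; 60 mT/m, 160 T/m/s at 0.66 mm) produce constraint-clean 6.8 ms
arms; an audit method recomputes gradient/slew from the sampled waveform.

The tiny-golden-angle-shuffling schedule rotates the arm by 23.628° per TR
about a primary axis that cycles x → y → z per group.  Each group also
carries a fixed secondary tilt chosen so the per-group ring of plane
normals sits at a golden-ratio-stratified latitude, plus a golden-fraction
start angle.  On 480 TRs this reaches a spherical-cap discrepancy of
~0.054 (scattered golden-means points: ~0.013; i.i.d. uniform points:
~0.051).

Density compensation is Pipe–Menon (`w ← w/(GGᴴw)`, 30 iterations, unit
mean).  Small sample sets use an exact pairwise radial Kaiser–Bessel
convolution (isotropic — weights are exactly rotation invariant, and a
uniform Cartesian set gets exactly uniform weights); large sets use
gridded convolution (KB width 4, oversampling 1.25).

## NUFFT

Kaiser–Bessel gridding with table-interpolated kernels (numba).  The
forward transform matches the unnormalized centered DFT; forward and
adjoint are exact numerical transposes.  Defaults (oversampling 2.0,
width 7) give ~1e−6 relative accuracy versus brute-force DFT; the
reconstruction fast path uses width 4 / oversampling 1.25 (~1e−2), and the
forward simulation of demo data uses width 5 / oversampling 1.5 (~1e−4,
well below the simulated noise).

## Digital phantom (synthetic-data generator)

Nested-ellipsoid head: CSF shell, GM shell, WM core, two CSF ventricles;
tissue pools WM 750/60 ms (pd 0.77), GM 1300/75 (0.86), CSF 4000/2000
(1.0).  Each voxel is a two-pool mixture

    s(t) = pd [ mwf · S_120/20(t; b1) + (1 − mwf) · S_tissue(t; b1) ]

with no exchange or MT.  The MWF field inside WM is a smoothed Gaussian
random field rescaled to [0.05, 0.18]; B0 is a random quadratic polynomial
(±30 Hz) and B1+ likewise in [0.85, 1.15]; 8 complex Gaussian-lobe coil
sensitivities surround the head.  Everything derives from one integer
seed.

Noise: complex Gaussian per k-space sample.  The scale realizes a target
**single-frame image SNR**: the standard reconstruction of one time point
of non-Cartesian data (density-compensated, coil-combined adjoint) of the
first MRF time point shows SNR = (peak WM magnitude)/(per-voxel noise
std).  Numerator and denominator are evaluated numerically through the
identical operator, so the calibration is independent of FFT/adjoint
normalization conventions.  (A stricter alternative — per-coil, per-time-
point, fully-sampled image SNR — makes the same nominal number ~8x
noisier; under that reading the closed-loop least-squares ViSTa noise
floor already exceeds the WM myelin contrast, see "Known limitations".)

What the phantom does **not** emulate: realistic anatomy and partial
volume at tissue boundaries beyond voxelized ellipsoids, motion, eddy
currents, fat, MT/exchange, receive-field bias.  Passing closed-loop tests
therefore demonstrates the correctness and conditioning of the
acquisition-reconstruction-quantification chain, not robustness to those
real-data effects.

## Reconstruction

minimize_c ½‖W^(1/2)(MFSΦc − k)‖² + λ‖c‖_LLR, with Φ the rank-14 temporal
basis, W the Pipe–Menon weights (computed on one time point's sample set
and reused — the arm geometry is identical up to rotation), and the LLR
term the sum of nuclear norms of 8³-voxel casorati blocks with a random
cyclic shift per iteration.

* **Basis**: first 14 left singular vectors of the atom matrix (99.99% of
  dictionary signal energy).  For reconstruction the SVD training set is
  augmented with long-T1/T2 (CSF-range, up to 4400/2500 ms) evolutions,
  weighted ×100: these relaxation times lie outside the quantification
  grid but occur in the object, and an unrepresentable compartment would
  otherwise alias into the coefficient maps.
* **Basis balancing in the prox**: the data-term operator keeps the
  orthonormal Φ — because ΦᵀΦ = I the normal operator is naturally well
  conditioned across components, whereas scaling the operator columns by
  σ_k/σ_1 (dynamic-range balancing applied to the operator) makes the
  per-component curvature collapse as (σ_k/σ_1)² and the weak,
  myelin-information-carrying components never converge.  The balancing
  intent is preserved where it matters: the LLR threshold (and the λ
  calibration) act on coefficients rescaled by σ_1/σ_k, then scale back.
* **Backends**: an explicit per-timepoint-NUFFT operator (supports MFI,
  used for small problems and every oracle test), and a Toeplitz fast path
  that embeds the weighted normal operator as K×K stationary convolution
  kernels on the doubled grid — no NUFFT inside the iteration loop.
* **Solver**: FISTA, warm-started from the optimally scaled
  density-compensated adjoint; step = 0.95 / (inflated power-iteration
  estimate of ‖AᴴWA‖).
* **Preconditioning** (default): degree-2 Chebyshev approximation of the
  inverse of the normal operator's spectrum, applied to the gradient via
  Clenshaw recursion (d extra operator applications per iteration).  Two
  stability safeguards: the polynomial is normalized so max x·p(x) ≤ 0.98
  (FISTA with momentum requires an effective step below 1), and the fit
  interval extends to 1.45× the spectral estimate because eigenvalues
  above a finite-iteration power estimate would otherwise meet the
  exploding polynomial extrapolation.  A circulant alternative (Hermitian
  eigen-clipped per-frequency inverse of the K×K Toeplitz kernels) is
  available on the fast path; on the standard closed loop it did not
  outperform the polynomial and is not the default.
* **MFI off-resonance correction**: conjugate-phase demodulation at bin
  frequencies spanning the B0 range, with per-voxel least-squares
  interpolation coefficients over the readout; the approximation error
  decreases monotonically with the bin count.
* λ defaults to `lambda_scale` (3e-4 in the shipped closed-loop
  configuration, chosen once on the standard phantom) times the top
  casorati singular value of the balanced warm-start coefficients, so the
  threshold is a fixed fraction of the dominant coefficient scale;
  stronger settings visibly shrink the weak myelin components block-wise.
* Divergence guard: the run aborts with a diagnostic if the objective
  exceeds 10× its initial value.

The λ=0 solver path is verified against explicit dense normal-equation
solves (<1e−4 relative on an 8³ instance); the Toeplitz and explicit
normal operators agree to the gridding accuracy of the light kernel; the
gradient matches numerical directional derivatives.

## Quantification

Template matching runs in the subspace (⟨Φc, a⟩ = ⟨c, Φᵀa⟩), restricted to
the sub-dictionary at the B1 grid value nearest the voxel's B1+ (low
resolution side maps are linearly interpolated to the image grid).  PD is
the real matched-filter amplitude.  The ViSTa image is Φ[0,:]·c, and

    MWF = I_ViSTa / (I_PD · S_myelin(b1)),

where S_myelin is the EPG signal of the nominal 120/20 ms pool at the
ViSTa time point in 90°-of-full-Mz units (≈0.23–0.37 over the B1 grid).
The division by S_myelin follows from the signal model
I_ViSTa = MWF·PD·S_myelin.  Voxels with PD below 1% of its robust maximum
are zeroed; MWF is clipped to [0, 1], making the map invariant to joint
rescaling of PD and ViSTa.

### What the estimator estimates (apparent values)

Single-pool matching of a two-pool voxel returns *apparent* parameters.
With the phantom's WM (mwf 0.05–0.18, mean ≈0.115) the apparent T1 is
≈500 ms versus the 750 ms tissue pool — a deterministic ≈33% offset that
correlates −0.97 with mwf — and matched PD is ≈(0.96 − 0.65·mwf) of true
PD, which inflates the MWF-versus-true regression slope to ≈1.23 even for
a perfect, noiseless reconstruction.  (The apparent-T2 offset is much
smaller, ≈7%.)  This is a property of the method — direct MWF mapping
without multi-compartment fitting — not of the implementation, and the
direction (underestimated T1) matches what is expected when short-T1 water
is folded into a single pool.  Closed-loop validation therefore reports
recovery both against the generator's tissue parameters and against the
*apparent reference* obtained by matching the exact noiseless signals; the
latter isolates acquisition/reconstruction fidelity from the estimand
offset.

## Synthetic contrasts

Spin-echo (pd(1−e^{−TR/T1})e^{−TE/T2}), MPRAGE (single-shot inversion +
spoiled gradient-echo factor), FLAIR and DIR (single- and double-inversion
preparations from fully recovered Mz followed by a spin-echo factor).
Single-shot preparation makes the null conditions exact
(FLAIR: TI = T1·ln2); a root solver finds DIR inversion times nulling two
chosen T1s.  Steady-state saturation effects of short-TR readouts are not
modeled.

## Problem sizes of the shipped experiments

The standard closed-loop experiment uses a 32³ phantom (FOV 220 mm),
16 groups × 660 TRs of TGAS rotations, 8 coils, SNR 30, and the 14-basis
reconstruction; a gentler gradient set (10 mT/m, 50 T/m/s, pitch factor 3)
keeps a single arm near the along-arc Nyquist rate of the coarse matrix at
a 10 µs dwell.  The dictionary over the default grid has 95,425 atoms
(8,675 admissible (T1, T2) pairs × 11 B1 values).

### Reconstruction fidelity at the standard undersampling

On the standard 32³ / 16-group / SNR-30 closed loop the reconstructed
ViSTa image matches the true myelin-signal pattern at r ≈ 0.985 over the
volume, and quantification against the apparent reference reaches median
WM errors of ~4% (T1) and ~4% (T2) with an MWF regression slope ≈ 0.95.
The *within-WM voxelwise* MWF correlation is capped near 0.8: the
WM-internal myelin contrast spans only ~10% of the ViSTa amplitude, and
the ill-determined spatio-temporal directions of the 16-group
spiral-projection operator leave a systematic ViSTa-image floor
(~0.0026 in reconstruction units) that is invariant to the noise level,
regularization weight, preconditioning, iteration count and
gridding-kernel accuracy, and persists for noiseless in-subspace data.
More acquisition groups (or coarser MWF questions, e.g. ROI averages)
are the physical remedies.

## Known limitations

* Single-pool dictionary: apparent (not pool-specific) T1/T2/PD, as above.
* Ideal pulses: no slice profiles, no B1 effect on preparations, nominal
  19 s group timing carried as a constant.
* Off-resonance inside the EPG engine is a pure readout phase (spoiled
  FISP); intra-readout B0 blurring is modeled only in the k-space forward
  model and corrected by MFI.
* DCF weights are shared across time points (rotation invariance of the
  density); exact per-timepoint weights would differ at the percent level.
* The Toeplitz fast path requires MFI off; with B0 correction the explicit
  operator is used.
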