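# vistamrf

Simulation, reconstruction and quantification toolkit for **3D ViSTa-MRF**:
direct myelin-water-fraction (MWF) mapping together with quantitative
T1/T2/proton-density mapping from a single double-inversion-prepared MR
fingerprinting acquisition.  The package implements the whole pipeline at
desk scale — no scanner data required — for methods researchers who want a
reproducible, testable model of the sequence and its reconstruction.

## The method

ViSTa (Visualization of Short Transverse relaxation time component) uses a
double inversion-recovery preparation (TI1 = 560 ms, TI2 = 220 ms) that
nulls long-T1 water at the readout, leaving only the short-T1 myelin-water
pool (T1/T2 = 120/20 ms).  ViSTa-MRF embeds eight such preparation blocks
(20 readouts each) plus a 500-time-point FISP-MRF block into one 19 s
acquisition group, with a CRLB-optimized flip-angle train, and samples
k-space with a tiny-golden-angle-shuffling (TGAS) spiral-projection
trajectory.  The 660-point time series **x** is reconstructed in a
temporal subspace **x** = Φ**c** (Φ = first 14 singular vectors of an EPG
dictionary spanning T1, T2 and B1+) by solving

    min_c  1/2 || W^(1/2) (M F S Φ c − k) ||²  +  λ ||c||_LLR

(F = NUFFT at the spiral samples, S = coil sensitivities, W = Pipe–Menon
density compensation, LLR = block-wise nuclear norm), with a
polynomial-preconditioned FISTA.  T1/T2/PD come from B1-restricted
dictionary matching of Φ**c**; the MWF needs no multi-compartment fit:

    MWF = I_ViSTa / (I_PD · S_myelin(B1+)),

where I_ViSTa is the reconstructed first-time-point image and S_myelin the
EPG-simulated myelin-water signal (90°-of-full-Mz units).

The package covers: the EPG engine, CRLB flip-angle optimization,
spiral/TGAS/DCF design, a Kaiser–Bessel gridding NUFFT, a two-compartment
digital brain phantom with forward simulation to multi-coil k-space, the
subspace+LLR solver (explicit and Toeplitz-embedded fast paths, MFI
off-resonance correction), quantification, and Bloch-simulated synthetic
contrasts (T1w/T2w/MPRAGE/FLAIR/DIR).  See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```bash
vistamrf demo --size 16 --groups 4 --snr 30 --iters 4 --seed 7 --small-dict
```

runs the closed loop at reduced size — phantom → EPG signals → TGAS spiral
k-space → subspace/LLR reconstruction → maps — and prints the recovery
summary (output of the command above):

```
closed-loop recovery summary:
  WM median T1 relative error: 0.3067
  WM median T2 relative error: 0.0667
  MWF regression slope (WM):   1.0414
  MWF correlation r (WM):      0.5832
  ViSTa pattern correlation:   0.9771
  ViSTa-point signals: myelin 0.3148, WM 0.00118, GM 0.00035
```

The last line shows the double-inversion nulling at work: at the ViSTa
time point the simulated WM and GM signals are ~300× below myelin water.
The T1 number deserves a comment: single-pool matching of a two-pool voxel
returns *apparent* T1 (≈500 ms in WM containing 5–18% myelin water against
the 750 ms tissue pool), so the "error" against the tissue-pool value is a
deterministic property of direct single-pool quantification, not noise —
`docs/methods.md` quantifies this.  The full-size experiment
(`vistamrf demo` with defaults: 32³, 16 groups, full dictionary, 10
iterations, ~8 min) is what the acceptance suite runs; there the ViSTa
pattern correlation reaches 0.987 and, against the apparent reference, the
WM median T1/T2 errors are 4.0%/3.6% with an MWF regression slope of 0.96.

Individual stages are available as subcommands (`phantom`, `build-dict`,
`basis`, `optimize-fa`, `simulate`, `recon`, `fit`, `synth`), exchanging
HDF5 (k-space, dictionary/basis), NIfTI (maps) and plain-text (flip-angle
trains) files, each writing a manifest with config hash and seeds.

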