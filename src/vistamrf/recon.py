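"""Temporal-subspace reconstruction with locally-low-rank regularization.

Solves, for coefficient maps c (one 3D volume per temporal basis vector),

    min_c  1/2 || W^(1/2) (A c - k) ||_2^2  +  lambda * ||c||_LLR

where A = M F S Phi (basis expansion, coil sensitivities, NUFFT at the
spiral-projection sample locations, undersampling), W holds Pipe–Menon
density-compensation weights, and ||.||_LLR sums nuclear norms of small
spatial blocks of the coefficient volume (singular-value soft-thresholding
with random cyclic shifts as the proximal step).

The solver is FISTA with an optional Chebyshev polynomial preconditioner
applied to the gradient.  Two operator backends:

* explicit — per-timepoint NUFFTs, supports multi-frequency-interpolation
  (MFI) off-resonance correction; used for small problems and oracles.
* toeplitz — the weighted normal operator embedded as K x K stationary
  convolution kernels on the doubled grid; no per-iteration NUFFT.  Used
  for production-size B0-free reconstructions.

Basis balancing: the basis columns are scaled by their singular values
(relative to the first), equalizing coefficient dynamic range; outputs are
rescaled back to the plain-basis convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from numba import njit

from .dictionary import TemporalBasis
from .nufft import NufftPlan
from .phantom import KSpaceDataset
from .trajectory import pipe_menon_dcf

__all__ = [
    "ReconConfig",
    "CoefficientMaps",
    "mfi_weights",
    "llr_prox",
    "SubspaceOperator",
    "subspace_recon",
]


@dataclass(frozen=True)
class ReconConfig:
    lambda_llr: float | None = None  # None -> auto from lambda_scale
    #: auto-regularization: threshold = lambda_scale x top casorati singular
    #: value of the balanced warm-start coefficients
    lambda_scale: float = 0.001
    llr_block: int = 8
    n_iter: int = 12
    #: gradient preconditioner: auto (= chebyshev) | chebyshev |
    #: circulant (toeplitz backend only) | none
    preconditioner: str = "auto"
    precond_degree: int = 2
    precond_delta: float = 1e-3
    use_dcf: bool = True
    mfi_bins: int = 0
    step_size: float | None = None  # None -> 0.95 / power-iteration estimate
    random_shift_seed: int = 0
    backend: str = "auto"  # auto | explicit | toeplitz
    # kernel accuracy ~1e-4: the forward-model error must stay well below
    # the ViSTa signal fraction (~7% of the MRF signal) or it dominates
    # the reconstructed myelin map
    oversamp: float = 1.5
    width: int = 5
    n_power_iter: int = 6

    def __post_init__(self):
        if self.lambda_llr is not None and self.lambda_llr < 0:
            raise ValueError("lambda_llr must be >= 0")
        if self.llr_block < 2:
            raise ValueError("llr_block must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class CoefficientMaps:
    """Per-voxel temporal-subspace coefficients, shape (K, nx, ny, nz),
    in the plain (unbalanced) basis convention."""

    c: np.ndarray
    basis_hash: str
    objective_trace: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.c.shape[0]


# --------------------------------------------------------------------- MFI
def mfi_weights(b0_map: np.ndarray, readout_times_ms: np.ndarray,
                mfi_bins: int):
    """Least-squares multi-frequency-interpolation coefficients.

    Returns ``(coeffs, bin_freqs, max_err)`` where ``coeffs`` has shape
    ``b0_map.shape + (n_bins,)`` and approximates, for every voxel
    frequency f, the demodulation phasor exp(2i*pi*f*t) over the readout as
    a combination of the bin phasors exp(2i*pi*f_b*t).
    """
    b0 = np.asarray(b0_map, dtype=float)
    t = np.asarray(readout_times_ms, dtype=float) * 1e-3  # seconds
    lo, hi = float(b0.min()), float(b0.max())
    if lo == hi == 0.0 or mfi_bins < 2 or hi - lo < 1e-12:
        # degenerate field: single-bin passthrough
        freqs = np.array([lo])
        coeffs = np.ones(b0.shape + (1,), dtype=complex)
        return coeffs, freqs, 0.0
    freqs = np.linspace(lo, hi, mfi_bins)
    basis = np.exp(2j * np.pi * np.outer(t, freqs))  # (T, B)
    targets = np.exp(2j * np.pi * np.outer(b0.ravel(), t))  # (V, T)
    sol, *_ = np.linalg.lstsq(basis, targets.T, rcond=None)  # (B, V)
    coeffs = np.ascontiguousarray(sol.T).reshape(b0.shape + (mfi_bins,))
    resid = targets - (basis @ sol).T
    max_err = float(np.abs(resid).max())
    return coeffs, freqs, max_err


# --------------------------------------------------------------------- LLR
def llr_prox(c: np.ndarray, threshold: float, block_edge: int,
             shift=(0, 0, 0)) -> np.ndarray:
    """Singular-value soft-thresholding of block-wise casorati matrices.

    The coefficient volume (K, nx, ny, nz) is cyclically shifted, cut into
    ``block_edge``^3 spatial blocks, and each (block^3 x K) casorati matrix
    is soft-thresholded in its singular values.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    k, nx, ny, nz = c.shape
    b = int(block_edge)
    if b > min(nx, ny, nz):
        raise ValueError("block larger than volume")
    if threshold == 0:
        return c.copy()
    x = np.roll(c, shift, axis=(1, 2, 3))
    pad = [(0, (-n) % b) for n in (nx, ny, nz)]
    x = np.pad(x, [(0, 0)] + pad, mode="wrap")
    mx, my, mz = (s // b for s in x.shape[1:])
    # (nblocks, b^3, K) casorati stack
    blocks = (x.reshape(k, mx, b, my, b, mz, b)
              .transpose(1, 3, 5, 2, 4, 6, 0)
              .reshape(mx * my * mz, b**3, k))
    u, s, vh = np.linalg.svd(blocks, full_matrices=False)
    s = np.maximum(s - threshold, 0.0)
    blocks = (u * s[:, None, :]) @ vh
    x = (blocks.reshape(mx, my, mz, b, b, b, k)
         .transpose(6, 0, 3, 1, 4, 2, 5)
         .reshape(k, mx * b, my * b, mz * b))
    x = x[:, :nx, :ny, :nz]
    return np.roll(x, [-s_ for s_ in shift], axis=(1, 2, 3))


def _block_nuclear_norm(c: np.ndarray, block_edge: int, shift=(0, 0, 0)) -> float:
    k, nx, ny, nz = c.shape
    b = int(block_edge)
    x = np.roll(c, shift, axis=(1, 2, 3))
    pad = [(0, (-n) % b) for n in (nx, ny, nz)]
    x = np.pad(x, [(0, 0)] + pad, mode="wrap")
    mx, my, mz = (s // b for s in x.shape[1:])
    blocks = (x.reshape(k, mx, b, my, b, mz, b)
              .transpose(1, 3, 5, 2, 4, 6, 0)
              .reshape(mx * my * mz, b**3, k))
    return float(np.linalg.svd(blocks, compute_uv=False).sum())


# ----------------------------------------------------------- operators
class SubspaceOperator:
    """Explicit forward model A c = M F S Phi c (optionally with MFI).

    ``coords``: (n_timepoints, n_samples, 3) in grid-index units.
    ``phi``: (n_timepoints, K) temporal basis (possibly balanced).
    MFI: with ``b0_map`` and ``mfi_bins >= 2``, conjugate-phase
    demodulation at the bin frequencies with per-voxel LS interpolation.
    """

    def __init__(self, coords, shape, sens, phi, sample_times_ms=None,
                 b0_map=None, mfi_bins: int = 0, oversamp: float = 1.25,
                 width: int = 4, dtype=np.complex64):
        self.shape = tuple(shape)
        self.sens = np.asarray(sens)
        self.phi = np.asarray(phi)
        self.nt, self.k = self.phi.shape
        coords = np.asarray(coords)
        if coords.ndim != 3 or coords.shape[0] != self.nt:
            raise ValueError("coords must be (n_timepoints, n_samples, 3)")
        self.ns = coords.shape[1]
        self.dtype = np.dtype(dtype)
        self.plans = [NufftPlan(self.shape, coords[t], oversamp=oversamp,
                                width=width, dtype=dtype)
                      for t in range(self.nt)]
        use_b0 = (b0_map is not None and mfi_bins != 0
                  and np.any(np.asarray(b0_map) != 0))
        if use_b0:
            if sample_times_ms is None:
                raise ValueError("sample_times_ms required for MFI")
            coeffs, freqs, _ = mfi_weights(b0_map, sample_times_ms, mfi_bins)
            self.mfi_coeffs = [np.ascontiguousarray(coeffs[..., b])
                               for b in range(coeffs.shape[-1])]
            t_s = np.asarray(sample_times_ms) * 1e-3
            self.mfi_phases = [np.exp(2j * np.pi * f * t_s) for f in freqs]
        else:
            self.mfi_coeffs = [np.ones(self.shape)]
            self.mfi_phases = [np.ones(self.ns)]

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]

    def forward(self, c: np.ndarray) -> np.ndarray:
        if c.shape[0] != self.k:
            raise ValueError(
                f"coefficient count {c.shape[0]} does not match basis K={self.k}"
            )
        out = np.zeros((self.n_coils, self.nt, self.ns), dtype=self.dtype)
        for t in range(self.nt):
            x_t = np.tensordot(self.phi[t], c, axes=(0, 0))
            for a_b, ph_b in zip(self.mfi_coeffs, self.mfi_phases):
                imgs = (self.sens * (a_b * x_t)).astype(self.dtype)
                out[:, t] += self.plans[t].forward(imgs) * ph_b.astype(self.dtype)
        return out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        c = np.zeros((self.k,) + self.shape, dtype=self.dtype)
        for t in range(self.nt):
            x_t = np.zeros(self.shape, dtype=np.complex128)
            for a_b, ph_b in zip(self.mfi_coeffs, self.mfi_phases):
                imgs = self.plans[t].adjoint(
                    (y[:, t] * np.conj(ph_b)).astype(self.dtype))
                x_t += np.conj(a_b) * np.sum(np.conj(self.sens) * imgs, axis=0)
            for j in range(self.k):
                c[j] += (self.phi[t, j] * x_t).astype(self.dtype)
        return c


@njit(cache=True, fastmath=True)
def _pair_contract(xf, kern, pk, pl, out):  # pragma: no cover
    # xf: (C, K, M) FFT'd coil-coefficient grids; kern: (P, M) Toeplitz
    # kernels; (pk, pl): pair index lists; out: (C, K, M)
    ncoil, nk, m = xf.shape
    npair = kern.shape[0]
    for p in range(npair):
        k = pk[p]
        l = pl[p]
        if k == l:
            for c in range(ncoil):
                for i in range(m):
                    out[c, k, i] += kern[p, i] * xf[c, l, i]
        else:
            for c in range(ncoil):
                for i in range(m):
                    out[c, k, i] += kern[p, i] * xf[c, l, i]
                    out[c, l, i] += kern[p, i] * xf[c, k, i]


@njit(cache=True, fastmath=True)
def _pair_contract_herm(xf, kern, pk, pl, out):  # pragma: no cover
    # Hermitian pair kernels: the mirrored (l, k) entry is the conjugate
    ncoil, nk, m = xf.shape
    npair = kern.shape[0]
    for p in range(npair):
        k = pk[p]
        l = pl[p]
        if k == l:
            for c in range(ncoil):
                for i in range(m):
                    out[c, k, i] += kern[p, i] * xf[c, l, i]
        else:
            for c in range(ncoil):
                for i in range(m):
                    out[c, k, i] += kern[p, i] * xf[c, l, i]
                    out[c, l, i] += np.conj(kern[p, i]) * xf[c, k, i]


class ToeplitzNormal:
    """Weighted normal operator AᴴWA as K x K stationary convolutions.

    The point-spread function of every basis-pair (k, l), weighted by the
    DCF and the per-timepoint basis products, is gridded once onto the
    doubled matrix; each application then costs 2K FFTs per coil and one
    pairwise kernel contraction — no NUFFT in the iteration loop.
    """

    def __init__(self, coords, shape, sens, phi, weights,
                 oversamp: float = 1.25, width: int = 4,
                 dtype=np.complex64, chunk: int = 12):
        self.shape = tuple(shape)
        self.sens = np.asarray(sens)
        self.phi = np.asarray(phi)
        self.nt, self.k = self.phi.shape
        self.dtype = np.dtype(dtype)
        n2 = tuple(2 * n for n in self.shape)
        self.n2 = n2
        coords = np.asarray(coords, dtype=np.float64)
        nt, ns, _ = coords.shape
        w = np.broadcast_to(np.asarray(weights, dtype=np.float64),
                            (nt, ns))
        pairs = [(a, b) for a in range(self.k) for b in range(a, self.k)]
        self.pk = np.array([p[0] for p in pairs], dtype=np.int64)
        self.pl = np.array([p[1] for p in pairs], dtype=np.int64)
        # per-sample weights for every pair: w * phi_k(t) * phi_l(t)
        plan2 = NufftPlan(n2, coords.reshape(-1, 3) * 2.0, oversamp=oversamp,
                          width=width, dtype=dtype)
        kernels = np.empty((len(pairs), int(np.prod(n2))), dtype=dtype)
        for start in range(0, len(pairs), chunk):
            sel = slice(start, min(start + chunk, len(pairs)))
            wk = (w[None] * self.phi.T[self.pk[sel], :, None]
                  * self.phi.T[self.pl[sel], :, None]).reshape(sel.stop - start, -1)
            psf = plan2.adjoint(wk.astype(dtype))
            grids = sfft.fftn(sfft.ifftshift(psf, axes=(-3, -2, -1)),
                              axes=(-3, -2, -1), workers=1)
            kernels[sel] = grids.reshape(sel.stop - start, -1).astype(dtype)
        self.kernels = kernels
        self._pad_slices = tuple(slice(n // 2, n // 2 + n) for n in self.shape)

    def apply(self, c: np.ndarray) -> np.ndarray:
        k, dtype = self.k, self.dtype
        ncoil = self.sens.shape[0]
        pad = np.zeros((ncoil, k) + self.n2, dtype=dtype)
        u = self.sens[:, None] * c[None]
        pad[(slice(None), slice(None)) + self._pad_slices] = u
        xf = sfft.fftn(pad, axes=(-3, -2, -1), workers=1).astype(dtype)
        xf = np.ascontiguousarray(xf.reshape(ncoil, k, -1))
        out = np.zeros_like(xf)
        _pair_contract(xf, self.kernels, self.pk, self.pl, out)
        out = sfft.ifftn(out.reshape((ncoil, k) + self.n2),
                         axes=(-3, -2, -1), workers=1)
        out = out[(slice(None), slice(None)) + self._pad_slices]
        return np.sum(np.conj(self.sens)[:, None] * out, axis=0).astype(dtype)

    # --------------------------------------------------- preconditioner
    def build_circulant_inverse(self, delta: float = 1e-5) -> None:
        """Per-frequency regularized inverse of the K x K kernel matrix.

        The normal operator is (up to the spatially smooth coil term) a
        stationary K x K convolution; inverting the kernel frequency by
        frequency yields a near-exact preconditioner that also reaches the
        small-eigenvalue directions a low-degree polynomial cannot.
        ``delta`` regularizes (relative to the mean kernel diagonal) so
        unsampled frequencies stay bounded.
        """
        k = self.k
        m = self.kernels.shape[1]
        kmat = np.zeros((m, k, k), dtype=np.complex64)
        for p in range(self.kernels.shape[0]):
            a, b = int(self.pk[p]), int(self.pl[p])
            kmat[:, a, b] = self.kernels[p]
            if a != b:
                # the pair kernels are complex-symmetric (phi is real)
                kmat[:, b, a] = self.kernels[p]
        # the preconditioner must be Hermitian PSD for a stable FISTA:
        # take the Hermitian part and clip its eigenvalues from below
        kmat = 0.5 * (kmat + np.conj(np.swapaxes(kmat, 1, 2)))
        diag_mean = float(np.mean(np.real(np.trace(kmat, axis1=1,
                                                   axis2=2))) / k)
        inv_pairs = np.empty_like(self.kernels)
        chunk = 32768
        for s0 in range(0, m, chunk):
            sl = slice(s0, min(s0 + chunk, m))
            evals, evecs = np.linalg.eigh(kmat[sl].astype(np.complex128))
            evals = np.maximum(evals, delta * diag_mean)
            kinv = (evecs * (1.0 / evals)[:, None, :]) @ np.conj(
                np.swapaxes(evecs, 1, 2))
            for p in range(self.kernels.shape[0]):
                inv_pairs[p, sl] = kinv[:, int(self.pk[p]), int(self.pl[p])]
        self._inv_kernels = np.ascontiguousarray(inv_pairs)
        # normalization: the coil term contributes ~mean SoS^2
        sos2 = np.sum(np.abs(self.sens) ** 2, axis=0)
        self._sos2_mean = float(np.mean(sos2[sos2 > 0.01 * sos2.max()]))

    def precondition(self, g: np.ndarray) -> np.ndarray:
        """Apply the circulant approximate inverse to a gradient volume."""
        k, dtype = self.k, self.dtype
        pad = np.zeros((1, k) + self.n2, dtype=dtype)
        pad[(slice(None), slice(None)) + self._pad_slices] = g[None]
        xf = sfft.fftn(pad, axes=(-3, -2, -1), workers=1).astype(dtype)
        xf = np.ascontiguousarray(xf.reshape(1, k, -1))
        out = np.zeros_like(xf)
        _pair_contract_herm(xf, self._inv_kernels, self.pk, self.pl, out)
        out = sfft.ifftn(out.reshape((1, k) + self.n2),
                         axes=(-3, -2, -1), workers=1)
        out = out[(slice(None), slice(None)) + self._pad_slices][0]
        return (out / self._sos2_mean).astype(dtype)


def forward_operator(kdata: KSpaceDataset, sens: np.ndarray,
                     basis: TemporalBasis, mfi_bins: int = 0,
                     oversamp: float = 1.25, width: int = 4) -> SubspaceOperator:
    """Build the explicit forward model A = M F S Phi for a dataset."""
    coords = kdata.grid_coords().astype(np.float64)
    n = kdata.matrix_size
    b0_full = None
    if mfi_bins != 0 and kdata.b0_map is not None:
        b0_full = _fit_to_shape(
            ndimage.zoom(kdata.b0_map, 1.0 / kdata.sidemap_zoom, order=1),
            (n, n, n))
    n_arm = kdata.meta.get("n_arm", coords.shape[1])
    t_samp = np.tile(np.arange(n_arm) * kdata.dwell_us * 1e-3,
                     coords.shape[1] // max(n_arm, 1))[: coords.shape[1]]
    return SubspaceOperator(coords, (n, n, n), sens, basis.phi,
                            sample_times_ms=t_samp, b0_map=b0_full,
                            mfi_bins=mfi_bins, oversamp=oversamp, width=width)


# ------------------------------------------------------------------ solver
def _chebyshev_coeffs(degree: int, a: float, b: float) -> np.ndarray:
    """Chebyshev-interpolation coefficients of 1/x on [a, b] (power basis
    evaluated via Clenshaw on the mapped variable)."""
    nodes = np.cos(np.pi * (np.arange(degree + 1) + 0.5) / (degree + 1))
    x = 0.5 * (b - a) * nodes + 0.5 * (b + a)
    f = 1.0 / x
    coeffs = np.polynomial.chebyshev.chebfit(nodes, f, degree)
    # normalize so the effective step x*p(x) stays below 1 over the whole
    # spectrum (required for FISTA stability with momentum)
    xs = np.linspace(b * 1e-6, b, 2048)
    u = (2.0 * xs - (b + a)) / (b - a)
    xp = xs * np.polynomial.chebyshev.chebval(u, coeffs)
    return coeffs * (0.98 / xp.max())


def _apply_cheb_poly(normal_op, g, coeffs, a, b):
    """Evaluate p(N) g with p given in Chebyshev basis on [a, b] via
    Clenshaw recursion (degree applications of the normal operator)."""
    def nmap(v):
        return (2.0 * normal_op(v) - (b + a) * v) / (b - a)

    b1 = np.zeros_like(g)
    b2 = np.zeros_like(g)
    for c in coeffs[:0:-1]:
        b1, b2 = c * g + 2.0 * nmap(b1) - b2, b1
    return coeffs[0] * g + nmap(b1) - b2


def subspace_recon(kdata: KSpaceDataset, sens: np.ndarray,
                   basis: TemporalBasis, config: ReconConfig | None = None,
                   verbose: bool = False) -> CoefficientMaps:
    """FISTA solution of the LLR-regularized subspace problem.

    Returns coefficient maps in the plain (unbalanced) basis convention
    together with the objective trace (evaluated at the extrapolated FISTA
    point each iteration; exactly at the first and final iterates).
    """
    config = config or ReconConfig()
    n = kdata.matrix_size
    shape = (n, n, n)
    phi = basis.phi
    nt, K = phi.shape
    if nt != kdata.n_timepoints:
        raise ValueError("basis length does not match k-space time points")
    # Basis balancing happens inside the prox only: the data-term operator
    # keeps the orthonormal basis (Phi^T Phi = I keeps the normal operator
    # well conditioned across components), while the LLR threshold acts on
    # coefficients rescaled to comparable dynamic range (c_k / (s_k/s_1)).
    bal = (basis.singular_values[:K] / basis.singular_values[0])
    bal_col = bal[:, None, None, None].astype(np.float32)
    coords = kdata.grid_coords().astype(np.float64)

    if config.use_dcf:
        # density pattern is rotation-invariant across time points: compute
        # Pipe-Menon weights on the first time point's sample set, reuse
        w = pipe_menon_dcf(coords[0], shape, method="grid",
                           oversamp=config.oversamp, width=config.width)
    else:
        w = np.ones(coords.shape[1])

    use_mfi = (config.mfi_bins != 0 and kdata.b0_map is not None
               and np.any(kdata.b0_map != 0))
    backend = config.backend
    if backend == "auto":
        backend = "explicit" if (use_mfi or nt * coords.shape[1] < 200_000) \
            else "toeplitz"

    y = kdata.samples
    wk = (y * w[None, None, :]).astype(np.complex64)
    kwk = float(np.sum(w[None, None, :] * np.abs(y) ** 2))

    if backend == "explicit":
        b0_full = None
        if use_mfi:
            b0_full = ndimage.zoom(kdata.b0_map, 1.0 / kdata.sidemap_zoom,
                                   order=1)
            b0_full = _fit_to_shape(b0_full, shape)
        t_samp = np.arange(kdata.meta.get("n_arm", coords.shape[1])) \
            * kdata.dwell_us * 1e-3
        t_samp = np.tile(t_samp, coords.shape[1]
                         // max(len(t_samp), 1))[: coords.shape[1]]
        op = SubspaceOperator(coords, shape, sens, phi,
                              sample_times_ms=t_samp, b0_map=b0_full,
                              mfi_bins=config.mfi_bins,
                              oversamp=config.oversamp, width=config.width)
        rhs = op.adjoint(wk)

        def normal(c):
            return op.adjoint((op.forward(c) * w[None, None, :])
                              .astype(np.complex64))
    else:
        top = ToeplitzNormal(coords, shape, sens, phi, w,
                             oversamp=config.oversamp, width=config.width)
        normal = top.apply
        # rhs = A^H W k accumulated per time point
        rhs = np.zeros((K,) + shape, dtype=np.complex64)
        for t in range(nt):
            plan = NufftPlan(shape, coords[t], oversamp=config.oversamp,
                             width=config.width, dtype=np.complex64)
            imgs = plan.adjoint(wk[:, t])
            x_t = np.sum(np.conj(sens) * imgs, axis=0)
            rhs += (phi[t, :, None, None, None]
                    * x_t[None]).astype(np.complex64)

    # Lipschitz estimate by power iteration
    rng = np.random.default_rng(config.random_shift_seed)
    v = (rng.standard_normal((K,) + shape)
         + 1j * rng.standard_normal((K,) + shape)).astype(np.complex64)
    v /= np.linalg.norm(v)
    lmax = 1.0
    for _ in range(config.n_power_iter):
        nv = normal(v)
        # Rayleigh quotient converges twice as fast as the norm estimate
        lmax = float(np.real(np.vdot(v, nv)))
        v = (nv / max(np.linalg.norm(nv), 1e-30)).astype(np.complex64)
    # a finite power iteration underestimates ||N||; inflate for safety
    lmax *= 1.15
    step = config.step_size if config.step_size is not None else 0.95 / lmax

    precond_mode = config.preconditioner
    if precond_mode == "auto":
        # the Chebyshev polynomial is the default; the circulant
        # kernel-inverse is available on the toeplitz backend
        precond_mode = "chebyshev"
    if not (config.precond_degree and config.precond_degree > 0):
        precond_mode = "none"
    if precond_mode == "circulant" and backend != "toeplitz":
        raise ValueError("circulant preconditioner requires the toeplitz "
                         "backend")
    if precond_mode == "circulant":
        top.build_circulant_inverse(config.precond_delta)
        # spectral norm of the preconditioned operator for the step size
        pv = (rng.standard_normal((K,) + shape)
              + 1j * rng.standard_normal((K,) + shape)).astype(np.complex64)
        pv /= np.linalg.norm(pv)
        plmax = 1.0
        for _ in range(config.n_power_iter):
            npv = top.precondition(normal(pv))
            plmax = abs(np.vdot(pv, npv))
            pv = (npv / max(np.linalg.norm(npv), 1e-30)).astype(np.complex64)
        p_step = 0.95 / (1.25 * float(plmax))


    if precond_mode == "chebyshev":
        # widen the fit interval: eigenvalues above the (finite) power
        # iteration estimate would otherwise hit the exploding polynomial
        # extrapolation and destabilize FISTA
        b_spec = 1.45 * lmax
        a_spec = 0.01 * b_spec
        cheb = _chebyshev_coeffs(config.precond_degree, a_spec, b_spec)

    def objective(c, ncv=None):
        ncv = normal(c) if ncv is None else ncv
        data = 0.5 * float(np.real(np.vdot(c, ncv))
                           - 2.0 * np.real(np.vdot(c, rhs)) + kwk)
        if lam > 0:
            return data + lam * _block_nuclear_norm(c / bal_col,
                                                    config.llr_block)
        return data

    # warm start: with the circulant preconditioner available this is a
    # regularized direct solve P(A^H W k); otherwise the scaled adjoint.
    # The scalar minimizes the data term along the warm-start direction.
    base = top.precondition(rhs) if precond_mode == "circulant" else rhs
    nr = normal(base)
    alpha = float(np.real(np.vdot(base, rhs))
                  / max(np.real(np.vdot(base, nr)), 1e-30))
    c = (alpha * base).astype(np.complex64)

    lam = config.lambda_llr
    if lam is None:
        # calibrated on the balanced warm-start coefficients so the
        # threshold is a fixed fraction of the dominant casorati scale
        lam = (config.lambda_scale
               * _top_casorati_sv(c / bal_col, config.llr_block) * lmax)

    z = c.copy()
    t_m = 1.0
    trace = []
    f0 = objective(c, ncv=alpha * nr)
    trace.append(f0)
    shift_rng = np.random.default_rng(config.random_shift_seed)
    for it in range(config.n_iter):
        nz = normal(z)
        grad = nz - rhs
        fz = 0.5 * float(np.real(np.vdot(z, nz))
                         - 2.0 * np.real(np.vdot(z, rhs)) + kwk)
        if lam > 0:
            fz += lam * _block_nuclear_norm(z / bal_col, config.llr_block)
        trace.append(fz)
        if fz > 10.0 * max(abs(f0), 1e-30) and it > 0:
            raise RuntimeError(
                f"reconstruction diverging: objective {fz:.3e} exceeds 10x "
                f"initial {f0:.3e} at iteration {it}"
            )
        if precond_mode == "circulant":
            upd = p_step * top.precondition(grad)
            thresh = lam / lmax  # preconditioned update has ~unit curvature
        elif precond_mode == "chebyshev":
            upd = _apply_cheb_poly(normal, grad, cheb, a_spec, b_spec)
            thresh = lam / lmax
        else:
            upd = step * grad
            thresh = lam * step
        c_new = z - upd
        if lam > 0:
            shift = tuple(shift_rng.integers(0, config.llr_block, size=3))
            c_new = (llr_prox(c_new / bal_col, thresh, config.llr_block,
                              shift) * bal_col).astype(np.complex64)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_m**2))
        z = (c_new + (t_m - 1.0) / t_new * (c_new - c)).astype(np.complex64)
        c, t_m = c_new, t_new
        if verbose:
            print(f"iter {it + 1}: objective(z)={fz:.5e}")
    f_final = objective(c)
    trace.append(f_final)
    return CoefficientMaps(
        c=c.astype(np.complex64),
        basis_hash=f"k={K};s0={basis.singular_values[0]:.6e}",
        objective_trace=np.asarray(trace),
        meta={"lambda": float(lam), "step": float(step), "lmax": float(lmax),
              "backend": backend, "preconditioner": precond_mode,
              "final_objective": f_final,
              "initial_objective": f0},
    )


def _fit_to_shape(vol: np.ndarray, shape) -> np.ndarray:
    """Zoom a volume to an exact target shape (linear interpolation)."""
    factors = [s / v for s, v in zip(shape, vol.shape)]
    out = ndimage.zoom(vol, factors, order=1)
    slices = tuple(slice(0, s) for s in shape)
    pad = [(0, max(0, s - o)) for s, o in zip(shape, out.shape)]
    return np.pad(out, pad, mode="edge")[slices]


def _top_casorati_sv(c: np.ndarray, block_edge: int) -> float:
    k, nx, ny, nz = c.shape
    b = int(block_edge)
    pad = [(0, (-n) % b) for n in (nx, ny, nz)]
    x = np.pad(c, [(0, 0)] + pad, mode="wrap")
    mx, my, mz = (s // b for s in x.shape[1:])
    blocks = (x.reshape(k, mx, b, my, b, mz, b)
              .transpose(1, 3, 5, 2, 4, 6, 0)
              .reshape(mx * my * mz, b**3, k))
    return float(np.linalg.svd(blocks, compute_uv=False).max())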