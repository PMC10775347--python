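"""Quantitative maps from reconstructed subspace coefficients.

Template matching with per-voxel B1+ sub-dictionary selection yields T1, T2
and PD; the first reconstructed time point is the ViSTa image (long-T1
signal nulled by the double inversion preparation), and the myelin-water
fraction follows directly — no multi-compartment fitting:

    MWF = I_ViSTa / (I_PD * S_myelin(b1))

where ``S_myelin`` is the EPG-simulated signal of the nominal myelin-water
pool (T1/T2 = 120/20 ms) at the ViSTa time point, in units where a
90-degree tip of fully recovered Mz equals 1.  Synthetic contrast-weighted
images (spin-echo T1w/T2w, MPRAGE, FLAIR, DIR) are generated from the
quantitative maps with single-shot inversion-recovery signal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .dictionary import Dictionary, TemporalBasis, match_batch
from .epg import MYELIN_WATER, batch_simulate
from .protocol import SequenceProtocol
from .recon import CoefficientMaps

__all__ = [
    "QuantMaps",
    "MyelinReference",
    "myelin_reference",
    "fit_maps",
    "compute_mwf",
    "synthesize_contrast",
    "dir_null_times",
]


@dataclass(frozen=True)
class QuantMaps:
    t1_map: np.ndarray        # ms
    t2_map: np.ndarray        # ms
    pd_map: np.ndarray        # reconstruction units
    vista_image: np.ndarray   # pd units x myelin signal fraction
    b1_map_used: np.ndarray
    mwf_map: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MyelinReference:
    """EPG signal of the nominal myelin-water pool at the ViSTa time point,
    per B1 grid value (units: 90-degree tip of full Mz = 1)."""

    b1_values: np.ndarray
    s_myelin: np.ndarray

    def __post_init__(self):
        if np.any(self.s_myelin <= 0) or np.any(self.s_myelin >= 1):
            raise ValueError(
                "myelin reference signal must lie in (0, 1); check protocol"
            )

    def at(self, b1_local) -> np.ndarray:
        idx = np.argmin(np.abs(self.b1_values[None, :]
                               - np.atleast_1d(b1_local).ravel()[:, None]),
                        axis=1)
        out = self.s_myelin[idx]
        return out.reshape(np.shape(b1_local)) if np.ndim(b1_local) else out[0]


def myelin_reference(protocol: SequenceProtocol, b1_values,
                     n_settle_groups: int = 3) -> MyelinReference:
    """Simulate the B1-corrected myelin-water ViSTa signal per B1 value."""
    b1 = np.asarray(b1_values, dtype=float)
    sig = batch_simulate(protocol, np.full(b1.size, MYELIN_WATER.t1),
                         np.full(b1.size, MYELIN_WATER.t2), b1,
                         n_settle_groups)
    return MyelinReference(b1_values=b1,
                           s_myelin=sig[:, protocol.vista_index].copy())


def _resample_to(vol: np.ndarray, shape) -> np.ndarray:
    """Linear interpolation of a (low-resolution) side map onto ``shape``."""
    vol = np.asarray(vol, dtype=float)
    if vol.shape == tuple(shape):
        return vol
    out = ndimage.zoom(vol, [s / v for s, v in zip(shape, vol.shape)], order=1)
    pad = [(0, max(0, s - o)) for s, o in zip(shape, out.shape)]
    return np.pad(out, pad, mode="edge")[tuple(slice(0, s) for s in shape)]


def fit_maps(coeffs: CoefficientMaps, basis: TemporalBasis,
             dictionary: Dictionary, b1_map: np.ndarray | None = None,
             mask: np.ndarray | None = None,
             background_quantile: float = 0.10) -> QuantMaps:
    """Voxelwise template matching of the coefficient maps.

    Matching happens in the temporal subspace: the inner product of the
    voxel series Phi c with an atom equals <c, Phi^T atom>, so the full
    time series is never expanded.  B1 maps of any (lower) resolution are
    linearly interpolated to the coefficient grid; without a B1 map,
    matching proceeds at b1 = 1 with a logged warning.
    """
    c = coeffs.c
    k, nx, ny, nz = c.shape
    shape = (nx, ny, nz)
    if b1_map is None:
        import logging

        logging.getLogger(__name__).warning(
            "no B1+ map provided: matching without B1 correction (b1=1)"
        )
        b1_full = np.ones(shape)
    else:
        b1_full = _resample_to(b1_map, shape)
    phi = basis.phi[:, :k]
    proj = dictionary.atoms @ phi  # (n_atoms, K): subspace-projected atoms
    sig = np.real(c.reshape(k, -1).T)  # matched filter on the real part
    vista = np.real(np.tensordot(phi[dictionary.protocol.vista_index],
                                 c, axes=(0, 0)))
    if mask is None:
        # reject low-signal voxels (noise background)
        mag = np.linalg.norm(sig, axis=1)
        mask_flat = mag > background_quantile * np.quantile(mag, 0.99)
    else:
        mask_flat = np.asarray(mask).ravel()
    t1 = np.zeros(nx * ny * nz)
    t2 = np.zeros(nx * ny * nz)
    pd = np.zeros(nx * ny * nz)
    idx = np.flatnonzero(mask_flat)
    if idx.size:
        sub = _SubspaceDictionary(dictionary, proj)
        t1[idx], t2[idx], pd[idx] = match_batch(
            sig[idx], sub, b1_full.ravel()[idx])
    vista = np.where(mask_flat.reshape(shape), vista, 0.0)
    return QuantMaps(t1_map=t1.reshape(shape), t2_map=t2.reshape(shape),
                     pd_map=pd.reshape(shape), vista_image=vista,
                     b1_map_used=b1_full,
                     meta={"basis_hash": coeffs.basis_hash})


class _SubspaceDictionary:
    """Dictionary view whose atoms are the subspace projections Phi^T a,
    but whose norms/scales refer to the full-length atoms (so matching in
    the subspace is exactly equivalent for signals within the subspace)."""

    def __init__(self, dictionary: Dictionary, proj: np.ndarray):
        self.atoms = proj
        self.t1 = dictionary.t1
        self.t2 = dictionary.t2
        self.b1 = dictionary.b1
        self.grid = dictionary.grid
        self.n_atoms = dictionary.n_atoms
        self.norms = dictionary.norms
        self._b1_slice = dictionary.b1_slice

    def b1_slice(self, b1_local):
        return self._b1_slice(b1_local)


def compute_mwf(vista_image: np.ndarray, pd_map: np.ndarray,
                myelin_ref: MyelinReference,
                b1_map: np.ndarray | None = None,
                pd_floor_fraction: float = 0.01) -> np.ndarray:
    """Myelin-water fraction: MWF = vista / (pd * S_myelin(b1)).

    Voxels whose PD falls below ``pd_floor_fraction`` of the robust PD
    maximum (99.9th percentile) are set to zero; the result is clipped to
    [0, 1].  Scale-invariant: rescaling pd and vista together leaves the
    map unchanged.
    """
    vista = np.asarray(vista_image, dtype=float)
    pd = np.asarray(pd_map, dtype=float)
    if vista.shape != pd.shape:
        raise ValueError("vista and pd shapes differ")
    if b1_map is None:
        s_my = np.full(pd.shape, float(np.mean(myelin_ref.s_myelin)))
    else:
        b1_full = _resample_to(b1_map, pd.shape)
        s_my = myelin_ref.at(b1_full)
    robust_max = np.quantile(np.abs(pd), 0.999)
    floor = pd_floor_fraction * robust_max
    with np.errstate(divide="ignore", invalid="ignore"):
        mwf = np.where(np.abs(pd) > floor, vista / (pd * s_my), 0.0)
    return np.clip(np.nan_to_num(mwf), 0.0, 1.0)


# ------------------------------------------------------- synthetic contrast
def _ir_longitudinal(t1, inversions_ms):
    """Longitudinal magnetization after a single-shot preparation that
    starts from full recovery and applies ideal inversions at given delays.

    ``inversions_ms``: delays between consecutive inversions, last entry =
    delay from the final inversion to the readout.
    """
    mz = np.ones_like(np.asarray(t1, dtype=float))
    for tau in inversions_ms:
        mz = -mz
        mz = 1.0 - (1.0 - mz) * np.exp(-tau / np.maximum(t1, 1e-9))
    return mz


def synthesize_contrast(t1_map, t2_map, pd_map, contrast: str,
                        **params) -> np.ndarray:
    """Bloch-simulated contrast-weighted image from quantitative maps.

    Supported contrasts and their timing parameters (ms):

    * ``t1w``    — spin echo, ``tr``, ``te``
    * ``t2w``    — spin echo, ``tr``, ``te``
    * ``mprage`` — inversion + gradient-echo readout: ``ti``, ``te``,
      ``flip_deg``
    * ``flair``  — inversion + spin-echo readout: ``ti``, ``te``
    * ``dir``    — double inversion + spin-echo readout: ``ti1``, ``ti2``,
      ``te`` (``ti1``: first-to-second inversion, ``ti2``: second
      inversion to readout)

    Inversion-prepared signals are single-shot (preparation from fully
    recovered Mz), so a FLAIR with ti = T1 * ln 2 exactly nulls that T1.
    """
    t1 = np.maximum(np.asarray(t1_map, dtype=float), 1e-9)
    t2 = np.maximum(np.asarray(t2_map, dtype=float), 1e-9)
    pd = np.asarray(pd_map, dtype=float)
    bg = np.asarray(t1_map) <= 0
    name = contrast.lower()
    if name in ("t1w", "t2w"):
        tr = params.get("tr", 500.0 if name == "t1w" else 4000.0)
        te = params.get("te", 10.0 if name == "t1w" else 100.0)
        img = pd * (1.0 - np.exp(-tr / t1)) * np.exp(-te / t2)
    elif name == "mprage":
        ti = params.get("ti", 1100.0)
        te = params.get("te", 3.0)
        flip = np.deg2rad(params.get("flip_deg", 9.0))
        mz = _ir_longitudinal(t1, [ti])
        img = pd * mz * np.sin(flip) * np.exp(-te / t2)
    elif name == "flair":
        ti = params.get("ti")
        if ti is None:
            raise ValueError("flair requires ti")
        te = params.get("te", 100.0)
        img = pd * _ir_longitudinal(t1, [ti]) * np.exp(-te / t2)
    elif name == "dir":
        ti1, ti2 = params.get("ti1"), params.get("ti2")
        if ti1 is None or ti2 is None:
            raise ValueError("dir requires ti1 and ti2")
        te = params.get("te", 10.0)
        img = pd * _ir_longitudinal(t1, [ti1, ti2]) * np.exp(-te / t2)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return np.where(bg, 0.0, img)


def dir_null_times(t1_a: float, t1_b: float, guess=(3000.0, 500.0)):
    """Solve the double-inversion-recovery null conditions for two T1s.

    Returns (ti1, ti2) such that both tissues' longitudinal magnetization
    is zero at readout (single-shot preparation).
    """

    def residual(x):
        ti1, ti2 = x
        return [_ir_longitudinal(np.array(t), [ti1, ti2]) for t in (t1_a, t1_b)]

    sol, info, ier, msg = optimize.fsolve(
        lambda x: np.ravel(residual(x)), guess, full_output=True)
    if ier != 1:
        raise RuntimeError(f"DIR null solve failed: {msg}")
    return float(sol[0]), float(sol[1])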