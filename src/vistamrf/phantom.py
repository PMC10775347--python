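"""Digital two-compartment brain phantom and forward simulation to
multi-coil non-Cartesian k-space.

Each voxel is a two-pool mixture: a myelin-water pool with fixed
T1/T2 = 120/20 ms whose signal fraction is the local myelin-water fraction
(MWF), and a tissue pool (WM/GM/CSF relaxation values) carrying the rest.
The pools evolve independently through the sequence (no exchange or
magnetization transfer):

    s(t) = pd * [ mwf * S_120/20(t; b1) + (1 - mwf) * S_tissue(t; b1) ]

The geometry is a nested-ellipsoid head: CSF shell, GM shell, WM core and
two CSF ventricles.  B0 and B1+ are smooth low-order polynomial fields;
coil sensitivities are smooth complex Gaussian lobes around the head.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .epg import MYELIN_WATER, batch_simulate
from .nufft import NufftPlan
from .protocol import SequenceProtocol
from .trajectory import RotationSchedule, SpiralReadout

__all__ = [
    "PhantomConfig",
    "DigitalPhantom",
    "KSpaceDataset",
    "make_phantom",
    "make_coil_sensitivities",
    "voxel_timeseries",
    "sample_kspace",
]

BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry (semi-axes as fractions of the half-matrix) and tissue
    parameters of the digital phantom."""

    outer_axes: tuple = (0.92, 0.86, 0.90)      # CSF outer boundary
    gm_axes: tuple = (0.80, 0.74, 0.78)         # GM outer boundary
    wm_axes: tuple = (0.60, 0.55, 0.58)         # WM outer boundary
    ventricle_axes: tuple = (0.16, 0.10, 0.22)  # each CSF ventricle
    ventricle_offset: tuple = (0.22, 0.0, 0.0)  # +/- along x
    # tissue pool (t1 ms, t2 ms, pd)
    wm: tuple = (750.0, 60.0, 0.77)
    gm: tuple = (1300.0, 75.0, 0.86)
    csf: tuple = (4000.0, 2000.0, 1.0)
    mwf_range: tuple = (0.05, 0.18)  # smooth MWF range inside WM
    b0_amp_hz: float = 30.0
    b1_range: tuple = (0.85, 1.15)

    def expected_fractions(self) -> dict:
        """Analytic volume fractions of each label (fraction of the box)."""
        def vol(axes):
            # fraction of the [-1, 1]^3 box (volume 8)
            return 4.0 / 3.0 * np.pi * np.prod(axes) / 8.0

        outer = vol(self.outer_axes)
        gmv = vol(self.gm_axes)
        wmv = vol(self.wm_axes)
        vent = 2.0 * vol(self.ventricle_axes)
        return {
            "background": 1.0 - outer,
            "csf": (outer - gmv) + vent,
            "gm": gmv - wmv,
            "wm": wmv - vent,
        }


@dataclass(frozen=True)
class DigitalPhantom:
    shape: tuple
    tissue_label: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    mwf_map: np.ndarray
    b0_map: np.ndarray
    b1_map: np.ndarray
    seed: int
    config: PhantomConfig

    @property
    def mask(self) -> np.ndarray:
        return self.tissue_label != BACKGROUND


def _smooth_poly(coords, rng, order: int = 2) -> np.ndarray:
    """Random low-order polynomial field on [-1, 1]^3, max-|.| normalized."""
    x, y, z = coords
    basis = [np.ones_like(x), x, y, z, x * y, x * z, y * z,
             x**2, y**2, z**2]
    if order >= 3:
        basis += [x**3, y**3, z**3, x * y * z]
    w = rng.standard_normal(len(basis))
    f = sum(wi * b for wi, b in zip(w, basis))
    return f / np.max(np.abs(f))


def _ellipsoid(coords, axes, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    # axes are semi-axes in the [-1, 1] box coordinates
    x, y, z = coords
    return ((x - center[0]) ** 2 / axes[0] ** 2
            + (y - center[1]) ** 2 / axes[1] ** 2
            + (z - center[2]) ** 2 / axes[2] ** 2) <= 1.0


def make_phantom(shape, seed: int = 0,
                 config: PhantomConfig | None = None) -> DigitalPhantom:
    """Generate the nested-ellipsoid brain phantom; deterministic per seed."""
    shape = tuple(int(n) for n in shape)
    if any(n < 16 for n in shape):
        raise ValueError("phantom needs at least 16 voxels per axis")
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    grids = [np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n for n in shape]
    coords = np.meshgrid(*grids, indexing="ij")

    label = np.zeros(shape, dtype=np.int8)
    label[_ellipsoid(coords, cfg.outer_axes)] = LABEL_CSF
    label[_ellipsoid(coords, cfg.gm_axes)] = LABEL_GM
    label[_ellipsoid(coords, cfg.wm_axes)] = LABEL_WM
    off = np.asarray(cfg.ventricle_offset)
    for sgn in (+1, -1):
        label[_ellipsoid(coords, cfg.ventricle_axes, sgn * off)] = LABEL_CSF

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    pd = np.zeros(shape)
    for lab, (tt1, tt2, tpd) in ((LABEL_WM, cfg.wm), (LABEL_GM, cfg.gm),
                                 (LABEL_CSF, cfg.csf)):
        sel = label == lab
        t1[sel], t2[sel], pd[sel] = tt1, tt2, tpd

    # smooth MWF field inside WM
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=max(min(shape) / 8.0, 1.0))
    lo, hi = smooth.min(), smooth.max()
    unit = (smooth - lo) / max(hi - lo, 1e-12)
    mlo, mhi = cfg.mwf_range
    mwf = np.where(label == LABEL_WM, mlo + (mhi - mlo) * unit, 0.0)

    b0 = cfg.b0_amp_hz * _smooth_poly(coords, rng)
    b1c, b1w = np.mean(cfg.b1_range), 0.5 * np.ptp(cfg.b1_range)
    b1 = np.clip(b1c + b1w * _smooth_poly(coords, rng), *cfg.b1_range)
    return DigitalPhantom(shape=shape, tissue_label=label, t1_map=t1,
                          t2_map=t2, pd_map=pd, mwf_map=mwf, b0_map=b0,
                          b1_map=b1, seed=int(seed), config=cfg)


def make_coil_sensitivities(shape, n_coils: int = 8, seed: int = 0,
                            radius: float = 1.3, width: float = 0.9) -> np.ndarray:
    """Smooth complex coil sensitivities (Gaussian lobes around the head).

    Sum-of-squares magnitude is strictly positive everywhere inside the
    FOV; normalized so the SoS peak is 1.
    """
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    grids = [np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n for n in shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    sens = np.empty((n_coils,) + shape, dtype=np.complex128)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        cz = 0.5 * np.sin(2.0 * ang)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
                     / (2.0 * width**2))
        ph = (rng.uniform(-np.pi, np.pi)
              + 0.5 * (rng.standard_normal() * x + rng.standard_normal() * y
                       + rng.standard_normal() * z))
        sens[c] = mag * np.exp(1j * ph)
    sos = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    return sens / sos.max()


def voxel_timeseries(phantom: DigitalPhantom, protocol: SequenceProtocol,
                     n_settle_groups: int = 3) -> np.ndarray:
    """Per-voxel two-pool signal evolution volume, shape (nx, ny, nz, nt).

    Background voxels are exactly zero.  The result is linear in both pd
    and mwf by construction.
    """
    mask = phantom.mask
    idx = np.flatnonzero(mask.ravel())
    nt = protocol.n_timepoints
    out = np.zeros(phantom.shape + (nt,), dtype=np.float32)
    if idx.size == 0:
        return out
    t1 = phantom.t1_map.ravel()[idx]
    t2 = phantom.t2_map.ravel()[idx]
    b1 = phantom.b1_map.ravel()[idx]
    pd = phantom.pd_map.ravel()[idx]
    mwf = phantom.mwf_map.ravel()[idx]
    tissue = batch_simulate(protocol, t1, t2, b1, n_settle_groups)
    signals = (1.0 - mwf)[:, None] * tissue
    has_my = mwf > 0
    if np.any(has_my):
        my = batch_simulate(protocol, np.full(has_my.sum(), MYELIN_WATER.t1),
                            np.full(has_my.sum(), MYELIN_WATER.t2),
                            b1[has_my], n_settle_groups)
        signals[has_my] += mwf[has_my, None] * my
    signals *= pd[:, None]
    out.reshape(-1, nt)[idx] = signals.astype(np.float32)
    return out


@dataclass(frozen=True)
class KSpaceDataset:
    """Multi-coil non-Cartesian samples with trajectory and side maps.

    ``samples``: (n_coils, n_timepoints, n_samples_per_timepoint) complex.
    ``coords``: (n_timepoints, n_samples, 3) in *normalized* units where
    coordinate x matrix size = grid-index units (range [-1/2, 1/2]).
    """

    samples: np.ndarray
    coords: np.ndarray
    matrix_size: int
    fov_mm: float
    resolution_mm: float
    dwell_us: float
    te_ms: float
    noise_sigma: float
    seed: int
    b0_map: np.ndarray | None = None
    b1_map: np.ndarray | None = None
    sidemap_zoom: float = 1.0  # side-map grid relative to matrix grid
    meta: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    def grid_coords(self) -> np.ndarray:
        return self.coords * self.matrix_size


def sample_kspace(timeseries: np.ndarray, schedule: RotationSchedule,
                  spiral: SpiralReadout, sens: np.ndarray,
                  b0_map: np.ndarray | None = None,
                  b1_map: np.ndarray | None = None,
                  noise_sigma: float = 0.0, seed: int = 0,
                  n_time_segments: int | None = None,
                  sidemap_zoom: float = 0.25, te_ms: float = 1.8,
                  oversamp: float = 2.0, width: int = 7) -> KSpaceDataset:
    """Forward-simulate undersampled multi-coil spiral-projection k-space.

    Per time point t, the spiral arm rotated by every group's TR-t rotation
    is evaluated by NUFFT of the coil-weighted image.  Off-resonance phase
    accrual ``exp(2i*pi*b0*t_sample)`` (readout time measured from the echo
    at the arm origin) is applied piecewise-constantly along the readout —
    exactly per dwell sample when ``n_time_segments`` is None.  Seeded
    complex Gaussian noise is added to every coil sample.
    """
    ts = np.asarray(timeseries)
    nx, ny, nz, nt = ts.shape
    if not (nx == ny == nz):
        raise ValueError("cubic matrix expected")
    n = nx
    if schedule.n_tr < nt:
        raise ValueError("rotation schedule has fewer TRs than time points")
    if sens.ndim != 4 or sens.shape[1:] != (nx, ny, nz):
        raise ValueError("sens must be (n_coils, nx, ny, nz)")
    n_coils = sens.shape[0]
    arm = spiral.grid_coords(n)  # (n_arm, 2) grid units
    arm3 = np.concatenate([arm, np.zeros((len(arm), 1))], axis=1)
    n_arm = len(arm3)
    n_groups = schedule.n_groups
    mats = schedule.matrices  # (G, T, 3, 3)

    coords_all = np.empty((nt, n_groups * n_arm, 3), dtype=np.float64)
    for t in range(nt):
        for g in range(n_groups):
            coords_all[t, g * n_arm:(g + 1) * n_arm] = arm3 @ mats[g, t].T

    use_b0 = b0_map is not None and np.any(np.asarray(b0_map) != 0)
    if use_b0:
        t_samp = np.arange(n_arm) * spiral.dwell_us * 1e-3  # ms
        if n_time_segments is None:
            seg_bounds = np.arange(n_arm + 1)
        else:
            seg_bounds = np.linspace(0, n_arm, n_time_segments + 1).astype(int)

    rng = np.random.default_rng(seed)
    samples = np.empty((n_coils, nt, n_groups * n_arm), dtype=np.complex64)
    for t in range(nt):
        img_t = ts[..., t]
        coil_imgs = (sens * img_t).astype(np.complex64)
        if not use_b0:
            plan = NufftPlan((n, n, n), coords_all[t], oversamp=oversamp,
                             width=width, dtype=np.complex64)
            samples[:, t] = plan.forward(coil_imgs)
        else:
            for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
                if s1 <= s0:
                    continue
                t_mid = 0.5 * (t_samp[s0] + t_samp[s1 - 1])
                ph = np.exp(2j * np.pi * np.asarray(b0_map) * t_mid * 1e-3)
                seg_idx = np.concatenate([
                    np.arange(g * n_arm + s0, g * n_arm + s1)
                    for g in range(n_groups)
                ])
                seg_plan = NufftPlan((n, n, n), coords_all[t, seg_idx],
                                     oversamp=oversamp, width=width,
                                     dtype=np.complex64)
                samples[:, t, seg_idx] = seg_plan.forward(
                    (coil_imgs * ph).astype(np.complex64))
    if noise_sigma > 0:
        noise = rng.normal(scale=noise_sigma / np.sqrt(2.0),
                           size=(2,) + samples.shape)
        samples = samples + (noise[0] + 1j * noise[1]).astype(np.complex64)

    def lowres(m):
        if m is None:
            return None
        return ndimage.zoom(np.asarray(m, dtype=np.float64), sidemap_zoom,
                            order=1)

    return KSpaceDataset(
        samples=samples, coords=coords_all.astype(np.float32) / n,
        matrix_size=n, fov_mm=spiral.fov_mm,
        resolution_mm=spiral.resolution_mm, dwell_us=spiral.dwell_us,
        te_ms=te_ms, noise_sigma=float(noise_sigma), seed=int(seed),
        b0_map=lowres(b0_map), b1_map=lowres(b1_map),
        sidemap_zoom=sidemap_zoom,
        meta={"n_groups": n_groups, "n_arm": n_arm,
              "pitch_factor": spiral.pitch_factor},
    )
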