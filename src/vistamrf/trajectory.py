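"""Variable-density spiral readout, tiny-golden-angle-shuffling (TGAS)
3D rotation schedule, and Pipe–Menon density compensation.

One planar spiral-out arm is acquired per TR; the TGAS schedule rotates the
arm incrementally about three cycling axes so that the union of rotated
planes covers 3D k-space pseudo-uniformly (spiral-projection imaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nufft import NufftPlan, kaiser_bessel_beta

__all__ = [
    "SpiralReadout",
    "RotationSchedule",
    "design_spiral",
    "tgas_schedule",
    "rotation_matrix",
    "pipe_menon_dcf",
    "TINY_GOLDEN_ANGLE_DEG",
]

#: gyromagnetic ratio of 1H: cycles/mm per (mT/m * ms)
GAMMA = 0.0425774785

#: default tiny golden angle (member of the tiny-golden-angle family),
#: degrees per TR
TINY_GOLDEN_ANGLE_DEG = 23.628

_GOLDEN_FRAC = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SpiralReadout:
    """A single spiral-out arm.  ``k_samples``: (n, 2) in cycles/mm."""

    k_samples: np.ndarray
    dwell_us: float
    duration_ms: float
    gmax: float  # mT/m
    smax: float  # T/m/s
    fov_mm: float
    resolution_mm: float
    pitch_factor: float  # radial undersampling relative to Nyquist pitch

    @property
    def kmax(self) -> float:
        return 0.5 / self.resolution_mm

    def grid_coords(self, matrix_size: int) -> np.ndarray:
        """Samples in grid-index units (coordinate x matrix = grid index):
        cycles/mm * resolution -> cycles per voxel in [-1/2, 1/2], scaled
        by the matrix size."""
        return self.k_samples * self.resolution_mm * matrix_size

    def audit(self) -> dict:
        """Recompute gradient and slew from the sampled waveform."""
        dt = self.dwell_us * 1e-3  # ms
        g = np.diff(self.k_samples, axis=0) / dt / GAMMA  # mT/m
        slew = np.diff(g, axis=0) / dt  # mT/m/ms == T/m/s
        gmag = np.linalg.norm(g, axis=1)
        smag = np.linalg.norm(slew, axis=1)
        return {
            "max_gradient": float(gmag.max()),
            "max_slew": float(smag.max()),
            "gradient_ok": bool(gmag.max() <= self.gmax * 1.001),
            "slew_ok": bool(smag.max() <= self.smax * 1.001),
            "kmax_reached": bool(
                np.linalg.norm(self.k_samples[-1]) >= self.kmax * 0.999
            ),
        }


def _integrate_spiral(pitch_nyq, outer_factor, kmax, dwell_ms, vmax, amax,
                      max_duration_ms, safety=0.9, vd_inner=0.05):
    """Integrate a variable-density spiral under amplitude/slew constraints.

    The radial pitch is Nyquist (``pitch_nyq``) out to ``vd_inner * kmax``
    and ramps linearly to ``outer_factor`` times Nyquist at the k-space
    edge.  The speed budget splits the slew limit between centripetal and
    tangential acceleration with a safety margin.  Returns
    ``(samples, reached)``.
    """
    theta = 0.0
    r = 0.0
    v = 0.0
    pts = [(0.0, 0.0)]
    max_steps = int(np.floor(max_duration_ms / dwell_ms + 1e-9))
    for _ in range(max_steps):
        frac = max(r / kmax - vd_inner, 0.0) / max(1.0 - vd_inner, 1e-9)
        lam = pitch_nyq * (1.0 + (outer_factor - 1.0) * frac) / (2.0 * np.pi)
        kappa = (r**2 + 2.0 * lam**2) / (lam**2 + r**2) ** 1.5
        v_allow = min(vmax, np.sqrt(safety * amax / kappa))
        a_cent = v**2 * kappa
        a_tan = np.sqrt(max((safety * amax) ** 2 - a_cent**2, 0.0))
        v = min(v_allow, v + a_tan * dwell_ms)
        dtheta = v * dwell_ms / np.sqrt(lam**2 + r**2)
        theta += dtheta
        r += lam * dtheta
        pts.append((r * np.cos(theta), r * np.sin(theta)))
        if r >= kmax:
            return np.asarray(pts), True
    return np.asarray(pts), False


def design_spiral(fov_mm: float, resolution_mm: float, dwell_us: float = 10.0,
                  gmax: float = 40.0, smax: float = 100.0,
                  max_duration_ms: float = 6.8,
                  pitch_factor: float | None = None) -> SpiralReadout:
    """Design a constraint-satisfying spiral-out arm reaching k_max.

    If ``pitch_factor`` is None the radial pitch starts at Nyquist
    (1/FOV) and is increased (variable-density/undersampled readout) until
    the arm fits within ``max_duration_ms``; the factor used is reported.
    Raises ``ValueError`` when even a maximally undersampled arm cannot
    reach k_max under the gradient limits.
    """
    if fov_mm <= 0 or resolution_mm <= 0:
        raise ValueError("fov and resolution must be positive")
    kmax = 0.5 / resolution_mm
    vmax = GAMMA * gmax
    amax = GAMMA * smax  # smax in T/m/s == mT/m/ms
    dwell_ms = dwell_us * 1e-3
    if kmax / vmax > max_duration_ms:
        raise ValueError(
            f"infeasible: even a straight radial line needs "
            f"{kmax / vmax:.2f} ms > {max_duration_ms} ms at gmax={gmax} mT/m"
        )

    def attempt(factor):
        pts, ok = _integrate_spiral(1.0 / fov_mm, factor, kmax, dwell_ms,
                                    vmax, amax, max_duration_ms)
        return pts, ok

    if pitch_factor is not None:
        pts, ok = attempt(pitch_factor)
        if not ok:
            raise ValueError(
                f"infeasible: pitch factor {pitch_factor} cannot reach k_max "
                f"within {max_duration_ms} ms"
            )
        factor = float(pitch_factor)
    else:
        pts, ok = attempt(1.0)
        factor = 1.0
        if not ok:
            lo, hi = 1.0, 2.0
            while True:  # find an upper bracket
                pts, ok = attempt(hi)
                if ok:
                    break
                lo = hi
                hi *= 2.0
                if hi > 1024:
                    raise ValueError("infeasible spiral design")
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                p, ok = attempt(mid)
                if ok:
                    hi, pts = mid, p
                else:
                    lo = mid
            factor = hi
    # clip terminal sample to k_max exactly
    r_end = np.linalg.norm(pts[-1])
    if r_end > kmax:
        pts[-1] *= kmax / r_end
    duration = (len(pts) - 1) * dwell_ms
    return SpiralReadout(k_samples=pts, dwell_us=dwell_us,
                         duration_ms=duration, gmax=gmax, smax=smax,
                         fov_mm=fov_mm, resolution_mm=resolution_mm,
                         pitch_factor=factor)


def rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    """Right-handed rotation about coordinate axis 0 (x), 1 (y) or 2 (z)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


@dataclass(frozen=True)
class RotationSchedule:
    """Per-(group, TR) rotation matrices, shape (n_groups, n_tr, 3, 3)."""

    matrices: np.ndarray
    increment_deg: float
    axis_order: tuple = (0, 1, 2)

    @property
    def n_groups(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_tr(self) -> int:
        return self.matrices.shape[1]

    def normals(self) -> np.ndarray:
        """Unit normals of the rotated readout planes, shape (G, T, 3)."""
        return self.matrices @ np.array([0.0, 0.0, 1.0])


def tgas_schedule(n_groups: int, n_tr_per_group: int,
                  increment_deg: float = TINY_GOLDEN_ANGLE_DEG) -> RotationSchedule:
    """Tiny-golden-angle-shuffling rotation schedule.

    Within a group, successive TRs advance by the tiny golden angle about
    the group's primary axis; groups cycle the primary axis through
    x -> y -> z.  Each group additionally carries a fixed secondary tilt
    (golden-ratio stratified) about the next axis so that the per-group
    rings of readout normals interleave across latitudes.  Deterministic.
    """
    if n_groups < 1 or n_tr_per_group < 1:
        raise ValueError("n_groups and n_tr_per_group must be >= 1")
    inc = np.deg2rad(increment_deg)
    zhat = np.array([0.0, 0.0, 1.0])
    mats = np.empty((n_groups, n_tr_per_group, 3, 3))
    for g in range(n_groups):
        axis = g % 3
        # stratify the ring latitude (normal component along the primary
        # axis) by the golden ratio, separately per axis
        u = ((g // 3 + 0.5) * _GOLDEN_FRAC) % 1.0
        mu = 1.0 - 2.0 * u
        a = np.zeros(3)
        a[axis] = 1.0
        e = np.zeros(3)
        e[(axis + 1) % 3] = 1.0
        target = mu * a + np.sqrt(max(1.0 - mu * mu, 0.0)) * e
        second = _align_rotation(zhat, target)
        base = 2.0 * np.pi * ((g * _GOLDEN_FRAC) % 1.0)
        for j in range(n_tr_per_group):
            mats[g, j] = rotation_matrix(axis, base + inc * j) @ second
    return RotationSchedule(matrices=mats, increment_deg=increment_deg)


def _align_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``src`` onto unit vector ``dst``."""
    v = np.cross(src, dst)
    s = np.linalg.norm(v)
    c = float(src @ dst)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate half a turn about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(src[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(src, perp)
        v /= np.linalg.norm(v)
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        return np.eye(3) + 2.0 * (k @ k)
    v = v / s
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    ang = np.arctan2(s, c)
    return np.eye(3) + np.sin(ang) * k + (1.0 - np.cos(ang)) * (k @ k)


def pipe_menon_dcf(coords_grid: np.ndarray, grid_shape, n_iter: int = 30,
                   oversamp: float = 1.25, width: int = 4,
                   method: str = "auto") -> np.ndarray:
    """Pipe–Menon iterative density compensation: ``w <- w / (G Gᴴ w)``.

    ``coords_grid``: (n, 3) sample coordinates in grid-index units.
    Two convolution backends implement G Gᴴ:

    * ``pairwise`` — exact radially-symmetric Kaiser–Bessel convolution
      evaluated over all sample pairs (minimum-image distances on the
      periodic k-space box).  Isotropic, so the weights are invariant under
      global rotations of the sample set, and a uniform Cartesian set maps
      to exactly uniform weights.  O(n^2); used below 4096 samples.
    * ``grid`` — Kaiser–Bessel spread + re-interpolation on an oversampled
      grid.  O(n); used for large sample sets.

    Weights are strictly positive and normalized to unit mean.
    """
    coords_grid = np.asarray(coords_grid, dtype=float)
    if coords_grid.size == 0:
        raise ValueError("empty sample set")
    if method == "auto":
        method = "pairwise" if coords_grid.shape[0] <= 4096 else "grid"
    eps = 1e-12
    if method == "pairwise":
        beta = kaiser_bessel_beta(width, 2.0)
        period = np.asarray(grid_shape, dtype=float)
        delta = coords_grid[:, None, :] - coords_grid[None, :, :]
        delta -= period * np.round(delta / period)  # minimum image
        dist = np.linalg.norm(delta, axis=-1)
        arg = np.clip(1.0 - (2.0 * dist / width) ** 2, 0.0, None)
        conv = np.where(dist < width / 2.0,
                        np.i0(beta * np.sqrt(arg)) / np.i0(beta), 0.0)
        w = np.ones(coords_grid.shape[0])
        for _ in range(n_iter):
            w = w / np.maximum(conv @ w, eps)
    elif method == "grid":
        plan = NufftPlan(grid_shape, coords_grid, oversamp=oversamp,
                         width=width)
        w = np.ones(plan.n_samples)
        for _ in range(n_iter):
            w = w / np.maximum(plan.density(w), eps)
    else:
        raise ValueError(f"unknown method {method!r}")
    return w / w.mean()
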