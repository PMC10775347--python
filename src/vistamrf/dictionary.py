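"""ViSTa-MRF dictionary over a (T1, T2, B1+) grid, temporal subspace, and
B1-restricted template matching.

The dictionary holds one EPG-simulated evolution per grid point at unit
proton density.  The temporal basis is the span of the first K left singular
vectors of the (time x atoms) matrix; K = 14 captures >= 99% of the signal
energy for the default grid and protocol.  Matching restricts the search to
the sub-dictionary at the B1 grid value nearest the voxel's measured B1+
("sub-dictionary selection"), which corrects the B1-induced T1/T2 bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import batch_simulate
from .protocol import SequenceProtocol

__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "TemporalBasis",
    "default_grid",
    "build_dictionary",
    "compute_basis",
    "match_voxel",
    "match_batch",
]


def _span(start, stop, step):
    n = int(round((stop - start) / step))
    return [start + i * step for i in range(n + 1)]


@dataclass(frozen=True)
class DictionaryGrid:
    """Quantification grid.  T1/T2 in ms, B1 dimensionless; pairs with
    t2 > t1 are excluded when the dictionary is built."""

    t1_values: np.ndarray
    t2_values: np.ndarray
    b1_values: np.ndarray

    def __post_init__(self):
        for name in ("t1_values", "t2_values", "b1_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size == 0:
                raise ValueError(f"{name} is empty")
            if np.unique(v).size != v.size:
                raise ValueError(f"duplicate entries in {name}")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)

    @property
    def n_pairs(self) -> int:
        return int(np.sum(self.t2_values[None, :] <= self.t1_values[:, None]))


def default_grid() -> DictionaryGrid:
    """Default grid: fine around myelin water (120/20 ms), coarser toward
    long relaxation times; B1 0.70:0.05:1.20 (11 values)."""
    t1 = _span(60, 300, 10) + _span(320, 1000, 20) + _span(1050, 3000, 50)
    t2 = _span(10, 100, 2) + _span(105, 300, 5) + _span(320, 500, 20)
    b1 = _span(0.70, 1.20, 0.05)
    return DictionaryGrid(np.array(t1, float), np.array(t2, float),
                          np.round(np.array(b1, float), 10))


@dataclass(frozen=True)
class Dictionary:
    """Atom matrix (n_atoms x n_timepoints, unit proton density) with its
    (t1, t2, b1) index.  Atoms are ordered by (b1, t1, t2) so that each B1
    sub-dictionary is a contiguous block."""

    atoms: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    b1: np.ndarray
    grid: DictionaryGrid
    protocol: SequenceProtocol

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.atoms, axis=1)

    def b1_slice(self, b1_local: float) -> slice:
        """Contiguous slice of the sub-dictionary nearest ``b1_local``."""
        b1v = self.grid.b1_values
        pad = 0.025 if b1v.size > 1 else 0.5 * abs(b1v[0])
        if not (b1v.min() - pad - 1e-12 <= b1_local <= b1v.max() + pad + 1e-12):
            raise ValueError(
                f"b1={b1_local} outside dictionary support "
                f"[{b1v.min() - pad}, {b1v.max() + pad}]"
            )
        idx = int(np.argmin(np.abs(b1v - b1_local)))
        n_per = self.n_atoms // b1v.size
        return slice(idx * n_per, (idx + 1) * n_per)


@dataclass(frozen=True)
class TemporalBasis:
    """Orthonormal temporal subspace Phi (n_timepoints x k)."""

    phi: np.ndarray
    singular_values: np.ndarray
    k: int
    energy_fraction: float


def build_dictionary(grid: DictionaryGrid, protocol: SequenceProtocol,
                     n_settle_groups: int = 3) -> Dictionary:
    """Simulate every admissible (t1, t2, b1) grid point at steady state.

    Deterministic given inputs (no randomness in the EPG engine).
    """
    mask = grid.t2_values[None, :] <= grid.t1_values[:, None]
    t1p, t2p = np.meshgrid(grid.t1_values, grid.t2_values, indexing="ij")
    t1_pairs = t1p[mask]
    t2_pairs = t2p[mask]
    if t1_pairs.size == 0:
        raise ValueError("grid contains no admissible (t1, t2) pairs")
    t1 = np.tile(t1_pairs, grid.b1_values.size)
    t2 = np.tile(t2_pairs, grid.b1_values.size)
    b1 = np.repeat(grid.b1_values, t1_pairs.size)
    atoms = batch_simulate(protocol, t1, t2, b1, n_settle_groups)
    return Dictionary(atoms=atoms, t1=t1, t2=t2, b1=b1, grid=grid,
                      protocol=protocol)


def compute_basis(dictionary: Dictionary, k: int = 14,
                  augment_atoms: np.ndarray | None = None,
                  augment_weight: float = 1.0) -> TemporalBasis:
    """Rank-k SVD temporal subspace of the (time x atoms) matrix.

    The SVD is taken on the unnormalized atom matrix, so the reported
    energy fraction measures represented dictionary *signal* energy,
    ``sum ||Phi^T a||^2 / sum ||a||^2``.

    ``augment_atoms`` adds extra training signals (weighted by
    ``augment_weight``) to the SVD — e.g. long-T1/T2 CSF-range evolutions
    that lie outside the quantification grid but are present in the object
    and must be representable, otherwise their residual aliases into the
    reconstruction.  The energy fraction is always reported with respect
    to the dictionary atoms alone.
    """
    a = dictionary.atoms
    max_k = min(a.shape)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}]")
    # Gram trick: n_atoms >> n_timepoints, eigendecompose A^T A
    gram = a.T @ a
    if augment_atoms is not None:
        aug = np.asarray(augment_atoms)
        if aug.ndim != 2 or aug.shape[1] != a.shape[1]:
            raise ValueError("augment_atoms must be (n, n_timepoints)")
        gram = gram + augment_weight * (aug.T @ aug)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    phi = evecs[:, order[:k]]
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(phi[:, j])))
        if phi[i, j] < 0:
            phi[:, j] = -phi[:, j]
    sing = np.sqrt(evals[: min(a.shape)])
    energy = float(np.sum((a @ phi) ** 2) / np.sum(a**2))
    return TemporalBasis(phi=np.ascontiguousarray(phi), singular_values=sing,
                         k=k, energy_fraction=energy)


def csf_range_atoms(protocol: SequenceProtocol, b1_values) -> np.ndarray:
    """EPG evolutions over a coarse long-T1/long-T2 (CSF-like) range.

    These relaxation times lie outside the quantification grid but occur
    in brain tissue; used to augment the temporal-basis training set.
    """
    t1s, t2s = [], []
    for t1 in (3200.0, 3600.0, 4000.0, 4400.0):
        for t2 in (600.0, 1000.0, 1500.0, 2000.0, 2500.0):
            t1s.append(t1)
            t2s.append(t2)
    b1_values = np.asarray(b1_values, dtype=float)
    return batch_simulate(protocol, np.tile(t1s, b1_values.size),
                          np.tile(t2s, b1_values.size),
                          np.repeat(b1_values, len(t1s)))


def match_batch(signals: np.ndarray, dictionary: Dictionary,
                b1_locals: np.ndarray):
    """Template-match a batch of signals against B1 sub-dictionaries.

    ``signals``: (n_voxels, n_timepoints); ``b1_locals``: (n_voxels,).
    Returns arrays (t1, t2, pd_scale).  All-zero signals are flagged as
    background (all outputs zero).  Ties in the normalized inner product
    resolve to the lowest atom index.
    """
    signals = np.atleast_2d(np.asarray(signals))
    b1_locals = np.atleast_1d(np.asarray(b1_locals, dtype=float))
    if signals.shape[0] != b1_locals.size:
        raise ValueError("signals and b1_locals length mismatch")
    n = signals.shape[0]
    t1 = np.zeros(n)
    t2 = np.zeros(n)
    pd = np.zeros(n)
    norms = dictionary.norms
    b1v = dictionary.grid.b1_values
    bins = np.argmin(np.abs(b1v[None, :] - b1_locals[:, None]), axis=1)
    for bi in np.unique(bins):
        sel = np.flatnonzero(bins == bi)
        sl = dictionary.b1_slice(b1v[bi])
        sub = dictionary.atoms[sl]
        sub_norms = norms[sl]
        sig = signals[sel]
        nonzero = np.flatnonzero(np.any(sig != 0, axis=1))
        if nonzero.size == 0:
            continue
        inner = sig[nonzero] @ sub.T
        scores = np.abs(inner) / sub_norms[None, :]
        best = np.argmax(scores, axis=1)
        rows = nonzero
        t1[sel[rows]] = dictionary.t1[sl][best]
        t2[sel[rows]] = dictionary.t2[sl][best]
        pd[sel[rows]] = (inner[np.arange(best.size), best].real
                         / sub_norms[best] ** 2)
    return t1, t2, pd


def match_voxel(signal: np.ndarray, dictionary: Dictionary, b1_local: float):
    """Match a single voxel's time series; see :func:`match_batch`."""
    dictionary.b1_slice(b1_local)  # precondition check (raises if outside)
    t1, t2, pd = match_batch(signal[None, :], dictionary, [b1_local])
    return float(t1[0]), float(t2[0]), float(pd[0])
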