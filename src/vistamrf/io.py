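"""File formats: HDF5 containers (dictionary/basis, k-space), NIfTI maps,
plain-text FA trains and CSV traces, and run manifests.

All HDF5 containers are self-describing with a ``format_version``
attribute; NIfTI volumes are written as float32 with the voxel size (mm)
in the affine.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .dictionary import Dictionary, DictionaryGrid, TemporalBasis
from .phantom import KSpaceDataset
from .protocol import SequenceProtocol

FORMAT_VERSION = "1"


def protocol_hash(protocol: SequenceProtocol) -> str:
    payload = json.dumps({
        "ti1": protocol.ti1, "ti2": protocol.ti2, "td": protocol.td,
        "tr": protocol.tr, "te": protocol.te,
        "blocks": [protocol.n_vista_blocks,
                   protocol.n_vista_timepoints_per_block,
                   protocol.n_mrf_timepoints, protocol.mrf_inversion_index],
        "rest": protocol.mrf_rest_duration,
        "fa": np.round(protocol.fa_train, 6).tolist(),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ------------------------------------------------------------- dictionary
def save_dictionary(path, dictionary: Dictionary,
                    basis: TemporalBasis | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        f.attrs["protocol_hash"] = protocol_hash(dictionary.protocol)
        f.create_dataset("atoms", data=dictionary.atoms,
                         compression="gzip", compression_opts=4)
        for name in ("t1", "t2", "b1"):
            f.create_dataset(name, data=getattr(dictionary, name))
        g = f.create_group("grid")
        g.create_dataset("t1_values", data=dictionary.grid.t1_values)
        g.create_dataset("t2_values", data=dictionary.grid.t2_values)
        g.create_dataset("b1_values", data=dictionary.grid.b1_values)
        p = f.create_group("protocol")
        for key, val in asdict(dictionary.protocol).items():
            p.attrs[key] = val
        if basis is not None:
            b = f.create_group("basis")
            b.create_dataset("phi", data=basis.phi)
            b.create_dataset("singular_values", data=basis.singular_values)
            b.attrs["k"] = basis.k
            b.attrs["energy_fraction"] = basis.energy_fraction


def load_dictionary(path):
    """Returns ``(Dictionary, TemporalBasis | None)``."""
    with h5py.File(path, "r") as f:
        grid = DictionaryGrid(f["grid/t1_values"][:], f["grid/t2_values"][:],
                              f["grid/b1_values"][:])
        pattrs = dict(f["protocol"].attrs)
        protocol = SequenceProtocol(**{
            k: (int(v) if isinstance(v, (np.integer, int)) else
                np.asarray(v, dtype=float) if np.ndim(v) else float(v))
            for k, v in pattrs.items()
        })
        d = Dictionary(atoms=f["atoms"][:], t1=f["t1"][:], t2=f["t2"][:],
                       b1=f["b1"][:], grid=grid, protocol=protocol)
        basis = None
        if "basis" in f:
            basis = TemporalBasis(
                phi=f["basis/phi"][:],
                singular_values=f["basis/singular_values"][:],
                k=int(f["basis"].attrs["k"]),
                energy_fraction=float(f["basis"].attrs["energy_fraction"]),
            )
    return d, basis


# ---------------------------------------------------------------- k-space
def save_kspace(path, kdata: KSpaceDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        for key in ("matrix_size", "fov_mm", "resolution_mm", "dwell_us",
                    "te_ms", "noise_sigma", "seed", "sidemap_zoom"):
            f.attrs[key] = getattr(kdata, key)
        f.attrs["meta"] = json.dumps(kdata.meta)
        f.create_dataset("samples", data=kdata.samples)
        f.create_dataset("coords", data=kdata.coords)
        if kdata.b0_map is not None:
            f.create_dataset("b0_map", data=kdata.b0_map)
        if kdata.b1_map is not None:
            f.create_dataset("b1_map", data=kdata.b1_map)


def load_kspace(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        kw = {key: f.attrs[key] for key in
              ("matrix_size", "fov_mm", "resolution_mm", "dwell_us",
               "te_ms", "noise_sigma", "seed", "sidemap_zoom")}
        kw["matrix_size"] = int(kw["matrix_size"])
        kw["seed"] = int(kw["seed"])
        return KSpaceDataset(
            samples=f["samples"][:], coords=f["coords"][:],
            b0_map=f["b0_map"][:] if "b0_map" in f else None,
            b1_map=f["b1_map"][:] if "b1_map" in f else None,
            meta=json.loads(f.attrs["meta"]), **kw)


# ------------------------------------------------------------------ NIfTI
def save_nifti(path, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


# -------------------------------------------------------------- CSV / text
def save_trace(path, trace: np.ndarray, header: str = "objective") -> None:
    with open(path, "w") as fh:
        fh.write(f"iteration,{header}\n")
        for i, v in enumerate(np.asarray(trace).ravel()):
            fh.write(f"{i},{v!r}\n")


# --------------------------------------------------------------- manifest
def write_manifest(directory, config: dict, seed: int) -> Path:
    """Record the run configuration next to its outputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": config,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str) + "\n")
    return path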