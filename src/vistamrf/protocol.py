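"""Sequence timing and flip-angle description of the ViSTa-MRF acquisition.

One *acquisition group* consists of eight double-inversion-recovery (ViSTa)
preparation blocks of 20 readouts each, followed by a 500-time-point
FISP-MRF block.  Each ViSTa block applies two ideal inversions separated by
``ti1`` ms, waits ``ti2`` ms, acquires 20 spoiled gradient-echo readouts,
and (except in the last block) ends with an ideal 90-degree saturation and a
recovery delay ``td``.  The MRF block inserts a rest period and an inversion
at time point ``mrf_inversion_index``.  Groups are separated by another
saturation + ``td`` so that the short-T1 magnetization reaches a steady
state from group to group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SequenceProtocol",
    "default_protocol",
    "load_fa_train",
    "save_fa_train",
    "optimized_fa_train",
]

#: nominal duration of one acquisition group as run on the scanner, seconds.
#: The sum of the printed timing parameters alone (inversions, readouts,
#: saturation delays, MRF rest) comes to ~18 s; the remainder is taken up by
#: pulse/spoiler durations that this timing model does not represent.  Scan
#: durations are therefore quoted from this nominal value.
NOMINAL_GROUP_SECONDS = 19.0


@dataclass(frozen=True)
class SequenceProtocol:
    """Complete timing + flip-angle description of one acquisition group.

    All durations are in milliseconds, flip angles in degrees.
    """

    ti1: float = 560.0
    ti2: float = 220.0
    td: float = 380.0
    tr: float = 12.0
    te: float = 1.8
    n_vista_blocks: int = 8
    n_vista_timepoints_per_block: int = 20
    n_mrf_timepoints: int = 500
    mrf_inversion_index: int = 200
    mrf_rest_duration: float = 1000.0
    fa_train: np.ndarray = field(default=None)  # type: ignore[assignment]
    rf_phase_deg: float = 90.0

    def __post_init__(self):
        if self.fa_train is None:
            object.__setattr__(self, "fa_train", optimized_fa_train(self.n_timepoints))
        fa = np.ascontiguousarray(np.asarray(self.fa_train, dtype=float))
        object.__setattr__(self, "fa_train", fa)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_vista_timepoints(self) -> int:
        return self.n_vista_blocks * self.n_vista_timepoints_per_block

    @property
    def n_timepoints(self) -> int:
        return self.n_vista_timepoints + self.n_mrf_timepoints

    @property
    def vista_index(self) -> int:
        """Index of the first ViSTa readout of the first block (the 'ViSTa signal')."""
        return 0

    def validate(self) -> None:
        if self.ti1 <= 0 or self.ti2 <= 0 or self.td < 0 or self.tr <= 0 or self.te < 0:
            raise ValueError("timings must be positive")
        if self.te >= self.tr:
            raise ValueError(f"te ({self.te}) must be shorter than tr ({self.tr})")
        if self.ti2 >= self.ti1:
            raise ValueError(f"ti2 ({self.ti2}) must be shorter than ti1 ({self.ti1})")
        if self.n_vista_blocks < 0 or self.n_vista_timepoints_per_block < 0:
            raise ValueError("block counts must be non-negative")
        if self.n_mrf_timepoints > 0 and not (
            0 <= self.mrf_inversion_index <= self.n_mrf_timepoints
        ):
            raise ValueError("mrf_inversion_index outside MRF block")
        fa = self.fa_train
        if fa.ndim != 1 or len(fa) != self.n_timepoints:
            raise ValueError(
                f"fa_train length {len(fa)} does not match "
                f"{self.n_timepoints} time points"
            )
        if np.any(fa < 0) or np.any(fa > 90):
            raise ValueError("flip angles must lie in [0, 90] degrees")

    def with_fa_train(self, fa_train) -> "SequenceProtocol":
        return replace(self, fa_train=np.asarray(fa_train, dtype=float))

    # ---------------------------------------------------------- timings
    def group_duration_modeled_ms(self) -> float:
        """Sum of the explicitly modeled intervals in one acquisition group.

        This is the delay/readout budget only; RF pulse and spoiler durations
        are idealized to zero, so the result undershoots the nominal 19 s
        group duration by roughly 1 s (see module docstring).
        """
        block = self.ti1 + self.ti2 + self.n_vista_timepoints_per_block * self.tr
        total = self.n_vista_blocks * block
        total += (self.n_vista_blocks - 1) * self.td  # sat+TD omitted in last block
        total += self.n_mrf_timepoints * self.tr + self.mrf_rest_duration
        total += self.td  # inter-group saturation recovery
        return total

    def scan_duration_seconds(self, n_groups: int) -> float:
        """Total scan time for ``n_groups`` acquisition groups (nominal 19 s each)."""
        return n_groups * NOMINAL_GROUP_SECONDS

    def scan_duration_minutes(self, n_groups: int) -> float:
        return self.scan_duration_seconds(n_groups) / 60.0

    @staticmethod
    def standard_vista_slice_seconds(n_interleaves: int = 48,
                                     ti1: float = 560.0, ti2: float = 220.0,
                                     td: float = 380.0) -> float:
        """Per-slice time of the standard (non-MRF) 2D ViSTa sequence.

        One fully-sampled slice needs ``n_interleaves`` spiral interleaves,
        each costing a full double-inversion preparation TI1 + TI2 + TD.
        """
        return n_interleaves * (ti1 + ti2 + td) / 1000.0

    # ------------------------------------------------------------- I/O
    def to_file(self, path) -> None:
        """Write a human-readable key/value config plus a FA-train text file."""
        path = Path(path)
        fa_path = path.with_suffix(".fa.txt")
        lines = [
            "# ViSTa-MRF sequence protocol (durations in ms, angles in degrees)",
            f"ti1 = {self.ti1}",
            f"ti2 = {self.ti2}",
            f"td = {self.td}",
            f"tr = {self.tr}",
            f"te = {self.te}",
            f"n_vista_blocks = {self.n_vista_blocks}",
            f"n_vista_timepoints_per_block = {self.n_vista_timepoints_per_block}",
            f"n_mrf_timepoints = {self.n_mrf_timepoints}",
            f"mrf_inversion_index = {self.mrf_inversion_index}",
            f"mrf_rest_duration = {self.mrf_rest_duration}",
            f"rf_phase_deg = {self.rf_phase_deg}",
            f"fa_train_file = {fa_path.name}",
        ]
        path.write_text("\n".join(lines) + "\n")
        save_fa_train(fa_path, self.fa_train)

    @classmethod
    def from_file(cls, path) -> "SequenceProtocol":
        path = Path(path)
        kv: dict[str, str] = {}
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed protocol line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        fa_file = kv.pop("fa_train_file", None)
        fa = load_fa_train(path.parent / fa_file) if fa_file else None
        ints = {"n_vista_blocks", "n_vista_timepoints_per_block",
                "n_mrf_timepoints", "mrf_inversion_index"}
        kwargs = {k: (int(v) if k in ints else float(v)) for k, v in kv.items()}
        return cls(fa_train=fa, **kwargs)


def load_fa_train(path) -> np.ndarray:
    """Read a flip-angle train from a one-angle-per-line text file (degrees)."""
    vals = [float(s) for s in Path(path).read_text().split()]
    return np.asarray(vals, dtype=float)


def save_fa_train(path, fa_train) -> None:
    Path(path).write_text(
        "\n".join(f"{a:.6f}" for a in np.asarray(fa_train, dtype=float)) + "\n"
    )


def optimized_fa_train(n: int = 660) -> np.ndarray:
    """The shipped CRLB-optimized flip-angle train (degrees).

    Produced by :func:`vistamrf.crlb.optimize_fa` from a constant 35-degree
    start under the default three-tissue target configuration.
    """
    with resources.files("vistamrf.data").joinpath("fa_optimized.txt").open() as fh:
        fa = np.asarray([float(s) for s in fh.read().split()], dtype=float)
    if n == len(fa):
        return fa
    # resample to other train lengths (keeps the overall shape)
    x = np.linspace(0.0, 1.0, len(fa))
    return np.interp(np.linspace(0.0, 1.0, n), x, fa)


def default_protocol(fa_train=None) -> SequenceProtocol:
    """The default 660-time-point ViSTa-MRF protocol."""
    return SequenceProtocol(fa_train=fa_train)
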