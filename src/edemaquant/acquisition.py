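"""Acquisition metadata and the echo-resolved image container.

The pipeline models a multi-slice multi-echo spin-echo (MSME) acquisition:
one image per echo time, a fixed repetition time, and an axial slice stack.
Signal in a voxel follows the monoexponential decay

    SI(TE) = K * PD * exp(-TE/T2) * (1 - exp(-TR/T1))

where ``K`` is a scanner constant and the T1 saturation factor is the same
at every echo, so both are absorbed into the fitted amplitude.  Only the
amplitude (proportional to proton density) and T2 are ever estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "MultiEchoVolume", "default_echo_times"]


def default_echo_times(first_te: float = 6.5, n_echoes: int = 12) -> tuple[float, ...]:
    """Echo train TE_k = first_te * k, k = 1..n_echoes, in milliseconds."""
    return tuple(first_te * k for k in range(1, n_echoes + 1))


@dataclass(frozen=True)
class AcquisitionParams:
    """MSME acquisition geometry and timing.

    Defaults mirror a 7 T small-animal protocol: 128 x 128 matrix over a
    50 x 50 mm^2 field of view, 18 axial slices of 1 mm, TR 2500 ms and a
    12-echo train with 6.5 ms spacing.
    """

    repetition_time: float = 2500.0  # ms
    echo_times: tuple[float, ...] = field(default_factory=default_echo_times)
    matrix_rows: int = 128
    matrix_cols: int = 128
    n_slices: int = 18
    slice_thickness: float = 1.0  # mm
    field_of_view: tuple[float, float] = (50.0, 50.0)  # mm

    def __post_init__(self) -> None:
        tes = np.asarray(self.echo_times, dtype=float)
        if tes.ndim != 1 or tes.size < 1:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(tes <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.repetition_time <= tes.max():
            raise ValueError("repetition_time must exceed the last echo time")
        for name in ("matrix_rows", "matrix_cols", "n_slices"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if len(self.field_of_view) != 2 or any(f <= 0 for f in self.field_of_view):
            raise ValueError("field_of_view must be two positive extents")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(n_slices, rows, cols) of a single-echo image stack."""
        return (self.n_slices, self.matrix_rows, self.matrix_cols)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """In-plane spacing (row, col) and slice thickness, mm."""
        return (
            self.field_of_view[0] / self.matrix_rows,
            self.field_of_view[1] / self.matrix_cols,
            self.slice_thickness,
        )

    def to_dict(self) -> dict:
        return {
            "repetition_time": self.repetition_time,
            "echo_times": list(self.echo_times),
            "matrix_rows": self.matrix_rows,
            "matrix_cols": self.matrix_cols,
            "n_slices": self.n_slices,
            "slice_thickness": self.slice_thickness,
            "field_of_view": list(self.field_of_view),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(
            repetition_time=float(d["repetition_time"]),
            echo_times=tuple(float(t) for t in d["echo_times"]),
            matrix_rows=int(d["matrix_rows"]),
            matrix_cols=int(d["matrix_cols"]),
            n_slices=int(d["n_slices"]),
            slice_thickness=float(d["slice_thickness"]),
            field_of_view=tuple(float(f) for f in d["field_of_view"]),
        )


@dataclass
class MultiEchoVolume:
    """One MSME scan: intensities indexed (slice, row, col, echo)."""

    intensities: np.ndarray
    params: AcquisitionParams
    subject_id: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4-D (slice, row, col, echo)")
        if self.intensities.shape[-1] != self.params.n_echoes:
            raise ValueError(
                f"echo axis length {self.intensities.shape[-1]} != "
                f"{self.params.n_echoes} echo times"
            )
        if self.intensities.shape[:3] != self.params.grid_shape:
            raise ValueError(
                f"grid {self.intensities.shape[:3]} != {self.params.grid_shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]
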