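"""In-memory containers for session records and spike-sorted metadata.

A :class:`SessionRecord` mirrors the published session container: one
sample-by-channel matrix holding iEMG channels (mV), raw force-sensor
channels (V), the movement-code stream and the cue-level stream, plus the
channel label list, the movement table and the sampling rate.  Forces are
deliberately kept in raw sensor volts; conversion to newtons is explicit via
:func:`volts_to_newtons`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import decode_code
from .errors import IntegrityError, UnknownCodeError

__all__ = [
    "SessionRecord",
    "SpikeSortResult",
    "ForceCalibration",
    "volts_to_newtons",
    "newtons_to_volts",
    "segment_by_code",
]

log = logging.getLogger(__name__)

#: label of the movement-code column in generated records
CODE_LABEL = "Movement code"
#: label of the cue-level column in generated records
CUE_LABEL = "Cue"
#: prefix of force columns in generated records
FORCE_PREFIX = "Force "


@dataclass(frozen=True)
class ForceCalibration:
    """Affine transfer function of the bidirectional force transducers.

    The sensors output 0-5 V mapped linearly onto -100 .. +100 N, i.e.
    ``force = volts * 40 - 100``.
    """

    gain: float = 40.0  # N per volt
    offset: float = -100.0  # N at 0 V
    span_volts: tuple[float, float] = (0.0, 5.0)

    def to_newtons(self, volts):
        v = np.asarray(volts, dtype=float)
        lo, hi = self.span_volts
        if np.any(v < lo) or np.any(v > hi):
            log.warning("force reading outside the %g-%g V sensor span", lo, hi)
        return v * self.gain + self.offset

    def to_volts(self, newtons):
        return (np.asarray(newtons, dtype=float) - self.offset) / self.gain


_DEFAULT_CAL = ForceCalibration()


def volts_to_newtons(volts, calibration: ForceCalibration = _DEFAULT_CAL):
    """Convert raw force-sensor volts to newtons (force = v*40 - 100)."""
    return calibration.to_newtons(volts)


def newtons_to_volts(newtons, calibration: ForceCalibration = _DEFAULT_CAL):
    """Inverse of :func:`volts_to_newtons`."""
    return calibration.to_volts(newtons)


@dataclass
class SessionRecord:
    """One recording session: data matrix, labels, movement table, rate."""

    data: np.ndarray  # (n_samples, n_channels) float
    channels: list[str]
    movements: pd.DataFrame  # columns: code, description
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channels = [str(c) for c in self.channels]

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SessionRecord":
        """Check container invariants; raise IntegrityError on violation."""
        if self.data.ndim != 2:
            raise IntegrityError("Data must be a 2-D sample-by-channel matrix")
        if len(self.channels) != self.data.shape[1]:
            raise IntegrityError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[1]} data columns"
            )
        if not self.fs > 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.fs}")
        if CODE_LABEL in self.channels:
            for c in np.unique(self.code_stream()):
                if c == 0:
                    continue  # inter-stage idle
                try:
                    decode_code(c)
                except UnknownCodeError as exc:
                    raise IntegrityError(
                        f"movement-code stream holds unknown code {c:.2f}"
                    ) from exc
        return self

    # -- column access ------------------------------------------------------

    def column(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.data[:, idx]

    @property
    def emg_labels(self) -> list[str]:
        """Labels of iEMG columns (everything that is not force/code/cue)."""
        special = {CODE_LABEL, CUE_LABEL}
        return [
            c
            for c in self.channels
            if c not in special and not c.startswith(FORCE_PREFIX)
        ]

    @property
    def force_labels(self) -> list[str]:
        return [c for c in self.channels if c.startswith(FORCE_PREFIX)]

    def emg_data(self) -> np.ndarray:
        return self.data[:, [self.channels.index(c) for c in self.emg_labels]]

    def force_data(self) -> np.ndarray:
        return self.data[:, [self.channels.index(c) for c in self.force_labels]]

    def code_stream(self) -> np.ndarray:
        return self.column(CODE_LABEL)

    def cue_stream(self) -> np.ndarray:
        return self.column(CUE_LABEL)

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs


@dataclass
class SpikeSortResult:
    """Spike-sorted metadata: per-unit spike trains and waveform templates.

    ``samples`` holds 0-based spike sample indices per unit; ``times`` is the
    same train divided by ``fs``.  The published files store 1-based indices
    (MATLAB provenance); the IO layer performs the shift.
    """

    samples: list[np.ndarray]
    templates: list[np.ndarray]
    fs: float
    unknown: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        self.samples = [np.asarray(s, dtype=np.int64) for s in self.samples]
        self.templates = [np.asarray(t, dtype=float) for t in self.templates]
        self.unknown = np.asarray(self.unknown, dtype=np.int64)

    @property
    def times(self) -> list[np.ndarray]:
        """Spike times in seconds: exactly samples / fs per unit."""
        return [s / self.fs for s in self.samples]

    @property
    def n_units(self) -> int:
        return len(self.samples)

    def validate(self) -> "SpikeSortResult":
        if not self.fs > 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.fs}")
        if len(self.templates) != len(self.samples):
            raise IntegrityError(
                f"{len(self.templates)} templates for {len(self.samples)} units"
            )
        for i, s in enumerate(self.samples):
            if len(s) > 1 and not np.all(np.diff(s) > 0):
                raise IntegrityError(
                    f"unit {i} spike train is not strictly increasing"
                )
        return self


def segment_by_code(rec: SessionRecord, code: float) -> list[tuple[int, int]]:
    """Maximal runs of ``code`` in the movement-code stream.

    Codes are compared at two-decimal precision.  Returns 0-based half-open
    ``(start, end)`` sample intervals, sorted and disjoint; an absent code
    yields an empty list.
    """
    stream = np.round(rec.code_stream() * 100).astype(np.int64)
    target = round(float(code) * 100)
    mask = stream == target
    if not mask.any():
        return []
    starts = list(np.flatnonzero(mask[1:] & ~mask[:-1]) + 1)
    ends = list(np.flatnonzero(~mask[1:] & mask[:-1]) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))
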