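"""EEG recording I/O, fixed-length instance segmentation, and common average referencing.

EDF (European Data Format) reading is delegated to MNE; since no EDF-writing
library is available as a dependency, a minimal 16-bit EDF writer is provided
for exporting synthetic cohorts and building test fixtures.  All in-memory
amplitudes are in microvolts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

CONDITIONS = ("eyes_open", "eyes_closed", "synthetic")


@dataclass
class EEGRecording:
    """A multi-channel EEG recording.

    ``data`` is channel-major, shape ``(n_channels, n_samples)``, in microvolts.
    ``channel_names`` follow the montage labels of the source file (10-10 names
    for the motor-imagery database) or synthetic labels ``ch00 ...``.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal n_channels")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGInstance:
    """One fixed-length window cut from a recording."""

    subject_id: str
    data: np.ndarray
    index: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class InstanceSet:
    """An ordered collection of instances with one subject label per instance."""

    instances: list[EEGInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("InstanceSet must be non-empty")
        n_ch = {inst.n_channels for inst in self.instances}
        if len(n_ch) != 1:
            raise ValueError(f"heterogeneous channel counts in InstanceSet: {n_ch}")

    @property
    def subject_ids(self) -> list[str]:
        return [inst.subject_id for inst in self.instances]

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[EEGInstance]:
        return iter(self.instances)

    def __getitem__(self, i: int) -> EEGInstance:
        return self.instances[i]


def read_edf_recording(path: str | os.PathLike, condition: str = "synthetic",
                       subject_id: str | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording`.

    Header sampling rate and channel labels are taken as-is; no resampling or
    filtering is applied.  MNE scales EEG channels to volts internally; the
    returned data are converted back to microvolts so the EDF physical units
    are preserved at face value.
    """
    import mne

    if not os.path.isfile(path):
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt header, truncated records, ...
        raise IOError(f"failed to read EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6
    if data.shape[0] == 0:
        raise ValueError(f"EDF file {path} contains zero channels")
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    return EEGRecording(
        subject_id=subject_id,
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=[str(name) for name in raw.ch_names],
        condition=condition,
    )


def write_edf_recording(path: str | os.PathLike, rec: EEGRecording) -> None:
    """Write a recording as a minimal EDF file (16-bit, 1-second data records).

    Requires an integer sampling rate; trailing samples beyond a whole number
    of 1-s records are dropped, mirroring the EDF record structure.  Physical
    dimension is microvolts; amplitudes are quantized to the 16-bit digital
    range, so a read-back matches the input only up to that quantization.
    """
    if not float(rec.fs).is_integer():
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(rec.fs)
    n_ch = rec.n_channels
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]
    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    pmaxs = np.where(pmaxs - pmins < 1e-9, pmins + 1.0, pmaxs)  # avoid zero span
    dmin, dmax = -32768, 32767
    scale = (pmaxs - pmins) / (dmax - dmin)

    with open(path, "wb") as f:
        def w(text: str, width: int) -> None:
            f.write(text.encode("ascii")[:width].ljust(width))

        w("0", 8)
        w(f"{rec.subject_id} X X X", 80)
        w("Startdate 01-JAN-2020 X X X", 80)
        w("01.01.20", 8)
        w("00.00.00", 8)
        w(str(256 + 256 * n_ch), 8)
        w("", 44)
        w(str(n_rec), 8)
        w("1", 8)
        w(str(n_ch), 4)
        for name in rec.channel_names:
            w(str(name), 16)
        for _ in range(n_ch):
            w("", 80)  # transducer
        for _ in range(n_ch):
            w("uV", 8)
        for v in pmins:
            w(f"{v:.6g}", 8)
        for v in pmaxs:
            w(f"{v:.6g}", 8)
        for _ in range(n_ch):
            w(str(dmin), 8)
        for _ in range(n_ch):
            w(str(dmax), 8)
        for _ in range(n_ch):
            w("", 80)  # prefiltering
        for _ in range(n_ch):
            w(str(fs), 8)
        for _ in range(n_ch):
            w("", 32)
        for r in range(n_rec):
            for i in range(n_ch):
                chunk = data[i, r * fs : (r + 1) * fs]
                dig = np.round((chunk - pmins[i]) / scale[i]) + dmin
                f.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())


def segment_instances(rec: EEGRecording, window_seconds: float = 1.0) -> InstanceSet:
    """Cut a recording into consecutive non-overlapping windows from sample 0.

    The window count is ``floor(n_samples / window_samples)``; a trailing
    remainder is discarded.  A 60-s recording at 160 Hz yields 60 one-second
    instances of 160 samples.
    """
    window_samples = int(round(window_seconds * rec.fs))
    if window_samples < 2:
        raise ValueError("window must span at least 2 samples")
    n_inst = rec.n_samples // window_samples
    if n_inst == 0:
        raise ValueError(
            f"window of {window_samples} samples longer than recording "
            f"({rec.n_samples} samples)"
        )
    instances = [
        EEGInstance(
            subject_id=rec.subject_id,
            data=rec.data[:, k * window_samples : (k + 1) * window_samples].copy(),
            index=k,
        )
        for k in range(n_inst)
    ]
    return InstanceSet(instances)


def common_average_reference(instance: EEGInstance) -> EEGInstance:
    """Subtract the instantaneous across-channel mean from every channel.

    Removes signal components common to all electrodes (reference drift, mains
    pickup).  Output columns sum to zero; a single-channel input yields zeros.
    """
    data = instance.data
    referenced = data - data.mean(axis=0, keepdims=True)
    return EEGInstance(subject_id=instance.subject_id, data=referenced,
                       index=instance.index)
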