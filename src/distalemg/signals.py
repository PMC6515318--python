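"""Multichannel signal container and the plain-text signal-file dialect.

A signal file is tab-delimited: two header lines declaring the sampling
rate and the channel labels, then one row per sample::

    # sampling_rate_hz=2000.0
    # channels=L1,L2,L3,L4,L5,L6
    0.0123\t-0.0042\t...

Channels are stored row-wise in memory (``samples[channel, sample]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MUSCLE_LABELS = ("L1", "L2", "L3", "L4", "L5", "L6")
DISTAL_LABELS = ("A1", "A2", "A3", "A4", "A5")

#: Target muscles behind the L1..L6 labels.
MUSCLE_NAMES = {
    "L1": "tibialis anterior",
    "L2": "gastrocnemius lateral",
    "L3": "gastrocnemius medial",
    "L4": "soleus lateral",
    "L5": "soleus medial",
    "L6": "peroneus",
}


class ParameterError(ValueError):
    """An argument violates an operation's preconditions."""


class SignalFileError(ValueError):
    """A signal file could not be parsed; message carries the line number."""


@dataclass
class SignalRecord:
    """Raw multichannel time series with sampling rate and channel labels."""

    samples: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ParameterError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[i]

    def copy_with(self, samples: np.ndarray) -> "SignalRecord":
        return SignalRecord(samples, self.sampling_rate, list(self.channel_labels))


def write_signal_file(record: SignalRecord, path) -> None:
    """Write ``record`` in the delimited text dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={record.sampling_rate!r}\n")
        fh.write("# channels=" + ",".join(record.channel_labels) + "\n")
        for row in record.samples.T:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_signal_file(path) -> SignalRecord:
    """Parse a signal file, raising :class:`SignalFileError` with a line number."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise SignalFileError(f"{path}: fewer than two header lines")
    if not lines[0].startswith("# sampling_rate_hz="):
        raise SignalFileError(f"{path}:1: missing '# sampling_rate_hz=' header")
    try:
        fs = float(lines[0].split("=", 1)[1])
    except ValueError:
        raise SignalFileError(f"{path}:1: non-numeric sampling rate") from None
    if not lines[1].startswith("# channels="):
        raise SignalFileError(f"{path}:2: missing '# channels=' header")
    labels = [s for s in lines[1].split("=", 1)[1].split(",") if s]
    if not labels:
        raise SignalFileError(f"{path}:2: empty channel list")
    rows = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(labels):
            raise SignalFileError(
                f"{path}:{lineno}: expected {len(labels)} columns, got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            raise SignalFileError(f"{path}:{lineno}: non-numeric cell") from None
    samples = np.array(rows, dtype=float).T if rows else np.empty((len(labels), 0))
    return SignalRecord(samples, fs, labels)
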