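"""Core in-memory container for a multichannel scalp EEG recording."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .montage import CHANNELS_19

GROUPS = ("AIE", "CVA", "TBI")
STATES = ("baseline", "induction", "steady_state", "recovery")


@dataclass
class EEGRecording:
    """channels x samples EEG matrix in microvolts with 10-20 labels.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    group : str or None
        Etiology group (``AIE``, ``CVA`` or ``TBI``); None when unknown.
    state : str or None
        Anesthesia state: ``baseline``, ``induction``, ``steady_state`` or
        ``recovery``; None when unknown.
    fs : float
        Sampling rate in Hz, > 0.
    channels : list of str
        Channel labels drawn from the 19-label 10-20 set, unique, in data order.
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts; all finite.
    """

    subject_id: str
    group: str | None
    state: str | None
    fs: float
    channels: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if self.group is not None and self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")
        if self.state is not None and self.state not in STATES:
            raise ParameterError(f"unknown state {self.state!r}")
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples array")
        if len(self.channels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ParameterError("duplicate channel labels")
        unknown = [c for c in self.channels if c not in CHANNELS_19]
        if unknown:
            raise ParameterError(f"labels outside the 19-channel 10-20 set: {unknown}")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ParameterError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector of one channel."""
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise ParameterError(f"no channel {label!r} in recording") from None

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  channels: list[str] | None = None) -> "EEGRecording":
        """Copy of this recording with new data (and optionally fs/channels)."""
        return replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            channels=list(self.channels) if channels is None else list(channels),
        )
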