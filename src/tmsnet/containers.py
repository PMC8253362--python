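"""Shared data containers used by every pipeline stage.

A :class:`Recording` is the raw substrate: a continuous multichannel signal in
microvolts with a labeled event stream.  An :class:`EpochSet` is the
event-aligned trials x channels x time tensor every analysis stage consumes.
Sample windows are half-open and 0-based, with t = 0 at the alignment event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multichannel EEG signal (µV) with a labeled event stream.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Unique 10-20 channel labels, one per signal row.
    events : list of (str, int)
        ``(label, sample_index)`` pairs; indices must lie inside the signal.
    """

    signal: np.ndarray
    fs: float
    channels: list[str]
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError("channel label count does not match signal rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        n = self.signal.shape[1]
        for label, s in self.events:
            if not (0 <= int(s) < n):
                raise ValueError(
                    f"event {label!r} at sample {s} outside recording [0, {n})"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def event_samples(self, label: str) -> np.ndarray:
        """Sample indices of all events carrying ``label``, in order."""
        return np.array([s for lab, s in self.events if lab == label], dtype=int)


@dataclass
class EpochSet:
    """Event-aligned epochs: trials x channels x time, in µV.

    ``times`` is the uniform time axis in seconds relative to the alignment
    event (step 1/fs); ``mask`` flags bad (artifact-interpolated) samples per
    trial and is honored by ERP averaging but not by the network stage.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times)
    times: np.ndarray  # (n_times,) seconds relative to alignment event
    fs: float
    channels: list[str]
    align_label: str
    metadata: pd.DataFrame | None = None
    mask: np.ndarray | None = None  # (n_trials, n_times) True where bad

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel label count mismatch")
        if self.metadata is not None and len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count must equal trial count")
        if self.mask is None:
            self.mask = np.zeros((self.data.shape[0], self.times.size), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.data.shape[0], self.times.size):
                raise ValueError("mask must be (n_trials, n_times)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.times.size

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            fs=self.fs,
            channels=list(self.channels),
            align_label=self.align_label,
            metadata=None if self.metadata is None else self.metadata.copy(),
            mask=self.mask.copy(),
        )

    def select(self, rows: np.ndarray) -> "EpochSet":
        """Subset trials by boolean or integer index array."""
        rows = np.asarray(rows)
        md = None
        if self.metadata is not None:
            md = self.metadata.iloc[rows].reset_index(drop=True) if rows.dtype != bool \
                else self.metadata.loc[rows].reset_index(drop=True)
        return EpochSet(
            data=self.data[rows],
            times=self.times.copy(),
            fs=self.fs,
            channels=list(self.channels),
            align_label=self.align_label,
            metadata=md,
            mask=self.mask[rows],
        )
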