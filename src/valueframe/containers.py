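"""Shared in-memory containers for continuous and epoched multichannel data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "EpochsContainer", "n_samples_for_window"]


def n_samples_for_window(fs: float, window_ms: tuple[float, float]) -> int:
    """Sample count of a half-open window [t_start, t_end) at rate fs.

    Windows are half-open so that e.g. -1000..2000 ms at 200 Hz is exactly
    600 samples with no off-by-one ambiguity.
    """
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must have t_end > t_start")
    return int(round(fs * (t1 - t0) / 1000.0))


@dataclass
class ContinuousRecording:
    """Continuous multichannel data with channel roles and an event list.

    data
        channels x samples array.
    fs
        Sampling rate in Hz.
    channel_roles
        One role per channel, e.g. "signal" or "eog".
    events
        DataFrame with columns ``sample`` (index into the recording) and
        ``code``.
    """

    data: np.ndarray
    fs: float
    channel_roles: list[str]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample", "code"]))
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("one role per channel required")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.events) and (
            (self.events["sample"] < 0).any()
            or (self.events["sample"] >= self.data.shape[1]).any()
        ):
            raise ValueError("event samples outside recording bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == role])


@dataclass
class EpochsContainer:
    """Event-locked epochs: trials x channels x samples at a fixed rate.

    The epoch window and baseline window are half-open intervals in ms
    relative to the locking event.  ``rejected`` marks trials excluded from
    analysis (bounds violations at epoching time, artifact rejection later);
    the data themselves are never mutated by rejection.
    """

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    locking: str = "stimulus"
    baseline_ms: tuple[float, float] | None = None
    trial_ids: np.ndarray | None = None
    channel_names: list[str] | None = None
    rejected: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        expect = n_samples_for_window(self.fs, self.window_ms)
        if self.data.shape[2] != expect:
            raise ValueError(
                f"window {self.window_ms} at {self.fs} Hz implies {expect} samples, "
                f"got {self.data.shape[2]}"
            )
        if self.baseline_ms is not None:
            b0, b1 = self.baseline_ms
            if b0 < self.window_ms[0] or b1 > self.window_ms[1]:
                raise ValueError("baseline window must lie inside the epoch window")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs

    def select(self, mask) -> "EpochsContainer":
        """Subset of trials; keeps epoch/trial alignment intact."""
        mask = np.asarray(mask)
        return EpochsContainer(
            data=self.data[mask],
            fs=self.fs,
            window_ms=self.window_ms,
            locking=self.locking,
            baseline_ms=self.baseline_ms,
            trial_ids=self.trial_ids[mask],
            channel_names=self.channel_names,
            rejected=self.rejected[mask],
        )
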