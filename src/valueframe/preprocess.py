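"""Preprocessing of continuous multichannel recordings.

Blink detection from the EOG channel, removal of the blink's spatial
topography from the continuous data, epoching with baseline correction, and
automated artifact rejection.  All operations are deterministic and never
mutate their inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochsContainer, n_samples_for_window

__all__ = [
    "detect_blinks",
    "remove_blinks",
    "epoch",
    "reject_artifacts",
]


def detect_blinks(
    eog: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (1.0, 15.0),
    threshold_sd: float = 3.0,
    refractory_ms: float = 200.0,
    template_ms: float | None = 300.0,
) -> np.ndarray:
    """Blink peak samples from a single EOG channel.

    The channel is band-pass filtered (zero-phase, so peak latencies are
    preserved), z-scored, and local maxima exceeding ``threshold_sd``
    standard deviations are returned, enforcing a refractory period between
    successive detections.  By default the z-scored trace is additionally
    matched-filtered with a raised-cosine blink template of ``template_ms``,
    which sharpens peak localization to about a sample; ``template_ms=None``
    disables it.
    """
    eog = np.asarray(eog, dtype=float)
    if eog.std() == 0:
        raise ValueError("flat EOG channel: cannot detect blinks")
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, eog)
    z = (filt - filt.mean()) / filt.std()
    if template_ms is not None:
        from .synthetic import raised_cosine

        half = int(round(template_ms / 2 * fs / 1000.0))
        tpl_t = np.arange(-half, half + 1) * 1000.0 / fs
        tpl = raised_cosine(tpl_t, 0.0, template_ms)
        tpl /= np.linalg.norm(tpl)
        z = np.convolve(z, tpl[::-1], mode="same")
        z = (z - z.mean()) / z.std()
    distance = max(int(round(refractory_ms * fs / 1000.0)), 1)
    peaks, _ = signal.find_peaks(z, height=threshold_sd, distance=distance)
    return peaks


def remove_blinks(
    recording: ContinuousRecording,
    blink_samples: np.ndarray,
    n_components: int = 1,
    template_window_ms: tuple[float, float] = (-200.0, 400.0),
    topographies: np.ndarray | None = None,
):
    """Regress the average blink's spatial topographies out of the data.

    An average blink-locked epoch is computed over the signal channels, PCA
    over channels of that average yields spatial topographies of the blink,
    and the leading ``n_components`` topographies are removed from the
    continuous data by least squares.  Events and sampling rate are untouched.
    With no blinks the data are returned unchanged; passing ``topographies``
    reuses previously estimated components (removal is then a projection and
    hence idempotent).

    Returns (cleaned ContinuousRecording, topographies array
    channels x n_components).
    """
    sig_idx = recording.channel_indices("signal")
    if n_components >= sig_idx.size:
        raise ValueError("n_components must be smaller than the signal channel count")
    fs = recording.fs
    blink_samples = np.asarray(blink_samples, dtype=int)
    if blink_samples.size == 0 and topographies is None:
        out = ContinuousRecording(
            data=recording.data.copy(), fs=fs,
            channel_roles=list(recording.channel_roles),
            events=recording.events.copy(),
            channel_names=list(recording.channel_names),
        )
        return out, np.zeros((sig_idx.size, 0))
    if topographies is None:
        lo = int(round(template_window_ms[0] * fs / 1000.0))
        hi = int(round(template_window_ms[1] * fs / 1000.0))
        n = recording.n_samples
        segs = [
            recording.data[np.ix_(sig_idx, range(b + lo, b + hi))]
            for b in blink_samples
            if b + lo >= 0 and b + hi <= n
        ]
        if not segs:
            raise ValueError("no blink falls fully inside the recording")
        template = np.mean(segs, axis=0)  # channels x samples
        template = template - template.mean(axis=1, keepdims=True)
        # spatial PCA of the averaged blink
        u, s, _ = np.linalg.svd(template, full_matrices=False)
        topos = u[:, :n_components]  # channels x k, orthonormal
    else:
        topos = np.asarray(topographies, dtype=float)
    cleaned = recording.data.copy()
    x = cleaned[sig_idx]
    # least-squares removal; orthonormal topographies make this a projection
    coefs, *_ = np.linalg.lstsq(topos, x, rcond=None)
    cleaned[sig_idx] = x - topos @ coefs
    out = ContinuousRecording(
        data=cleaned,
        fs=fs,
        channel_roles=list(recording.channel_roles),
        events=recording.events.copy(),
        channel_names=list(recording.channel_names),
    )
    return out, topos


def epoch(
    recording: ContinuousRecording,
    events: np.ndarray,
    window_ms: tuple[float, float],
    baseline_ms: tuple[float, float] | None = None,
    locking: str = "stimulus",
    channels: np.ndarray | None = None,
) -> EpochsContainer:
    """Slice event-locked epochs and subtract the per-channel baseline mean.

    Events whose window exceeds the recording bounds are kept (zero-filled)
    but flagged in the rejection mask rather than silently dropped, so trial
    tables and epochs stay aligned.
    """
    fs = recording.fs
    events = np.asarray(events, dtype=int)
    if channels is None:
        channels = np.arange(recording.n_channels)
    n_samp = n_samples_for_window(fs, window_ms)
    off0 = int(round(window_ms[0] * fs / 1000.0))
    n_total = recording.n_samples
    data = np.zeros((events.size, channels.size, n_samp))
    rejected = np.zeros(events.size, dtype=bool)
    for i, ev in enumerate(events):
        a, b = ev + off0, ev + off0 + n_samp
        if a < 0 or b > n_total:
            rejected[i] = True
            continue
        data[i] = recording.data[np.ix_(channels, range(a, b))]
    if baseline_ms is not None:
        b0, b1 = baseline_ms
        i0 = int(round((b0 - window_ms[0]) * fs / 1000.0))
        i1 = int(round((b1 - window_ms[0]) * fs / 1000.0))
        if i0 < 0 or i1 > n_samp or i1 <= i0:
            raise ValueError("baseline window must lie inside the epoch window")
        data -= data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return EpochsContainer(
        data=data,
        fs=fs,
        window_ms=window_ms,
        locking=locking,
        baseline_ms=baseline_ms,
        channel_names=[recording.channel_names[c] for c in channels],
        rejected=rejected,
    )


def reject_artifacts(
    epochs: EpochsContainer,
    peak_to_peak_limit: float,
    flat_limit: float,
) -> np.ndarray:
    """Automated artifact mask: excessive peak-to-peak range or flat channels.

    An epoch is marked when any channel's peak-to-peak amplitude exceeds
    ``peak_to_peak_limit`` or falls below ``flat_limit``.  The mask is
    returned and stored on the container; the data are untouched.
    """
    if peak_to_peak_limit <= 0 or flat_limit <= 0:
        raise ValueError("limits must be > 0")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    mask = (ptp > peak_to_peak_limit).any(axis=1) | (ptp < flat_limit).any(axis=1)
    epochs.rejected = epochs.rejected | mask
    return mask
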