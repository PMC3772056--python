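"""Synthetic behavioural sessions and source-level oscillatory epochs.

The generator produces the data the downstream analyses assume: two-option
risky gambles (reward magnitude x reward probability) in two trial types
("comparison": both options shown at once, respond freely; "sequential":
options shown one after the other, respond after a go cue), choices from a
Prospect-theory/softmax agent, and single-virtual-channel epochs whose
beta-band oscillatory power is modulated by value and choice regressors at
controlled latencies, on top of 1/f plus white noise.

Everything is seeded: identical seeds give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import ProspectParams, choice_probability, subjective_value
from .containers import EpochsContainer, n_samples_for_window

__all__ = [
    "GroundTruth",
    "SyntheticSession",
    "generate_stimulus_set",
    "simulate_choices",
    "simulate_epochs",
    "simulate_session",
    "sample_subject_truths",
    "inject_blinks",
    "one_over_f_noise",
    "raised_cosine",
]

DEFAULT_PROBABILITY_SET = tuple(np.round(np.arange(0.10, 0.91, 0.05), 2))
DEFAULT_MAGNITUDE_RANGE = (10.0, 100.0)


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth generative settings for one synthetic subject.

    Effect amplitudes are fractional modulations of band power per unit
    regressor (negative values model desynchronisation); latencies are in ms
    from the locking event; the effect envelope is a raised cosine.
    """

    prospect: ProspectParams = field(default_factory=lambda: ProspectParams(0.8, 0.7, 3.0))
    g_value: float = -0.3
    g_choice: float = -0.3
    tau_value_ms: float = 500.0
    tau_choice_ms: float = 700.0
    envelope_ms: float = 400.0
    carrier_hz: float = 20.0
    noise_exponent: float = 1.0
    snr: float = 1.0
    amplitude: float = 1.0
    white_ratio: float = 0.3
    order_bias: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.envelope_ms <= 0:
            raise ValueError("envelope width must be > 0")
        if not (13.0 <= self.carrier_hz <= 30.0):
            raise ValueError("carrier frequency must lie in the beta band (13-30 Hz)")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def sample_subject_truths(
    base: GroundTruth,
    n_subjects: int,
    g_sd: float = 0.08,
    tau_sd_ms: float = 100.0,
    seed: int = 0,
) -> list[GroundTruth]:
    """Draw per-subject ground truths around group means.

    Effect amplitudes and latencies vary across subjects (normal around the
    group value); between-subject variance is what the group one-sample T
    operates on.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        out.append(
            replace(
                base,
                g_value=float(base.g_value + rng.normal(0, g_sd)),
                g_choice=float(base.g_choice + rng.normal(0, g_sd)),
                tau_value_ms=float(base.tau_value_ms + rng.normal(0, tau_sd_ms)),
                tau_choice_ms=float(base.tau_choice_ms + rng.normal(0, tau_sd_ms)),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stimuli and choices
# ---------------------------------------------------------------------------


def _classify_nobrainer(p1, m1, p2, m2):
    return ((p1 > p2) & (m1 > m2)) | ((p1 < p2) & (m1 < m2))


def generate_stimulus_set(
    n_per_type: int = 324,
    magnitude_range=DEFAULT_MAGNITUDE_RANGE,
    probability_set=DEFAULT_PROBABILITY_SET,
    nobrainer_prop: float = 0.5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Generate 2*n_per_type option pairs (both trial types).

    Probabilities are drawn without replacement from a finite grid and
    magnitudes uniformly from ``magnitude_range``, so the two options never
    share a probability or a magnitude.  A configurable proportion of trials
    is "nobrainer" (one option dominates on both attributes); the rest are
    "harder" (attributes advocate opposite options).  Option 1's side is
    counterbalanced within each trial type; on sequential trials option 1 is
    always the first presented.
    """
    if n_per_type <= 0:
        raise ValueError("n_per_type must be > 0")
    probs = np.unique(np.asarray(probability_set, dtype=float))
    if probs.size < 2:
        raise ValueError("probability_set needs >= 2 distinct values")
    lo, hi = magnitude_range
    if not hi > lo > 0:
        raise ValueError("magnitude_range must be nondegenerate and positive")
    rng = np.random.default_rng(seed)
    rows = []
    for trial_type in ("comparison", "sequential"):
        n_nb = int(round(n_per_type * nobrainer_prop))
        want_nb = rng.permutation(
            np.r_[np.ones(n_nb, bool), np.zeros(n_per_type - n_nb, bool)]
        )
        sides = rng.permutation(
            np.r_[["left"] * (n_per_type // 2), ["right"] * (n_per_type - n_per_type // 2)]
        )
        for k in range(n_per_type):
            while True:  # rejection-sample the wanted harder/nobrainer class
                p1, p2 = rng.choice(probs, size=2, replace=False)
                m1, m2 = rng.uniform(lo, hi, size=2)
                if m1 == m2:
                    continue
                if bool(_classify_nobrainer(p1, m1, p2, m2)) == bool(want_nb[k]):
                    break
            rows.append(
                dict(
                    trial_type=trial_type,
                    p1=p1,
                    m1=m1,
                    p2=p2,
                    m2=m2,
                    side1=sides[k],
                    nobrainer=bool(want_nb[k]),
                )
            )
    trials = pd.DataFrame(rows)
    trials.insert(0, "trial_id", np.arange(len(trials)))
    return trials


def simulate_choices(
    trials: pd.DataFrame,
    params: ProspectParams,
    order_bias: float = 0.0,
    seed: int | None = 0,
    rt_shift_ms: float = 300.0,
    rt_scale: float = 600.0,
    rt_sigma: float = 0.3,
    rt_slope: float = 0.15,
) -> pd.DataFrame:
    """Simulate choices (and response times) from a Prospect/softmax agent.

    ``order_bias`` is an additive bump on the softmax logit of the
    second-presented option on sequential trials, reproducing a slight bias
    towards choosing the later option.  Response times are shifted lognormal
    and decrease with the absolute subjective value difference.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy().reset_index(drop=True)
    v1 = subjective_value(out["p1"], out["m1"], params)
    v2 = subjective_value(out["p2"], out["m2"], params)
    logits = params.beta * np.stack([v1, v2], axis=-1)
    seq = (out["trial_type"] == "sequential").to_numpy()
    logits[seq, 1] += order_bias
    shifted = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(shifted)
    p /= p.sum(axis=1, keepdims=True)
    choice = np.where(rng.random(len(out)) < p[:, 0], 1, 2)
    out["choice"] = choice
    dv = np.abs(v1 - v2)
    dv_z = (dv - dv.mean()) / dv.std() if dv.std() > 0 else np.zeros_like(dv)
    out["rt_ms"] = rt_shift_ms + np.exp(
        np.log(rt_scale) - rt_slope * dv_z + rng.normal(0, rt_sigma, len(out))
    )
    out["sv1"] = v1
    out["sv2"] = v2
    return out


# ---------------------------------------------------------------------------
# oscillatory epochs
# ---------------------------------------------------------------------------


def raised_cosine(times_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Raised-cosine envelope, peak 1 at ``center_ms``, support ``width_ms``."""
    x = (times_ms - center_ms) / width_ms
    env = 0.5 * (1.0 + np.cos(2.0 * np.pi * x))
    env[np.abs(x) > 0.5] = 0.0
    return env


def one_over_f_noise(shape, exponent: float, fs: float, rng) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    return out / rms


def simulate_epochs(
    z_value: np.ndarray,
    choice_pm: np.ndarray,
    truth: GroundTruth,
    fs: float = 200.0,
    window_ms: tuple[float, float] = (-1000.0, 2000.0),
    locking: str = "stimulus",
    seed: int | None = None,
    trial_ids: np.ndarray | None = None,
) -> EpochsContainer:
    """Single-virtual-channel epochs with injected value and choice effects.

    Per trial the signal is a carrier oscillation at ``truth.carrier_hz``
    whose instantaneous band power follows

        P(t) = A0^2 * (1 + g_value * z_v * env(t - tau_value)
                         + g_choice * c * env(t - tau_choice))

    with ``z_v`` the standardized value regressor, ``c`` the +/-1 choice
    coding and ``env`` a raised cosine of width ``envelope_ms`` (the carrier
    amplitude is the square root of the bracket, floored at 0.05 so it stays
    real).  1/f noise plus white noise is added with total RMS equal to the
    carrier RMS divided by ``snr``.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be > 0")
    t0, t1 = window_ms
    for tau in (truth.tau_value_ms, truth.tau_choice_ms):
        if not (t0 <= tau < t1):
            raise ValueError(f"effect latency {tau} ms outside window {window_ms}")
    z_value = np.asarray(z_value, dtype=float)
    choice_pm = np.asarray(choice_pm, dtype=float)
    n_trials = z_value.shape[0]
    if choice_pm.shape[0] != n_trials:
        raise ValueError("z_value and choice_pm must have one entry per trial")
    n = n_samples_for_window(fs, window_ms)
    times = t0 + np.arange(n) * 1000.0 / fs
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    env_v = raised_cosine(times, truth.tau_value_ms, truth.envelope_ms)
    env_c = raised_cosine(times, truth.tau_choice_ms, truth.envelope_ms)
    power_mod = (
        1.0
        + truth.g_value * z_value[:, None] * env_v[None, :]
        + truth.g_choice * choice_pm[:, None] * env_c[None, :]
    )
    amp = truth.amplitude * np.sqrt(np.clip(power_mod, 0.05, None))
    phase = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
    carrier = amp * np.cos(2 * np.pi * truth.carrier_hz * times[None, :] / 1000.0 + phase)

    carrier_rms = truth.amplitude / np.sqrt(2.0)
    noise_rms = carrier_rms / truth.snr
    pink = one_over_f_noise((n_trials, n), truth.noise_exponent, fs, rng)
    mix = pink + truth.white_ratio * rng.standard_normal((n_trials, n))
    mix_rms = np.sqrt(np.mean(mix**2))
    noise = noise_rms * mix / mix_rms

    data = (carrier + noise)[:, None, :]  # one virtual channel
    return EpochsContainer(
        data=data,
        fs=fs,
        window_ms=window_ms,
        locking=locking,
        baseline_ms=(max(t0, -200.0), min(t1, 0.0)) if t0 < 0 < t1 else None,
        trial_ids=trial_ids,
        channel_names=["virtual"],
    )


@dataclass
class SyntheticSession:
    """One subject's simulated session: trial table + epochs per locking event."""

    trials: pd.DataFrame
    epochs: dict[str, EpochsContainer]
    truth: GroundTruth

    def __post_init__(self):
        for ep in self.epochs.values():
            if not np.array_equal(ep.trial_ids, self._ids_for(ep)):
                raise ValueError("epochs and trial table must share trial ordering")

    def _ids_for(self, ep):
        mask = self.trials["trial_id"].isin(ep.trial_ids)
        return self.trials.loc[mask, "trial_id"].to_numpy()


def _standardized(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std()


def simulate_session(
    truth: GroundTruth,
    n_per_type: int = 324,
    fs: float = 200.0,
    seed: int | None = None,
    **stimulus_kw,
) -> SyntheticSession:
    """Full synthetic session for one subject.

    Generates stimuli, simulates choices from ``truth.prospect``, and builds
    three epoch sets mirroring the experiment's locking conventions:

    - ``option1`` (sequential trials, -1000..2000 ms): value effect driven by
      the standardized subjective value of option 1;
    - ``option2`` (sequential trials, -1000..2000 ms): value effect driven by
      the standardized subjective value difference option 1 - option 2;
    - ``response`` (comparison trials, -2000..1000 ms): value effect driven by
      the standardized chosen-minus-unchosen subjective value, with effect
      latencies mirrored to pre-response times.

    Choice is coded +1 when option 1 was chosen.
    """
    master = np.random.default_rng(truth.seed if seed is None else seed)
    s_stim, s_choice, s1, s2, s3 = master.integers(2**31 - 1, size=5)
    trials = generate_stimulus_set(n_per_type=n_per_type, seed=int(s_stim), **stimulus_kw)
    trials = simulate_choices(
        trials, truth.prospect, order_bias=truth.order_bias, seed=int(s_choice)
    )
    seq = trials[trials["trial_type"] == "sequential"]
    comp = trials[trials["trial_type"] == "comparison"]
    c_seq = np.where(seq["choice"] == 1, 1.0, -1.0)
    c_comp = np.where(comp["choice"] == 1, 1.0, -1.0)

    epochs = {
        "option1": simulate_epochs(
            _standardized(seq["sv1"]), c_seq, truth, fs=fs,
            window_ms=(-1000.0, 2000.0), locking="option1",
            seed=int(s1), trial_ids=seq["trial_id"].to_numpy(),
        ),
        "option2": simulate_epochs(
            _standardized(seq["sv1"] - seq["sv2"]), c_seq, truth, fs=fs,
            window_ms=(-1000.0, 2000.0), locking="option2",
            seed=int(s2), trial_ids=seq["trial_id"].to_numpy(),
        ),
        "response": simulate_epochs(
            _standardized(np.where(comp["choice"] == 1,
                                   comp["sv1"] - comp["sv2"],
                                   comp["sv2"] - comp["sv1"])),
            c_comp,
            replace(truth,
                    tau_value_ms=-truth.tau_value_ms,
                    tau_choice_ms=-truth.tau_choice_ms),
            fs=fs, window_ms=(-2000.0, 1000.0), locking="response",
            seed=int(s3), trial_ids=comp["trial_id"].to_numpy(),
        ),
    }
    return SyntheticSession(trials=trials, epochs=epochs, truth=truth)


# ---------------------------------------------------------------------------
# blink artifacts
# ---------------------------------------------------------------------------


def inject_blinks(
    eog: np.ndarray,
    data: np.ndarray,
    fs: float,
    rate_hz: float,
    topography: np.ndarray | None = None,
    seed: int | None = 0,
    amplitude_sd: float = 8.0,
    duration_ms: float = 300.0,
):
    """Add stereotyped blink pulses to an EOG channel and leak them into data.

    Blink peak times follow a Poisson process at ``rate_hz``; each blink is a
    raised-cosine pulse of ``duration_ms`` scaled to ``amplitude_sd`` times
    the background EOG standard deviation.  The identical time course, scaled
    per channel by ``topography``, is added to ``data``.

    Returns (contaminated_eog, contaminated_data, blink_peak_samples).
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    eog = np.asarray(eog, dtype=float).copy()
    data = np.atleast_2d(np.asarray(data, dtype=float)).copy()
    n = eog.shape[0]
    rng = np.random.default_rng(seed)
    if rate_hz == 0:
        return eog, data, np.array([], dtype=int)
    if topography is None:
        topography = rng.normal(0, 1, size=data.shape[0])
    half = int(round(duration_ms / 2 * fs / 1000.0))
    gaps = rng.exponential(1.0 / rate_hz, size=max(int(3 * rate_hz * n / fs) + 10, 10))
    times = np.cumsum(gaps) * fs
    times = times[(times > half) & (times < n - half - 1)].astype(int)
    if times.size > 1:  # blinks cannot overlap: thin to at least one duration apart
        keep = [times[0]]
        for t in times[1:]:
            if t - keep[-1] > 2 * half:
                keep.append(t)
        times = np.array(keep)
    pulse_t = np.arange(-half, half + 1) * 1000.0 / fs
    pulse = raised_cosine(pulse_t, 0.0, duration_ms)
    amp = amplitude_sd * eog.std()
    course = np.zeros(n)
    for t in times:
        course[t - half : t + half + 1] += pulse
    eog += amp * course
    data += np.outer(topography, amp * course)
    return eog, data, times
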