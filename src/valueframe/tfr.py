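"""Single-trial Morlet time-frequency power and trial-wise regression.

Each epoch is convolved with complex Morlet wavelets (constant ratio of
centre frequency to spectral bandwidth, the "Morlet factor"); the squared
magnitude gives instantaneous power per trial, frequency and time point.
Ordinary least squares is then run independently at every (frequency, time)
bin on a trial-wise design of standardized value regressors, a +/-1
categorical choice term and a constant.  The per-subject summary statistic
for each regressor is the variance-normalized effect beta_hat / SE(beta_hat),
which downstream group statistics treat as one observation per subject.

The regression surface follows statsmodels: ``TrialPowerRegression`` is the
model, ``fit()`` returns a ``TFRegressionResults`` carrying coefficient maps,
their standard errors and degrees of freedom, with ``effect_map`` and
``contrast`` accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .containers import EpochsContainer

__all__ = [
    "TFConfig",
    "TFPower",
    "DesignMatrix",
    "EffectMap",
    "morlet_wavelet",
    "morlet_power",
    "build_design",
    "TrialPowerRegression",
    "TFRegressionResults",
    "regress_power",
    "contrast",
    "hemispheric_difference",
    "MODEL_SPECS",
]


@dataclass(frozen=True)
class TFConfig:
    """Time-frequency decomposition settings.

    freqs
        Analysis frequencies in Hz; default 40 bins linearly spaced 1-40 Hz.
    morlet_factor
        Ratio of centre frequency to the wavelet's spectral standard
        deviation; sigma_t = factor / (2 pi f).
    stride_ms
        Decimation of the power time axis (effects evaluated every 25 ms by
        default).
    bands
        Named frequency bands for band-restricted analyses.
    """

    freqs: tuple = tuple(np.linspace(1.0, 40.0, 40))
    morlet_factor: float = 5.0
    stride_ms: float = 25.0
    bands: dict = field(default_factory=lambda: {"beta": (13.0, 30.0)})
    edge_sigmas: float = 3.0

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if self.morlet_factor <= 1:
            raise ValueError("Morlet factor must be > 1")

    def band_mask(self, band: str | tuple) -> np.ndarray:
        lo, hi = self.bands[band] if isinstance(band, str) else band
        f = np.asarray(self.freqs)
        return (f >= lo) & (f <= hi)


@dataclass
class TFPower:
    """Instantaneous power, trials x frequencies x time points.

    ``valid`` flags (frequency, time) bins outside the wavelet edge zone;
    bins within half the wavelet support of either epoch edge are unreliable
    and excluded from cluster statistics downstream.
    """

    power: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    valid: np.ndarray
    locking: str = "stimulus"
    window_ms: tuple | None = None

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.power.shape[1:] != (self.freqs.size, self.times_ms.size):
            raise ValueError("power dimensions inconsistent with axes")

    def crop(self, tmin_ms: float, tmax_ms: float) -> "TFPower":
        """Restrict the time axis to [tmin_ms, tmax_ms]."""
        keep = (self.times_ms >= tmin_ms) & (self.times_ms <= tmax_ms)
        return TFPower(
            power=self.power[:, :, keep],
            freqs=self.freqs,
            times_ms=self.times_ms[keep],
            valid=self.valid[:, keep],
            locking=self.locking,
            window_ms=self.window_ms,
        )


def morlet_wavelet(freq: float, fs: float, morlet_factor: float = 5.0,
                   n_sigmas: float = 3.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at ``freq`` Hz."""
    sigma_t = morlet_factor / (2.0 * np.pi * freq)
    half = int(np.ceil(n_sigmas * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_power(
    epochs: EpochsContainer | np.ndarray,
    cfg: TFConfig = TFConfig(),
    fs: float | None = None,
    channel: int = 0,
    window_ms: tuple | None = None,
    locking: str = "stimulus",
) -> TFPower:
    """Morlet power of single-channel epochs on the configured (f, t) grid.

    Accepts an :class:`EpochsContainer` (one channel selected) or a raw
    trials x samples array with ``fs`` given.  Convolution is 'same'-aligned
    so each power sample is centred on its epoch time; the time axis is then
    decimated to ``cfg.stride_ms``.
    """
    if isinstance(epochs, EpochsContainer):
        data = epochs.data[:, channel, :]
        fs = epochs.fs
        window_ms = epochs.window_ms
        locking = epochs.locking
    else:
        data = np.atleast_2d(np.asarray(epochs, dtype=float))
        if fs is None:
            raise ValueError("fs required for raw arrays")
    freqs = np.asarray(cfg.freqs, dtype=float)
    if np.any(freqs >= fs / 2.0):
        raise ValueError("analysis frequency at or above Nyquist")
    n_trials, n_samp = data.shape

    wavelets = [morlet_wavelet(f, fs, cfg.morlet_factor, cfg.edge_sigmas) for f in freqs]
    max_len = max(len(w) for w in wavelets)
    nfft = next_fast_len(n_samp + max_len - 1)
    spec = np.fft.fft(data, nfft, axis=-1)

    step = max(int(round(cfg.stride_ms * fs / 1000.0)), 1)
    keep = np.arange(0, n_samp, step)
    t0 = window_ms[0] if window_ms is not None else 0.0
    times = t0 + keep * 1000.0 / fs

    power = np.empty((n_trials, freqs.size, keep.size))
    valid = np.ones((freqs.size, keep.size), dtype=bool)
    for i, w in enumerate(wavelets):
        wspec = np.fft.fft(w, nfft)
        conv = np.fft.ifft(spec * wspec[None, :], axis=-1)
        start = (len(w) - 1) // 2  # 'same' alignment
        seg = conv[:, start : start + n_samp]
        power[:, i, :] = np.abs(seg[:, keep]) ** 2
        half = len(w) // 2
        edge = (keep < half) | (keep >= n_samp - half)
        valid[i, edge] = False
    return TFPower(
        power=power, freqs=freqs, times_ms=times, valid=valid,
        locking=locking, window_ms=window_ms,
    )


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

#: named trial-wise regression models; value columns are standardized and a
#: constant plus a +/-1 categorical choice term are always appended
MODEL_SPECS = {
    "option1_sequential": ("v_opt1",),
    "action_space": ("v_contra", "v_ipsi"),
    "goods_space": ("v_chosen", "v_unchosen"),
    "options": ("v_opt1", "v_opt2"),
}


@dataclass
class DesignMatrix:
    """Trial-wise design: constant, standardized value columns, +/-1 choice."""

    X: np.ndarray
    names: list[str]
    standardized: list[str]
    trial_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if "const" not in self.names:
            raise ValueError("design must contain a constant column")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            corr = np.corrcoef(self.X.T + 1e-12 * np.random.default_rng(0).normal(
                size=self.X.T.shape))
            bad = [
                (self.names[i], self.names[j])
                for i in range(len(self.names))
                for j in range(i + 1, len(self.names))
                if abs(corr[i, j]) > 0.9999
            ]
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def _value_columns(trials: pd.DataFrame, wanted, hemisphere: str):
    sv1 = trials["sv1"].to_numpy(dtype=float)
    sv2 = trials["sv2"].to_numpy(dtype=float)
    chose1 = trials["choice"].to_numpy() == 1
    side1 = trials["side1"].to_numpy()
    opt1_contra = side1 == ("right" if hemisphere == "left" else "left")
    cols = {}
    for name in wanted:
        if name == "v_opt1":
            cols[name] = sv1
        elif name == "v_opt2":
            cols[name] = sv2
        elif name == "v_chosen":
            cols[name] = np.where(chose1, sv1, sv2)
        elif name == "v_unchosen":
            cols[name] = np.where(chose1, sv2, sv1)
        elif name == "v_contra":
            cols[name] = np.where(opt1_contra, sv1, sv2)
        elif name == "v_ipsi":
            cols[name] = np.where(opt1_contra, sv2, sv1)
        else:
            raise ValueError(f"unknown value regressor {name!r}")
    return cols, chose1, opt1_contra


def build_design(
    trials: pd.DataFrame,
    model_spec: str,
    trial_selection: str | None = None,
    hemisphere: str = "left",
) -> DesignMatrix:
    """Design matrix for one of the named trial-wise regression models.

    ``trial_selection`` restricts to "harder" or "nobrainer" trials.  The
    choice term is +1 when option 1 was chosen (for the action-space model:
    +1 when the contralateral option was chosen).  Value columns are
    standardized over the selected trials; a rank check names collinear
    columns on failure.
    """
    if model_spec not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {model_spec!r}; one of {list(MODEL_SPECS)}")
    if trial_selection == "harder":
        trials = trials[~trials["nobrainer"].astype(bool)]
    elif trial_selection == "nobrainer":
        trials = trials[trials["nobrainer"].astype(bool)]
    elif trial_selection is not None:
        raise ValueError(f"unknown trial selection {trial_selection!r}")
    wanted = MODEL_SPECS[model_spec]
    cols, chose1, opt1_contra = _value_columns(trials, wanted, hemisphere)
    names = ["const"]
    columns = [np.ones(len(trials))]
    for name in wanted:
        x = cols[name]
        sd = x.std()
        if sd == 0:
            raise ValueError(f"value regressor {name!r} is constant")
        columns.append((x - x.mean()) / sd)
        names.append(name)
    if model_spec == "action_space":
        choice = np.where(chose1 == opt1_contra, 1.0, -1.0)
    else:
        choice = np.where(chose1, 1.0, -1.0)
    columns.append(choice)
    names.append("choice")
    return DesignMatrix(
        X=np.column_stack(columns),
        names=names,
        standardized=list(wanted),
        trial_ids=trials["trial_id"].to_numpy() if "trial_id" in trials else None,
    )


# ---------------------------------------------------------------------------
# mass-univariate OLS
# ---------------------------------------------------------------------------


@dataclass
class EffectMap:
    """Frequency x time map of a variance-normalized effect for one subject."""

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    df: int
    name: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)
        if self.values.shape != (self.freqs.size, self.times_ms.size):
            raise ValueError("map shape inconsistent with axes")

    def __sub__(self, other: "EffectMap") -> "EffectMap":
        if (self.freqs.size != other.freqs.size
                or not np.allclose(self.freqs, other.freqs)
                or not np.allclose(self.times_ms, other.times_ms)):
            raise ValueError("effect maps on mismatched grids")
        return EffectMap(
            values=self.values - other.values,
            freqs=self.freqs,
            times_ms=self.times_ms,
            df=min(self.df, other.df),
            name=f"{self.name}-{other.name}",
            valid=self.valid & other.valid,
        )


class TrialPowerRegression:
    """Mass-univariate OLS of single-trial power on a trial-wise design."""

    def __init__(self, power: TFPower, design: DesignMatrix,
                 trial_mask: np.ndarray | None = None, log_power: bool = False):
        if power.power.shape[0] != design.n_trials:
            raise ValueError("power and design must agree on the trial dimension")
        self.power = power
        self.design = design
        self.log_power = log_power
        if trial_mask is None:
            trial_mask = np.ones(design.n_trials, dtype=bool)
        self.trial_mask = np.asarray(trial_mask, dtype=bool)
        n, k = self.trial_mask.sum(), design.X.shape[1]
        if n < k + 2:
            raise ValueError(f"need at least {k + 2} trials, have {n}")

    def fit(self) -> "TFRegressionResults":
        X = self.design.X[self.trial_mask]
        Y = self.power.power[self.trial_mask]
        if self.log_power:
            Y = np.log(np.maximum(Y, np.finfo(float).tiny))
        n, k = X.shape
        nf, nt = Y.shape[1], Y.shape[2]
        Yf = Y.reshape(n, nf * nt)
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ Yf)  # k x bins
        resid = Yf - X @ beta
        df = n - k
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        return TFRegressionResults(
            beta=beta.reshape(k, nf, nt),
            sigma2=sigma2.reshape(nf, nt),
            xtx_inv=xtx_inv,
            df=df,
            names=list(self.design.names),
            power=self.power,
        )


@dataclass
class TFRegressionResults:
    """OLS estimates at every (frequency, time) bin of one subject."""

    beta: np.ndarray           # k x F x T
    sigma2: np.ndarray         # F x T
    xtx_inv: np.ndarray        # k x k
    df: int
    names: list[str]
    power: TFPower

    def effect_map(self, name: str, kind: str = "t") -> EffectMap:
        """Variance-normalized effect of one regressor.

        ``kind="t"`` gives beta_hat / SE (the default per-subject summary);
        ``kind="beta_over_var"`` divides by the squared SE instead.
        """
        j = self.names.index(name)
        se2 = self.sigma2 * self.xtx_inv[j, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            if kind == "t":
                vals = self.beta[j] / np.sqrt(se2)
            elif kind == "beta_over_var":
                vals = self.beta[j] / se2
            else:
                raise ValueError(f"unknown kind {kind!r}")
        vals = np.where(se2 > 0, vals, 0.0)
        return EffectMap(
            values=vals, freqs=self.power.freqs, times_ms=self.power.times_ms,
            df=self.df, name=name, valid=self.power.valid.copy(),
        )

    def contrast(self, weights: dict[str, float], name: str | None = None,
                 kind: str = "t") -> EffectMap:
        """Contrast of coefficients with SE propagated via the design Gram matrix."""
        w = np.zeros(len(self.names))
        for key, val in weights.items():
            w[self.names.index(key)] = val
        c = np.tensordot(w, self.beta, axes=(0, 0))
        se2 = self.sigma2 * float(w @ self.xtx_inv @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = c / np.sqrt(se2) if kind == "t" else c / se2
        vals = np.where(se2 > 0, vals, 0.0)
        label = name or "+".join(f"{v:+g}*{k}" for k, v in weights.items())
        return EffectMap(
            values=vals, freqs=self.power.freqs, times_ms=self.power.times_ms,
            df=self.df, name=label, valid=self.power.valid.copy(),
        )


def regress_power(power: TFPower, design: DesignMatrix,
                  trial_mask: np.ndarray | None = None) -> dict[str, EffectMap]:
    """Effect map per regressor (convenience over :class:`TrialPowerRegression`)."""
    res = TrialPowerRegression(power, design, trial_mask=trial_mask).fit()
    return {name: res.effect_map(name) for name in res.names}


def contrast(results: TFRegressionResults, weights: dict[str, float],
             name: str | None = None) -> EffectMap:
    """Module-level alias for :meth:`TFRegressionResults.contrast`."""
    return results.contrast(weights, name=name)


def hemispheric_difference(contra: EffectMap, ipsi: EffectMap) -> EffectMap:
    """Contralateral-minus-ipsilateral difference map (one subject's summary)."""
    out = contra - ipsi
    out.name = f"{contra.name}_hemidiff"
    return out
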