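"""Peak-latency extraction and formal contrasts of effect timing and size.

Per subject, the peak of a named effect is the signed extremum of the
variance-normalized effect map within a frequency band and time window
(e.g. the most negative beta-band value effect 0-1000 ms after the second
option).  Latencies are compared across effects with a paired T-test, and
the region-by-trial-type organisation of peak effect sizes is tested with a
2x2 repeated-measures interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tfr import EffectMap

__all__ = [
    "PeakRecord",
    "PairedTestResult",
    "peak_latency",
    "paired_latency_test",
    "interaction_2x2",
]


@dataclass
class PeakRecord:
    """Signed peak of one effect for one subject."""

    subject: str
    effect: str
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    latency_ms: float
    peak_value: float
    sign: int
    freq_hz: float


@dataclass
class PairedTestResult:
    """Paired T-test on per-subject differences (latencies or peak sizes)."""

    differences: np.ndarray
    t: float
    df: int
    p: float
    median: float
    degenerate: bool = False

    def summary(self) -> str:
        flag = "  [zero-variance differences]" if self.degenerate else ""
        return (f"paired T({self.df}) = {self.t:.3f}, p = {self.p:.4f}, "
                f"median difference = {self.median:.1f}{flag}")


def peak_latency(
    effect: EffectMap,
    band_hz: tuple[float, float],
    window_ms: tuple[float, float],
    sign: int,
    subject: str = "",
) -> PeakRecord:
    """Extremum of the expected sign within band x window.

    ``sign=+1`` takes the maximum, ``sign=-1`` the minimum.  Edge-flagged
    bins are excluded.  Ties are broken deterministically: earliest time,
    then lowest frequency.
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    fmask = (effect.freqs >= band_hz[0]) & (effect.freqs <= band_hz[1])
    tmask = (effect.times_ms >= window_ms[0]) & (effect.times_ms <= window_ms[1])
    region = np.ix_(np.flatnonzero(fmask), np.flatnonzero(tmask))
    vals = effect.values[region]
    ok = effect.valid[region]
    if not ok.any():
        raise ValueError("empty search region (band/window outside map or all edge)")
    signed = sign * np.where(ok, vals, -np.inf)
    best = signed.max()
    cand = np.argwhere(signed == best)  # rows (freq, time) within region
    order = np.lexsort((cand[:, 0], cand[:, 1]))  # time first, then frequency
    fi, ti = cand[order[0]]
    f_idx = np.flatnonzero(fmask)[fi]
    t_idx = np.flatnonzero(tmask)[ti]
    return PeakRecord(
        subject=subject,
        effect=effect.name,
        band_hz=band_hz,
        window_ms=window_ms,
        latency_ms=float(effect.times_ms[t_idx]),
        peak_value=float(effect.values[f_idx, t_idx]),
        sign=sign,
        freq_hz=float(effect.freqs[f_idx]),
    )


def _paired(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
        return PairedTestResult(
            differences=d, t=float(t), df=n - 1,
            p=1.0 if t == 0 else 0.0, median=float(np.median(d)), degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(
        differences=d, t=float(t), df=n - 1, p=float(p), median=float(np.median(d)),
    )


def paired_latency_test(peaks_a: list[PeakRecord], peaks_b: list[PeakRecord]) -> PairedTestResult:
    """Paired T on per-subject latency differences (A minus B), plus the median."""
    subj_a = [p.subject for p in peaks_a]
    subj_b = [p.subject for p in peaks_b]
    if subj_a != subj_b:
        raise ValueError("mismatched subject sets")
    return _paired([p.latency_ms for p in peaks_a], [p.latency_ms for p in peaks_b])


def interaction_2x2(table: np.ndarray, tail: str = "two-sided") -> dict:
    """Region x condition repeated-measures interaction on peak effect sizes.

    ``table`` is subjects x 2 regions x 2 conditions.  The interaction is the
    one-sample test of the within-subject double difference
    d = (A1 - A2) - (B1 - B2); its F(1, n-1) equals the squared paired T on
    d.  Post-hoc paired T-tests compare the two conditions within each
    region (``tail`` applies to the post-hoc tests).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3 or table.shape[1:] != (2, 2):
        raise ValueError("table must be subjects x 2 x 2")
    if not np.all(np.isfinite(table)):
        raise ValueError("missing cells in the 2x2 table")
    n = table.shape[0]
    d = (table[:, 0, 0] - table[:, 0, 1]) - (table[:, 1, 0] - table[:, 1, 1])
    base = _paired(d, np.zeros(n))
    f = base.t**2
    p = stats.f.sf(f, 1, n - 1) if np.isfinite(f) else 0.0
    post = {}
    for r, label in enumerate(("region_a", "region_b")):
        res = _paired(table[:, r, 0], table[:, r, 1])
        if tail == "one-sided":
            res.p = res.p / 2 if res.t > 0 else 1 - res.p / 2
        post[label] = res
    return {
        "F": float(f),
        "df": (1, n - 1),
        "p": float(p),
        "double_difference_t": base,
        "post_hoc": post,
        "tail": tail,
    }
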