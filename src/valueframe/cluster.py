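"""Group-level inference: one-sample T-maps and sign-flip cluster permutation.

The per-subject inputs are variance-normalized effect maps (one frequency x
time map per subject).  Under the null hypothesis of zero group mean each
subject's map is symmetric around zero, so the group design can be randomly
sign-flipped: each permutation multiplies every subject's whole map by an
independent +/-1, the one-sample T-map is recomputed, and the maximum extent
of any supra-threshold cluster is recorded.  Comparing the observed cluster
extents to this null distribution yields p-values corrected for multiple
comparisons across the whole time-frequency plane.

The default family is two-sided: clusters are formed where |T| exceeds the
cluster-forming threshold and compared against the null of the maximum
|T|-cluster extent, which controls the family-wise error at the nominal
alpha while detecting synchronisation (positive) and desynchronisation
(negative) effects alike.  One-tailed families per sign are available via
``ClusterConfig(tail=...)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tfr import EffectMap

__all__ = [
    "GroupStack",
    "ClusterConfig",
    "Cluster",
    "ClusterResult",
    "group_tmap",
    "extract_clusters",
    "signflip_null",
    "corrected_p",
    "cluster_permutation_test",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class GroupStack:
    """Per-subject effect maps stacked subjects x frequencies x time."""

    data: np.ndarray
    freqs: np.ndarray | None = None
    times_ms: np.ndarray | None = None
    valid: np.ndarray | None = None
    df_subject: int | None = None

    @classmethod
    def from_effect_maps(cls, maps: list[EffectMap]) -> "GroupStack":
        ref = maps[0]
        for m in maps[1:]:
            if not (np.allclose(m.freqs, ref.freqs) and np.allclose(m.times_ms, ref.times_ms)):
                raise ValueError("effect maps on mismatched grids")
        valid = np.logical_and.reduce([m.valid for m in maps])
        return cls(
            data=np.stack([m.values for m in maps]),
            freqs=ref.freqs, times_ms=ref.times_ms, valid=valid,
            df_subject=ref.df,
        )

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("need >= 2 subjects of 2-D maps")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1:], dtype=bool)
        if not np.all(np.isfinite(self.data[:, self.valid])):
            raise ValueError("non-finite values inside the valid region")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ClusterConfig:
    """Settings for the cluster permutation test.

    ``tail``: "both" (default; clusters of |T|, single two-sided family),
    "pos" or "neg" (one-tailed family of that sign), or "both_onetailed"
    (two separate one-tailed families, each against its own signed null).
    ``statistic``: cluster "extent" (bin count) or "mass" (summed |T|).
    """

    threshold: float = 2.0
    n_permutations: int = 5000
    connectivity: int = 4
    tail: str = "both"
    alpha: float = 0.05
    statistic: str = "extent"
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.tail not in ("both", "pos", "neg", "both_onetailed"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.statistic not in ("extent", "mass"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class Cluster:
    """One contiguous supra-threshold region of the time-frequency plane."""

    bins: np.ndarray          # (m, 2) array of (freq_idx, time_idx)
    extent: int
    mass: float
    sign: int
    peak_t: float
    peak_freq_idx: int
    peak_time_idx: int
    p: float | None = None


@dataclass
class ClusterResult:
    """Observed clusters with permutation-corrected p-values."""

    clusters: list[Cluster]
    null_max: dict[str, np.ndarray]
    tmap: np.ndarray
    df: int
    config: ClusterConfig

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < self.config.alpha]

    def summary(self) -> str:
        lines = [f"cluster permutation test (df={self.df}, "
                 f"threshold={self.config.threshold}, "
                 f"{self.config.n_permutations} permutations, tail={self.config.tail})"]
        if not self.clusters:
            lines.append("  no supra-threshold clusters")
        for c in sorted(self.clusters, key=lambda c: c.p):
            star = " *" if c.p < self.config.alpha else ""
            lines.append(
                f"  sign {c.sign:+d}  extent {c.extent:4d}  peak T {c.peak_t:+.2f}"
                f"  p = {c.p:.4f}{star}"
            )
        return "\n".join(lines)


def group_tmap(stack: GroupStack):
    """One-sample T against zero per bin; df = n_subjects - 1.

    Bins with zero between-subject variance get +/-inf (flagged, not raised).
    """
    x = stack.data
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    return t, n - 1


def _cluster_stat(extent, mass, statistic):
    return extent if statistic == "extent" else mass


def extract_clusters(tmap: np.ndarray, cfg: ClusterConfig,
                     valid: np.ndarray | None = None) -> list[Cluster]:
    """Connected components of supra-threshold bins under the adjacency rule."""
    if valid is None:
        valid = np.ones_like(tmap, dtype=bool)
    structure = _STRUCTURES[cfg.connectivity]
    out: list[Cluster] = []

    def _components(mask, sign):
        labels, n = ndimage.label(mask & valid, structure=structure)
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            vals = tmap[idx[:, 0], idx[:, 1]]
            k = int(np.argmax(np.abs(vals)))
            out.append(Cluster(
                bins=idx, extent=idx.shape[0], mass=float(np.abs(vals).sum()),
                sign=sign, peak_t=float(vals[k]),
                peak_freq_idx=int(idx[k, 0]), peak_time_idx=int(idx[k, 1]),
            ))

    if cfg.tail == "both":
        # |T| clusters, but split sign by the peak so reporting stays signed
        _components(tmap > cfg.threshold, +1)
        _components(tmap < -cfg.threshold, -1)
    elif cfg.tail in ("pos",):
        _components(tmap > cfg.threshold, +1)
    elif cfg.tail in ("neg",):
        _components(tmap < -cfg.threshold, -1)
    else:  # both_onetailed
        _components(tmap > cfg.threshold, +1)
        _components(tmap < -cfg.threshold, -1)
    return out


def _max_cluster_stats(tmap, cfg, valid):
    """Max supra-threshold cluster statistic of one map, per family."""
    structure = _STRUCTURES[cfg.connectivity]

    def _max_of(mask):
        labels, n = ndimage.label(mask & valid, structure=structure)
        if n == 0:
            return 0.0
        if cfg.statistic == "extent":
            return float(np.max(np.bincount(labels.ravel())[1:]))
        sums = ndimage.sum_labels(np.abs(tmap), labels, index=np.arange(1, n + 1))
        return float(np.max(sums))

    if cfg.tail == "both":
        return {"both": _max_of(np.abs(tmap) > cfg.threshold)}
    if cfg.tail == "pos":
        return {"pos": _max_of(tmap > cfg.threshold)}
    if cfg.tail == "neg":
        return {"neg": _max_of(tmap < -cfg.threshold)}
    return {"pos": _max_of(tmap > cfg.threshold),
            "neg": _max_of(tmap < -cfg.threshold)}


def _flip_tmaps(stack: GroupStack, flips: np.ndarray) -> np.ndarray:
    """T-maps for many sign-flip assignments at once.

    Sign flips leave each subject's squared values unchanged, so the
    second moment is computed once and only the flipped means vary.
    """
    x = stack.data.reshape(stack.n_subjects, -1)
    n = stack.n_subjects
    sumsq = np.sum(x**2, axis=0)  # invariant under sign flips
    means = (flips @ x) / n
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return t.reshape(flips.shape[0], *stack.data.shape[1:])


def signflip_null(stack: GroupStack, cfg: ClusterConfig,
                  exhaustive: bool | None = None) -> dict[str, np.ndarray]:
    """Null distribution of the maximum cluster statistic under sign flips.

    Monte-Carlo by default (independent fair +/-1 per subject per
    permutation, seeded); for n <= 12 subjects ``exhaustive=True`` (or
    ``None`` with n_permutations >= 2**n) enumerates all 2**n assignments.
    """
    n = stack.n_subjects
    if exhaustive is None:
        exhaustive = n <= 12 and cfg.n_permutations >= 2**n
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration is limited to n <= 20")
        flips = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        rng = np.random.default_rng(cfg.seed)
        flips = rng.choice([1.0, -1.0], size=(cfg.n_permutations, n))
    valid = stack.valid
    keys = _max_cluster_stats(np.zeros_like(stack.data[0]), cfg, valid).keys()
    null = {k: np.empty(flips.shape[0]) for k in keys}
    chunk = max(1, int(2e7 // stack.data[0].size))
    for a in range(0, flips.shape[0], chunk):
        tmaps = _flip_tmaps(stack, flips[a : a + chunk])
        for j in range(tmaps.shape[0]):
            stats = _max_cluster_stats(tmaps[j], cfg, valid)
            for k, v in stats.items():
                null[k][a + j] = v
    return null


def corrected_p(clusters: list[Cluster], null: dict[str, np.ndarray],
                cfg: ClusterConfig) -> list[Cluster]:
    """Permutation-corrected p per cluster: (1 + #{null >= obs}) / (1 + n_perm).

    The +1 counts the observed data among the permutations, so p is never 0.
    """
    for c in clusters:
        key = ("both" if cfg.tail == "both"
               else "pos" if c.sign > 0 else "neg")
        dist = null[key]
        obs = _cluster_stat(c.extent, c.mass, cfg.statistic)
        c.p = float((1 + np.sum(dist >= obs)) / (1 + dist.size))
    return clusters


def cluster_permutation_test(stack: GroupStack,
                             cfg: ClusterConfig = ClusterConfig(),
                             exhaustive: bool | None = None) -> ClusterResult:
    """Full test: group T-map, observed clusters, sign-flip null, corrected p."""
    tmap, df = group_tmap(stack)
    clusters = extract_clusters(tmap, cfg, valid=stack.valid)
    null = signflip_null(stack, cfg, exhaustive=exhaustive)
    clusters = corrected_p(clusters, null, cfg)
    return ClusterResult(clusters=clusters, null_max=null, tmap=tmap, df=df, config=cfg)
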