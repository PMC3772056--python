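"""Behavioural choice models for two-option risky gambles.

Implements a three-parameter Prospect-theory model (magnitude curvature
``alpha``, probability weighting ``gamma``, softmax inverse temperature
``beta``) fitted per subject by maximum likelihood, a one-parameter
objective-expected-value baseline, BIC model comparison, and a logistic
regression of choice on attribute differences with group-level tests.

The modelling surface follows the statsmodels convention: a model object is
built from a trial table, ``fit()`` returns a results object carrying the
estimates, likelihood, BIC and convergence diagnostics, and ``summary()``
renders a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_softmax
import statsmodels.api as sm

__all__ = [
    "ProspectParams",
    "subjective_value",
    "choice_probability",
    "negative_log_likelihood",
    "ProspectModel",
    "ObjectiveEVModel",
    "ProspectResults",
    "fit_prospect",
    "compare_bic",
    "logistic_choice_analysis",
    "LogisticChoiceModel",
]

#: probability floor inside the log-likelihood
_P_FLOOR = 1e-10

#: default box bounds for the maximum-likelihood fit
DEFAULT_BOUNDS = {"alpha": (0.05, 3.0), "gamma": (0.05, 3.0), "beta": (0.0, 50.0)}


@dataclass(frozen=True)
class ProspectParams:
    """Subject-level Prospect-theory parameters.

    alpha
        Curvature of the utility of reward magnitude, u(r) = r**alpha.
    gamma
        Probability-weighting parameter.
    beta
        Softmax inverse temperature (1/tau); beta = 0 is random choice.
    weighting
        ``"tk1992"`` for w(p) = p**g / (p**g + (1-p)**g)**(1/g)
        or ``"power"`` for w(p) = p**g.
    """

    alpha: float = 1.0
    gamma: float = 1.0
    beta: float = 1.0
    weighting: str = "tk1992"

    def __post_init__(self):
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.weighting not in ("tk1992", "power"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


def _weight_probability(p, gamma, weighting="tk1992"):
    p = np.asarray(p, dtype=float)
    if weighting == "power":
        return p**gamma
    num = p**gamma
    return num / (num + (1.0 - p) ** gamma) ** (1.0 / gamma)


def subjective_value(p, r, params: ProspectParams):
    """Subjective expected value w(p; gamma) * u(r; alpha) of a single prospect.

    With alpha = gamma = 1 this reduces to the objective expected value p*r.
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if np.any(r <= 0):
        raise ValueError("reward magnitudes must be positive")
    return _weight_probability(p, params.gamma, params.weighting) * r**params.alpha


def choice_probability(values, beta):
    """Softmax choice probabilities over a pair (or array) of subjective values.

    Computed through a log-softmax so that large beta*value products cannot
    overflow; the probabilities sum to one exactly.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    v = np.asarray(values, dtype=float)
    return np.exp(log_softmax(beta * v, axis=-1))


def _trial_arrays(trials: pd.DataFrame):
    cols = ("p1", "m1", "p2", "m2", "choice")
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    return (trials[c].to_numpy(dtype=float) for c in cols)


def negative_log_likelihood(trials: pd.DataFrame, params: ProspectParams):
    """NLL of the recorded choices under a Prospect/softmax agent.

    ``choice`` is 1 when option 1 was chosen, 2 otherwise.  Probabilities are
    floored at 1e-10 so the result is always finite.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    p1, m1, p2, m2, choice = _trial_arrays(trials)
    v = np.stack(
        [subjective_value(p1, m1, params), subjective_value(p2, m2, params)], axis=-1
    )
    probs = choice_probability(v, params.beta)
    chosen = np.where(choice == 1, probs[:, 0], probs[:, 1])
    return -float(np.sum(np.log(np.maximum(chosen, _P_FLOOR))))


@dataclass
class ProspectResults:
    """Maximum-likelihood fit of a behavioural choice model."""

    params: ProspectParams
    nll: float
    n_trials: int
    k_params: int
    converged: bool
    n_restarts: int
    restart_nlls: np.ndarray = field(repr=False, default=None)
    model_name: str = "prospect"

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n_trials) + 2.0 * self.nll

    def summary(self) -> str:
        lines = [
            f"{self.model_name} choice model ({self.k_params} free parameters)",
            f"  n_trials   {self.n_trials}",
            f"  alpha      {self.params.alpha:.4f}",
            f"  gamma      {self.params.gamma:.4f}",
            f"  beta       {self.params.beta:.4f}",
            f"  NLL        {self.nll:.4f}",
            f"  BIC        {self.bic:.4f}",
            f"  converged  {self.converged} ({self.n_restarts} restarts)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "alpha": self.params.alpha,
            "gamma": self.params.gamma,
            "beta": self.params.beta,
            "nll": self.nll,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "converged": self.converged,
        }


class ProspectModel:
    """Three-parameter Prospect-theory/softmax model of one subject's choices.

    The likelihood is multimodal in (gamma, beta); ``fit`` therefore runs a
    bounded quasi-Newton optimiser from several random starting points and
    keeps the best minimum.

    Parameters
    ----------
    trials
        Trial table with columns p1, m1, p2, m2, choice (1 or 2); optionally
        restricted to one trial type beforehand.
    weighting
        Probability-weighting form, ``"tk1992"`` (default) or ``"power"``.
    bounds
        Box bounds per parameter; defaults to alpha, gamma in [0.05, 3] and
        beta in [0, 50].
    """

    k_params = 3
    model_name = "prospect"

    def __init__(self, trials: pd.DataFrame, weighting: str = "tk1992", bounds=None):
        if len(trials) == 0:
            raise ValueError("empty trial list")
        self.trials = trials.reset_index(drop=True)
        self.weighting = weighting
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self._p1, self._m1, self._p2, self._m2, self._choice = (
            np.asarray(a) for a in _trial_arrays(self.trials)
        )
        self._chose1 = self._choice == 1

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, trial_type: str | None = None, **kw):
        if trial_type is not None:
            trials = trials[trials["trial_type"] == trial_type]
        return cls(trials, **kw)

    # vectorised objective --------------------------------------------------
    def _nll(self, theta) -> float:
        alpha, gamma, beta = theta
        u1 = self._m1**alpha
        u2 = self._m2**alpha
        w1 = _weight_probability(self._p1, gamma, self.weighting)
        w2 = _weight_probability(self._p2, gamma, self.weighting)
        v = np.stack([w1 * u1, w2 * u2], axis=-1)
        logp = log_softmax(beta * v, axis=-1)
        chosen = np.where(self._chose1, logp[:, 0], logp[:, 1])
        chosen = np.maximum(chosen, np.log(_P_FLOOR))
        return -float(np.sum(chosen))

    def fit(self, n_restarts: int = 10, seed: int | None = 0) -> ProspectResults:
        rng = np.random.default_rng(seed)
        lo = np.array([self.bounds[k][0] for k in ("alpha", "gamma", "beta")])
        hi = np.array([self.bounds[k][1] for k in ("alpha", "gamma", "beta")])
        # cap the beta starting range: huge beta starts sit on a flat plateau
        hi_start = np.minimum(hi, [3.0, 3.0, 10.0])
        starts = [np.array([1.0, 1.0, 1.0])]
        starts += [rng.uniform(lo, hi_start) for _ in range(max(n_restarts - 1, 0))]
        best, restart_nlls = None, []
        for x0 in starts:
            res = optimize.minimize(
                self._nll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            restart_nlls.append(res.fun)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"all {len(starts)} restarts failed: {restart_nlls}")
        params = ProspectParams(*best.x, weighting=self.weighting)
        return ProspectResults(
            params=params,
            nll=float(best.fun),
            n_trials=len(self.trials),
            k_params=self.k_params,
            converged=bool(best.success),
            n_restarts=len(starts),
            restart_nlls=np.asarray(restart_nlls),
            model_name=self.model_name,
        )


class ObjectiveEVModel(ProspectModel):
    """One-parameter baseline: softmax on objective expected value p*r."""

    k_params = 1
    model_name = "objective_ev"

    def _nll(self, theta) -> float:
        (beta,) = np.atleast_1d(theta)
        v = np.stack([self._p1 * self._m1, self._p2 * self._m2], axis=-1)
        logp = log_softmax(beta * v, axis=-1)
        chosen = np.where(self._chose1, logp[:, 0], logp[:, 1])
        return -float(np.sum(np.maximum(chosen, np.log(_P_FLOOR))))

    def fit(self, n_restarts: int = 5, seed: int | None = 0) -> ProspectResults:
        rng = np.random.default_rng(seed)
        lo, hi = self.bounds["beta"]
        starts = [0.1] + list(rng.uniform(lo, min(hi, 5.0), max(n_restarts - 1, 0)))
        best, restart_nlls = None, []
        for x0 in starts:
            res = optimize.minimize(
                self._nll, [x0], method="L-BFGS-B", bounds=[(lo, hi)]
            )
            restart_nlls.append(res.fun)
            if best is None or res.fun < best.fun:
                best = res
        params = ProspectParams(1.0, 1.0, float(best.x[0]))
        return ProspectResults(
            params=params,
            nll=float(best.fun),
            n_trials=len(self.trials),
            k_params=self.k_params,
            converged=bool(best.success),
            n_restarts=len(starts),
            restart_nlls=np.asarray(restart_nlls),
            model_name=self.model_name,
        )


def fit_prospect(trials, n_restarts: int = 10, seed: int | None = 0, **kw):
    """Convenience wrapper: ``ProspectModel(trials).fit(...)``."""
    return ProspectModel(trials, **kw).fit(n_restarts=n_restarts, seed=seed)


def compare_bic(trials, n_restarts: int = 10, seed: int | None = 0) -> dict:
    """Fit Prospect and objective-EV models on the same trials and compare BIC.

    Returns a record with both fits and ``delta_bic`` = BIC(prospect) -
    BIC(objective EV); negative values favour Prospect.
    """
    prospect = ProspectModel(trials).fit(n_restarts=n_restarts, seed=seed)
    baseline = ObjectiveEVModel(trials).fit(seed=seed)
    return {
        "prospect": prospect,
        "objective_ev": baseline,
        "delta_bic": prospect.bic - baseline.bic,
        "preferred": "prospect" if prospect.bic < baseline.bic else "objective_ev",
    }


# ---------------------------------------------------------------------------
# logistic regression of choice on attribute differences
# ---------------------------------------------------------------------------

#: coefficient magnitude above which a subject is flagged as separated
_SEPARATION_CAP = 10.0


def _standardize(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant regressor cannot be standardized")
    return (x - x.mean()) / sd


class LogisticChoiceModel:
    """Per-subject logistic regression of choosing option 1.

    Explanatory variables are the attribute differences p1-p2, r1-r2 and the
    objective expected-value difference EV1-EV2, each standardized within
    subject, plus a constant capturing any overall bias.
    """

    regressor_names = ("const", "dp", "dr", "dev")

    def __init__(self, trials: pd.DataFrame):
        self.trials = trials.reset_index(drop=True)
        p1, m1, p2, m2, choice = (np.asarray(a) for a in _trial_arrays(self.trials))
        X = np.column_stack(
            [
                np.ones(len(self.trials)),
                _standardize(p1 - p2),
                _standardize(m1 - m2),
                _standardize(p1 * m1 - p2 * m2),
            ]
        )
        self.exog = X
        self.endog = (choice == 1).astype(float)

    def fit(self):
        """Maximum-likelihood logistic fit; flags and caps perfect separation."""
        model = sm.Logit(self.endog, self.exog)
        separated = False
        try:
            with np.errstate(all="ignore"):
                res = model.fit(disp=False, maxiter=200)
            coefs = np.asarray(res.params)
        except Exception:  # statsmodels raises on perfect separation
            separated = True
            with np.errstate(all="ignore"):
                res = model.fit_regularized(alpha=1e-3, disp=False)
            coefs = np.asarray(res.params)
        if np.any(np.abs(coefs) > _SEPARATION_CAP):
            separated = True
            coefs = np.clip(coefs, -_SEPARATION_CAP, _SEPARATION_CAP)
        return {
            "coefs": dict(zip(self.regressor_names, coefs)),
            "separated": separated,
        }


def logistic_choice_analysis(sessions: dict[str, pd.DataFrame]) -> dict:
    """Group logistic-regression analysis over subjects.

    Parameters
    ----------
    sessions
        Mapping subject id -> trial table containing both trial types
        (column ``trial_type`` in {"comparison", "sequential"}).

    Returns
    -------
    dict with per-subject coefficient tables, a one-sample T-test per
    coefficient per trial type, and a paired T-test between trial types.
    """
    trial_types = ("comparison", "sequential")
    names = LogisticChoiceModel.regressor_names
    coefs = {tt: [] for tt in trial_types}
    flags = {tt: [] for tt in trial_types}
    for sid in sorted(sessions):
        trials = sessions[sid]
        for tt in trial_types:
            sub = trials[trials["trial_type"] == tt]
            fit = LogisticChoiceModel(sub).fit()
            coefs[tt].append([fit["coefs"][n] for n in names])
            flags[tt].append(fit["separated"])
    tables = {tt: pd.DataFrame(coefs[tt], columns=names) for tt in trial_types}
    one_sample = {
        tt: {
            n: stats.ttest_1samp(tables[tt][n], 0.0)._asdict() for n in names
        }
        for tt in trial_types
    }
    paired = {
        n: stats.ttest_rel(tables["comparison"][n], tables["sequential"][n])._asdict()
        for n in names
    }
    return {
        "coefficients": tables,
        "separated": flags,
        "one_sample_t": one_sample,
        "paired_t": paired,
    }
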