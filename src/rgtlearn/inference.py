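"""Hierarchical Bayesian estimation of the RL models, with diagnostics.

Subjects within a task group are partially pooled: each subject's
parameter vector on the unconstrained scale is ``mu + sigma * z`` with
standard-normal ``z`` (noncentered parameterization), group means
``mu ~ Normal(0, 1)`` (``Normal(0, 2)`` for the offset b), and group SDs
``sigma ~ half-Normal(0, 1)``.  Constraint transforms: learning rates
through the standard-normal CDF, positive parameters (beta, m, r, mRew)
through exp, the offset b identity.

Sampling uses the gradient-based HMC backend in :mod:`rgtlearn.sampler`.
If any split-R-hat exceeds the threshold the warmup is doubled (up to a
cap) and the fit re-run.  A fast multi-start maximum-likelihood path is
provided for desk-scale work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from . import sampler
from ._kernels import (
    MODEL_CODES,
    MODEL_K,
    MODEL_PARAM_NAMES,
    MODEL_TRANSFORMS,
    _hier_logp_grad_mixed,
    _pointwise_matrix,
    _subject_ll_grad,
)
from .models import MODEL_PARAMS, RLParams, trials_to_arrays

__all__ = [
    "MCMCConfig",
    "DESK_MCMC",
    "PosteriorFit",
    "WAICResult",
    "MLEResult",
    "fit_hierarchical",
    "fit_mle",
    "rhat",
    "waic",
    "waic_difference",
    "HierarchicalRLModel",
    "MLERLModel",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    Defaults mirror the full-scale analysis (four chains of 1000 draws
    after 1000 warmup iterations, warmup escalated to at most 5000 when
    R-hat exceeds 1.01); ``DESK_MCMC`` is a light preset for desk-scale
    cohorts.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    warmup_cap: int = 5000
    n_samples: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    target_accept: float = 0.8
    max_leapfrog: int = 48
    dense_mass: bool = True
    parameterization: str = "auto"
    max_divergence_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_samples", "warmup_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must be > 1")
        if self.parameterization not in ("auto", "centered", "noncentered"):
            raise ValueError(
                "parameterization must be 'auto', 'centered' or 'noncentered'"
            )


#: desk-scale preset: 2 chains x 500 draws
DESK_MCMC = MCMCConfig(n_chains=2, n_warmup=500, warmup_cap=2000, n_samples=500)


def _transform(u: np.ndarray, tcode: int) -> np.ndarray:
    if tcode == 0:
        return np.exp(u)
    if tcode == 1:
        return ndtr(u)
    return u


def _default_mu_init(model_id: str) -> np.ndarray:
    """Weakly sensible unconstrained group-mean start values."""
    start = {"beta": 0.0, "eta_plus": -0.84, "eta_minus": -0.84,
             "m": np.log(0.1), "b": 0.0, "r": np.log(0.5), "m_rew": 0.0}
    return np.array([start[n] for n in MODEL_PARAMS[model_id]])


@dataclass
class PosteriorFit:
    """Posterior samples and diagnostics from one hierarchical fit."""

    model_id: str
    param_names: tuple
    subject_ids: list
    mu: np.ndarray  # (n_chains, n_draws, K), unconstrained group means
    log_sigma: np.ndarray  # (n_chains, n_draws, K)
    z: np.ndarray  # (n_chains, n_draws, S, K)
    diagnostics: Dict[str, float]
    config: MCMCConfig
    n_warmup_used: int
    divergence_rate: float
    _data: tuple = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_points(self) -> int:
        return len(self._data[1])

    def _tcodes(self) -> np.ndarray:
        code = MODEL_CODES[self.model_id]
        return MODEL_TRANSFORMS[code, : len(self.param_names)]

    def group_mean_samples(self, parameter: str, constrained: bool = True) -> np.ndarray:
        """Flattened posterior samples of the group mean of one parameter."""
        k = self.param_names.index(parameter)
        u = self.mu[:, :, k].ravel()
        return _transform(u, int(self._tcodes()[k])) if constrained else u

    def subject_samples(self, constrained: bool = True) -> np.ndarray:
        """Subject-level parameter samples, shape (n_total_draws, S, K)."""
        nc, nd, S, K = self.z.shape
        u = self.mu[:, :, None, :] + np.exp(self.log_sigma)[:, :, None, :] * self.z
        u = u.reshape(nc * nd, S, K)
        if not constrained:
            return u
        out = np.empty_like(u)
        for k, tc in enumerate(self._tcodes()):
            out[:, :, k] = _transform(u[:, :, k], int(tc))
        return out

    def subject_posterior_means(self, estimator: str = "mean") -> pd.DataFrame:
        """Per-subject point estimates on the constrained scale."""
        s = self.subject_samples(constrained=True)
        agg = np.mean(s, axis=0) if estimator == "mean" else np.median(s, axis=0)
        return pd.DataFrame(agg, index=self.subject_ids, columns=list(self.param_names))

    def subject_rlparams(self, estimator: str = "mean") -> List[RLParams]:
        df = self.subject_posterior_means(estimator=estimator)
        return [
            RLParams.from_vector(self.model_id, row.to_numpy())
            for _, row in df.iterrows()
        ]

    def pointwise_loglik(self, thin: int = 1) -> np.ndarray:
        """(n_draws_used, n_trials) pointwise log-likelihood matrix."""
        offsets, choices, is_win, rewards, penalties = self._data
        cdraws = np.ascontiguousarray(self.subject_samples(constrained=True)[::thin])
        code = MODEL_CODES[self.model_id]
        return _pointwise_matrix(
            cdraws, code, len(self.subject_ids), offsets,
            choices, is_win, rewards, penalties,
        )

    def to_inference_data(self):
        """Export to an arviz InferenceData (NetCDF-serializable)."""
        import arviz as az

        post = {
            f"mu_{n}": self.mu[:, :, k] for k, n in enumerate(self.param_names)
        }
        post.update(
            {f"sigma_{n}": np.exp(self.log_sigma[:, :, k]) for k, n in enumerate(self.param_names)}
        )
        for k, n in enumerate(self.param_names):
            post[f"z_{n}"] = self.z[:, :, :, k]
        return az.from_dict(posterior=post)


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in
    half; R-hat compares between- to within-chain variance.  Returns NaN
    (with a warning) when the within-chain variance is zero.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >=2 chains with >=4 draws each")
    n_half = chains.shape[1] // 2
    split = np.concatenate(
        [chains[:, :n_half], chains[:, n_half : 2 * n_half]], axis=0
    )
    w = split.var(axis=1, ddof=1).mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", RuntimeWarning)
        return float("nan")
    b_over_n = split.mean(axis=1).var(ddof=1)
    var_plus = (n_half - 1) / n_half * w + b_over_n
    return float(np.sqrt(var_plus / w))


@dataclass
class WAICResult:
    """Watanabe-Akaike information criterion on the -2*elpd scale."""

    elpd: float
    p_waic: float
    waic: float
    se: float
    n_points: int
    pointwise: np.ndarray = field(repr=False, default=None)  # -2*elpd_i


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from a (n_samples, n_points) pointwise log-likelihood matrix.

    elpd_i = log mean_s exp(ll_si) - var_s(ll_si); waic = -2 sum elpd_i;
    se = sqrt(n * var_i(-2 elpd_i)).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >=2 posterior samples")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    n_s, n_i = ll.shape
    m = ll.max(axis=0)
    lppd_i = m + np.log(np.mean(np.exp(ll - m), axis=0))
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    pointwise = -2.0 * elpd_i
    se = float(np.sqrt(n_i * pointwise.var(ddof=1))) if n_i > 1 else 0.0
    return WAICResult(
        elpd=float(elpd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(pointwise.sum()),
        se=se,
        n_points=n_i,
        pointwise=pointwise,
    )


def waic_difference(fit_model, fit_reference) -> tuple[float, float]:
    """Paired WAIC difference (reference - model) with its pointwise SEM.

    Accepts :class:`PosteriorFit` or :class:`WAICResult` arguments fit to
    the same data points.  A positive value means ``fit_model`` predicts
    better (lower WAIC) than the reference.
    """
    wa = fit_model if isinstance(fit_model, WAICResult) else waic(fit_model.pointwise_loglik())
    wb = (
        fit_reference
        if isinstance(fit_reference, WAICResult)
        else waic(fit_reference.pointwise_loglik())
    )
    if wa.n_points != wb.n_points:
        raise ValueError("WAIC difference requires the same data points")
    d = wb.pointwise - wa.pointwise
    sem = float(np.sqrt(wa.n_points * d.var(ddof=1))) if wa.n_points > 1 else 0.0
    return float(d.sum()), sem


def _prepare_group_data(
    logs: pd.DataFrame, fit_sessions: Optional[tuple] = (1, 5)
) -> tuple:
    """Flatten a trial-log DataFrame into per-subject contiguous arrays."""
    df = logs[logs["outcome"].isin(["win", "loss"])]
    if fit_sessions is not None:
        lo, hi = fit_sessions
        df = df[(df["session"] >= lo) & (df["session"] <= hi)]
    subject_ids = sorted(df["subject_id"].unique())
    if len(subject_ids) < 2:
        raise ValueError("hierarchical fitting requires >=2 subjects")
    parts = []
    offsets = [0]
    for sid in subject_ids:
        sub = df[df["subject_id"] == sid].sort_values(["session", "trial_index"])
        parts.append(sub)
        offsets.append(offsets[-1] + len(sub))
    allt = pd.concat(parts, ignore_index=True)
    choices, is_win, rewards, penalties = trials_to_arrays(
        allt[["session", "trial_index", "choice", "outcome", "pellets", "penalty_s"]]
        .assign(session=1, trial_index=np.arange(1, len(allt) + 1))
    )
    return subject_ids, np.array(offsets, np.int64), choices, is_win, rewards, penalties


def fit_hierarchical(
    model_id: str,
    logs: pd.DataFrame,
    config: Optional[MCMCConfig] = None,
    fit_sessions: Optional[tuple] = (1, 5),
) -> PosteriorFit:
    """Fit one RL model to one task group's trial logs.

    ``logs`` is a canonical trial-log DataFrame; by default only valid
    choices from sessions 1-5 enter the likelihood.  Warmup escalates by
    doubling (up to ``config.warmup_cap``) until every split-R-hat is at
    or below ``config.rhat_threshold``.
    """
    if model_id not in MODEL_CODES:
        raise ValueError(f"unknown model_id {model_id!r}")
    config = config or MCMCConfig()
    code = MODEL_CODES[model_id]
    K = int(MODEL_K[code])
    tcodes = np.ascontiguousarray(MODEL_TRANSFORMS[code, :K])
    names = MODEL_PARAM_NAMES[code]
    subject_ids, offsets, choices, is_win, rewards, penalties = _prepare_group_data(
        logs, fit_sessions
    )
    S = len(subject_ids)
    mu_prior_sd = np.array([2.0 if tc == 2 else 1.0 for tc in tcodes])
    sigma_prior_sd = np.ones(K)

    # Per-parameter centering: the data strongly identify each subject's
    # beta and learning rates (hundreds of trials), where the centered form
    # mixes best; the cost-transform parameters (m, b, r, mRew) are weakly
    # identified per subject and their group SD can collapse toward zero,
    # the regime where the noncentered form avoids the funnel.
    if config.parameterization == "centered":
        cent = np.ones(K, dtype=np.int64)
    elif config.parameterization == "noncentered":
        cent = np.zeros(K, dtype=np.int64)
    else:  # auto
        cent = np.array(
            [1 if n in ("beta", "eta_plus", "eta_minus") else 0 for n in names],
            dtype=np.int64,
        )

    def logp_grad(theta: np.ndarray):
        lp, g = _hier_logp_grad_mixed(
            theta, code, K, S, offsets, choices, is_win, rewards, penalties,
            tcodes, mu_prior_sd, sigma_prior_sd, cent,
        )
        if not np.isfinite(lp):
            return -np.inf, np.zeros_like(theta)
        return lp, g

    dim = 2 * K + S * K
    mu0 = _default_mu_init(model_id)

    def make_inits(rng: np.random.Generator):
        inits = []
        for _ in range(config.n_chains):
            th = np.empty(dim)
            th[:K] = mu0 + 0.1 * rng.standard_normal(K)
            th[K : 2 * K] = np.log(0.3) + 0.1 * rng.standard_normal(K)
            z0 = 0.1 * rng.standard_normal(S * K)
            # centered coordinates start near the group means
            u0 = (np.tile(th[:K], S) + np.exp(np.tile(th[K : 2 * K], S)) * z0)
            th[2 * K :] = np.where(np.tile(cent, S) == 1, u0, z0)
            inits.append(th)
        return inits

    warmup = config.n_warmup
    attempt = 0
    while True:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, attempt)))
        inits = make_inits(rng)
        draws, chain_stats = sampler.run_chains(
            logp_grad, inits, warmup, config.n_samples,
            seed=int(np.random.SeedSequence((config.seed, attempt, 1)).generate_state(1)[0] % (2**31)),
            target_accept=config.target_accept, max_leapfrog=config.max_leapfrog,
            dense_mass=config.dense_mass,
        )
        # draws: (n_chains, n_samples, dim)
        diagnostics: Dict[str, float] = {}
        for k in range(K):
            diagnostics[f"mu_{names[k]}"] = rhat(draws[:, :, k])
            diagnostics[f"sigma_{names[k]}"] = rhat(draws[:, :, K + k])
        for s_i in range(S):
            for k in range(K):
                diagnostics[f"subject[{s_i}]_{names[k]}"] = rhat(
                    draws[:, :, 2 * K + s_i * K + k]
                )
        worst = np.nanmax(list(diagnostics.values()))
        if worst <= config.rhat_threshold or warmup >= config.warmup_cap:
            if worst > config.rhat_threshold:
                warnings.warn(
                    f"max R-hat {worst:.3f} > {config.rhat_threshold} at warmup cap "
                    f"{config.warmup_cap}; accepting fit with a convergence flag",
                    RuntimeWarning,
                )
            break
        warmup = min(2 * warmup, config.warmup_cap)
        attempt += 1

    div_rate = sum(c.divergences for c in chain_stats) / (
        config.n_chains * config.n_samples
    )
    if div_rate > config.max_divergence_rate:
        warnings.warn(
            f"divergence rate {div_rate:.3f} exceeds {config.max_divergence_rate}",
            RuntimeWarning,
        )
    mu = draws[:, :, :K]
    log_sigma = draws[:, :, K : 2 * K]
    subj = draws[:, :, 2 * K :].reshape(config.n_chains, config.n_samples, S, K)
    # store z-scores uniformly so reconstruction is always mu + sigma*z
    z_from_u = (subj - mu[:, :, None, :]) / np.exp(log_sigma)[:, :, None, :]
    z = np.where(cent[None, None, None, :] == 1, z_from_u, subj)
    return PosteriorFit(
        model_id=model_id,
        param_names=names,
        subject_ids=subject_ids,
        mu=mu,
        log_sigma=log_sigma,
        z=z,
        diagnostics=diagnostics,
        config=config,
        n_warmup_used=warmup,
        divergence_rate=float(div_rate),
        _data=(offsets, choices, is_win, rewards, penalties),
    )


#: default MLE box constraints on the constrained scale
DEFAULT_BOUNDS = {
    "beta": (1e-3, 30.0),
    "eta_plus": (1e-6, 1.0 - 1e-6),
    "eta_minus": (1e-6, 1.0 - 1e-6),
    "m": (1e-6, 2.0),
    "r": (1e-6, 3.0),
    "b": (-20.0, 20.0),
    "m_rew": (1e-6, 5.0),
}


@dataclass
class MLEResult:
    """Best point estimate from multi-start bounded optimization."""

    params: Optional[RLParams]
    loglik: float
    success: bool
    n_starts: int
    n_converged: int
    low_information: bool = False


def fit_mle(
    model_id: str,
    trials,
    n_starts: int = 10,
    bounds: Optional[dict] = None,
    seed: int = 0,
) -> MLEResult:
    """Multi-start maximum-likelihood fit of one subject's valid choices.

    Starts are a Latin hypercube over the box constraints; optimization
    is L-BFGS-B with the analytic likelihood gradient.  Fits on fewer
    than 10 trials are flagged ``low_information``.
    """
    if model_id not in MODEL_CODES:
        raise ValueError(f"unknown model_id {model_id!r}")
    choices, is_win, rewards, penalties = trials_to_arrays(trials)
    if len(choices) < 1:
        raise ValueError("need at least one valid trial")
    code = MODEL_CODES[model_id]
    K = int(MODEL_K[code])
    names = MODEL_PARAM_NAMES[code]
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])
    starts = lo + qmc.LatinHypercube(d=K, seed=seed).random(n_starts) * (hi - lo)
    grad_buf = np.empty(K)

    def neg_ll(x: np.ndarray):
        ll = _subject_ll_grad(
            np.ascontiguousarray(x), K, code, choices, is_win, rewards, penalties, grad_buf
        )
        return -ll, -grad_buf.copy()

    best = None
    n_conv = 0
    for x0 in starts:
        try:
            res = minimize(
                neg_ll, x0, jac=True, method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        n_conv += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return MLEResult(None, -np.inf, False, n_starts, 0)
    return MLEResult(
        params=RLParams.from_vector(model_id, best.x),
        loglik=float(-best.fun),
        success=True,
        n_starts=n_starts,
        n_converged=n_conv,
        low_information=len(choices) < 10,
    )


class HierarchicalRLModel(BaseEstimator):
    """sklearn-style wrapper around :func:`fit_hierarchical`.

    Parameters
    ----------
    model_id : str
        One of ``basic``, ``scaled``, ``scaled_offset``, ``nonlinear``,
        ``reward_scaled``.
    config : MCMCConfig or None
        Sampler settings; ``None`` uses the full-scale defaults.
    fit_sessions : tuple or None
        Inclusive session window entering the likelihood (default 1-5).

    After ``fit(X)`` (X a trial-log DataFrame):

    - ``fit_`` : the :class:`PosteriorFit`
    - ``group_means_`` : dict of constrained-scale posterior group means
    - ``subject_means_`` : per-subject posterior-mean DataFrame
    - ``rhat_max_`` : worst split-R-hat across all parameters
    """

    def __init__(self, model_id: str = "nonlinear", config: Optional[MCMCConfig] = None,
                 fit_sessions: Optional[tuple] = (1, 5)):
        self.model_id = model_id
        self.config = config
        self.fit_sessions = fit_sessions

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalRLModel":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a trial-log DataFrame")
        self.fit_ = fit_hierarchical(
            self.model_id, X, config=self.config, fit_sessions=self.fit_sessions
        )
        self.group_means_ = {
            n: float(self.fit_.group_mean_samples(n).mean())
            for n in self.fit_.param_names
        }
        self.subject_means_ = self.fit_.subject_posterior_means()
        self.rhat_max_ = float(np.nanmax(list(self.fit_.diagnostics.values())))
        return self

    def score(self, X=None, y=None) -> float:
        """Expected log pointwise predictive density (higher is better)."""
        return waic(self.fit_.pointwise_loglik()).elpd


class MLERLModel(BaseEstimator):
    """Per-subject multi-start maximum-likelihood fits, sklearn-style.

    ``fit(X)`` accepts a trial-log DataFrame (possibly several subjects);
    ``params_`` holds one row of constrained estimates per subject and
    ``loglik_`` the per-subject maxima.
    """

    def __init__(self, model_id: str = "nonlinear", n_starts: int = 10, seed: int = 0,
                 fit_sessions: Optional[tuple] = (1, 5)):
        self.model_id = model_id
        self.n_starts = n_starts
        self.seed = seed
        self.fit_sessions = fit_sessions

    def fit(self, X: pd.DataFrame, y=None) -> "MLERLModel":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a trial-log DataFrame")
        df = X[X["outcome"].isin(["win", "loss"])]
        if self.fit_sessions is not None:
            lo, hi = self.fit_sessions
            df = df[(df["session"] >= lo) & (df["session"] <= hi)]
        rows, lls = {}, {}
        for sid, sub in df.groupby("subject_id"):
            res = fit_mle(
                self.model_id,
                sub.sort_values(["session", "trial_index"]),
                n_starts=self.n_starts,
                seed=self.seed,
            )
            if res.success:
                rows[sid] = res.params.to_vector()
                lls[sid] = res.loglik
        self.params_ = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(MODEL_PARAMS[self.model_id])
        ).sort_index()
        self.loglik_ = pd.Series(lls).sort_index()
        return self
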