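"""Per-subject Bayesian fitting of diffusion model variants.

The observation model is moments-based: the probability of choosing the
default option comes from the closed-form absorption probability
(Bernoulli likelihood for the observed choice) and the observed response
time is modelled as Gaussian around the closed-form conditional mean RT
for the observed outcome, with a fitted noise SD shared across trials.
That keeps the whole likelihood in closed form, as in EZ-style fitting.

Point estimation is MAP (log-likelihood plus Gaussian log-prior on the
unconstrained parameter scale) via multi-start quasi-Newton optimization;
the log model evidence is a Laplace approximation at the MAP,

    log p(y) ~= log p(y|th) + log p(th) + (d/2) log 2pi - 0.5 log det H,

with H the negative Hessian of the log-posterior.  When H is not positive
definite a BIC-style evidence is substituted and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .ddm_core import DDMParams, cond_mean_upper, p_upper
from .model_space import ModelSpec, trial_params_vec

__all__ = ["FitResult", "trial_loglik", "total_loglik", "fit_subject"]

logger = logging.getLogger(__name__)

_P_CLIP = 1e-12
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitResult:
    """Posterior summary of one subject-model fit."""

    subject_id: object
    model: str
    param_names: tuple
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    log_evidence: float
    log_likelihood: float
    map_log_posterior: float
    n_trials: int
    n_excluded: int
    iterations: int
    gradient_norm: float
    seed: int
    evidence_method: str = "laplace"  # or "bic" fallback
    converged: bool = True

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, map(float, self.posterior_mean)))

    def to_dict(self) -> dict:
        subj = self.subject_id
        if isinstance(subj, np.integer):
            subj = int(subj)
        d = {
            "subject_id": subj,
            "model": self.model,
            "param_names": list(self.param_names),
            "posterior_mean": [float(x) for x in self.posterior_mean],
            "posterior_sd": [float(x) for x in self.posterior_sd],
            "log_evidence": float(self.log_evidence),
            "log_likelihood": float(self.log_likelihood),
            "map_log_posterior": float(self.map_log_posterior),
            "n_trials": int(self.n_trials),
            "n_excluded": int(self.n_excluded),
            "iterations": int(self.iterations),
            "gradient_norm": float(self.gradient_norm),
            "seed": int(self.seed),
            "evidence_method": self.evidence_method,
            "converged": bool(self.converged),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["param_names"] = tuple(d["param_names"])
        d["posterior_mean"] = np.asarray(d["posterior_mean"], float)
        d["posterior_sd"] = np.asarray(d["posterior_sd"], float)
        return cls(**d)


def _loglik_arrays(mu, z, a, tnd, rt_noise, choice, rt, sigma=1.0):
    """Vectorized per-trial log-likelihoods (choice + RT terms)."""
    s2 = sigma * sigma
    p_def = np.clip(p_upper(z, a, mu, s2), _P_CLIP, 1.0 - _P_CLIP)
    ll_choice = np.where(choice == 1, np.log(p_def), np.log1p(-p_def))
    t_def = tnd + cond_mean_upper(z, a, mu, s2)
    t_alt = tnd + cond_mean_upper(a - z, a, -mu, s2)
    pred = np.where(choice == 1, t_def, t_alt)
    resid = rt - pred
    ll_rt = -0.5 * (_LOG_2PI + 2.0 * np.log(rt_noise) + (resid / rt_noise) ** 2)
    return ll_choice + ll_rt


def trial_loglik(params: DDMParams, choice: int, rt: float, rt_noise_sd: float) -> float:
    """Log-likelihood of a single trial's (choice, rt) observation.

    ``choice`` is 1 when the default option was chosen, 0 otherwise.
    Trials with non-positive RT carry no information and raise a warning
    upstream; here they are rejected outright.
    """
    if rt_noise_sd <= 0:
        raise ValueError("rt_noise_sd must be > 0")
    if rt <= 0:
        raise ValueError("non-positive RT")
    ll = _loglik_arrays(
        np.array([params.mu]),
        np.array([params.z]),
        params.A,
        params.tnd,
        rt_noise_sd,
        np.array([int(choice)]),
        np.array([float(rt)]),
        sigma=params.sigma,
    )
    return float(ll[0])


def total_loglik(spec: ModelSpec, theta: np.ndarray, trials: pd.DataFrame) -> float:
    """Summed log-likelihood of a trial table under raw parameters."""
    mu, z, a, tnd, rt_noise = trial_params_vec(spec, theta, trials)
    ll = _loglik_arrays(
        mu,
        z,
        a,
        tnd,
        rt_noise,
        trials["choice"].to_numpy(int),
        trials["rt"].to_numpy(float),
    )
    return float(np.sum(ll))


def _neg_log_posterior(theta, spec, trials, prior_mean, prior_sd, choice, rt):
    try:
        with np.errstate(all="ignore"):
            mu, z, a, tnd, rt_noise = trial_params_vec(spec, theta, trials)
            if not (np.all(np.isfinite(mu)) and np.isfinite(a) and a > 0):
                return 1e12
            ll = _loglik_arrays(mu, z, a, tnd, rt_noise, choice, rt)
    except (ValueError, FloatingPointError, OverflowError):
        return 1e12
    lp = -0.5 * np.sum(((theta - prior_mean) / prior_sd) ** 2) - np.sum(
        np.log(prior_sd)
    ) - 0.5 * len(theta) * _LOG_2PI
    total = np.sum(ll) + lp
    if not np.isfinite(total):
        return 1e12
    return -total


def _hessian_fd(fun, x, eps=1e-4):
    """Central finite-difference Hessian."""
    d = len(x)
    h = np.empty((d, d))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = steps[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        h[i, i] = (fpp - 2.0 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = steps[j]
            fpq = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmq = fun(x - ei - ej)
            h[i, j] = h[j, i] = (fpq - fpm - fmp + fmq) / (4.0 * steps[i] * steps[j])
    return h


def fit_subject(
    trials: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    n_starts: int = 5,
    jitter_sd: float = 0.5,
    maxiter: int = 500,
) -> FitResult:
    """MAP fit of one model to one subject's trials + Laplace evidence.

    Optimization runs ``n_starts`` L-BFGS-B starts from the prior mean plus
    seeded Gaussian jitter (the first start is the prior mean itself; for
    drift/start coefficients a moment-matched heuristic start is added) and
    keeps the best posterior.  The likelihood is mildly multimodal for
    per-opposition models, hence the multi-start.
    """
    subject_id = trials["subject_id"].iloc[0] if "subject_id" in trials.columns else None
    n0 = len(trials)
    trials = trials[trials["rt"] > 0]
    n_excluded = n0 - len(trials)
    if n_excluded:
        logger.warning("excluded %d trials with non-positive RT", n_excluded)
    if spec.requires_fixations:
        if "d_def" not in trials.columns:
            raise ValueError(f"model {spec.name} requires fixation durations")
        usable = (trials["d_def"].to_numpy(float) + trials["d_alt"].to_numpy(float)) > 0
        n_excluded += int((~usable).sum())
        trials = trials[usable]
    trials = trials.reset_index(drop=True)
    choice = trials["choice"].to_numpy(int)
    rt = trials["rt"].to_numpy(float)

    prior_mean = spec.prior_mean()
    prior_sd = spec.prior_sd()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    # heuristic start: alpha from choice~dv_it slope scale, A/tnd from RTs
    idx = {p: i for i, p in enumerate(spec.param_names)}
    heur = prior_mean.copy()
    dv_sd = max(float(trials["dv_it"].std()), 1e-3)
    heur[idx["alpha"]] = 1.0 / dv_sd
    heur[idx["log_A"]] = np.log(1.5)
    heur[idx["log_tnd"]] = np.log(max(0.5 * float(rt.min()), 0.05))
    heur[idx["log_rt_noise"]] = np.log(max(0.5 * float(rt.std()), 0.05))

    obj = lambda th: _neg_log_posterior(th, spec, trials, prior_mean, prior_sd, choice, rt)
    starts = [heur, prior_mean]
    while len(starts) < max(n_starts, 2):
        starts.append(heur + rng.normal(0.0, jitter_sd, size=spec.n_params))
    best = None
    for x0 in starts[: max(n_starts, 2)]:
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-10}
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    nlp = best.fun
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan

    hess = _hessian_fd(obj, theta_hat)
    d = spec.n_params
    evidence_method = "laplace"
    try:
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(hess)
        post_var = np.diag(cov)
        if np.any(post_var <= 0):
            raise np.linalg.LinAlgError
        post_sd = np.sqrt(post_var)
        log_evidence = -nlp + 0.5 * d * _LOG_2PI - 0.5 * logdet
    except np.linalg.LinAlgError:
        evidence_method = "bic"
        ll_hat = total_loglik(spec, theta_hat, trials)
        log_evidence = ll_hat - 0.5 * d * np.log(max(len(trials), 2))
        post_sd = np.full(d, np.nan)
        diag = np.diag(hess)
        ok = diag > 0
        post_sd[ok] = 1.0 / np.sqrt(diag[ok])
        post_sd[~ok] = prior_sd[~ok]
        logger.warning(
            "non-positive-definite Hessian for %s/%s; BIC evidence used",
            subject_id,
            spec.name,
        )
    ll_hat = total_loglik(spec, theta_hat, trials)

    return FitResult(
        subject_id=subject_id,
        model=spec.name,
        param_names=spec.param_names,
        posterior_mean=theta_hat,
        posterior_sd=post_sd,
        log_evidence=float(log_evidence),
        log_likelihood=float(ll_hat),
        map_log_posterior=float(-nlp),
        n_trials=len(trials),
        n_excluded=n_excluded,
        iterations=int(best.nit),
        gradient_norm=grad_norm,
        seed=int(seed),
        evidence_method=evidence_method,
        converged=bool(best.success),
    )
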