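"""Random-effects Bayesian model selection at the group level.

Given a subjects x models matrix of log model evidences, the population is
modelled as a mixture: each subject's data arise from one model, with
unknown population frequencies r ~ Dirichlet(alpha).  A variational update
alternates posterior model responsibilities per subject (softmax of the
log evidence plus the digamma of the concentration) with the concentration
update alpha = alpha0 + summed responsibilities.  The exceedance
probability (xp) of a model is the posterior probability that its
frequency exceeds every competitor's, estimated by Monte-Carlo sampling of
the Dirichlet posterior; for two models it has the Beta-CDF closed form
used as the unit-test oracle.

Family-level comparison sums Dirichlet samples within families, with the
prior mass equalized across families (per-model prior concentration
1/family size) so that family size does not bias the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = ["BMSResult", "rfx_bms", "family_bms"]


@dataclass
class BMSResult:
    """Posterior of the random-effects model-frequency analysis."""

    model_names: tuple
    alpha: np.ndarray  # Dirichlet posterior concentrations
    expected_freq: np.ndarray
    xp: np.ndarray
    n_samples: int
    seed: int
    prior_alpha: np.ndarray
    families: dict | None = None  # family -> list of model names
    family_xp: dict | None = None
    family_expected_freq: dict | None = None
    iterations: int = 0

    def to_dict(self) -> dict:
        d = {
            "model_names": list(self.model_names),
            "alpha": [float(x) for x in self.alpha],
            "expected_freq": [float(x) for x in self.expected_freq],
            "xp": [float(x) for x in self.xp],
            "n_samples": int(self.n_samples),
            "seed": int(self.seed),
            "prior_alpha": [float(x) for x in self.prior_alpha],
            "iterations": int(self.iterations),
        }
        if self.families is not None:
            d["families"] = {k: list(v) for k, v in self.families.items()}
            d["family_xp"] = {k: float(v) for k, v in self.family_xp.items()}
            d["family_expected_freq"] = {
                k: float(v) for k, v in self.family_expected_freq.items()
            }
        return d


def _check_evidences(log_evidences, model_names):
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2:
        raise ValueError("log_evidences must be a subjects x models matrix")
    n, k = lme.shape
    if k < 2:
        raise ValueError("need at least 2 models")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    bad = ~np.isfinite(lme)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite log evidence for subject {i}, model {j}")
    if model_names is None:
        model_names = tuple(f"m{j}" for j in range(k))
    if len(model_names) != k:
        raise ValueError("model_names length mismatch")
    return lme, tuple(model_names)


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, max_iter=200, tol=1e-8):
    alpha = alpha0.copy()
    for it in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, it + 1


def _sample_xp(alpha: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    """Monte-Carlo exceedance probabilities under Dirichlet(alpha).

    Always sampled, so the K = 2 Beta-CDF closed form stays available as
    an independent oracle in the tests.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    k = len(alpha)
    wins = np.zeros(k)
    chunk = 200_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        r = rng.dirichlet(alpha, size=m)
        wins += np.bincount(np.argmax(r, axis=1), minlength=k)
        done += m
    return wins / n_samples


def rfx_bms(
    log_evidences,
    model_names=None,
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects model selection over per-subject log evidences.

    Returns Dirichlet posterior concentrations, expected model frequencies
    and exceedance probabilities.  For K = 2 the xp is computed exactly
    from the Beta CDF; otherwise by Monte-Carlo sampling.
    """
    lme, names = _check_evidences(log_evidences, model_names)
    alpha0 = np.full(lme.shape[1], float(prior_alpha))
    alpha, it = _vb_dirichlet(lme, alpha0)
    xp = _sample_xp(alpha, n_samples, seed)
    return BMSResult(
        model_names=names,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        xp=xp,
        n_samples=n_samples,
        seed=seed,
        prior_alpha=alpha0,
        iterations=it,
    )


def family_bms(
    log_evidences,
    partition: dict,
    model_names=None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Family-level comparison over a partition of the model space.

    ``partition`` maps model name -> family label and must cover every
    model.  Per-model prior concentration is 1/(family size) so each
    family carries equal prior mass regardless of how many members it has;
    family xp is the probability that the summed frequency of its members
    exceeds every other family's.
    """
    lme, names = _check_evidences(log_evidences, model_names)
    missing = [m for m in names if m not in partition]
    if missing:
        raise ValueError(f"partition does not cover models: {missing}")
    families: dict[str, list[str]] = {}
    for m in names:
        families.setdefault(partition[m], []).append(m)
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    if any(len(v) == 0 for v in families.values()):
        raise ValueError("empty family")
    fam_names = sorted(families)
    alpha0 = np.array([1.0 / len(families[partition[m]]) for m in names])
    alpha, it = _vb_dirichlet(lme, alpha0)

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    fam_idx = [np.array([names.index(m) for m in families[f]]) for f in fam_names]
    fam_wins = np.zeros(len(fam_names))
    chunk = 200_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        r = rng.dirichlet(alpha, size=m)
        fam_r = np.stack([r[:, ix].sum(axis=1) for ix in fam_idx], axis=1)
        fam_wins += np.bincount(np.argmax(fam_r, axis=1), minlength=len(fam_names))
        done += m
    fam_xp = fam_wins / n_samples
    fam_ef = {
        f: float(alpha[ix].sum() / alpha.sum()) for f, ix in zip(fam_names, fam_idx)
    }
    xp = _sample_xp(alpha, n_samples, seed + 1)
    return BMSResult(
        model_names=names,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        xp=xp,
        n_samples=n_samples,
        seed=seed,
        prior_alpha=alpha0,
        families={f: list(families[f]) for f in fam_names},
        family_xp=dict(zip(fam_names, map(float, fam_xp))),
        family_expected_freq=fam_ef,
        iterations=it,
    )
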