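"""Declarative model variants: how trial covariates map to diffusion parameters.

Each :class:`ModelSpec` composes a *start rule* (how the starting-point
shift S is built: fixed at zero, one free shift, one free shift per
category opposition, or proportional to the category preference DV_CAT)
with a *drift rule* (drift proportional to the item value difference DV_IT,
optionally offset by a constant, per-opposition constants, a DV_CAT term,
or gated by gaze fixations with an attentional discount theta).

Free parameters live on an unconstrained ("raw") scale used by the
optimizer: boundary separation and non-decision time are log-transformed,
the starting point passes through a scaled tanh so that |S| < A/2 always
holds, and theta maps through a scaled logistic into (0, 1.05) so that
values at or slightly above 1 remain reachable.  Priors are Gaussian on
the raw scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm_core import DDMParams, attentional_drift

__all__ = [
    "ModelSpec",
    "trial_params",
    "trial_params_vec",
    "enumerate_model_space",
    "get_model",
    "MAIN_MODELS",
    "EYETRACKING_MODELS",
    "theta_from_raw",
    "theta_to_raw",
]

N_BLOCKS = 12  # category oppositions; "per-block" parameters are per opposition

START_RULES = ("zero", "single_free", "per_block_free", "proportional_to_dv_cat")
DRIFT_RULES = (
    "alpha_dv_it",
    "alpha_dv_it_plus_const",
    "alpha_dv_it_per_block_const",
    "alpha_dv_it_plus_beta_dv_cat",
    "attentional",
)

# raw-scale Gaussian priors, weakly informative on each parameter's own
# natural scale (an order of magnitude above typical fitted values): value
# coefficients act per rating unit on evidence scales of order 1, so an
# absurdly wide prior would veto any extra parameter through its Occam
# factor alone (Bartlett's paradox) rather than through the data
_PRIORS = {
    "alpha": (0.0, 1.0),  # drift per rating unit of DV_IT (~0.05 typical)
    "log_A": (np.log(1.5), 1.0),
    "log_tnd": (np.log(0.3), 1.0),
    "log_rt_noise": (np.log(0.3), 1.0),
    "a_start": (0.0, 0.1),  # start shift per rating unit of DV_CAT (~0.02)
    "s0": (0.0, 1.0),  # start shift, evidence units
    "b0": (0.0, 1.0),  # drift offset, evidence units / s
    "beta_cat": (0.0, 0.1),  # drift offset per rating unit of DV_CAT
    "theta": (3.0, 2.0),  # raw scale; theta_from_raw(3.0) = 1.0
}
for _b in range(1, N_BLOCKS + 1):
    _PRIORS[f"s_{_b}"] = (0.0, 1.0)
    _PRIORS[f"b_{_b}"] = (0.0, 1.0)


def theta_from_raw(raw: float) -> float:
    """Scaled logistic map raw -> theta in (0, 1.05)."""
    return 1.05 / (1.0 + np.exp(-raw))


def theta_to_raw(theta: float) -> float:
    if not 0 < theta < 1.05:
        raise ValueError("theta must lie in (0, 1.05)")
    p = theta / 1.05
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class ModelSpec:
    """One model variant of the comparison space."""

    name: str
    start_rule: str
    drift_rule: str
    family: str
    priors: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start_rule not in START_RULES:
            raise ValueError(f"unknown start rule {self.start_rule!r}")
        if self.drift_rule not in DRIFT_RULES:
            raise ValueError(f"unknown drift rule {self.drift_rule!r}")
        if not self.priors:
            object.__setattr__(
                self, "priors", {p: _PRIORS[p] for p in self.param_names}
            )

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha", "log_A", "log_tnd", "log_rt_noise"]
        if self.start_rule == "single_free":
            names.append("s0")
        elif self.start_rule == "per_block_free":
            names += [f"s_{b}" for b in range(1, N_BLOCKS + 1)]
        elif self.start_rule == "proportional_to_dv_cat":
            names.append("a_start")
        if self.drift_rule == "alpha_dv_it_plus_const":
            names.append("b0")
        elif self.drift_rule == "alpha_dv_it_per_block_const":
            names += [f"b_{b}" for b in range(1, N_BLOCKS + 1)]
        elif self.drift_rule == "alpha_dv_it_plus_beta_dv_cat":
            names.append("beta_cat")
        elif self.drift_rule == "attentional":
            names.append("theta")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def requires_fixations(self) -> bool:
        return self.drift_rule == "attentional"

    def prior_mean(self) -> np.ndarray:
        return np.array([self.priors[p][0] for p in self.param_names])

    def prior_sd(self) -> np.ndarray:
        return np.array([self.priors[p][1] for p in self.param_names])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "start_rule": self.start_rule,
            "drift_rule": self.drift_rule,
            "family": self.family,
            "priors": {k: list(v) for k, v in self.priors.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        priors = {k: tuple(v) for k, v in d.get("priors", {}).items()}
        return cls(d["name"], d["start_rule"], d["drift_rule"], d["family"], priors)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


def _squash_start(s_lin, a):
    """Smooth map keeping |S| < A/2; near-identity for small shifts.

    The (1 - 1e-9) factor keeps the start strictly inside the boundaries
    even where tanh saturates to exactly +-1 in floating point.
    """
    return (a / 2.0) * (1.0 - 1e-9) * np.tanh(2.0 * np.asarray(s_lin, dtype=float) / a)


def trial_params(
    spec: ModelSpec,
    theta: np.ndarray,
    *,
    dv_it: float,
    dv_cat: float,
    opposition_id: int,
    sigma: float = 1.0,
    v_def: float | None = None,
    v_alt: float | None = None,
    d_def: float | None = None,
    d_alt: float | None = None,
) -> DDMParams:
    """Assemble one trial's diffusion parameters from the raw vector.

    Boundary separation, non-decision time and sigma are shared across
    oppositions within a subject; drift and starting point follow the
    spec's rules.  Attentional rules require the trial's option values and
    fixation durations.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"parameter vector length {theta.shape} does not match "
            f"{spec.name} ({spec.n_params} parameters)"
        )
    idx = {p: i for i, p in enumerate(spec.param_names)}
    a = float(np.exp(theta[idx["log_A"]]))
    tnd = float(np.exp(theta[idx["log_tnd"]]))
    alpha = float(theta[idx["alpha"]])

    if spec.start_rule == "zero":
        s_lin = 0.0
    elif spec.start_rule == "single_free":
        s_lin = theta[idx["s0"]]
    elif spec.start_rule == "per_block_free":
        if not 1 <= opposition_id <= N_BLOCKS:
            raise ValueError(f"opposition_id must be 1..{N_BLOCKS}")
        s_lin = theta[idx[f"s_{int(opposition_id)}"]]
    else:
        s_lin = theta[idx["a_start"]] * dv_cat
    s = float(_squash_start(s_lin, a))

    if spec.drift_rule == "alpha_dv_it":
        mu = alpha * dv_it
    elif spec.drift_rule == "alpha_dv_it_plus_const":
        mu = alpha * dv_it + theta[idx["b0"]]
    elif spec.drift_rule == "alpha_dv_it_per_block_const":
        mu = alpha * dv_it + theta[idx[f"b_{int(opposition_id)}"]]
    elif spec.drift_rule == "alpha_dv_it_plus_beta_dv_cat":
        mu = alpha * dv_it + theta[idx["beta_cat"]] * dv_cat
    else:  # attentional
        if d_def is None or d_alt is None or v_def is None or v_alt is None:
            raise ValueError(
                f"model {spec.name} requires option values and fixation durations"
            )
        th = theta_from_raw(theta[idx["theta"]])
        mu = attentional_drift(v_def, v_alt, d_def, d_alt, th, alpha)
    return DDMParams(A=a, S=s, mu=float(mu), sigma=sigma, tnd=tnd)


def trial_params_vec(
    spec: ModelSpec, theta: np.ndarray, trials: pd.DataFrame, sigma: float = 1.0
):
    """Vectorized per-trial (mu, z, A, tnd, rt_noise_sd) over a trial table.

    Used by the fitting routines; mirrors :func:`trial_params` exactly.
    """
    theta = np.asarray(theta, dtype=float)
    idx = {p: i for i, p in enumerate(spec.param_names)}
    a = float(np.exp(theta[idx["log_A"]]))
    tnd = float(np.exp(theta[idx["log_tnd"]]))
    rt_noise = float(np.exp(theta[idx["log_rt_noise"]]))
    alpha = float(theta[idx["alpha"]])
    dv_it = trials["dv_it"].to_numpy(float)
    dv_cat = trials["dv_cat"].to_numpy(float)
    opp = trials["opposition_id"].to_numpy(int)

    if spec.start_rule == "zero":
        s_lin = np.zeros(len(trials))
    elif spec.start_rule == "single_free":
        s_lin = np.full(len(trials), theta[idx["s0"]])
    elif spec.start_rule == "per_block_free":
        per = np.array([theta[idx[f"s_{b}"]] for b in range(1, N_BLOCKS + 1)])
        s_lin = per[opp - 1]
    else:
        s_lin = theta[idx["a_start"]] * dv_cat
    z = a / 2.0 + _squash_start(s_lin, a)

    if spec.drift_rule == "alpha_dv_it":
        mu = alpha * dv_it
    elif spec.drift_rule == "alpha_dv_it_plus_const":
        mu = alpha * dv_it + theta[idx["b0"]]
    elif spec.drift_rule == "alpha_dv_it_per_block_const":
        per = np.array([theta[idx[f"b_{b}"]] for b in range(1, N_BLOCKS + 1)])
        mu = alpha * dv_it + per[opp - 1]
    elif spec.drift_rule == "alpha_dv_it_plus_beta_dv_cat":
        mu = alpha * dv_it + theta[idx["beta_cat"]] * dv_cat
    else:
        for col in ("d_def", "d_alt", "v_def", "v_alt"):
            if col not in trials.columns:
                raise ValueError(f"model {spec.name} requires column {col!r}")
        th = theta_from_raw(theta[idx["theta"]])
        mu = attentional_drift(
            trials["v_def"].to_numpy(float),
            trials["v_alt"].to_numpy(float),
            trials["d_def"].to_numpy(float),
            trials["d_alt"].to_numpy(float),
            th,
            alpha,
        )
    return np.asarray(mu, float), z, a, tnd, rt_noise


MAIN_MODELS = (
    ModelSpec("null", "zero", "alpha_dv_it", "null"),
    ModelSpec("s_free", "single_free", "alpha_dv_it", "start"),
    ModelSpec("s_12free", "per_block_free", "alpha_dv_it", "start"),
    ModelSpec("s_dvcat", "proportional_to_dv_cat", "alpha_dv_it", "start"),
    ModelSpec("mu_const", "zero", "alpha_dv_it_plus_const", "drift"),
    ModelSpec("mu_12const", "zero", "alpha_dv_it_per_block_const", "drift"),
    ModelSpec("mu_dvcat", "zero", "alpha_dv_it_plus_beta_dv_cat", "drift"),
)

EYETRACKING_MODELS = (
    ModelSpec("null", "zero", "alpha_dv_it", "null"),
    ModelSpec("sddm", "proportional_to_dv_cat", "alpha_dv_it", "start"),
    ModelSpec("addm", "zero", "attentional", "attention"),
    ModelSpec("asddm", "proportional_to_dv_cat", "attentional", "attention_start"),
)

_CATALOG = {m.name: m for m in MAIN_MODELS}
_CATALOG.update({m.name: m for m in EYETRACKING_MODELS})


def enumerate_model_space(experiment: str = "main") -> list[ModelSpec]:
    """The model comparison space: 7 variants for the main experiment
    (null + 3 starting-point + 3 drift mechanisms) or 4 for the
    eye-tracking experiment (null, sDDM, aDDM, asDDM)."""
    if experiment == "main":
        return list(MAIN_MODELS)
    if experiment == "eyetracking":
        return list(EYETRACKING_MODELS)
    raise ValueError(f"experiment must be 'main' or 'eyetracking', got {experiment!r}")


def get_model(name: str) -> ModelSpec:
    """Look a model variant up by name."""
    try:
        return _CATALOG[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(_CATALOG)}") from None


def natural_to_raw(spec: ModelSpec, config) -> dict:
    """Raw parameter values realizing a generator config's natural truth."""
    out = {}
    if spec.start_rule == "proportional_to_dv_cat":
        out["a_start"] = config.start_coef
    if spec.drift_rule == "attentional":
        out["theta"] = theta_to_raw(config.theta)
    return out
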