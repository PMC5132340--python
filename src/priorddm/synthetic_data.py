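"""Synthetic value-based choice experiments with a category-induced default.

The generator emulates a study design in which participants first rate the
likeability of 432 items (3 reward domains x 4 categories x 36 items, on a
0-100 scale) and then make 432 binary choices organized as 12 category
oppositions x 4 blocks x 9 trials.  Within each opposition one option is
drawn from the a-priori preferred category (the *default*) and one from the
less preferred category (the *alternative*).  Choices and response times are
produced by Monte-Carlo simulation of a Wiener diffusion whose drift is
proportional to the item-level value difference DV_IT and whose starting
point is shifted in proportion to the category-level preference DV_CAT
(or by any other model variant passed in).  Optional gaze-fixation streams
alternate between the two options and, for attentional variants, gate the
momentary drift.

All outputs are plain pandas DataFrames written as TSV; a fixed seed makes
every table byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from numba import njit

from . import model_space
from .ddm_core import DDMParams

__all__ = [
    "GeneratorConfig",
    "generate_ratings",
    "build_choice_design",
    "simulate_behavior",
    "generate_experiment",
    "generate_debrief",
    "write_tables",
]

DOMAINS = ("food", "magazine", "music")
CATEGORIES_PER_DOMAIN = 4
ITEMS_PER_CATEGORY = 36
N_CATEGORIES = len(DOMAINS) * CATEGORIES_PER_DOMAIN
N_ITEMS = N_CATEGORIES * ITEMS_PER_CATEGORY  # 432
OPPOSITIONS_PER_DOMAIN = ((1, 3), (1, 4), (2, 3), (2, 4))  # preference ranks
N_OPPOSITIONS = len(DOMAINS) * len(OPPOSITIONS_PER_DOMAIN)  # 12
BLOCKS_PER_OPPOSITION = 4
TRIALS_PER_BLOCK = 9
TRIALS_PER_OPPOSITION = BLOCKS_PER_OPPOSITION * TRIALS_PER_BLOCK  # 36


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the scale of the modelled study: 24 subjects, 432
    items rated on [0, 100], category means spaced so that every domain has
    a clear preference order, and diffusion parameters yielding choice and
    RT biases of realistic magnitude (a category-preference-to-starting-
    point coefficient of 0.01 evidence units per rating unit shifts the
    start by ~15% of the boundary separation at the average DV_CAT).
    """

    n_subjects: int = 24
    # ratings
    category_mean_levels: tuple = (45.0, 52.0, 59.0, 66.0)
    category_mean_jitter_sd: float = 3.0  # subject-level spread of category means
    rating_noise_sd: float = 10.0  # item-level spread within category
    round_ratings: bool = False  # quantize to the 101-point scale
    # diffusion truth (defaults: starting point proportional to DV_CAT)
    model: str = "s_dvcat"
    alpha: float = 0.05  # drift per rating unit of DV_IT
    start_coef: float = 0.02  # starting-point shift per rating unit of DV_CAT
    boundary: float = 2.0
    sigma: float = 1.0
    tnd: float = 0.35
    rt_noise_sd: float = 0.1  # extra Gaussian RT noise, seconds
    extra_params: dict = field(default_factory=dict)  # other model params by name
    # attentional/fixation process
    theta: float = 1.0
    fixations: bool = False
    first_fix_left_prob: float = 0.7
    fix_duration_median: float = 0.3  # seconds, log-normal
    fix_duration_log_sd: float = 0.5
    # simulation
    dt: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("rating_noise_sd", "category_mean_jitter_sd", "rt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.boundary <= 0 or self.sigma <= 0:
            raise ValueError("boundary separation and diffusion SD must be > 0")
        if len(self.category_mean_levels) != CATEGORIES_PER_DOMAIN:
            raise ValueError(
                f"need {CATEGORIES_PER_DOMAIN} category mean levels per domain"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_mean_levels"] = list(d["category_mean_levels"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["category_mean_levels"] = tuple(d["category_mean_levels"])
        return cls(**d)


def _category_labels() -> list[tuple[str, str]]:
    """(domain, category) labels; 4 categories per domain, 12 total."""
    return [(d, f"{d}_{i + 1}") for d in DOMAINS for i in range(CATEGORIES_PER_DOMAIN)]


def generate_ratings(config: GeneratorConfig) -> pd.DataFrame:
    """Per-subject item likeability ratings.

    Each subject's 12 category means are the configured levels (shuffled
    across the 4 categories of each domain) plus subject-level jitter;
    item ratings add independent noise and are clipped to [0, 100].

    Returns a DataFrame with columns
    ``subject_id, item_id, domain, category, rating``.
    """
    rng = np.random.default_rng(config.seed)
    labels = _category_labels()
    rows = []
    for subj in range(config.n_subjects):
        for d_idx, domain in enumerate(DOMAINS):
            levels = rng.permutation(np.asarray(config.category_mean_levels, dtype=float))
            means = levels + rng.normal(0.0, config.category_mean_jitter_sd, size=len(levels))
            for c_idx in range(CATEGORIES_PER_DOMAIN):
                cat = labels[d_idx * CATEGORIES_PER_DOMAIN + c_idx][1]
                base = means[c_idx]
                # item noise bounded at +-2.5 SD: items within a coherent
                # category stay in a credible likeability band
                noise = rng.normal(0.0, config.rating_noise_sd, size=ITEMS_PER_CATEGORY)
                noise = np.clip(noise, -2.5 * config.rating_noise_sd, 2.5 * config.rating_noise_sd)
                vals = np.clip(base + noise, 0.0, 100.0)
                if config.round_ratings:
                    vals = np.round(vals)
                for i_idx, v in enumerate(vals):
                    item_id = (d_idx * CATEGORIES_PER_DOMAIN + c_idx) * ITEMS_PER_CATEGORY + i_idx
                    rows.append((subj, item_id, domain, cat, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "item_id", "domain", "category", "rating"])


def _rank_categories(sub: pd.DataFrame) -> dict[str, list[str]]:
    """Categories of each domain ordered by decreasing mean rating.

    Ties in category means are broken by category label (stable and
    deterministic), ties in item ratings by item id.
    """
    out = {}
    for domain, grp in sub.groupby("domain"):
        means = grp.groupby("category")["rating"].mean()
        order = sorted(means.index, key=lambda c: (-means[c], c))
        out[domain] = order
    return out


def _decorrelate_pairs(pairs: list, val_map: pd.Series, tol: float = 0.05, max_sweeps: int = 8):
    """Deterministic swap pass enforcing mean/relative-value orthogonality.

    Greedy hill climb exchanging the alternative-category members of pair
    couples whenever the swap lowers |corr(pair average, |pair difference|)|;
    stops below ``tol`` or when no swap improves.  Preserves the
    each-item-once structure of the pair set.
    """
    d_items = np.array([p[0] for p in pairs])
    a_items = np.array([p[1] for p in pairs])
    dv = val_map.loc[d_items].to_numpy()
    av = val_map.loc[a_items].to_numpy()

    def score(_=None):
        avg = dv + av
        diff = np.abs(dv - av)
        ac = avg - avg.mean()
        dc = diff - diff.mean()
        den = float(np.sqrt((ac @ ac) * (dc @ dc)))
        if den == 0.0:
            return 0.0
        return abs(float(ac @ dc) / den)

    best = score()
    n = len(pairs)
    for _ in range(max_sweeps):
        if best < tol:
            break
        improved = False
        for vals, ids in ((av, a_items), (dv, d_items)):
            for i in range(n):
                for j in range(i + 1, n):
                    vals[i], vals[j] = vals[j], vals[i]
                    s = score()
                    if s < best - 1e-9:
                        best = s
                        ids[i], ids[j] = ids[j], ids[i]
                        improved = True
                    else:
                        vals[i], vals[j] = vals[j], vals[i]
        if not improved:
            break
    return list(zip(d_items.tolist(), a_items.tolist()))


def build_choice_design(ratings: pd.DataFrame) -> pd.DataFrame:
    """Choice-pair design for one subject's complete rating table.

    Per domain the four categories are ranked by mean rating; the preferred
    two are opposed to the less preferred two (oppositions 1-3, 1-4, 2-3,
    2-4).  Within an opposition the items of each category are sorted by
    rating and paired so that half the 36 trials vary the rating difference
    at a roughly constant pair average ("mean+X with mean-X") and half vary
    the average at a roughly constant rank difference, which orthogonalizes
    the mean and relative option value.  Every item is used once per
    opposition, hence twice overall.  The 36 trials of an opposition are
    shuffled into 4 blocks of 9 and the screen side of the default-category
    item is counterbalanced.
    """
    subjects = ratings["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("build_choice_design expects a single subject's ratings")
    subj = subjects[0]
    if len(ratings) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} rated items, got {len(ratings)}")
    rng = np.random.default_rng(int(np.int64(subj)) * 7919 + 17)
    ranked = _rank_categories(ratings)
    rows = []
    opp_id = 0
    m = ITEMS_PER_CATEGORY  # 36
    h = m // 2  # 18
    q = m // 4  # 9
    for domain in DOMAINS:
        order = ranked[domain]
        for hi, lo in OPPOSITIONS_PER_DOMAIN:
            cat_def, cat_alt = order[hi - 1], order[lo - 1]
            opp_id += 1
            items = {}
            values = {}
            for cat in (cat_def, cat_alt):
                grp = ratings[ratings["category"] == cat]
                # ascending rating; rank 1 = least liked; ties by item id
                grp = grp.sort_values(["rating", "item_id"]).reset_index(drop=True)
                items[cat] = grp["item_id"].to_numpy()
                values[cat] = grp["rating"].to_numpy()
            target = float(values[cat_def].mean() + values[cat_alt].mean())
            pairs = []
            # difference-varying half: default items from the rank extremes,
            # each greedily matched with the unused alternative item that
            # keeps the pair sum closest to the opposition mean, so the
            # signed value difference sweeps from strongly negative to
            # strongly positive at a ~constant pair average
            alt_used = np.zeros(m, dtype=bool)
            extreme = list(range(m - 1, m - q - 1, -1)) + list(range(q))
            for di in extreme:
                dval = values[cat_def][di]
                cand = np.where(~alt_used)[0]
                aj = cand[np.argmin(np.abs(dval + values[cat_alt][cand] - target))]
                alt_used[aj] = True
                pairs.append((items[cat_def][di], items[cat_alt][aj]))
            # average-varying half: the remaining (middle-rank) items of both
            # categories paired in rating order, minimal within-pair rank
            # difference while the pair average sweeps low -> high
            alt_rest = np.where(~alt_used)[0]
            for kk, aj in zip(range(q, m - q), alt_rest):
                pairs.append((items[cat_def][kk], items[cat_alt][aj]))
            assert len(pairs) == m
            val_map = ratings.set_index("item_id")["rating"]
            pairs = _decorrelate_pairs(pairs, val_map)
            perm = rng.permutation(m)
            for t_idx, p_idx in enumerate(perm):
                item_def, item_alt = pairs[p_idx]
                block = t_idx // TRIALS_PER_BLOCK + 1
                side_default = "left" if rng.random() < 0.5 else "right"
                rows.append(
                    (
                        subj,
                        opp_id,
                        cat_def,
                        cat_alt,
                        block,
                        t_idx % TRIALS_PER_BLOCK + 1,
                        int(item_def) if side_default == "left" else int(item_alt),
                        int(item_alt) if side_default == "left" else int(item_def),
                        side_default,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "opposition_id",
            "cat_default",
            "cat_alternative",
            "block",
            "trial_in_block",
            "item_left",
            "item_right",
            "side_of_default",
        ],
    )


@njit(cache=True)
def _sim_const_drift(mu, z, a, sigma, dt, seed, horizon):  # pragma: no cover - jit
    np.random.seed(seed)
    n = mu.shape[0]
    choice = np.empty(n, dtype=np.int64)
    dtime = np.empty(n, dtype=np.float64)
    sd = sigma * np.sqrt(dt)
    s2dt = sigma * sigma * dt
    cut = 20.0 * s2dt  # bridge probability < exp(-40) beyond this
    max_steps = int(horizon / dt)
    for i in range(n):
        x = z[i]
        m = mu[i]
        c = -1
        t = 0.0
        for step in range(max_steps):
            x1 = x + m * dt + sd * np.random.standard_normal()
            t = (step + 1) * dt
            if x1 >= a:
                c = 1
                break
            if x1 <= 0.0:
                c = 0
                break
            du = (a - x) * (a - x1)
            dl = x * x1
            if du < cut or dl < cut:
                pu = np.exp(-2.0 * du / s2dt)
                pl = np.exp(-2.0 * dl / s2dt)
                u = np.random.random()
                if u < pu:
                    c = 1
                    break
                if u < pu + pl:
                    c = 0
                    break
            x = x1
        if c == -1:  # truncated: resolve by position, keep horizon time
            c = 1 if x >= a / 2.0 else 0
        choice[i] = c
        dtime[i] = t
    return choice, dtime


_MAX_FIX = 64


@njit(cache=True)
def _sim_addm_trial(  # pragma: no cover - jit
    v_def,
    v_alt,
    theta,
    alpha,
    z,
    a,
    sigma,
    dt,
    first_left,
    side_def_left,
    fix_mu,
    fix_sd,
    horizon,
):
    """One aDDM trial: drift gated by the currently fixated option.

    Returns (choice, decision_time, n_fix, targets, durations) where targets
    are 1 = default, 0 = alternative, truncated at the decision time.
    """
    targets = np.empty(_MAX_FIX, dtype=np.int64)
    durs = np.empty(_MAX_FIX, dtype=np.float64)
    x = z
    sd = sigma * np.sqrt(dt)
    s2dt = sigma * sigma * dt
    mu_def = alpha * (v_def - theta * v_alt)
    mu_alt = -alpha * (v_alt - theta * v_def)
    look_left = first_left
    t = 0.0
    n_fix = 0
    choice = -1
    while t < horizon and n_fix < _MAX_FIX:
        on_default = (look_left and side_def_left) or (not look_left and not side_def_left)
        m = mu_def if on_default else mu_alt
        planned = np.exp(fix_mu + fix_sd * np.random.standard_normal())
        steps = max(1, int(planned / dt))
        used = 0.0
        cut = 20.0 * s2dt
        for _ in range(steps):
            x1 = x + m * dt + sd * np.random.standard_normal()
            used += dt
            crossed = 0
            if x1 >= a:
                choice = 1
                crossed = 1
            elif x1 <= 0.0:
                choice = 0
                crossed = 1
            else:
                du = (a - x) * (a - x1)
                dl = x * x1
                if du < cut or dl < cut:
                    pu = np.exp(-2.0 * du / s2dt)
                    pl = np.exp(-2.0 * dl / s2dt)
                    u = np.random.random()
                    if u < pu:
                        choice = 1
                        crossed = 1
                    elif u < pu + pl:
                        choice = 0
                        crossed = 1
            x = x1
            if crossed == 1:
                break
        targets[n_fix] = 1 if on_default else 0
        durs[n_fix] = used
        n_fix += 1
        t += used
        if choice >= 0:
            break
        look_left = not look_left
    if choice == -1:
        choice = 1 if x >= a / 2.0 else 0
    return choice, t, n_fix, targets, durs


def simulate_behavior(
    design: pd.DataFrame,
    ratings: pd.DataFrame,
    config: GeneratorConfig,
    spec: "model_space.ModelSpec | None" = None,
) -> pd.DataFrame:
    """Simulate choices and RTs for one subject's design.

    The per-trial drift and starting point come from ``model_space.
    trial_params`` applied to the generating model (``config.model`` unless
    an explicit spec is passed), so the generator and the fitted models
    share one definition of every variant.  Choices/RTs are produced by
    Euler-Maruyama simulation of the diffusion (Brownian-bridge corrected);
    Gaussian RT noise is added and resampled until rt > Tnd.

    Returns a trial DataFrame with columns ``subject_id, opposition_id,
    block, trial_in_block, v_def, v_alt, dv_it, dv_cat, choice, rt`` plus,
    when fixations are simulated, ``d_def, d_alt, first_fix, last_fix,
    n_fix, fix_targets, fix_durations``.
    """
    if spec is None:
        spec = model_space.get_model(config.model)
    subj = design["subject_id"].iloc[0]
    rate_map = ratings.set_index("item_id")["rating"]
    cat_means = ratings.groupby("category")["rating"].mean()
    seed = (int(np.int64(subj)) * 104729 + int(config.seed) * 13 + 1) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)

    d = design.copy()
    left_is_def = d["side_of_default"] == "left"
    d["item_def"] = np.where(left_is_def, d["item_left"], d["item_right"])
    d["item_alt"] = np.where(left_is_def, d["item_right"], d["item_left"])
    d["v_def"] = rate_map.loc[d["item_def"]].to_numpy()
    d["v_alt"] = rate_map.loc[d["item_alt"]].to_numpy()
    d["dv_it"] = d["v_def"] - d["v_alt"]
    d["dv_cat"] = (
        cat_means.loc[d["cat_default"]].to_numpy() - cat_means.loc[d["cat_alternative"]].to_numpy()
    )

    theta_free = "theta" in spec.param_names
    truth = {
        "alpha": config.alpha,
        "log_A": np.log(config.boundary),
        "log_tnd": np.log(config.tnd),
        "log_rt_noise": np.log(max(config.rt_noise_sd, 1e-3)),
    }
    truth.update(model_space.natural_to_raw(spec, config))
    truth.update(config.extra_params)
    theta_vec = np.array([truth.get(p, 0.0) for p in spec.param_names])

    if spec.drift_rule.startswith("attentional"):
        if not config.fixations:
            raise ValueError("attentional generating model requires fixations=True")
        return _simulate_attentional(d, config, spec, theta_vec, rng, seed)

    mu, z, a_fit, tnd_fit, _ = model_space.trial_params_vec(
        spec, theta_vec, d, sigma=config.sigma
    )
    choice, dec_t = _sim_const_drift(
        mu, z, a_fit, config.sigma, config.dt, seed, 60.0
    )
    rt = _add_rt_noise(dec_t + tnd_fit, config, rng)
    out = d[
        ["subject_id", "opposition_id", "block", "trial_in_block", "v_def", "v_alt", "dv_it", "dv_cat", "side_of_default"]
    ].copy()
    out["choice"] = choice
    out["rt"] = rt
    if config.fixations:
        _attach_choice_independent_fixations(out, dec_t, config, rng)
    return out.reset_index(drop=True)


def _add_rt_noise(rt_clean: np.ndarray, config: GeneratorConfig, rng) -> np.ndarray:
    """Gaussian RT noise, resampled so every RT stays above Tnd."""
    if config.rt_noise_sd == 0:
        return rt_clean.copy()
    rt = rt_clean + rng.normal(0.0, config.rt_noise_sd, size=len(rt_clean))
    bad = rt <= config.tnd
    for _ in range(100):
        if not bad.any():
            break
        rt[bad] = rt_clean[bad] + rng.normal(0.0, config.rt_noise_sd, size=int(bad.sum()))
        bad = rt <= config.tnd
    rt[bad] = config.tnd + 1e-3
    return rt


def _fixation_stream(total: float, config: GeneratorConfig, rng) -> tuple[list, list]:
    """Alternating left/right fixation stream truncated at ``total`` seconds."""
    fix_mu = np.log(config.fix_duration_median)
    left = rng.random() < config.first_fix_left_prob
    t = 0.0
    sides, durs = [], []
    while t < total:
        dur = float(rng.lognormal(fix_mu, config.fix_duration_log_sd))
        dur = min(dur, total - t)
        sides.append("left" if left else "right")
        durs.append(dur)
        t += dur
        left = not left
    return sides, durs


def _attach_choice_independent_fixations(
    out: pd.DataFrame, dec_t: np.ndarray, config: GeneratorConfig, rng
) -> None:
    """Fixations generated independently of the accumulator (theta = 1)."""
    cols = {k: [] for k in ("d_def", "d_alt", "first_fix", "last_fix", "n_fix", "fix_targets", "fix_durations")}
    for i, row in enumerate(out.itertuples(index=False)):
        sides, durs = _fixation_stream(float(dec_t[i]), config, rng)
        def_side = row.side_of_default
        targets = ["default" if s == def_side else "alternative" for s in sides]
        d_def = sum(d for tgt, d in zip(targets, durs) if tgt == "default")
        d_alt = sum(d for tgt, d in zip(targets, durs) if tgt == "alternative")
        cols["d_def"].append(d_def)
        cols["d_alt"].append(d_alt)
        cols["first_fix"].append(targets[0] if targets else "none")
        cols["last_fix"].append(targets[-1] if targets else "none")
        cols["n_fix"].append(len(targets))
        cols["fix_targets"].append(",".join(t[0] for t in targets))  # d/a codes
        cols["fix_durations"].append(",".join(f"{x:.4f}" for x in durs))
    for k, v in cols.items():
        out[k] = v


def _simulate_attentional(
    d: pd.DataFrame, config: GeneratorConfig, spec, theta_vec, rng, seed
) -> pd.DataFrame:
    """aDDM generator: momentary drift follows the fixated option."""
    idx = {p: i for i, p in enumerate(spec.param_names)}
    alpha = theta_vec[idx["alpha"]]
    a = np.exp(theta_vec[idx["log_A"]])
    theta = (
        model_space.theta_from_raw(theta_vec[idx["theta"]]) if "theta" in idx else 1.0
    )
    fix_mu = np.log(config.fix_duration_median)
    np.random.seed(seed & 0x7FFFFFFF)  # numba kernel RNG
    rows = {k: [] for k in (
        "choice", "rt", "d_def", "d_alt", "first_fix", "last_fix", "n_fix", "fix_targets", "fix_durations"
    )}
    for row in d.itertuples(index=False):
        par = model_space.trial_params(
            spec,
            theta_vec,
            dv_it=row.dv_it,
            dv_cat=row.dv_cat,
            opposition_id=row.opposition_id,
            sigma=config.sigma,
            v_def=row.v_def,
            v_alt=row.v_alt,
            d_def=1.0,
            d_alt=1.0,  # placeholder durations; kernel gates drift itself
        )
        first_left = rng.random() < config.first_fix_left_prob
        choice, dec_t, n_fix, targets, durs = _sim_addm_trial(
            row.v_def,
            row.v_alt,
            theta,
            alpha,
            par.z,
            a,
            config.sigma,
            config.dt,
            first_left,
            row.side_of_default == "left",
            fix_mu,
            config.fix_duration_log_sd,
            60.0,
        )
        targets = targets[:n_fix]
        durs = durs[:n_fix]
        rows["choice"].append(int(choice))
        rows["rt"].append(float(dec_t))
        rows["d_def"].append(float(durs[targets == 1].sum()))
        rows["d_alt"].append(float(durs[targets == 0].sum()))
        rows["first_fix"].append("default" if targets[0] == 1 else "alternative")
        rows["last_fix"].append("default" if targets[-1] == 1 else "alternative")
        rows["n_fix"].append(int(n_fix))
        rows["fix_targets"].append(",".join("d" if t == 1 else "a" for t in targets))
        rows["fix_durations"].append(",".join(f"{x:.4f}" for x in durs))
    out = d[
        ["subject_id", "opposition_id", "block", "trial_in_block", "v_def", "v_alt", "dv_it", "dv_cat", "side_of_default"]
    ].copy()
    for k in ("choice", "d_def", "d_alt", "first_fix", "last_fix", "n_fix", "fix_targets", "fix_durations"):
        out[k] = rows[k]
    rt_clean = np.asarray(rows["rt"]) + config.tnd
    out["rt"] = _add_rt_noise(rt_clean, config, rng)
    return out.reset_index(drop=True)


def generate_experiment(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full multi-subject experiment: (ratings, trials)."""
    ratings = generate_ratings(config)
    all_trials = []
    for subj, sub in ratings.groupby("subject_id"):
        design = build_choice_design(sub)
        all_trials.append(simulate_behavior(design, sub, config))
    trials = pd.concat(all_trials, ignore_index=True)
    return ratings, trials


def generate_debrief(
    ratings: pd.DataFrame,
    temperature: float = 5.0,
    conf_noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Post-session debriefing: explicit category-pair choices + confidence.

    Within each domain every category pair is presented; the higher-mean
    category is chosen through a softmax on the mean-rating difference
    (``temperature`` in rating units; 0 = deterministic) and confidence is
    proportional to |difference| plus noise, on a 0-100 scale.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subj, sub in ratings.groupby("subject_id"):
        means = sub.groupby("category")["rating"].mean()
        for domain, grp in sub.groupby("domain"):
            cats = sorted(grp["category"].unique())
            for i in range(len(cats)):
                for j in range(i + 1, len(cats)):
                    c1, c2 = cats[i], cats[j]
                    diff = means[c1] - means[c2]
                    if temperature > 0:
                        p1 = 1.0 / (1.0 + np.exp(-diff / temperature))
                        pick1 = rng.random() < p1
                    else:
                        pick1 = diff >= 0
                    conf = np.clip(abs(diff) * 2.0 + rng.normal(0, conf_noise_sd), 0, 100)
                    rows.append(
                        (subj, domain, c1, c2, c1 if pick1 else c2, float(conf), float(diff))
                    )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "domain", "cat_a", "cat_b", "chosen_cat", "confidence", "dv_cat_ab"],
    )


def write_tables(outdir, ratings: pd.DataFrame, trials: pd.DataFrame, config: GeneratorConfig) -> None:
    """Write ratings/trials TSVs and the generating config (YAML + JSON)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ratings.to_csv(outdir / "ratings.tsv", sep="\t", index=False)
    trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    if "fix_targets" in trials.columns:
        rows = []
        for idx, row in enumerate(trials.itertuples(index=False)):
            if not isinstance(row.fix_targets, str) or not row.fix_targets:
                continue
            onset = 0.0
            targets = row.fix_targets.split(",")
            durs = [float(x) for x in row.fix_durations.split(",")]
            for f_idx, (tgt, dur) in enumerate(zip(targets, durs)):
                rows.append(
                    (row.subject_id, idx, f_idx,
                     "default" if tgt == "d" else "alternative", onset, dur)
                )
                onset += dur
        pd.DataFrame(
            rows,
            columns=["subject_id", "trial_index", "fix_index", "target", "onset", "duration"],
        ).to_csv(outdir / "fixations.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "generator_config.yaml")
    with open(outdir / "generator_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
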