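"""Behavioral statistics of the default-option bias.

Choice bias is the excess probability of choosing the default option at a
null item-level value difference (DV_IT = 0), expressed in percentage
points above the 50% indifference level and estimated from a logistic
regression of choice on the two option values.  RT bias is the difference
between the response-time intercepts of alternative- and default-chosen
trials at |DV_IT| = 0 (positive = default faster), from a linear model
with the unsigned decision value, the choice type and their interaction.
Block-level biases (one block = one category opposition) support the
bias-correlation analysis; RT-binned biases separate starting-point from
drift mechanisms; fixation summaries cover the eye-tracking analyses.

All group-level tests are two-tailed one-sample t-tests on per-subject
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "BiasEstimates",
    "choice_bias_logistic",
    "rt_bias_glm",
    "blockwise_bias_correlation",
    "bias_by_rt_bins",
    "choice_curve",
    "rt_curves",
    "fixation_summaries",
    "gaze_to_fixations",
    "debrief_consistency",
]

logger = logging.getLogger(__name__)


@dataclass
class BiasEstimates:
    """Bias statistics for one subject (or one subject-block)."""

    subject_id: object
    block_id: object = "all"
    choice_bias: float = np.nan  # percentage points above 50% at DV_IT = 0
    rt_bias: float = np.nan  # seconds; positive = default chosen faster
    coefficients: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    separated: bool = False
    n_trials: int = 0


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """L2-penalized logistic fit; fallback under complete separation.

    The intercept (first column) carries a 10x weaker penalty so that a
    fully one-sided block still yields a finite, near-saturated bias
    instead of being shrunk to indifference.
    """
    lams = np.full(X.shape[1], lam)
    lams[0] = lam / 10.0

    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(lams * b * b))

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="L-BFGS-B")
    return res.x


def _fit_logistic(X: np.ndarray, y: np.ndarray, names: list[str]):
    """(coefs, ses, separated flag); penalized fit when MLE diverges."""
    separated = len(np.unique(y)) < 2
    if not separated:
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.bse)) and np.max(np.abs(fit.params)) < 50:
                return (
                    dict(zip(names, fit.params)),
                    dict(zip(names, fit.bse)),
                    False,
                )
            separated = True
        except Exception:
            separated = True
    b = _ridge_logistic(X, y)
    return dict(zip(names, b)), {n: np.nan for n in names}, True


def choice_bias_logistic(
    trials: pd.DataFrame,
    include_dv_cat: bool = False,
    include_history: bool = False,
    block_id="all",
) -> BiasEstimates:
    """Logistic choice model and the derived choice bias.

    Regresses choice (default = 1) on a constant and the two option
    values, optionally adding DV_CAT and the lagged choice (coded 1/-1).
    The choice bias is the fitted P(default) evaluated at a null decision
    value (v_def = v_alt at their grand mean, other covariates at their
    mean / zero) minus 50%, in percentage points.
    """
    if len(trials) < 30:
        logger.warning("choice_bias_logistic on %d trials (<30)", len(trials))
    y = trials["choice"].to_numpy(int)
    # covariates centered at the grand mean option value, so the constant
    # is directly the log-odds of a default choice at a null decision value
    vbar = float(
        np.mean(np.concatenate([trials["v_def"].to_numpy(float), trials["v_alt"].to_numpy(float)]))
    )
    cols = {"const": np.ones(len(trials))}
    cols["v_def"] = trials["v_def"].to_numpy(float) - vbar
    cols["v_alt"] = trials["v_alt"].to_numpy(float) - vbar
    if include_dv_cat:
        # left uncentered: the constant then reads as the residual bias at a
        # null category preference, which is how DV_CAT "explains away" the
        # default bias
        cols["dv_cat"] = trials["dv_cat"].to_numpy(float)
    if include_history:
        prev = np.where(np.roll(y, 1) == 1, 1.0, -1.0)
        prev[0] = 0.0
        cols["prev_choice"] = prev
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    coefs, ses, separated = _fit_logistic(X, y, names)
    eta = coefs["const"]
    if include_dv_cat:
        eta += coefs["dv_cat"] * float(np.mean(cols["dv_cat"]))
    p0 = 1.0 / (1.0 + np.exp(-eta))
    return BiasEstimates(
        subject_id=trials["subject_id"].iloc[0] if "subject_id" in trials.columns else None,
        block_id=block_id,
        choice_bias=100.0 * (p0 - 0.5),
        coefficients=coefs,
        standard_errors=ses,
        separated=separated,
        n_trials=len(trials),
    )


def rt_bias_glm(trials: pd.DataFrame, block_id="all") -> BiasEstimates:
    """Linear RT model: |DV_IT|, choice type and their interaction.

    Choice type is coded 1 for alternative-chosen trials, so the type
    coefficient is directly the RT bias (alternative intercept minus
    default intercept; positive = default faster).
    """
    y = trials["rt"].to_numpy(float)
    absdv = np.abs(trials["dv_it"].to_numpy(float))
    alt = 1.0 - trials["choice"].to_numpy(float)
    if min((alt == 1).sum(), (alt == 0).sum()) < 3:
        raise ValueError(
            "need at least 3 trials of each choice type to estimate the RT bias"
        )
    X = np.column_stack([np.ones(len(y)), absdv, alt, absdv * alt])
    names = ["const", "abs_dv", "alt_chosen", "abs_dv_x_alt"]
    fit = sm.OLS(y, X).fit()
    coefs = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    return BiasEstimates(
        subject_id=trials["subject_id"].iloc[0] if "subject_id" in trials.columns else None,
        block_id=block_id,
        rt_bias=coefs["alt_chosen"],
        coefficients=coefs,
        standard_errors=ses,
        n_trials=len(trials),
    )


def _group_ttest(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    t, p = stats.ttest_1samp(values, 0.0)
    return {
        "mean": float(np.mean(values)),
        "sem": float(stats.sem(values)),
        "t": float(t),
        "p": float(p),
        "n": int(len(values)),
    }


def blockwise_biases(sub: pd.DataFrame, min_alt: int = 2) -> pd.DataFrame:
    """Per-opposition choice and RT biases for one subject.

    Estimated jointly across blocks with block-specific intercepts and
    value slopes shared across blocks: the choice model is a (weakly
    penalized) logistic regression of choice on per-block constants plus
    the centered option values; the RT model regresses RT on per-block
    constants, |DV_IT| and per-block alternative-choice effects.  Sharing
    the slopes stabilizes the 36-trial block estimates relative to fully
    separate per-block fits.  Blocks with fewer than ``min_alt``
    alternative (or default) choices have no estimable RT bias and are
    dropped.
    """
    opp = sub["opposition_id"].to_numpy(int)
    ids = np.unique(opp)
    B = (opp[:, None] == ids[None, :]).astype(float)
    vbar = float(np.mean(np.r_[sub["v_def"].to_numpy(float), sub["v_alt"].to_numpy(float)]))
    Xc = np.column_stack(
        [B, sub["v_def"].to_numpy(float) - vbar, sub["v_alt"].to_numpy(float) - vbar]
    )
    y = sub["choice"].to_numpy(float)
    lam = np.r_[np.full(len(ids), 0.1), [1.0, 1.0]]

    def nll(b):
        eta = Xc @ b
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(lam * b * b))

    b = optimize.minimize(nll, np.zeros(Xc.shape[1]), method="L-BFGS-B").x
    cb = 100.0 * (1.0 / (1.0 + np.exp(-b[: len(ids)])) - 0.5)

    absdv = np.abs(sub["dv_it"].to_numpy(float))
    alt = 1.0 - sub["choice"].to_numpy(float)
    Xr = np.column_stack([B, absdv, B * alt[:, None]])
    fit = sm.OLS(sub["rt"].to_numpy(float), Xr).fit()
    rb = fit.params[len(ids) + 1 :]
    n_alt = np.array([(alt[opp == i] == 1).sum() for i in ids])
    n_def = np.array([(alt[opp == i] == 0).sum() for i in ids])
    ok = (n_alt >= min_alt) & (n_def >= min_alt)
    dvc = np.array([float(sub.loc[opp == i, "dv_cat"].iloc[0]) for i in ids])
    return pd.DataFrame(
        {
            "opposition_id": ids[ok],
            "choice_bias": cb[ok],
            "rt_bias": rb[ok],
            "dv_cat": dvc[ok],
        }
    )


def blockwise_bias_correlation(trials: pd.DataFrame) -> dict:
    """Correlation of choice and RT biases across category oppositions.

    Per subject, the two biases are estimated per opposition (see
    :func:`blockwise_biases`; oppositions with an inestimable RT bias are
    dropped and counted), correlated with Pearson's r across oppositions,
    and the per-subject correlations are t-tested against zero at the
    group level.
    """
    per_subject = []
    for subj, sub in trials.groupby("subject_id"):
        blocks = blockwise_biases(sub)
        dropped = sub["opposition_id"].nunique() - len(blocks)
        if len(blocks) < 6:
            logger.warning("subject %s: only %d estimable blocks", subj, len(blocks))
            continue
        r = float(np.corrcoef(blocks["choice_bias"], blocks["rt_bias"])[0, 1])
        per_subject.append(
            {"subject_id": subj, "r": r, "n_blocks": len(blocks), "n_dropped": dropped, "blocks": blocks}
        )
    rs = np.array([d["r"] for d in per_subject])
    return {
        "per_subject": per_subject,
        "subject_r": rs,
        "group": _group_ttest(rs),
    }


def bias_by_rt_bins(trials: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Choice bias within per-subject RT quantile bins.

    A starting-point bias decays with decision time, so its choice bias
    shrinks across RT bins; a drift bias does not.  With a single bin this
    reduces exactly to the overall choice bias.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows = []
    for subj, sub in trials.groupby("subject_id"):
        if n_bins == 1:
            bins = np.zeros(len(sub), dtype=int)
        else:
            bins = pd.qcut(sub["rt"], n_bins, labels=False, duplicates="drop")
        for b in np.unique(bins):
            seg = sub[bins == b]
            est = choice_bias_logistic(seg, block_id=f"rtbin{b}")
            rows.append(
                (subj, int(b), float(seg["rt"].mean()), est.choice_bias, len(seg))
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "rt_bin", "rt_center", "choice_bias", "n_trials"]
    )


def choice_curve(trials: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """P(default) per DV_IT quantile bin (pooled over subjects)."""
    bins = pd.qcut(trials["dv_it"], n_bins, labels=False, duplicates="drop")
    g = trials.groupby(bins)
    return pd.DataFrame(
        {
            "dv_it": g["dv_it"].mean(),
            "p_default": g["choice"].mean(),
            "n": g["choice"].size(),
        }
    ).reset_index(drop=True)


def rt_curves(trials: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Mean RT per |DV_IT| quantile bin, split by choice type."""
    t = trials.copy()
    t["abs_dv"] = t["dv_it"].abs()
    out = []
    for label, seg in (("default", t[t["choice"] == 1]), ("alternative", t[t["choice"] == 0])):
        bins = pd.qcut(seg["abs_dv"], n_bins, labels=False, duplicates="drop")
        g = seg.groupby(bins)
        out.append(
            pd.DataFrame(
                {
                    "abs_dv": g["abs_dv"].mean(),
                    "rt": g["rt"].mean(),
                    "n": g["rt"].size(),
                    "choice_type": label,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _parse_fixations(row) -> tuple[np.ndarray, np.ndarray]:
    """Fixation stream from the compact trial-table encoding."""
    if not isinstance(row.fix_targets, str) or row.fix_targets == "":
        return np.array([], dtype=int), np.array([])
    targets = np.array([1 if c == "d" else 0 for c in row.fix_targets.split(",")])
    durs = np.array([float(x) for x in row.fix_durations.split(",")])
    return targets, durs


def fixation_summaries(trials: pd.DataFrame, time_step: float = 0.05, t_max: float = 2.0) -> dict:
    """Fixation-pattern statistics of the eye-tracking analyses.

    Per subject: P(choose the last-fixated option), P(choose the most
    fixated option) among trials with unequal durations, the 2 x 2
    (chosen/unchosen x default/alternative) fixation-duration cell means
    with a factorial ANOVA on the subject-level cell means, and fixation-
    proportion time courses locked to stimulus onset and to the response.
    Trials without recorded fixations are excluded and counted.
    """
    if "fix_targets" not in trials.columns:
        raise ValueError("trials carry no fixation streams")
    per_subj = []
    cells = []
    grid_on = np.arange(0.0, t_max + 1e-9, time_step)
    grid_resp = -grid_on[::-1]
    tc_on = {}
    tc_resp = {}
    n_excluded = 0
    for subj, sub in trials.groupby("subject_id"):
        last_match, most_match = [], []
        durs_cell = {("def", "chosen"): [], ("def", "unchosen"): [], ("alt", "chosen"): [], ("alt", "unchosen"): []}
        on_def = np.zeros((len(grid_on),))
        on_alt = np.zeros((len(grid_on),))
        rs_def = np.zeros((len(grid_resp),))
        rs_alt = np.zeros((len(grid_resp),))
        n_tr = 0
        for row in sub.itertuples(index=False):
            targets, durs = _parse_fixations(row)
            if len(targets) == 0:
                n_excluded += 1
                continue
            n_tr += 1
            chose_def = row.choice == 1
            last = targets[-1]
            last_match.append((last == 1) == chose_def)
            d_def = durs[targets == 1].sum()
            d_alt = durs[targets == 0].sum()
            if d_def != d_alt:
                most_match.append((d_def > d_alt) == chose_def)
            durs_cell[("def", "chosen" if chose_def else "unchosen")].append(d_def)
            durs_cell[("alt", "chosen" if not chose_def else "unchosen")].append(d_alt)
            # time courses: which option is fixated at each grid point
            edges = np.concatenate([[0.0], np.cumsum(durs)])
            total = edges[-1]
            for grid, acc_d, acc_a, t_of in (
                (grid_on, on_def, on_alt, grid_on),
                (grid_resp, rs_def, rs_alt, total + grid_resp),
            ):
                inside = (t_of >= 0) & (t_of < total)
                which = np.searchsorted(edges, t_of[inside], side="right") - 1
                which = np.clip(which, 0, len(targets) - 1)
                tgt = targets[which]
                np.add.at(acc_d, np.where(inside)[0][tgt == 1], 1)
                np.add.at(acc_a, np.where(inside)[0][tgt == 0], 1)
        if n_tr == 0:
            continue
        per_subj.append(
            {
                "subject_id": subj,
                "p_choose_last_fixated": float(np.mean(last_match)),
                "p_choose_most_fixated": float(np.mean(most_match)) if most_match else np.nan,
                "n_trials": n_tr,
            }
        )
        for (opt, ch), vals in durs_cell.items():
            if vals:
                cells.append({"subject_id": subj, "option": opt, "status": ch, "duration": float(np.mean(vals))})
        tc_on[subj] = (on_def / n_tr, on_alt / n_tr)
        tc_resp[subj] = (rs_def / n_tr, rs_alt / n_tr)

    per_subj_df = pd.DataFrame(per_subj)
    cell_df = pd.DataFrame(cells)
    anova = None
    if len(cell_df) >= 8:
        from statsmodels.formula.api import ols

        fit = ols("duration ~ C(option) * C(status)", data=cell_df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
    tc = {
        "time_onset": grid_on,
        "onset_default": np.mean([v[0] for v in tc_on.values()], axis=0),
        "onset_alternative": np.mean([v[1] for v in tc_on.values()], axis=0),
        "time_response": grid_resp,
        "response_default": np.mean([v[0] for v in tc_resp.values()], axis=0),
        "response_alternative": np.mean([v[1] for v in tc_resp.values()], axis=0),
    }
    return {
        "per_subject": per_subj_df,
        "group_last_fixated": _group_ttest(per_subj_df["p_choose_last_fixated"] - 0.5),
        "group_most_fixated": _group_ttest(per_subj_df["p_choose_most_fixated"] - 0.5),
        "cell_means": cell_df,
        "anova": anova,
        "time_courses": tc,
        "n_excluded": n_excluded,
    }


def gaze_to_fixations(
    samples: pd.DataFrame,
    window_left: tuple,
    window_right: tuple,
    side_of_default: str = "left",
) -> pd.DataFrame:
    """Classify raw gaze samples into fixations on default/alternative/none.

    ``samples`` has columns ``t, x, y`` with monotone timestamps; windows
    are ``(x0, y0, x1, y1)`` screen rectangles.  Consecutive samples on
    the same target merge into one fixation; each sample covers the
    interval up to the next sample (the last sample gets the median
    inter-sample interval).
    """
    t = samples["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be monotone")
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)

    def inside(win):
        x0, y0, x1, y1 = win
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    side = np.full(len(t), "none", dtype=object)
    side[inside(window_left)] = "left"
    side[inside(window_right)] = "right"
    target = np.where(
        side == "none",
        "none",
        np.where(side == ("left" if side_of_default == "left" else "right"), "default", "alternative"),
    )
    dt = np.diff(t)
    step = float(np.median(dt)) if len(dt) else 1.0 / 60.0
    dur = np.append(dt, step)
    rows = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and target[j + 1] == target[i]:
            j += 1
        rows.append((target[i], float(t[i]), float(dur[i : j + 1].sum())))
        i = j + 1
    return pd.DataFrame(rows, columns=["target", "onset", "duration"])


def debrief_consistency(ratings: pd.DataFrame, debrief: pd.DataFrame) -> dict:
    """Match rate of explicit category choices with rating-derived
    preferences, and the correlation of debriefing confidence with the
    category-level value difference; both t-tested at the group level."""
    rows = []
    for subj, sub in debrief.groupby("subject_id"):
        means = ratings[ratings["subject_id"] == subj].groupby("category")["rating"].mean()
        pred = np.where(
            means[sub["cat_a"]].to_numpy() >= means[sub["cat_b"]].to_numpy(),
            sub["cat_a"],
            sub["cat_b"],
        )
        match = float(np.mean(pred == sub["chosen_cat"].to_numpy()))
        absdv = np.abs(sub["dv_cat_ab"].to_numpy(float))
        if np.std(absdv) > 0 and np.std(sub["confidence"]) > 0:
            r = float(stats.pearsonr(absdv, sub["confidence"]).statistic)
        else:
            r = np.nan
        rows.append({"subject_id": subj, "match_rate": match, "confidence_r": r})
    df = pd.DataFrame(rows)
    return {
        "per_subject": df,
        "group_match": _group_ttest(df["match_rate"] - 0.5),
        "mean_match_rate": float(df["match_rate"].mean()),
        "group_confidence_r": _group_ttest(df["confidence_r"]),
    }
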