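"""End-to-end replication pipeline.

simulate -> fit every model variant per subject -> family-level then
within-family random-effects model selection -> behavioral bias statistics
-> report bundle (tables, JSON summary, optional figures), all derived
from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_stats, group_bms, model_space, synthetic_data
from .inference import FitResult, fit_subject

__all__ = ["RunConfig", "stage_seed", "run_replication", "fit_experiment", "blockwise_start_correlation"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one full replication run."""

    generator: synthetic_data.GeneratorConfig = field(
        default_factory=synthetic_data.GeneratorConfig
    )
    experiment: str = "main"  # which model space to fit
    models: tuple = ()  # empty = all models of the experiment's space
    n_starts: int = 5
    bms_samples: int = 1_000_000
    master_seed: int = 0
    outdir: str | None = None
    make_plots: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "generator": self.generator.to_dict(),
                "experiment": self.experiment,
                "models": list(self.models),
                "n_starts": self.n_starts,
                "bms_samples": self.bms_samples,
                "master_seed": self.master_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent but reproducible per-stage seed stream."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def fit_experiment(
    trials: pd.DataFrame,
    specs,
    master_seed: int = 0,
    n_starts: int = 5,
) -> list[FitResult]:
    """Fit every (subject, model) pair; returns the flat list of fits."""
    fits = []
    for spec in specs:
        for subj, sub in trials.groupby("subject_id"):
            seed = stage_seed(master_seed, f"fit:{spec.name}:{subj}")
            fits.append(fit_subject(sub, spec, seed=seed, n_starts=n_starts))
    return fits


def evidence_matrix(fits: list[FitResult], model_names) -> tuple[np.ndarray, list]:
    """Subjects x models log-evidence matrix from a flat fit list."""
    subjects = sorted({f.subject_id for f in fits})
    lut = {(f.subject_id, f.model): f.log_evidence for f in fits}
    lme = np.array([[lut[(s, m)] for m in model_names] for s in subjects])
    return lme, subjects


def blockwise_start_correlation(fits: list[FitResult], trials: pd.DataFrame) -> dict:
    """Correlation of per-opposition fitted starting points with DV_CAT.

    Uses the per-block free-start model's posterior means, mapped to the
    natural starting-point scale, correlated against each opposition's
    category preference within subject and t-tested across subjects.
    """
    block_fits = [f for f in fits if f.model in ("s_12free",)]
    dv = trials.groupby(["subject_id", "opposition_id"])["dv_cat"].first()
    rows = []
    for f in block_fits:
        pars = f.params_dict()
        a = float(np.exp(pars["log_A"]))
        s_nat = np.array(
            [
                (a / 2.0) * np.tanh(2.0 * pars[f"s_{b}"] / a)
                for b in range(1, model_space.N_BLOCKS + 1)
            ]
        )
        dvc = dv.loc[f.subject_id].reindex(range(1, model_space.N_BLOCKS + 1)).to_numpy()
        ok = np.isfinite(dvc)
        if ok.sum() < 3 or np.std(s_nat[ok]) == 0:
            continue
        r = float(np.corrcoef(s_nat[ok], dvc[ok])[0, 1])
        rows.append({"subject_id": f.subject_id, "r": r})
    df = pd.DataFrame(rows)
    return {
        "per_subject": df,
        "group": behavior_stats._group_ttest(df["r"]) if len(df) else None,
    }


def run_replication(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    report: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
    }
    gen = dataclasses.replace(config.generator, seed=stage_seed(config.master_seed, "simulate"))
    stage = "simulate"
    try:
        ratings, trials = synthetic_data.generate_experiment(gen)
        debrief = synthetic_data.generate_debrief(
            ratings, seed=stage_seed(config.master_seed, "debrief")
        )

        stage = "fit"
        specs = model_space.enumerate_model_space(config.experiment)
        if config.models:
            specs = [model_space.get_model(m) for m in config.models]
        fits = fit_experiment(trials, specs, config.master_seed, config.n_starts)
        names = [s.name for s in specs]
        lme, subjects = evidence_matrix(fits, names)

        stage = "bms"
        partition = {s.name: s.family for s in specs}
        if len(set(partition.values())) >= 2:
            fam = group_bms.family_bms(
                lme,
                partition,
                model_names=names,
                n_samples=config.bms_samples,
                seed=stage_seed(config.master_seed, "bms_family"),
            )
            report["family_bms"] = fam.to_dict()
        else:
            fam = None
        start_models = [s.name for s in specs if s.family == "start"]
        if len(start_models) >= 2:
            cols = [names.index(m) for m in start_models]
            within = group_bms.rfx_bms(
                lme[:, cols],
                model_names=start_models,
                n_samples=config.bms_samples,
                seed=stage_seed(config.master_seed, "bms_within"),
            )
            report["within_start_bms"] = within.to_dict()

        stage = "stats"
        biases = [behavior_stats.choice_bias_logistic(s) for _, s in trials.groupby("subject_id")]
        rts = [behavior_stats.rt_bias_glm(s) for _, s in trials.groupby("subject_id")]
        cb = np.array([b.choice_bias for b in biases])
        rb = np.array([b.rt_bias for b in rts])
        report["choice_bias"] = behavior_stats._group_ttest(cb)
        report["rt_bias"] = behavior_stats._group_ttest(rb)
        corr = behavior_stats.blockwise_bias_correlation(trials)
        report["bias_correlation"] = corr["group"]
        rtb = behavior_stats.bias_by_rt_bins(trials, n_bins=4)
        report["bias_by_rt_bin"] = {
            int(k): float(v) for k, v in rtb.groupby("rt_bin")["choice_bias"].mean().items()
        }
        if "s_12free" in names:
            sc = blockwise_start_correlation(fits, trials)
            report["start_dvcat_correlation"] = sc["group"]
        report["debrief"] = {
            "mean_match_rate": behavior_stats.debrief_consistency(ratings, debrief)["mean_match_rate"]
        }
        report["n_subjects"] = len(subjects)
        report["models"] = names

        if config.outdir is not None:
            stage = "write"
            _write_bundle(config, report, ratings, trials, fits, rtb)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        report["failed_stage"] = stage
        raise
    return report


def _write_bundle(config, report, ratings, trials, fits, rtb) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic_data.write_tables(out, ratings, trials, config.generator)
    with open(out / "fits.json", "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=1, default=_jsonable)
    rtb.to_csv(out / "bias_by_rt_bin.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "config_hash": report["config_hash"],
                "master_seed": config.master_seed,
                "files": sorted(p.name for p in out.iterdir()),
            },
            fh,
            indent=2,
        )
    if config.make_plots:
        _make_plots(out, trials, rtb)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _make_plots(out: Path, trials: pd.DataFrame, rtb: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    cc = behavior_stats.choice_curve(trials)
    fig, ax = plt.subplots()
    ax.plot(cc["dv_it"], 100 * cc["p_default"], "o-")
    ax.axhline(50, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("decision value DV_IT (rating units)")
    ax.set_ylabel("P(default) [%]")
    fig.savefig(plots / "choice_curve.png", dpi=120)
    plt.close(fig)

    rc = behavior_stats.rt_curves(trials)
    fig, ax = plt.subplots()
    for label, seg in rc.groupby("choice_type"):
        ax.plot(seg["abs_dv"], seg["rt"], "o-", label=label)
    ax.set_xlabel("|DV_IT| (rating units)")
    ax.set_ylabel("RT (s)")
    ax.legend()
    fig.savefig(plots / "rt_curves.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    g = rtb.groupby("rt_bin")["choice_bias"].mean()
    ax.plot(g.index, g.values, "o-")
    ax.set_xlabel("RT quantile bin")
    ax.set_ylabel("choice bias [% above 50]")
    fig.savefig(plots / "bias_by_rt_bin.png", dpi=120)
    plt.close(fig)
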