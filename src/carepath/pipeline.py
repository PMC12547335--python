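"""End-to-end experiment pipeline: generate → split → simulate → train →
fit transition model → counterfactual evaluation → fairness → report.

All randomness flows from one global seed; each stage derives its own stream
as ``sha256(global_seed:stage) mod 2^31``, so stages are independently
reproducible.  Every stage writes its artifacts into the output directory and
records their digests in a run manifest; re-running with an unchanged
configuration skips stages whose recorded outputs are intact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, effects, fairness, mdp
from .cohort import (
    CohortConfig,
    EnvironmentParams,
    cohort_summary,
    generate_cohort,
    group_labels,
    simulate_cohort,
    split_cohort,
)
from .exceptions import ArgumentError
from .policies import BehaviorPolicy, GreedyPolicy
from .sarsa import EpsilonSchedule, QNetworkSpec, TrainConfig, train_sarsa
from .transition import (
    TransitionModel,
    TransitionModelSpec,
    calibration_report,
    fit_transition_model,
)

STAGES = (
    "generate",
    "split",
    "simulate",
    "train",
    "fit_transition",
    "evaluate",
    "fairness",
    "report",
)


@dataclass(frozen=True)
class EvaluationConfig:
    horizon: int = 12
    n_boot: int = 1000
    ci_level: float = 0.95
    #: minimum evaluation-cohort size for the paired rollouts: the held-out
    #: test split is augmented with freshly generated (hence equally held-out)
    #: patients up to this size, so the paired contrast is not limited by the
    #: 10% split's sampling noise
    min_eval_patients: int = 2000

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ArgumentError("evaluation horizon must be >= 0")
        if self.n_boot < 1:
            raise ArgumentError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ArgumentError("ci_level must be in (0, 1)")
        if self.min_eval_patients < 0:
            raise ArgumentError("min_eval_patients must be >= 0")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment: cohort, environment, reward, training and evaluation."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(n_patients=2000))
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    reward: mdp.RewardConfig = field(default_factory=mdp.RewardConfig)
    qnet: QNetworkSpec = field(default_factory=QNetworkSpec)
    #: pipeline default: on-policy training with per-epoch rollouts, validated
    #: on the simulated event rate of the greedy policy
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            batch_size=64, validation_metric="event_rate", max_epochs=40, patience=6,
            epsilon=EpsilonSchedule(end=0.05), lr_decay=0.93, n_restarts=3,
        )
    )
    #: pipeline default: 5-member ensemble for stable multi-step rollouts
    transition: TransitionModelSpec = field(
        default_factory=lambda: TransitionModelSpec(ensemble_members=5)
    )
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 42
    output_dir: str = "carepath_run"

    def validate(self) -> None:
        """Raise a structured error listing every violated field."""
        problems = []
        if self.cohort.n_patients <= 0:
            problems.append("cohort.n_patients must be positive for a pipeline run")
        if self.cohort.horizon <= 0:
            problems.append("cohort.horizon must be positive for a pipeline run")
        if problems:
            raise ArgumentError("invalid experiment config: " + "; ".join(problems))

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(digest[:8], 16) % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_jsonable(self), sort_keys=True).encode()
        ).hexdigest()

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = {}
        sections = {
            "cohort": CohortConfig,
            "env": EnvironmentParams,
            "reward": mdp.RewardConfig,
            "qnet": QNetworkSpec,
            "train": TrainConfig,
            "transition": TransitionModelSpec,
            "evaluation": EvaluationConfig,
        }
        for name, typ in sections.items():
            if name in raw:
                section = dict(raw[name])
                for key in ("hidden",):
                    if key in section and isinstance(section[key], list):
                        section[key] = tuple(section[key])
                if name == "train" and "epsilon" in section:
                    from .sarsa import EpsilonSchedule

                    section["epsilon"] = EpsilonSchedule(**section["epsilon"])
                if name == "env" and "behavior_action_bias" in section:
                    section["behavior_action_bias"] = tuple(section["behavior_action_bias"])
                kwargs[name] = typ(**section)
        for key in ("seed", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_jsonable(self), fh, sort_keys=True)


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p.name): _digest(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "version": self.version,
                       "stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        m = cls(raw["config_hash"], raw["version"])
        m.stages = raw["stages"]
        return m


def _stage_intact(manifest: RunManifest | None, stage: str, outdir: Path) -> bool:
    if manifest is None or stage not in manifest.stages:
        return False
    for name, digest in manifest.stages[stage]["outputs"].items():
        p = outdir / name
        if not p.exists() or _digest(p) != digest:
            return False
    return True


def run_pipeline(config: ExperimentConfig, resume: bool = True) -> RunManifest:
    """Execute every stage in order, writing artifacts and a run manifest.

    With ``resume=True``, stages whose recorded outputs are intact under the
    same configuration hash are skipped.  Any stage failure propagates with
    the stage named.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    prior = None
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        loaded = RunManifest.load(manifest_path)
        if loaded.config_hash == chash:
            prior = loaded
    manifest = RunManifest(chash, __version__)
    if prior is not None:
        manifest.stages = dict(prior.stages)

    ctx: dict = {}

    def run_stage(stage: str, fn, outputs: list[str]):
        paths = [outdir / name for name in outputs]
        if _stage_intact(prior, stage, outdir):
            fn(ctx, config, outdir, skip_write=True)
            return
        t0 = time.perf_counter()
        try:
            fn(ctx, config, outdir, skip_write=False)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, paths, time.perf_counter() - t0)
        manifest.save(manifest_path)

    run_stage("generate", _stage_generate, ["cohort.csv", "cohort_summary.csv"])
    run_stage("split", _stage_split, ["splits.json"])
    run_stage("simulate", _stage_simulate, ["trajectories.csv"])
    run_stage("train", _stage_train, ["model.ckpt.npz", "training_log.json"])
    run_stage("fit_transition", _stage_fit_transition,
              ["transition.ckpt.npz", "calibration.json"])
    run_stage("evaluate", _stage_evaluate, ["outcomes.csv", "effects.json"])
    run_stage("fairness", _stage_fairness, ["fairness.json"])
    run_stage("report", _stage_report, ["report.txt"])
    manifest.save(manifest_path)
    return manifest


# -- stages -----------------------------------------------------------------


def _stage_generate(ctx, config, outdir, skip_write):
    cohort = generate_cohort(
        replace(config.cohort, seed=config.stage_seed("generate")), config.env
    )
    ctx["cohort"] = cohort
    if not skip_write:
        cohort.to_csv(outdir / "cohort.csv", index=False)
        cohort_summary(cohort).to_csv(outdir / "cohort_summary.csv", index=False)


def _stage_split(ctx, config, outdir, skip_write):
    train, val, test = split_cohort(ctx["cohort"], seed=config.stage_seed("split"))
    ctx["splits"] = {"train": train, "validation": val, "test": test}
    if not skip_write:
        with open(outdir / "splits.json", "w") as fh:
            json.dump({k: v["patient_id"].tolist() for k, v in ctx["splits"].items()}, fh)


def _stage_simulate(ctx, config, outdir, skip_write):
    behavior = BehaviorPolicy.from_env(config.env)
    seed = config.stage_seed("simulate")
    ctx["traj_train"] = simulate_cohort(
        ctx["splits"]["train"], behavior, config.env, config.cohort.horizon,
        seed=seed, reward_cfg=config.reward,
    )
    ctx["traj_val"] = simulate_cohort(
        ctx["splits"]["validation"], behavior, config.env, config.cohort.horizon,
        seed=seed + 1, reward_cfg=config.reward,
    )
    if not skip_write:
        ctx["traj_train"].to_frame().to_csv(outdir / "trajectories.csv", index=False)


def _stage_train(ctx, config, outdir, skip_write):
    cfg = replace(config.train, seed=config.stage_seed("train"))
    qf, log = train_sarsa(
        ctx["traj_train"], config.qnet, cfg,
        validation=ctx["traj_val"],
        env=config.env,
        train_cohort=ctx["splits"]["train"],
        validation_cohort=ctx["splits"]["validation"],
        horizon=config.cohort.horizon,
        reward_cfg=config.reward,
    )
    ctx["qfunc"] = qf
    ctx["train_log"] = log
    if not skip_write:
        qf.save(outdir / "model.ckpt.npz", train_config=cfg)
        with open(outdir / "training_log.json", "w") as fh:
            json.dump(log, fh, indent=2)


def _stage_fit_transition(ctx, config, outdir, skip_write):
    # pool behavior-logged and exploratory trajectories so the dynamics model
    # has support over both evaluated policy regimes
    from .cohort import concat_batches
    from .policies import EpsilonGreedyPolicy

    seed = config.stage_seed("fit_transition")
    explore = simulate_cohort(
        ctx["splits"]["train"], EpsilonGreedyPolicy(ctx["qfunc"], 0.2), config.env,
        config.cohort.horizon, seed=seed + 1, reward_cfg=config.reward,
    )
    model = fit_transition_model(
        concat_batches(ctx["traj_train"], explore), config.transition, seed=seed
    )
    ctx["transition"] = model
    val = ctx["traj_val"]
    T = val.horizon
    S = val.states[:, :T].reshape(-1, val.states.shape[2])
    A = val.actions.reshape(-1)
    pred = model.event_probability(S, A)
    report = calibration_report(pred, val.events.reshape(-1).astype(float))
    ctx["calibration"] = report
    if not skip_write:
        model.save(outdir / "transition.ckpt.npz")
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)


def _stage_evaluate(ctx, config, outdir, skip_write):
    from .cohort import assign_tertiles

    seed = config.stage_seed("evaluate")
    test = ctx["splits"]["test"]
    ev = config.evaluation
    # augment the held-out split with freshly generated patients (equally
    # unseen by training) so the paired contrast reaches the configured size
    extra_n = max(0, ev.min_eval_patients - len(test))
    if extra_n:
        extra = generate_cohort(
            replace(config.cohort, n_patients=extra_n, seed=seed + 17), config.env
        )
        extra["patient_id"] = "G" + extra["patient_id"].astype(str)
        eval_cohort = pd.concat([test, extra], ignore_index=True)
        eval_cohort["risk_tertile"] = assign_tertiles(
            eval_cohort["risk_score"].to_numpy()
        )
    else:
        eval_cohort = test
    ctx["eval_cohort"] = eval_cohort
    behavior = BehaviorPolicy.from_env(config.env)
    greedy = GreedyPolicy(ctx["qfunc"])
    outcomes = effects.rollout_paired(
        eval_cohort, behavior, greedy, ctx["transition"], ev.horizon, seed
    )
    ctx["outcomes"] = outcomes
    est = effects.estimate_effects(outcomes, n_boot=ev.n_boot, level=ev.ci_level,
                                   seed=seed + 1)
    strat = effects.stratified_effects(outcomes, n_boot=ev.n_boot,
                                       level=ev.ci_level, seed=seed + 2)
    # doubly robust sensitivity analysis on the pooled per-arm outcomes
    from .features import STATE_FEATURES

    X0 = eval_cohort[list(STATE_FEATURES)].to_numpy(dtype=float)
    Xdr = np.vstack([X0, X0])
    arm = np.concatenate([
        np.zeros(len(eval_cohort), dtype=int), np.ones(len(eval_cohort), dtype=int)
    ])
    y = np.concatenate([
        outcomes["event_statusquo"].to_numpy(), outcomes["event_sarsa"].to_numpy()
    ])
    dr_point, dr_ci = effects.doubly_robust_ate(Xdr, arm, y, seed=seed + 3)
    ctx["effects"] = {
        "overall": _effect_dict(est),
        "stratified": {k: _effect_dict(v) for k, v in strat.items()},
        "doubly_robust_arr_pp": {"estimate": dr_point, "ci": list(dr_ci)},
    }
    if not skip_write:
        outcomes.to_csv(outdir / "outcomes.csv", index=False)
        with open(outdir / "effects.json", "w") as fh:
            json.dump(_to_jsonable_effects(ctx["effects"]), fh, indent=2)


def _effect_dict(est: effects.EffectEstimate) -> dict:
    d = {
        "n": est.n,
        "rate_statusquo": est.rate_statusquo,
        "rate_sarsa": est.rate_sarsa,
        "arr_pp": est.arr,
        "rrr_pct": est.rrr,
        "nnt": est.nnt,
        "nnh": est.nnh,
        "flagged_empty": est.flagged_empty,
        "rounded": est.rounded() if not est.flagged_empty else None,
    }
    if est.ci:
        d["ci"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in est.ci.items()}
    return d


def _to_jsonable_effects(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable_effects(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable_effects(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else ("inf" if v > 0 else "-inf")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _stage_fairness(ctx, config, outdir, skip_write):
    eval_cohort = ctx["eval_cohort"]
    labels = {
        "gender": group_labels(eval_cohort, "gender"),
        "race_ethnicity": group_labels(eval_cohort, "race_ethnicity"),
    }
    report = fairness.fairness_report(ctx["outcomes"], labels)
    ctx["fairness"] = report
    if not skip_write:
        with open(outdir / "fairness.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in report.items()}, fh, indent=2)


def _stage_report(ctx, config, outdir, skip_write):
    lines = []
    cohort = ctx["cohort"]
    lines.append(f"Cohort characteristics (N={len(cohort)})")
    lines.append("-" * 46)
    summary = cohort_summary(cohort)
    for _, row in summary.iterrows():
        lines.append(f"  {row['attribute']:<28s} {row['n']:>6d} ({row['pct']})")
    lines.append("")
    lines.append("Counterfactual effectiveness (paired rollouts, test set)")
    lines.append("-" * 56)
    overall = ctx["effects"]["overall"]
    r = overall["rounded"]
    lines.append(f"  Acute event rate, SARSA       {r['rate_sarsa_pct']}%")
    lines.append(f"  Acute event rate, status quo  {r['rate_statusquo_pct']}%")
    lines.append(f"  Absolute risk reduction       {r['arr_pp']} pp")
    lines.append(f"  Relative risk reduction       {r['rrr_pct']}%")
    lines.append(f"  Number needed to treat        {r['nnt']}")
    lines.append(f"  Number needed to harm         {r['nnh']}")
    lines.append("")
    lines.append("Risk-stratified number needed to treat")
    for tert in ("high", "medium", "low"):
        sub = ctx["effects"]["stratified"][tert]
        val = sub["rounded"]["nnt"] if sub["rounded"] else "n/a (empty stratum)"
        lines.append(f"  {tert:<8s} {val}")
    lines.append("")
    lines.append("Fairness (max pairwise event-rate disparity, %)")
    for attr, rep in ctx["fairness"].items():
        rel = f"{rep.relative_reduction:.1f}%" if rep.relative_reduction is not None else "n/a"
        lines.append(
            f"  {attr:<16s} SARSA {rep.disparity_sarsa:.1f} vs status quo "
            f"{rep.disparity_statusquo:.1f} (relative reduction {rel})"
        )
    text = "\n".join(lines) + "\n"
    ctx["report"] = text
    if not skip_write:
        (outdir / "report.txt").write_text(text)
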