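"""Pipeline orchestration: simulate -> extract -> model -> evaluate.

Each stage is idempotent, reads/writes plain CSV/JSON/WAV intermediates
under the configured output directory, and stamps the master seed into
every artifact so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .acoustics import MicrophoneModel, session_spl
from .cough_flow import CPSParams, DEFAULT_CPS_PARAMS, compute_cps
from .estimator import TrainConfig, nested_cv
from .reference_vc import DEFAULT_LMS_CONFIG, LMSConfig, lln, vc_lms
from .synthetic_data import CohortParams, ContaminationSpec, generate_cohort, synthesize_session_set
from .wavio import read_wav, write_wav

logger = logging.getLogger("coughvc")

__all__ = ["RunConfig", "run_simulate", "run_extract", "run_models", "run_report", "run_all"]

METHOD_COLUMNS = ("VC_LMS", "NNVC_SPL", "NNVC_CPS")


@dataclass
class RunConfig:
    out_dir: Path = Path("coughvc_out")
    audio_dir: Path | None = None  # default: out_dir / "audio"
    participants_csv: Path | None = None  # default: out_dir / "participants.csv"
    seed: int = 0
    mic: MicrophoneModel = field(default_factory=MicrophoneModel)
    band_low: float = 140.0
    band_high: float = 2000.0
    filter_order: int = 4
    segment_duration: float = 5.0
    cps_params: CPSParams = field(default_factory=lambda: DEFAULT_CPS_PARAMS)
    lms_config: LMSConfig = field(default_factory=lambda: DEFAULT_LMS_CONFIG)
    cohort_params: CohortParams = field(default_factory=CohortParams)
    fs: float = 100_000.0
    n_trials: int = 3
    trial_jitter_db: float = 1.0
    trial_duration: float = 20.0
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    h_grid: tuple[int, ...] = (1, 2, 3)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    feature_sets: tuple[str, ...] = ("CPS+VC_LMS", "SPL+VC_LMS")

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.audio_dir is None:
            self.audio_dir = self.out_dir / "audio"
        if self.participants_csv is None:
            self.participants_csv = self.out_dir / "participants.csv"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for key in ("out_dir", "audio_dir", "participants_csv"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        for key in ("band_low", "band_high", "fs", "trial_jitter_db",
                    "segment_duration", "trial_duration"):
            if key in raw:
                kwargs[key] = float(raw[key])
        for key in ("filter_order", "n_trials"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if "h_grid" in raw:
            kwargs["h_grid"] = tuple(int(h) for h in raw["h_grid"])
        if "feature_sets" in raw:
            kwargs["feature_sets"] = tuple(raw["feature_sets"])
        if "mic" in raw:
            kwargs["mic"] = MicrophoneModel(**raw["mic"])
        if "cps_params" in raw:
            kwargs["cps_params"] = CPSParams(**raw["cps_params"])
        if "cohort_params" in raw:
            kwargs["cohort_params"] = CohortParams(**raw["cohort_params"])
        if "contamination" in raw:
            kwargs["contamination"] = ContaminationSpec(**raw["contamination"])
        if "train_config" in raw:
            kwargs["train_config"] = TrainConfig(**raw["train_config"])
        kwargs.update(overrides)
        return cls(**kwargs)


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = cfg.seed
    return df


def run_simulate(cfg: RunConfig) -> pd.DataFrame:
    """Generate the cohort, write participants + truth CSVs and trial WAVs."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cfg.audio_dir.mkdir(parents=True, exist_ok=True)
    params = cfg.cohort_params
    if params.seed != cfg.seed:
        from dataclasses import replace

        params = replace(params, seed=cfg.seed)
    cohort = generate_cohort(params, cfg.cps_params, cfg.lms_config)
    participants = cohort[
        ["participant_id", "group", "sex", "age", "height", "weight", "measured_vc"]
    ]
    _stamp(participants, cfg).to_csv(cfg.participants_csv, index=False)
    truth = cohort[
        ["participant_id", "true_vc", "true_cpf", "target_spl", "below_lln"]
    ]
    _stamp(truth, cfg).to_csv(cfg.out_dir / "truth.csv", index=False)
    sessions = synthesize_session_set(
        cohort,
        cfg.mic,
        fs=cfg.fs,
        n_trials=cfg.n_trials,
        trial_jitter_db=cfg.trial_jitter_db,
        contamination=cfg.contamination,
        seed=cfg.seed,
        trial_duration=cfg.trial_duration,
    )
    for pid, trials in sessions.items():
        for trial in trials:
            write_wav(cfg.audio_dir / f"{pid}_trial{trial.trial_index}.wav", trial)
    logger.info("simulate: wrote %d participants", len(cohort))
    return cohort


def run_extract(cfg: RunConfig) -> pd.DataFrame:
    """Per participant: session SPL, CPS, VC_LMS, LLN -> features.csv.

    Participants whose sessions violate preconditions (fewer than three
    trials on disk, silent recordings) are excluded with a logged reason in
    exclusions.csv; the run continues.
    """
    participants = pd.read_csv(cfg.participants_csv)
    rows, exclusions = [], []
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        paths = sorted(cfg.audio_dir.glob(f"{pid}_trial*.wav"))
        try:
            trials = [read_wav(path) for path in paths]
            result = session_spl(
                trials,
                cfg.mic,
                low=cfg.band_low,
                high=cfg.band_high,
                order=cfg.filter_order,
                segment_duration=cfg.segment_duration,
            )
            cps = compute_cps(result.session_spl_db, float(p["age"]), cfg.cps_params)
            ref = vc_lms(p["sex"], float(p["height"]), float(p["age"]), cfg.lms_config)
            lower = lln(p["sex"], float(p["height"]), float(p["age"]), cfg.lms_config)
        except (ValueError, FileNotFoundError) as exc:
            exclusions.append({"participant_id": pid, "reason": str(exc)})
            logger.warning("extract: excluded %s (%s)", pid, exc)
            continue
        rows.append(
            {
                "participant_id": pid,
                "session_spl_db": result.session_spl_db,
                "trial_spl_db": ";".join(f"{v:.6f}" for v in result.per_trial_max_db),
                "cps": cps,
                "vc_lms": ref,
                "lln": lower,
                "measured_vc": float(p["measured_vc"]),
                "group": p.get("group", ""),
                "sex": p["sex"],
                "age": float(p["age"]),
            }
        )
    features = _stamp(pd.DataFrame(rows), cfg)
    features.to_csv(cfg.out_dir / "features.csv", index=False)
    _stamp(pd.DataFrame(exclusions, columns=["participant_id", "reason"]), cfg).to_csv(
        cfg.out_dir / "exclusions.csv", index=False
    )
    logger.info("extract: %d rows, %d exclusions", len(rows), len(exclusions))
    return features


def run_models(cfg: RunConfig, features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Nested-CV predictions for each configured feature-set variant plus
    the VC_LMS baseline -> predictions.csv."""
    if features is None:
        features = pd.read_csv(cfg.out_dir / "features.csv")
    if len(features) < 8:
        raise ValueError("need at least 8 feature rows to model")
    y = features["measured_vc"].to_numpy()
    out = features[
        ["participant_id", "group", "measured_vc", "vc_lms", "lln"]
    ].copy()
    out.rename(columns={"vc_lms": "VC_LMS"}, inplace=True)
    variant_features = {
        "CPS+VC_LMS": ("NNVC_CPS", features[["cps", "vc_lms"]].to_numpy()),
        "SPL+VC_LMS": ("NNVC_SPL", features[["session_spl_db", "vc_lms"]].to_numpy()),
    }
    for fset in cfg.feature_sets:
        column, X = variant_features[fset]
        result = nested_cv(
            X, y, H_grid=cfg.h_grid, seed=cfg.seed, hyper=cfg.train_config,
            feature_set=fset,
        )
        out[column] = result.predictions
        out[f"{column}_H"] = result.chosen_H
        logger.info("model %s: overall RMSE %.4f L", column, result.overall_rmse)
    out = _stamp(out, cfg)
    out.to_csv(cfg.out_dir / "predictions.csv", index=False)
    return out


def _method_block(measured: np.ndarray, predictions: pd.DataFrame, methods) -> dict:
    block: dict = {}
    sq = ev.squared_error_table(
        measured, {m: predictions[m].to_numpy() for m in methods}
    )
    block["squared_error"] = {
        "mean": sq.attrs["mean"],
        "median": sq.attrs["median"],
    }
    if len(methods) >= 3 and len(predictions) >= 2:
        stat, p = ev.friedman(sq.to_numpy())
        block["friedman"] = {"statistic": stat, "p": p}
        pairs, raw_p = [], []
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                _, wp = ev.wilcoxon_signed_rank(sq[a].to_numpy(), sq[b].to_numpy())
                pairs.append(f"{a} vs {b}")
                raw_p.append(wp)
        adj = ev.holm_adjust(raw_p)
        block["posthoc_holm"] = {
            pair: {"p_raw": pr, "p_holm": float(pa)}
            for pair, pr, pa in zip(pairs, raw_p, adj)
        }
    block["per_method"] = {}
    for m in methods:
        est = predictions[m].to_numpy()
        rho, rho_p = ev.spearman(measured, est)
        ba = ev.bland_altman(measured, est)
        block["per_method"][m] = {
            "spearman_rho": rho,
            "spearman_p": rho_p,
            "bland_altman": {
                "mean_diff": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "limits": list(ba.limits),
                "fixed_bias_p": ba.fixed_bias_p,
                "proportional_bias_r": ba.proportional_bias_r,
                "proportional_bias_p": ba.proportional_bias_p,
                "orientation": ba.orientation,
            },
        }
    return block


def run_report(cfg: RunConfig, predictions: pd.DataFrame | None = None) -> dict:
    """Full evaluation report JSON plus figure-data CSVs."""
    if predictions is None:
        predictions = pd.read_csv(cfg.out_dir / "predictions.csv")
    methods = [m for m in METHOD_COLUMNS if m in predictions.columns]
    measured = predictions["measured_vc"].to_numpy()
    report: dict = {
        "metadata": {
            "seed": cfg.seed,
            "methods": methods,
            "screening_score": "LLN - estimate; threshold 0 reproduces 'estimate < LLN'",
        },
        "overall": _method_block(measured, predictions, methods),
        "by_group": {},
    }
    for group, sub in predictions.groupby("group"):
        report["by_group"][str(group)] = _method_block(
            sub["measured_vc"].to_numpy(), sub, methods
        )

    lln_values = predictions["lln"].to_numpy()
    labels = measured < lln_values
    screening: dict = {"positive_definition": "measured VC < LLN"}
    nn_methods = [m for m in ("NNVC_SPL", "NNVC_CPS") if m in predictions.columns]
    if labels.any() and not labels.all():
        for m in nn_methods:
            scores = ev.screening_score(predictions[m].to_numpy(), lln_values)
            roc = ev.roc_auc(scores, labels)
            conf = ev.screening_confusion(predictions[m].to_numpy(), measured, lln_values)
            screening[m] = {"auc": roc.auc, **conf}
            pd.DataFrame(
                {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
            ).to_csv(cfg.out_dir / f"fig_roc_{m}.csv", index=False)
        if len(nn_methods) == 2:
            d = ev.delong_test(
                ev.screening_score(predictions[nn_methods[1]].to_numpy(), lln_values),
                ev.screening_score(predictions[nn_methods[0]].to_numpy(), lln_values),
                labels,
            )
            screening["delong"] = {
                "auc_cps": d.auc_a, "auc_spl": d.auc_b, "z": d.z, "p": d.p,
                "degenerate": d.degenerate,
            }
    else:
        screening["available"] = False
        screening["reason"] = "single-class labels; ROC section unavailable"
    report["screening"] = screening

    # figure-data exports
    long_rows = []
    for m in methods:
        for mv, e in zip(measured, predictions[m].to_numpy()):
            long_rows.append({"method": m, "measured_vc": mv, "estimate": e,
                              "squared_error": (e - mv) ** 2})
    pd.DataFrame(long_rows).to_csv(cfg.out_dir / "fig_squared_error.csv", index=False)
    for m in methods:
        est = predictions[m].to_numpy()
        pd.DataFrame(
            {"mean": (measured + est) / 2, "diff": measured - est}
        ).to_csv(cfg.out_dir / f"fig_bland_altman_{m}.csv", index=False)

    (cfg.out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_all(cfg: RunConfig) -> dict:
    run_simulate(cfg)
    features = run_extract(cfg)
    predictions = run_models(cfg, features)
    return run_report(cfg, predictions)
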