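"""Prediction-error metrics, quadrant summaries, and the full pipeline.

Per-dimension error is the 1-D Euclidean distance |predicted - observed| in
rating units.  Error percentage uses the 8-unit span of the 1-9 scale
(error% = 100 x mean error / 8) and accuracy% = 100 - error%.  RMSE is
computed on the (r - 1)/8 scaled space, alongside the Pearson correlation
between predicted and observed means.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ModelError, PhysioAffectError
from .features import FEATURES, build_feature_matrix
from .linear import correlation_table, predict_linear, stepwise_forward
from .mlp import (DEFAULT_TEST_EXCERPTS, DEFAULT_TRAIN_EXCERPTS, MLPConfig,
                  RATING_RANGE, rating_to_unit, run_trials)
from .contributions import ensemble_contributions, rm_anova, threshold_report
from .synthetic import EffectModel, ExcerptSpec, StudyDesign, generate_study

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionRecord:
    """Predicted vs. observed mean ratings of one excerpt.

    Observed means must lie on the 1-9 scale.  Predictions normally do too
    (sigmoid network outputs always do), but an unclipped regression model
    can leave the scale — that is reported as a (large) error, not rejected.
    """

    excerpt: str
    predicted_v: float
    predicted_a: float
    observed_v: float
    observed_a: float

    def __post_init__(self) -> None:
        for name, v in (("observed_v", self.observed_v), ("observed_a", self.observed_a)):
            if not (1.0 <= v <= 9.0):
                raise ModelError(f"{name}={v} outside the 1-9 rating scale")
        for name, v in (("predicted_v", self.predicted_v), ("predicted_a", self.predicted_a)):
            if not np.isfinite(v):
                raise ModelError(f"{name}={v} is not finite")


def dimension_error(predicted: float, observed: float) -> float:
    """Per-dimension 1-D Euclidean distance in rating units."""
    return abs(float(predicted) - float(observed))


@dataclass
class ErrorSummary:
    """Error/accuracy metrics for one rating dimension across excerpts."""

    dimension: str
    excerpts: list[str]
    per_excerpt_error: list[float]
    mean_error: float
    error_pct: float
    accuracy_pct: float
    rmse_scaled: float
    r: float | None
    r_squared: float | None


def _summarize_dim(dim: str, excerpts: list[str], pred: np.ndarray, obs: np.ndarray
                   ) -> ErrorSummary:
    errors = np.abs(pred - obs)
    mean_error = float(errors.mean())
    error_pct = 100.0 * mean_error / RATING_RANGE
    rmse = float(np.sqrt(((rating_to_unit(pred) - rating_to_unit(obs)) ** 2).mean()))
    if np.std(pred) == 0 or np.std(obs) == 0 or len(pred) < 3:
        r = rsq = None
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
        rsq = r * r
    return ErrorSummary(dimension=dim, excerpts=list(excerpts),
                        per_excerpt_error=[float(e) for e in errors],
                        mean_error=mean_error, error_pct=error_pct,
                        accuracy_pct=100.0 - error_pct, rmse_scaled=rmse,
                        r=r, r_squared=rsq)


def summarize_errors(records: list[PredictionRecord]) -> dict[str, ErrorSummary]:
    """Per-dimension summaries (valence/arousal) plus nothing else; the 2-D
    combined distance is available via :func:`combined_distances`."""
    if not records:
        raise ModelError("no prediction records")
    excerpts = [r.excerpt for r in records]
    pv = np.array([r.predicted_v for r in records])
    ov = np.array([r.observed_v for r in records])
    pa = np.array([r.predicted_a for r in records])
    oa = np.array([r.observed_a for r in records])
    return {"valence": _summarize_dim("valence", excerpts, pv, ov),
            "arousal": _summarize_dim("arousal", excerpts, pa, oa)}


def combined_distances(records: list[PredictionRecord]) -> np.ndarray:
    """Supplementary 2-D Euclidean distance in the valence-arousal plane."""
    return np.array([np.hypot(r.predicted_v - r.observed_v,
                              r.predicted_a - r.observed_a) for r in records])


def quadrant_means(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-quadrant means of excerpt mean valence/arousal.

    ``table`` needs columns ``quadrant``, ``mean_valence``, ``mean_arousal``.
    Values are kept at full precision; round for display.
    """
    from .synthetic import QUADRANTS
    unknown = set(table["quadrant"]) - set(QUADRANTS)
    if unknown:
        raise ModelError(f"unknown quadrant labels: {sorted(unknown)}")
    return table.groupby("quadrant")[["mean_valence", "mean_arousal"]].mean()


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectModel = field(default_factory=EffectModel)
    nn: MLPConfig = field(default_factory=MLPConfig)
    train_excerpts: tuple[str, ...] = DEFAULT_TRAIN_EXCERPTS
    test_excerpts: tuple[str, ...] = DEFAULT_TEST_EXCERPTS
    alpha_enter: float = 0.10
    alpha_keep: float = 0.15

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        design = d.get("design", {})
        excerpts = design.pop("excerpts", None)
        sd = StudyDesign(**design) if excerpts is None else StudyDesign(
            excerpts=[ExcerptSpec(**e) for e in excerpts], **design)
        nn_kwargs = dict(d.get("nn", {}))
        split = d.get("split", {})
        return cls(
            design=sd,
            effects=EffectModel(**d.get("effects", {})),
            nn=MLPConfig(**nn_kwargs),
            train_excerpts=tuple(split.get("train", DEFAULT_TRAIN_EXCERPTS)),
            test_excerpts=tuple(split.get("test", DEFAULT_TEST_EXCERPTS)),
            alpha_enter=d.get("alpha_enter", 0.10),
            alpha_keep=d.get("alpha_keep", 0.15),
        )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({
        "design": {**{k: v for k, v in asdict(config.design).items()}},
        "effects": asdict(config.effects),
        "nn": asdict(config.nn),
        "split": [config.train_excerpts, config.test_excerpts],
        "alpha": [config.alpha_enter, config.alpha_keep],
    }, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """simulate -> extract -> linear models -> network ensemble -> evaluate
    -> contributions; returns (and optionally writes) a report bundle."""
    stage = "validate"
    try:
        overlap = set(config.train_excerpts) & set(config.test_excerpts)
        if overlap:
            raise ModelError(f"train/test excerpt overlap: {sorted(overlap)}")

        stage = "simulate"
        trials, ratings = generate_study(config.design, config.effects)

        stage = "extract"
        features = build_feature_matrix(trials, ratings)

        stage = "linreg"
        corr = correlation_table(features)
        lin_models = {}
        lin_records = []
        tr_idx = list(config.train_excerpts)
        te_idx = list(config.test_excerpts)
        for dim, col in (("valence", "mean_valence"), ("arousal", "mean_arousal")):
            m = stepwise_forward(features.loc[tr_idx], features.loc[tr_idx, col].to_numpy(),
                                 target=dim, alpha_enter=config.alpha_enter,
                                 alpha_keep=config.alpha_keep)
            lin_models[dim] = m
        # regression output is deliberately unclipped: off-scale predictions
        # show up as large errors, mirroring how the comparison is reported
        lin_pred_v = predict_linear(lin_models["valence"], features.loc[te_idx])
        lin_pred_a = predict_linear(lin_models["arousal"], features.loc[te_idx])
        for i, e in enumerate(te_idx):
            lin_records.append(PredictionRecord(
                e, float(lin_pred_v[i]), float(lin_pred_a[i]),
                float(features.loc[e, "mean_valence"]), float(features.loc[e, "mean_arousal"])))

        stage = "train"
        ensemble = run_trials(features, config.nn, config.train_excerpts, config.test_excerpts)

        stage = "predict"
        nn_records = []
        for i, e in enumerate(te_idx):
            pv, pa = ensemble.mean_predictions[i]
            nn_records.append(PredictionRecord(
                e, float(pv), float(pa),
                float(features.loc[e, "mean_valence"]), float(features.loc[e, "mean_arousal"])))

        stage = "evaluate"
        nn_summary = summarize_errors(nn_records)
        lin_summary = summarize_errors(lin_records)
        qtable = pd.DataFrame({
            "quadrant": [e.quadrant for e in config.design.excerpts],
            "mean_valence": [features.loc[e.id, "mean_valence"] for e in config.design.excerpts],
            "mean_arousal": [features.loc[e.id, "mean_arousal"] for e in config.design.excerpts],
        }, index=[e.id for e in config.design.excerpts])
        qmeans = quadrant_means(qtable)

        stage = "contributions"
        contrib = ensemble_contributions(ensemble.weights)
        contrib_mean = pd.DataFrame({o: contrib[o].mean() for o in contrib})
        anova = {o: asdict(rm_anova(contrib[o].abs().to_numpy())) for o in contrib}
        report_thr = threshold_report(contrib_mean)
    except PhysioAffectError as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.design.seed,
        "features": features.reset_index().to_dict(orient="list"),
        "correlations": corr.to_dict(orient="list"),
        "linear_models": {d: m.to_dict() for d, m in lin_models.items()},
        "nn": {
            "converged_trials": int(sum(t.converged for t in ensemble.traces)),
            "n_trials": config.nn.n_trials,
            "final_mse": [t.final_mse for t in ensemble.traces],
            "predictions": {d.excerpt: [d.predicted_v, d.predicted_a] for d in nn_records},
            "summary": {k: asdict(v) for k, v in nn_summary.items()},
        },
        "linear": {
            "predictions": {d.excerpt: [d.predicted_v, d.predicted_a] for d in lin_records},
            "summary": {k: asdict(v) for k, v in lin_summary.items()},
        },
        "quadrant_means": qmeans.to_dict(orient="index"),
        "contributions": {
            "mean": contrib_mean.to_dict(orient="index"),
            "anova": anova,
            "above_null_threshold": {o: report_thr[o] for o in report_thr},
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv")
        pred_rows = []
        for rec_list, model in ((nn_records, "nn"), (lin_records, "linear")):
            for rcd in rec_list:
                pred_rows.append([model, rcd.excerpt, rcd.predicted_v, rcd.predicted_a,
                                  rcd.observed_v, rcd.observed_a])
        pd.DataFrame(pred_rows, columns=["model", "excerpt", "predicted_v", "predicted_a",
                                         "observed_v", "observed_a"]
                     ).to_csv(out / "predictions.csv", index=False)
        err_rows = []
        for model, summ in (("nn", nn_summary), ("linear", lin_summary)):
            for dim, s in summ.items():
                for e, err in zip(s.excerpts, s.per_excerpt_error):
                    err_rows.append([model, dim, e, err])
        pd.DataFrame(err_rows, columns=["model", "dimension", "excerpt", "error"]
                     ).to_csv(out / "errors.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
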