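"""Dilution-series evaluation and end-to-end pipeline orchestration.

The trained model is validated on a spike-in dilution series: patient
plasma mixed into healthy control plasma at known concentrations, so the
predicted tumour content should rise linearly with concentration. The
concordance is summarized by ordinary least squares of prediction on
concentration, both with a free intercept (R^2 about the mean) and
through the origin (R^2 with the uncentered total sum of squares — the
two conventions disagree and the choice is stated explicitly).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import betaboost, features, io_profiles, labels, stability

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionSeries:
    """Known spike-in concentrations and the model's predictions."""

    concentrations: np.ndarray
    predictions: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2:
            raise ValueError("need at least 2 dilution points")
        if np.unique(c).size != c.size:
            raise ValueError("concentrations must be distinct")
        if len(c) != len(self.predictions):
            raise ValueError("concentrations/predictions length mismatch")


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r2_with_intercept: float
    slope_through_origin: float
    r2_through_origin: float


def evaluate_dilution(series: DilutionSeries) -> RegressionReport:
    """OLS of prediction on concentration, with and without an intercept.

    ``r2_with_intercept = 1 - RSS/TSS`` with TSS about the mean;
    ``r2_through_origin = 1 - RSS0 / sum(y^2)`` (uncentered convention).
    """
    x = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.predictions, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("concentrations are constant")
    # with intercept
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    tss = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    # through the origin
    slope0 = float(np.sum(x * y) / np.sum(x * x))
    rss0 = float(np.sum((y - slope0 * x) ** 2))
    r2_0 = 1.0 - rss0 / float(np.sum(y * y))
    return RegressionReport(
        slope=slope,
        intercept=intercept,
        r2_with_intercept=r2,
        slope_through_origin=slope0,
        r2_through_origin=r2_0,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Seeds and tuning knobs for the full pipeline, all recorded."""

    seed: int = 0
    pseudocount: float = 0.5
    wavelet_levels: int = 6
    stability_B: int = 50
    pfer: float = 1.0
    cutoff: float = 0.75
    nu: float = 0.1
    mstop_grid: tuple[int, ...] = tuple(range(0, 501))
    cv_folds: int = 25
    crp_alpha: float = 1.0
    crp_iters: int = 2000
    epsilon: float = 1e-3


@dataclass
class PipelineResult:
    report: RegressionReport
    model: betaboost.BoostedBetaModel
    stability_result: stability.StabilityResult
    cv: betaboost.CvResult
    train_labels: pd.DataFrame
    predictions: pd.DataFrame


def _load_manifest(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    required = {
        "sample_id", "histogram_path", "label_source",
        "label_value_or_mutation_path",
    }
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: manifest missing columns "
                         f"{sorted(required - set(frame.columns))}")
    return frame


def _stage(name: str):
    """Context that prefixes any stage failure with the stage name."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return ctx()


def _sample_seed(root_seed: int, index: int) -> int:
    """Stable per-sample child seed below 2^31."""
    state = np.random.SeedSequence([root_seed, index]).generate_state(1)[0]
    return int(state % (2**31))


def pipeline_end_to_end(
    train_manifest: str,
    test_manifest: str,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the whole method from manifests to a dilution report.

    Stages: read histograms -> normalize -> extract Fourier/wavelet
    features -> curate labels (panel mutations clustered per sample for
    cohort A, surrogate values passed through for cohort B) -> stability
    selection on the surrogate-labelled cohort -> bootstrap-tuned
    boosting on the panel-labelled cohort restricted to the selected
    features -> predict the test samples -> regress predictions on the
    known concentrations.
    """
    train = _load_manifest(train_manifest)
    test = _load_manifest(test_manifest)

    with _stage("features"):
        profiles = {}
        for frame in (train, test):
            for row in frame.itertuples():
                hist = io_profiles.read_histogram(
                    row.histogram_path, row.sample_id
                )
                profiles[row.sample_id] = io_profiles.normalize(
                    hist, pseudocount=config.pseudocount
                )
        X_all = features.feature_matrix(
            list(profiles.values()), levels=config.wavelet_levels
        )

    with _stage("labels"):
        label_rows = []
        for idx, row in enumerate(train.itertuples()):
            if row.label_source == "panel":
                mutations = labels.read_mutations(
                    row.label_value_or_mutation_path
                )
                lab = labels.panel_label(
                    mutations,
                    alpha=config.crp_alpha,
                    iters=config.crp_iters,
                    seed=_sample_seed(config.seed, idx),
                    epsilon=config.epsilon,
                )
                label_rows.append(
                    {"sample_id": row.sample_id, "value": lab.value,
                     "source": "panel"}
                )
            elif row.label_source == "surrogate":
                value = float(row.label_value_or_mutation_path)
                if value <= 0.0:
                    logger.info("dropping zero surrogate label for %s",
                                row.sample_id)
                    continue
                value = min(max(value, config.epsilon), 1.0 - config.epsilon)
                label_rows.append(
                    {"sample_id": row.sample_id, "value": value,
                     "source": "surrogate"}
                )
            else:
                raise ValueError(
                    f"train sample {row.sample_id} has unsupported "
                    f"label_source {row.label_source!r}"
                )
        label_frame = pd.DataFrame(label_rows).set_index("sample_id")

    panel_ids = label_frame.index[label_frame["source"] == "panel"]
    surrogate_ids = label_frame.index[label_frame["source"] == "surrogate"]

    with _stage("stability selection"):
        if len(surrogate_ids) == 0:
            raise ValueError("no surrogate-labelled samples for selection")
        cfg = stability.StabilityConfig(
            B=config.stability_B, pfer=config.pfer, cutoff=config.cutoff,
            seed=config.seed, nu=config.nu,
        )
        stab = stability.run_stability(
            X_all.loc[surrogate_ids],
            label_frame.loc[surrogate_ids, "value"].to_numpy(),
            cfg,
        )
        selected = list(stab.selected)
        if not selected:
            top = max(stab.frequencies, key=stab.frequencies.get)
            warnings.warn(
                "stability selection returned no feature at the cutoff; "
                f"falling back to the most frequent feature {top!r}",
                stacklevel=2,
            )
            selected = [top]

    with _stage("tuning"):
        if len(panel_ids) < 2:
            raise ValueError("need at least 2 panel-labelled samples")
        X_train = X_all.loc[panel_ids, selected]
        y_train = label_frame.loc[panel_ids, "value"].to_numpy()
        cv = betaboost.tune_mstop(
            X_train, y_train, grid=list(config.mstop_grid),
            folds=config.cv_folds, seed=config.seed, nu=config.nu,
        )

    with _stage("training"):
        model = betaboost.fit_boost(
            X_train, y_train, nu=config.nu, mstop=cv.mstop_opt,
            seed=config.seed,
        )

    with _stage("prediction"):
        test_ids = list(test["sample_id"])
        preds = betaboost.predict(model, X_all.loc[test_ids, selected])
        predictions = pd.DataFrame(
            {"sample_id": test_ids, "prediction": preds}
        )

    with _stage("evaluation"):
        conc_rows = test[test["label_source"] == "concentration"]
        if len(conc_rows) < 2:
            raise ValueError("test manifest has < 2 concentration points")
        conc = conc_rows["label_value_or_mutation_path"].astype(float)
        pred_map = dict(zip(predictions["sample_id"],
                            predictions["prediction"]))
        series = DilutionSeries(
            concentrations=conc.to_numpy(),
            predictions=np.array(
                [pred_map[s] for s in conc_rows["sample_id"]]
            ),
        )
        report = evaluate_dilution(series)

    return PipelineResult(
        report=report,
        model=model,
        stability_result=stab,
        cv=cv,
        train_labels=label_frame.reset_index(),
        predictions=predictions,
    )
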