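"""Leave-one-subject-out (LOSO) orchestration and all reported metrics.

Every approach is evaluated with leave-one-subject-out cross-validation:
each fold holds out *all* recordings of one patient (normally the ON/OFF
pair) and fits everything else — embedding vocabularies, dimensionality
reductions, model grids, kNN pools and few-shot example pools — on the
remaining patients only, so no information about the held-out subject
leaks into training.

Metrics mirror the standard reporting for this problem: accuracy /
macro precision / recall / F1 and the ROC-AUC for classification; RMSE,
MAE (± SD), median and quartiles of the absolute error, Spearman's rho
and R² (plus per-true-state MAE) for score regression; Brier score, ECE
and MCE over 10 equal-width confidence bins for calibration.  The
positive class throughout is ON.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)

from . import __version__
from .corpus_io import Dataset, MedState, NFSItem, load_nfs_items
from .embed import EmbeddingMatrix, dense_backend, fit_ngram_backend, reduce
from .errors import NfspeechError
from .llm_harness import ensemble_predict, llm_backend, make_bundle, select_fewshot
from .ml_models import ModelSpec, fit as ml_fit, predict_class, predict_score
from .preprocess import DEFAULT_POLICY, NormalizationPolicy, prepare
from .semsearch import classify_by_vote, item_frequency_profile, predict_score_knn, rank_items

APPROACHES = ("semsearch", "ml", "llm")


# ---------------------------------------------------------------------------
# fold plan

@dataclass(frozen=True)
class Fold:
    held_out_patient: str
    test_recording_ids: tuple[str, ...]
    train_recording_ids: tuple[str, ...]

    @property
    def degenerate(self) -> bool:
        return len(self.train_recording_ids) == 0


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]


def make_loso_folds(dataset: Dataset) -> FoldPlan:
    """One fold per patient, ordered by patient id; the fold's test set
    is exactly that patient's recordings."""
    by_patient: dict[str, list[str]] = {}
    for t in dataset:
        by_patient.setdefault(t.patient_id, []).append(t.recording_id)
    folds = []
    all_ids = [t.recording_id for t in dataset]
    for pid in sorted(by_patient):
        test = tuple(by_patient[pid])
        train = tuple(rid for rid in all_ids if rid not in set(test))
        folds.append(Fold(held_out_patient=pid, test_recording_ids=test, train_recording_ids=train))
    return FoldPlan(folds=tuple(folds))


# ---------------------------------------------------------------------------
# metric reports

def _state_str(s) -> str:
    return s.value if isinstance(s, MedState) else str(s).upper()


@dataclass
class ClassificationReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    confusion: dict[str, dict[str, int]]
    n: int
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.roc_points is not None:
            d["roc_points"] = [[float(f), float(t)] for f, t in self.roc_points]
        return d


def classification_metrics(
    truth: Sequence, predicted: Sequence, confidence_on: Sequence[float] | None = None
) -> ClassificationReport:
    """Accuracy and macro-averaged precision/recall/F1 over {ON, OFF};
    trapezoidal ROC-AUC (ON positive) when confidences are supplied."""
    y_true = [_state_str(s) for s in truth]
    y_pred = [_state_str(s) for s in predicted]
    if len(y_true) != len(y_pred):
        raise ValueError("truth and predicted lengths differ")
    labels = ["ON", "OFF"]
    acc = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    confusion = {
        tl: {pl: int(cm[i, j]) for j, pl in enumerate(labels)} for i, tl in enumerate(labels)
    }
    report = ClassificationReport(
        accuracy=acc,
        precision_macro=float(prec),
        recall_macro=float(rec),
        f1_macro=float(f1),
        confusion=confusion,
        n=len(y_true),
    )
    if confidence_on is not None:
        if len(confidence_on) != len(y_true):
            raise ValueError("confidence_on length differs from truth")
        y_bin = np.array([1 if t == "ON" else 0 for t in y_true])
        if 0 < y_bin.sum() < len(y_bin):
            scores = np.asarray(confidence_on, dtype=float)
            fpr, tpr, _ = roc_curve(y_bin, scores)
            report.auc = float(roc_auc_score(y_bin, scores))
            report.roc_points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    return report


@dataclass
class RegressionReport:
    rmse: float
    mae: float
    mae_std: float
    median_ae: float
    q1_ae: float
    q3_ae: float
    n: int
    spearman_rho: float | None = None
    r2: float | None = None
    degenerate: bool = False  # constant truth: rho/R² undefined
    per_state_mae: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def regression_metrics(
    truth: Sequence[float],
    predicted: Sequence[float],
    states: Sequence | None = None,
) -> RegressionReport:
    """RMSE, MAE ± SD, median/quartile absolute errors (linear
    interpolation), Spearman's rho (average ranks on ties), R², and MAE
    split by true medication state."""
    y = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need two aligned score vectors of length >= 2")
    err = np.abs(y - p)
    q1, med, q3 = np.percentile(err, [25, 50, 75])
    report = RegressionReport(
        rmse=float(np.sqrt(np.mean((y - p) ** 2))),
        mae=float(err.mean()),
        mae_std=float(err.std(ddof=1)),
        median_ae=float(med),
        q1_ae=float(q1),
        q3_ae=float(q3),
        n=int(y.size),
    )
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0 or np.all(p == p[0]):
        report.degenerate = True
    if sstot > 0.0:
        report.r2 = float(1.0 - np.sum((y - p) ** 2) / sstot)
    with warnings.catch_warnings():
        # constant input handled via the degenerate flag, not a warning
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        rho = sps.spearmanr(y, p).statistic
    if not math.isnan(rho):
        report.spearman_rho = float(rho)
    else:
        report.degenerate = True
    if states is not None:
        st = [_state_str(s) for s in states]
        for state in ("ON", "OFF"):
            mask = np.array([s == state for s in st])
            if mask.any():
                report.per_state_mae[state] = float(err[mask].mean())
    return report


@dataclass
class CalibrationReport:
    brier: float
    ece: float
    mce: float
    bins: list[tuple[float, float, int]]  # (mean_confidence, empirical_accuracy, count)
    n: int
    n_bins: int

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["bins"] = [[float(c), float(a), int(n)] for c, a, n in self.bins]
        return d


def calibration_metrics(
    confidence_on: Sequence[float], truth: Sequence, n_bins: int = 10
) -> CalibrationReport:
    """Reliability analysis of the probability-of-ON.

    Equal-width bins on [0, 1]; per bin the empirical ON frequency is
    compared with the mean confidence.  Brier is the mean squared error
    of the confidence against the 0/1 outcome; ECE the count-weighted
    mean absolute bin gap; MCE the maximum gap over non-empty bins.
    """
    conf = np.asarray(confidence_on, dtype=float)
    if conf.size == 0:
        raise ValueError("empty confidence vector")
    if conf.min() < 0 or conf.max() > 1:
        raise ValueError("confidences must lie in [0, 1]")
    y = np.array([1.0 if _state_str(s) == "ON" else 0.0 for s in truth])
    if y.size != conf.size:
        raise ValueError("truth length differs from confidence length")
    brier = float(np.mean((conf - y) ** 2))
    idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    bins: list[tuple[float, float, int]] = []
    ece = 0.0
    mce = 0.0
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        mean_conf = float(conf[mask].mean())
        acc = float(y[mask].mean())
        gap = abs(acc - mean_conf)
        ece += (count / conf.size) * gap
        mce = max(mce, gap)
        bins.append((mean_conf, acc, count))
    return CalibrationReport(
        brier=brier, ece=float(ece), mce=float(mce), bins=bins, n=int(conf.size), n_bins=n_bins
    )


# ---------------------------------------------------------------------------
# LOSO orchestration

@dataclass(frozen=True)
class ApproachConfig:
    """Everything run_approach needs; hashable into the run manifest."""

    embed_backend: str = "mock"  # "mock" | "ngram"
    mock_dim: int = 256
    mock_seed: int = 0
    ngram_n_min: int = 1
    ngram_n_max: int = 3
    ngram_weighting: str = "count"
    reduce_method: str = "variance_pca"
    variance_threshold: float = 0.9
    reduce_global_fit: bool = False
    vote_k: int = 5
    knn_k: int = 5
    classify_family: str = "random_forest"
    regress_family: str = "random_forest"
    model_seed: int = 0
    llm_backend_name: str = "stub"
    llm_seed: int = 0
    shots_classify: int = 6
    shots_regress: int = 9
    n_paraphrases: int = 9
    calibration_bins: int = 10
    nfs_items_path: str | None = None

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FoldPrediction:
    """One held-out recording's predictions plus audit detail."""

    recording_id: str
    patient_id: str
    true_state: str
    true_score: float | None
    pred_state: str | None = None
    p_on: float | None = None
    pred_score: float | None = None
    detail: dict[str, Any] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    approach: str
    n_folds: int
    n_predictions: int
    manifest: dict[str, Any]
    classification: ClassificationReport | None = None
    regression: RegressionReport | None = None
    calibration: CalibrationReport | None = None
    item_frequency: dict[str, dict[int, float]] | None = None
    failed_folds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        def clean(obj):
            if isinstance(obj, float):
                return None if math.isnan(obj) else obj
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        d: dict[str, Any] = {
            "approach": self.approach,
            "n_folds": self.n_folds,
            "n_predictions": self.n_predictions,
            "manifest": self.manifest,
            "failed_folds": list(self.failed_folds),
        }
        for name in ("classification", "regression", "calibration"):
            block = getattr(self, name)
            if block is not None:
                d[name] = block.to_dict()
        if self.item_frequency is not None:
            d["item_frequency"] = self.item_frequency
        return clean(d)


def _make_backend(config: ApproachConfig, train_texts: list[str]):
    if config.embed_backend == "mock":
        return dense_backend("mock", dim=config.mock_dim, seed=config.mock_seed)
    if config.embed_backend == "ngram":
        return fit_ngram_backend(
            train_texts,
            n_min=config.ngram_n_min,
            n_max=config.ngram_n_max,
            weighting=config.ngram_weighting,
        )
    return dense_backend(config.embed_backend)


def _prepared_texts(dataset: Dataset, policy: NormalizationPolicy) -> dict[str, str]:
    return {t.recording_id: prepare(t.text, policy) for t in dataset}


def run_approach(
    approach: str,
    dataset: Dataset,
    config: ApproachConfig = ApproachConfig(),
    policy: NormalizationPolicy = DEFAULT_POLICY,
    items: Sequence[NFSItem] | None = None,
) -> tuple[list[FoldPrediction], EvaluationReport]:
    """Run one approach over all LOSO folds and aggregate the reports.

    Per fold, every fitted component (vocabulary, reduction, model grid,
    retrieval pool, few-shot pool) sees training rows only.  A stage
    error marks the fold failed and is surfaced in the report instead of
    aborting the run.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    plan = make_loso_folds(dataset)
    by_id = {t.recording_id: t for t in dataset}
    texts = _prepared_texts(dataset, policy)
    if approach == "semsearch" and items is None:
        items = load_nfs_items(config.nfs_items_path)
    item_texts = [prepare(it.text, policy) for it in items] if items else []

    predictions: list[FoldPrediction] = []
    vote_results = []
    vote_states = []
    failed: list[str] = []

    global_reduction = None
    if approach == "ml" and config.reduce_global_fit:
        backend = _make_backend(config, [texts[t.recording_id] for t in dataset])
        all_matrix = backend.embed(
            [texts[t.recording_id] for t in dataset], [t.recording_id for t in dataset]
        )
        global_reduction, _ = reduce(
            all_matrix, method=config.reduce_method, variance_threshold=config.variance_threshold
        )

    for fold in plan.folds:
        try:
            preds = _run_fold(
                approach, fold, by_id, texts, item_texts, items, config, global_reduction
            )
        except NfspeechError as exc:
            failed.append(f"{fold.held_out_patient}: {exc}")
            continue
        for p in preds:
            if "vote" in p.detail:
                vote_results.append(p.detail.pop("vote"))
                vote_states.append(p.true_state)
        predictions.extend(preds)

    manifest = {
        "approach": approach,
        "config_digest": config.digest(),
        "config": asdict(config),
        "package_version": __version__,
        "dataset_provenance": dataset.provenance,
        "n_patients": len(dataset.patient_ids),
        "n_recordings": len(dataset),
    }
    report = EvaluationReport(
        approach=approach,
        n_folds=len(plan.folds),
        n_predictions=len(predictions),
        manifest=manifest,
        failed_folds=failed,
    )
    labelled = [
        p for p in predictions if p.true_state in ("ON", "OFF") and p.pred_state is not None
    ]
    if labelled:
        confs = [p.p_on for p in labelled]
        report.classification = classification_metrics(
            [p.true_state for p in labelled],
            [p.pred_state for p in labelled],
            confidence_on=confs if all(c is not None for c in confs) else None,
        )
        if all(c is not None for c in confs):
            report.calibration = calibration_metrics(
                confs, [p.true_state for p in labelled], n_bins=config.calibration_bins
            )
    scored = [
        p for p in predictions if p.true_score is not None and p.pred_score is not None
    ]
    if len(scored) >= 2:
        report.regression = regression_metrics(
            [p.true_score for p in scored],
            [p.pred_score for p in scored],
            states=[p.true_state for p in scored],
        )
    if approach == "semsearch" and vote_results:
        report.item_frequency = item_frequency_profile(
            vote_results, [MedState(s) for s in vote_states]
        )
    return predictions, report


def _run_fold(
    approach, fold, by_id, texts, item_texts, items, config, global_reduction
) -> list[FoldPrediction]:
    train = [by_id[r] for r in fold.train_recording_ids]
    test = [by_id[r] for r in fold.test_recording_ids]
    assert all(t.patient_id != fold.held_out_patient for t in train), "leakage"
    train_texts = [texts[t.recording_id] for t in train]
    preds = [
        FoldPrediction(
            recording_id=t.recording_id,
            patient_id=t.patient_id,
            true_state=t.med_state.value,
            true_score=t.score,
        )
        for t in test
    ]

    if approach == "semsearch":
        backend = _make_backend(config, train_texts + list(item_texts))
        item_matrix = backend.embed(item_texts, [str(it.item_id) for it in items])
        pool_recs = [t for t in train if t.score is not None]
        pool_matrix = backend.embed(
            [texts[t.recording_id] for t in pool_recs],
            [t.recording_id for t in pool_recs],
        )
        test_matrix = backend.embed([texts[t.recording_id] for t in test],
                                    [t.recording_id for t in test])
        for i, (t, p) in enumerate(zip(test, preds)):
            ranked = rank_items(test_matrix.row(i), item_matrix, items)
            vote = classify_by_vote(ranked, k=config.vote_k)
            p.pred_state = vote.label.value
            p.p_on = vote.p_on
            p.detail["vote"] = vote
            p.detail["voter_item_ids"] = [v[0] for v in vote.voters]
            if pool_recs and config.knn_k <= len(pool_recs):
                score, neighbours = predict_score_knn(
                    test_matrix.row(i),
                    pool_matrix,
                    [t2.score for t2 in pool_recs],
                    [t2.patient_id for t2 in pool_recs],
                    k=config.knn_k,
                    exclude_patient=fold.held_out_patient,
                )
                p.pred_score = score
                p.detail["neighbour_ids"] = [n[0] for n in neighbours]
        return preds

    if approach == "ml":
        backend = _make_backend(config, train_texts)
        train_matrix = backend.embed(train_texts, [t.recording_id for t in train])
        test_matrix = backend.embed([texts[t.recording_id] for t in test],
                                    [t.recording_id for t in test])
        if global_reduction is not None:
            reduction = global_reduction
            train_red = reduction.transform(train_matrix)
        else:
            reduction, train_red = reduce(
                train_matrix,
                method=config.reduce_method,
                variance_threshold=config.variance_threshold,
            )
        test_red = reduction.transform(test_matrix)
        clf = ml_fit(
            ModelSpec(task="classify", family=config.classify_family, seed=config.model_seed),
            train_red,
            [t.med_state for t in train],
        )
        labels, p_on = predict_class(clf, test_red)
        scored_idx = [i for i, t in enumerate(train) if t.score is not None]
        reg = None
        if len(scored_idx) >= 5:
            train_scored = EmbeddingMatrix(
                vectors=np.asarray(train_red.vectors)[scored_idx],
                doc_ids=[train_red.doc_ids[i] for i in scored_idx],
                backend_name=train_red.backend_name,
            )
            reg = ml_fit(
                ModelSpec(task="regress", family=config.regress_family, seed=config.model_seed),
                train_scored,
                [train[i].score for i in scored_idx],
            )
            scores = predict_score(reg, test_red)
        for i, p in enumerate(preds):
            p.pred_state = labels[i].value
            p.p_on = float(p_on[i])
            if reg is not None:
                p.pred_score = float(scores[i])
            p.detail["chosen_hyperparameters"] = clf.chosen_hyperparameters
        return preds

    # llm
    backend = llm_backend(config.llm_backend_name, seed=config.llm_seed)
    sim_backend = dense_backend("mock", dim=config.mock_dim, seed=config.mock_seed)
    pool_matrix = sim_backend.embed(train_texts, [t.recording_id for t in train])
    scored_recs = [t for t in train if t.score is not None]
    scored_matrix = sim_backend.embed(
        [texts[t.recording_id] for t in scored_recs], [t.recording_id for t in scored_recs]
    )
    for t, p in zip(test, preds):
        qvec = sim_backend.embed_one(texts[t.recording_id])
        idx = select_fewshot(
            qvec,
            pool_matrix,
            [t2.patient_id for t2 in train],
            k=min(config.shots_classify, pool_matrix.n_docs),
            exclude_patient=fold.held_out_patient,
        )
        examples = [(train[i].text, train[i].med_state) for i in idx]
        bundle = make_bundle(
            "classify",
            examples,
            t.text,
            [train[i].recording_id for i in idx],
            query_id=t.recording_id,
            n_paraphrases=config.n_paraphrases,
        )
        out = ensemble_predict(backend, bundle)
        p.pred_state = out.final_label.value
        p.p_on = out.confidence_on
        p.detail["example_ids"] = list(bundle.example_ids)
        p.detail["parse_failures"] = out.parse_failures
        if scored_recs:
            ridx = select_fewshot(
                qvec,
                scored_matrix,
                [t2.patient_id for t2 in scored_recs],
                k=min(config.shots_regress, scored_matrix.n_docs),
                exclude_patient=fold.held_out_patient,
            )
            rexamples = [(scored_recs[i].text, scored_recs[i].score) for i in ridx]
            rbundle = make_bundle(
                "regress",
                rexamples,
                t.text,
                [scored_recs[i].recording_id for i in ridx],
                query_id=t.recording_id,
                n_paraphrases=config.n_paraphrases,
            )
            rout = ensemble_predict(backend, rbundle)
            p.pred_score = rout.final_score
            p.detail["regress_example_ids"] = list(rbundle.example_ids)
    return preds
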