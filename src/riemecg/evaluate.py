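"""CPET outcome grouping, stratified patient leave-out evaluation, models
and metrics.

The protocol mirrors small-cohort clinical ML practice: the cohort is split
100 times, each split holding out exactly one randomly chosen patient per
lesion class as the test set (all of that patient's records leave the
training set), and metric means +/- standard deviations are reported over
the repeats.  Every fold-dependent fit — the tangent reference mean, the
text vocabulary, feature standardisation, augmentation pairs — uses
training patients only.

CPET labels are used two ways: directly (regression on VE/VCO2, VO2 %pred,
VO2 peak) and discretised into clinical groups (2/4/2 groups respectively)
for classification.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from . import geometry
from .augment import FusedSample, MixConfig, augment_regression, balance_classes, upsample_baseline
from .ecg import basic_interval_features, read_ecg_csv, record_covariance
from .text import (
    ClinicalHistory,
    TextMissingError,
    build_vocabulary,
    corpus_matrix,
    link_nearest_date,
    read_clinical_csv,
    vectorize,
)

__all__ = [
    "CpetOutcome",
    "GroupingScheme",
    "SplitPlan",
    "MetricReport",
    "ModelConfig",
    "PatientEntry",
    "CohortDataset",
    "ARMS",
    "OUTCOME_LABELS",
    "group_cpet",
    "make_split_plan",
    "fit_predict",
    "r_squared",
    "adjusted_r_squared",
    "rmse",
    "pearson_r",
    "classification_metrics",
    "run_ablation",
    "read_cpet_csv",
    "write_cpet_csv",
]

OUTCOME_LABELS = ("ve_vco2", "vo2_pred_pct", "vo2_peak")

ARMS = (
    "ecg_params_baseline",
    "tangent_ecg",
    "tangent_ecg+cov_aug",
    "tangent_ecg+text",
    "tangent_ecg+text+cov_aug",
    "tangent_ecg+text+cov_aug_ecg_upsample_text",
)


@dataclass
class CpetOutcome:
    """One cardiopulmonary exercise test result for a patient."""

    patient_id: str
    test_date: _dt.date
    ve_vco2: float
    vo2_pred_pct: float
    vo2_peak: float

    def __post_init__(self) -> None:
        if isinstance(self.test_date, str):
            self.test_date = _dt.date.fromisoformat(self.test_date)
        if not self.ve_vco2 > 0:
            raise ValueError(f"VE/VCO2 must be positive, got {self.ve_vco2}")
        if not 0 < self.vo2_pred_pct < 200:
            raise ValueError(f"VO2 %pred out of range (0, 200): {self.vo2_pred_pct}")
        if not self.vo2_peak > 0:
            raise ValueError(f"VO2 peak must be positive, got {self.vo2_peak}")

    def value(self, label: str) -> float:
        if label not in OUTCOME_LABELS:
            raise KeyError(f"unknown outcome label {label!r}; expected one of {OUTCOME_LABELS}")
        return float(getattr(self, label))


@dataclass(frozen=True)
class GroupingScheme:
    """Clinical group cuts for the three CPET labels.

    VE/VCO2 and VO2 peak each split into two groups; VO2 %pred into four.
    Boundary values go to the upper group (x >= cut).  The defaults place
    the VE/VCO2 cut at the top of its normal range (20-30) and the central
    VO2 %pred cuts at its normal range (60-85%); ``vo2_peak_cut`` defaults
    to None and is taken as the training-fold median at evaluation time
    (no clinically printed L/min threshold exists).
    """

    ve_vco2_cut: float = 30.0
    vo2_peak_cut: float | None = None
    vo2_pred_cuts: tuple[float, float, float] = (45.0, 60.0, 85.0)

    def __post_init__(self) -> None:
        cuts = self.vo2_pred_cuts
        if not (len(cuts) == 3 and cuts[0] < cuts[1] < cuts[2]):
            raise ValueError("vo2_pred_cuts must be three strictly ascending thresholds")


def _cut_group(x: float, cuts) -> int:
    return int(sum(float(x) >= float(c) for c in cuts))


def group_cpet(o: CpetOutcome, scheme: GroupingScheme) -> dict[str, int]:
    """Discretise one outcome into its three clinical group labels."""
    if scheme.vo2_peak_cut is None:
        raise ValueError("vo2_peak_cut unset; supply one (e.g. the training-fold median)")
    return {
        "ve_vco2": _cut_group(o.ve_vco2, [scheme.ve_vco2_cut]),
        "vo2_pred_pct": _cut_group(o.vo2_pred_pct, scheme.vo2_pred_cuts),
        "vo2_peak": _cut_group(o.vo2_peak, [scheme.vo2_peak_cut]),
    }


# ---------------------------------------------------------------------------
# split protocol


@dataclass(frozen=True)
class SplitPlan:
    """Stratified patient leave-out plan: per repeat, one test patient per class."""

    n_repeats: int
    seed: int
    splits: tuple  # tuple of (train_ids frozenset, test_ids frozenset)

    def __iter__(self):
        return iter(self.splits)


def make_split_plan(class_by_patient: dict, n_repeats: int = 100, seed: int = 0) -> SplitPlan:
    """Build the repeated stratified leave-out plan.

    Every repeat draws exactly one patient uniformly from each class for
    the test set; the rest train.  Deterministic under ``seed``; the same
    plan object is reused across every ablation arm so comparisons are
    paired.
    """
    classes: dict = {}
    for pid, cls in class_by_patient.items():
        classes.setdefault(cls, []).append(pid)
    for cls, pids in classes.items():
        if len(pids) < 2:
            raise ValueError(f"class {cls!r} has {len(pids)} patient(s); need >= 2 for leave-out")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    order = sorted(classes, key=repr)
    splits = []
    all_ids = frozenset(class_by_patient)
    for _ in range(n_repeats):
        test = frozenset(str(rng.choice(sorted(classes[cls]))) for cls in order)
        splits.append((all_ids - test, test))
    return SplitPlan(n_repeats=n_repeats, seed=seed, splits=tuple(splits))


# ---------------------------------------------------------------------------
# metrics


def _check_lengths(y, yhat, minimum: int = 2):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < minimum:
        raise ValueError(f"need at least {minimum} observations, got {y.size}")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSR/SST; may be negative.

    Returns NaN (with a warning) when y has zero variance (SST = 0).
    """
    y, yhat = _check_lengths(y, yhat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("R^2 undefined: zero variance in y", RuntimeWarning, stacklevel=2)
        return float("nan")
    ssr = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssr / sst


def adjusted_r_squared(y, yhat, p: int) -> float:
    """Adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1); NaN when n <= p + 1."""
    y, yhat = _check_lengths(y, yhat, minimum=2)
    n = y.size
    if n - p - 1 <= 0:
        warnings.warn(f"adjusted R^2 undefined for n={n}, p={p}", RuntimeWarning, stacklevel=2)
        return float("nan")
    r2 = r_squared(y, yhat)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = _check_lengths(y, yhat, minimum=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson_r(y, yhat) -> float:
    """Pearson correlation coefficient; NaN if either side is constant."""
    y, yhat = _check_lengths(y, yhat)
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        warnings.warn("pearson r undefined: constant input", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def macro_ovr_auc(y, scores, classes) -> float:
    """Macro one-vs-rest ROC AUC on decision scores.

    Binary problems use the positive-class score directly.  Classes absent
    from ``y`` (or present alone) are skipped; if nothing is scoreable the
    result is NaN and the caller excludes the repeat from AUC aggregation.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    classes = list(classes)
    if len(classes) == 2 and scores.ndim == 1:
        if len(set(y.tolist())) < 2:
            return float("nan")
        return float(roc_auc_score((y == classes[1]).astype(int), scores))
    aucs = []
    for k, cls in enumerate(classes):
        ind = (y == cls).astype(int)
        if ind.min() == ind.max():
            continue
        aucs.append(roc_auc_score(ind, scores[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def classification_metrics(y, yhat, scores=None, classes=None) -> dict[str, float]:
    """Accuracy, macro-OVR AUC and macro F1 for one evaluation fold."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    out = {
        "accuracy": float(accuracy_score(y, yhat)),
        "f1_macro": float(f1_score(y, yhat, average="macro", zero_division=0)),
    }
    if scores is not None and classes is not None:
        out["auc"] = macro_ovr_auc(y, scores, classes)
    else:
        out["auc"] = float("nan")
    return out


@dataclass
class MetricReport:
    """Per-repeat values of one metric with their mean +/- std summary."""

    name: str
    task: str
    values: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    @property
    def n_valid(self) -> int:
        return int(self.valid.size)

    @property
    def mean(self) -> float:
        return float(self.valid.mean()) if self.n_valid else float("nan")

    @property
    def std(self) -> float:
        return float(self.valid.std()) if self.n_valid else float("nan")


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ModelConfig:
    """Predictor settings.

    ``kind='svm'`` is the primary model (RBF kernel, C=1, epsilon=0.1 for
    regression); ``kind='baseline'`` is ordinary least squares for
    continuous labels and logistic regression for grouped labels.
    Features are standardised per training fold.
    """

    kind: str = "svm"
    C: float = 1.0
    epsilon: float = 0.1
    kernel: str = "rbf"
    gamma: str | float = "scale"
    standardize: bool = True

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "C": self.C,
            "epsilon": self.epsilon,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def fit_predict(train_X, train_y, test_X, task: str, cfg: ModelConfig | None = None, *, n_scaler_fit: int | None = None):
    """Fit the configured model on the training fold and predict the test fold.

    Returns ``(predictions, scores, classes)``; ``scores`` are decision
    values for classification (None for regression), ``classes`` the fitted
    class order (None for regression).  ``n_scaler_fit`` restricts the
    standardiser fit to the first rows (the original, non-augmented samples)
    so augmentation cannot shift the feature scaling.
    """
    cfg = cfg or ModelConfig()
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[0] == 0:
        raise ValueError("empty training fold")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError(f"feature dimension mismatch: {train_X.shape[1]} vs {test_X.shape[1]}")
    if cfg.standardize:
        fit_rows = train_X if n_scaler_fit is None else train_X[:n_scaler_fit]
        scaler = StandardScaler().fit(fit_rows)
        # constant columns: leave scale 1 to avoid division blow-ups
        scaler.scale_[scaler.scale_ == 0.0] = 1.0
        train_X = scaler.transform(train_X)
        test_X = scaler.transform(test_X)
    if task == "regression":
        y = np.asarray(train_y, dtype=float)
        model = (
            SVR(kernel=cfg.kernel, C=cfg.C, epsilon=cfg.epsilon, gamma=cfg.gamma)
            if cfg.kind == "svm"
            else LinearRegression()
        )
        model.fit(train_X, y)
        return model.predict(test_X), None, None
    if task == "classification":
        y = np.asarray(train_y)
        if len(set(y.tolist())) < 2:
            raise ValueError("degenerate single-class training fold")
        model = (
            SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
            if cfg.kind == "svm"
            else LogisticRegression(max_iter=1000)
        )
        model.fit(train_X, y)
        return model.predict(test_X), model.decision_function(test_X), list(model.classes_)
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class PatientEntry:
    """One ECG record with its linked clinical document and CPET outcome."""

    patient_id: str
    class_id: object
    cov: np.ndarray
    scalar_features: np.ndarray
    doc: ClinicalHistory | None
    outcome: CpetOutcome
    ecg_date: _dt.date | None = None


@dataclass
class CohortDataset:
    """Patients x (ECG covariance, text, CPET outcome) with split bookkeeping."""

    entries: list[PatientEntry] = field(default_factory=list)

    @property
    def patient_ids(self) -> list[str]:
        return sorted({e.patient_id for e in self.entries})

    @property
    def class_by_patient(self) -> dict:
        return {e.patient_id: e.class_id for e in self.entries}

    def entries_for(self, pids) -> list[PatientEntry]:
        pids = set(pids)
        return [e for e in self.entries if e.patient_id in pids]

    @classmethod
    def build(
        cls,
        records,
        class_by_patient: dict,
        histories,
        outcomes,
        *,
        use_aligned: bool = True,
        window_seconds: float = 1.0,
        align_offset: float = 0.4,
        shrinkage: float = 0.01,
    ) -> "CohortDataset":
        """Assemble a dataset from ingested components.

        For every ECG record: estimate the covariance, compute scalar rhythm
        features, and link the nearest-in-date clinical document and CPET
        outcome for that patient.  Patients without any CPET outcome are
        skipped (no label); patients without documents are kept with
        ``doc=None`` ("text-missing").
        """
        docs_by_pid: dict[str, list] = {}
        for h in histories:
            docs_by_pid.setdefault(h.patient_id, []).append(h)
        cpet_by_pid: dict[str, list] = {}
        for o in outcomes:
            cpet_by_pid.setdefault(o.patient_id, []).append(o)
        entries = []
        for rec in records:
            pid = rec.patient_id
            if pid not in cpet_by_pid:
                continue
            cov = record_covariance(
                rec,
                use_aligned=use_aligned,
                window_seconds=window_seconds,
                align_offset=align_offset,
                shrinkage=shrinkage,
            )
            feats = basic_interval_features(rec)
            ecg_date = rec.record_date or _dt.date(2000, 1, 1)
            outs = cpet_by_pid[pid]
            outcome = min(outs, key=lambda o: (abs((o.test_date - ecg_date).days), o.test_date))
            try:
                doc = link_nearest_date(ecg_date, docs_by_pid.get(pid, []))
            except TextMissingError:
                doc = None
            entries.append(
                PatientEntry(
                    patient_id=pid,
                    class_id=class_by_patient[pid],
                    cov=cov,
                    scalar_features=np.array(
                        [feats["vent_rate_bpm"], feats["rr_std_s"], feats["r_amplitude_mv"]]
                    ),
                    doc=doc,
                    outcome=outcome,
                    ecg_date=ecg_date,
                )
            )
        return cls(entries=entries)

    @classmethod
    def from_directory(cls, path, **build_kwargs) -> "CohortDataset":
        """Load a generated cohort directory (records.csv manifest + CSVs)."""
        path = Path(path)
        manifest = pd.read_csv(path / "records.csv", dtype=str)
        records = []
        class_by_patient = {}
        for _, row in manifest.iterrows():
            rec = read_ecg_csv(
                path / row["ecg_file"],
                fs=float(row.get("fs", 500.0)),
                patient_id=row["patient_id"],
                record_date=_dt.date.fromisoformat(row["ecg_date"]),
            )
            records.append(rec)
            class_by_patient[row["patient_id"]] = row["class_id"]
        histories = read_clinical_csv(path / "clinical.csv")
        outcomes = read_cpet_csv(path / "cpet.csv")
        return cls.build(records, class_by_patient, histories, outcomes, **build_kwargs)


def read_cpet_csv(path) -> list[CpetOutcome]:
    """Read the CPET outcome table (patient_id, test_date, ve_vco2, vo2_pred_pct, vo2_peak)."""
    df = pd.read_csv(path)
    need = {"patient_id", "test_date", "ve_vco2", "vo2_pred_pct", "vo2_peak"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CpetOutcome(
            patient_id=str(r.patient_id),
            test_date=str(r.test_date),
            ve_vco2=float(r.ve_vco2),
            vo2_pred_pct=float(r.vo2_pred_pct),
            vo2_peak=float(r.vo2_peak),
        )
        for r in df.itertuples()
    ]


def write_cpet_csv(outcomes, path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "test_date": o.test_date.isoformat(),
                "ve_vco2": o.ve_vco2,
                "vo2_pred_pct": o.vo2_pred_pct,
                "vo2_peak": o.vo2_peak,
            }
            for o in outcomes
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ablation harness


def _needs_text(arm: str) -> bool:
    return "text" in arm


def _assert_no_leakage(samples, train_ids, test_ids) -> None:
    """Every sample (incl. augmentation sources) must come from training patients."""
    train_ids = set(train_ids)
    test_ids = set(test_ids)
    for s in samples:
        srcs = set(s.source_ids)
        if srcs & test_ids or not srcs <= train_ids:
            raise AssertionError(f"leakage: sample sources {srcs} not within training fold")


def _aggregate_by_patient(pids, pred, scores, task):
    """Per-patient prediction = mean of that patient's record-level outputs.

    Classification averages decision scores then takes the arg-max class by
    score (majority vote when no scores are available).
    """
    pids = np.asarray(pids)
    uniq = sorted(set(pids.tolist()))
    agg_pred, agg_scores = [], []
    for pid in uniq:
        m = pids == pid
        if task == "regression":
            agg_pred.append(float(np.mean(np.asarray(pred)[m])))
        else:
            if scores is not None:
                agg_scores.append(np.mean(np.asarray(scores)[m], axis=0))
            vals, counts = np.unique(np.asarray(pred)[m], return_counts=True)
            agg_pred.append(vals[np.argmax(counts)])
    scores_out = np.array(agg_scores) if agg_scores else None
    return uniq, np.asarray(agg_pred), scores_out


def _arm_matrix(entries_feats, arm):
    """Stack the feature matrix for an arm from per-entry feature dicts."""
    cols = []
    for f in entries_feats:
        if arm == "ecg_params_baseline":
            cols.append(f["scalar"])
        elif arm == "tangent_ecg" or arm == "tangent_ecg+cov_aug":
            cols.append(f["tangent"])
        else:
            cols.append(np.concatenate([f["tangent"], f["text"]]))
    return np.array(cols, dtype=float)


def run_ablation(
    dataset: CohortDataset,
    plan: SplitPlan,
    task: str,
    labels=OUTCOME_LABELS,
    arms=("tangent_ecg", "tangent_ecg+text", "tangent_ecg+text+cov_aug"),
    *,
    scheme: GroupingScheme | None = None,
    model: ModelConfig | None = None,
    mix: MixConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the paired ablation over the shared split plan.

    Returns one row per arm x label x metric with mean, std and the number
    of repeats for which the metric was defined.  All arms of one call see
    identical train/test patient sets per repeat; repeats whose training
    fold degenerates to a single class are skipped and counted out of
    ``n_valid_repeats``.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    unknown = [a for a in arms if a not in ARMS]
    if unknown:
        raise ValueError(f"unknown arms {unknown}; choose from {ARMS}")
    labels = [labels] if isinstance(labels, str) else list(labels)
    scheme = scheme or GroupingScheme()
    model = model or ModelConfig()
    mix = mix or MixConfig()

    entries = list(dataset.entries)
    if any(_needs_text(a) for a in arms):
        missing = sorted({e.patient_id for e in entries if e.doc is None})
        if missing:
            warnings.warn(
                f"dropping {len(missing)} text-missing patient(s) from ALL arms for paired comparability",
                RuntimeWarning,
                stacklevel=2,
            )
            entries = [e for e in entries if e.patient_id not in missing]
    by_pid: dict[str, list[PatientEntry]] = {}
    for e in entries:
        by_pid.setdefault(e.patient_id, []).append(e)

    metric_values: dict[tuple, list] = {}

    for r, (train_ids, test_ids) in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        train_e = [e for pid in sorted(train_ids & set(by_pid)) for e in by_pid[pid]]
        test_e = [e for pid in sorted(test_ids & set(by_pid)) for e in by_pid[pid]]
        if not train_e or not test_e:
            continue

        # fold-level fits: tangent reference and vocabulary from train only
        ref = geometry.frechet_mean([e.cov for e in train_e])
        docs_train = [e.doc for e in train_e if e.doc is not None]
        vocab = build_vocabulary(docs_train) if docs_train else None

        def feats(e: PatientEntry) -> dict:
            f = {"tangent": geometry.tangent_project(e.cov, ref), "scalar": e.scalar_features}
            if vocab is not None and e.doc is not None:
                f["text"] = vectorize(e.doc, vocab).astype(float)
            return f

        train_f = [feats(e) for e in train_e]
        test_f = [feats(e) for e in test_e]

        train_vo2_peak = [e.outcome.vo2_peak for e in train_e]
        fold_scheme = scheme
        if task == "classification" and scheme.vo2_peak_cut is None:
            fold_scheme = GroupingScheme(
                ve_vco2_cut=scheme.ve_vco2_cut,
                vo2_peak_cut=float(np.median(train_vo2_peak)),
                vo2_pred_cuts=scheme.vo2_pred_cuts,
            )

        for lab in labels:
            if task == "regression":
                y_train = np.array([e.outcome.value(lab) for e in train_e])
                y_test_by_pid = {
                    pid: float(np.mean([e.outcome.value(lab) for e in by_pid[pid]]))
                    for pid in sorted(test_ids & set(by_pid))
                }
            else:
                y_train = np.array([group_cpet(e.outcome, fold_scheme)[lab] for e in train_e])
                y_test_by_pid = {
                    pid: group_cpet(by_pid[pid][0].outcome, fold_scheme)[lab]
                    for pid in sorted(test_ids & set(by_pid))
                }

            for arm in arms:
                samples = [
                    FusedSample(
                        patient_id=e.patient_id,
                        cov=e.cov,
                        tangent=f["tangent"],
                        text=f.get("text"),
                        label=y_train[i],
                        )
                    for i, (e, f) in enumerate(zip(train_e, train_f))
                ]
                # one augmentation stream per repeat, shared by every arm, so
                # paired arms see identical pairs and alphas and differ only
                # in their stated policy (e.g. text mixing vs duplication)
                arm_rng = np.random.default_rng(np.random.SeedSequence([seed, r, 17]))
                if "cov_aug" in arm:
                    text_policy = "duplicate" if "upsample_text" in arm else "mix"
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        if task == "classification":
                            samples = balance_classes(
                                samples, mix, arm_rng, reference=ref, text_policy=text_policy
                            )
                        else:
                            samples = augment_regression(
                                samples, len(samples), mix, arm_rng,
                                reference=ref, text_policy=text_policy,
                            )
                _assert_no_leakage(samples, train_ids, test_ids)

                feat_dicts = [
                    {"tangent": s.tangent, "scalar": train_f[i]["scalar"] if i < len(train_f) else None, "text": s.text}
                    for i, s in enumerate(samples)
                ]
                if arm == "ecg_params_baseline":
                    # augmentation does not apply to scalar vendor-style features
                    feat_dicts = [{"scalar": f["scalar"]} for f in train_f]
                    y_arm = y_train
                else:
                    y_arm = np.array([s.label for s in samples])
                X_train = _arm_matrix(feat_dicts, arm)
                X_test = _arm_matrix(test_f, arm)
                arm_model = ModelConfig(kind="baseline", standardize=model.standardize) if arm == "ecg_params_baseline" else model

                key = (arm, lab)
                n_orig = len(train_f) if arm != "ecg_params_baseline" else None
                try:
                    pred, scores, classes = fit_predict(
                        X_train, y_arm, X_test, task, arm_model, n_scaler_fit=n_orig
                    )
                except ValueError:
                    metric_values.setdefault(key, []).append(None)  # skipped repeat
                    continue
                pids_test = [e.patient_id for e in test_e]
                uniq, agg_pred, agg_scores = _aggregate_by_patient(pids_test, pred, scores, task)
                y_true = np.array([y_test_by_pid[pid] for pid in uniq])
                if task == "regression":
                    met = {"pred": agg_pred, "true": y_true}
                else:
                    met = classification_metrics(y_true, agg_pred, agg_scores, classes)
                metric_values.setdefault(key, []).append(met)

    return _summarise(metric_values, task, plan.n_repeats)


def _summarise(metric_values: dict, task: str, n_repeats: int) -> pd.DataFrame:
    rows = []
    for (arm, lab), per_repeat in sorted(metric_values.items()):
        if task == "regression":
            # pool per-repeat held-out predictions per metric over repeats
            per_metric: dict[str, list] = {"r2": [], "rmse": [], "pearson_r": []}
            for m in per_repeat:
                if m is None:
                    for v in per_metric.values():
                        v.append(np.nan)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    per_metric["r2"].append(r_squared(m["true"], m["pred"]) if len(m["true"]) > 1 else np.nan)
                    per_metric["rmse"].append(rmse(m["true"], m["pred"]))
                    per_metric["pearson_r"].append(pearson_r(m["true"], m["pred"]) if len(m["true"]) > 1 else np.nan)
        else:
            per_metric = {"accuracy": [], "auc": [], "f1_macro": []}
            for m in per_repeat:
                for name in per_metric:
                    per_metric[name].append(np.nan if m is None else m[name])
        for name, vals in per_metric.items():
            rep = MetricReport(name=name, task=task, values=np.asarray(vals, dtype=float))
            rows.append(
                {
                    "arm": arm,
                    "label": lab,
                    "metric": name,
                    "mean": rep.mean,
                    "std": rep.std,
                    "n_valid_repeats": rep.n_valid,
                }
            )
    return pd.DataFrame(rows, columns=["arm", "label", "metric", "mean", "std", "n_valid_repeats"])


def lesion_recovery_accuracy(
    dataset: CohortDataset,
    plan: SplitPlan,
    model: ModelConfig | None = None,
) -> MetricReport:
    """Mean held-out accuracy of lesion-class prediction from tangent features.

    The end-to-end identifiability check: covariance estimation -> tangent
    projection at the training-fold Frechet mean -> SVM, over the shared
    leave-out plan.
    """
    model = model or ModelConfig()
    by_pid: dict[str, list[PatientEntry]] = {}
    for e in dataset.entries:
        by_pid.setdefault(e.patient_id, []).append(e)
    accs = []
    for train_ids, test_ids in plan:
        train_e = [e for pid in sorted(train_ids & set(by_pid)) for e in by_pid[pid]]
        test_e = [e for pid in sorted(test_ids & set(by_pid)) for e in by_pid[pid]]
        ref = geometry.frechet_mean([e.cov for e in train_e])
        X_train = np.array([geometry.tangent_project(e.cov, ref) for e in train_e])
        X_test = np.array([geometry.tangent_project(e.cov, ref) for e in test_e])
        y_train = np.array([e.class_id for e in train_e])
        y_test = np.array([e.class_id for e in test_e])
        pred, _, _ = fit_predict(X_train, y_train, X_test, "classification", model)
        accs.append(float(np.mean(pred == y_test)))
    return MetricReport(name="accuracy", task="classification", values=np.asarray(accs))


def pooled_regression_metrics(dataset, plan, arm, label, **kwargs):
    """Pearson r (and R^2/RMSE) over all held-out predictions pooled across repeats.

    Per-repeat test folds hold one patient per class, too few points for a
    stable correlation; pooling the held-out (patient, prediction) pairs over
    the whole plan gives the cohort-level association strength.
    """
    preds = _collect_regression_predictions(dataset, plan, arm, label, **kwargs)
    y = np.array([p[1] for p in preds])
    yh = np.array([p[2] for p in preds])
    return {
        "pearson_r": pearson_r(y, yh),
        "r2": r_squared(y, yh),
        "rmse": rmse(y, yh),
        "n": int(y.size),
    }


def _collect_regression_predictions(
    dataset, plan, arm, label, *, model=None, mix=None, seed=0
):
    """Held-out (patient, truth, prediction) triples over every repeat of the plan."""
    df_rows = []
    model = model or ModelConfig()
    mix = mix or MixConfig()
    entries = list(dataset.entries)
    if _needs_text(arm):
        entries = [e for e in entries if e.doc is not None]
    by_pid: dict[str, list[PatientEntry]] = {}
    for e in entries:
        by_pid.setdefault(e.patient_id, []).append(e)
    for r, (train_ids, test_ids) in enumerate(plan):
        train_e = [e for pid in sorted(train_ids & set(by_pid)) for e in by_pid[pid]]
        test_e = [e for pid in sorted(test_ids & set(by_pid)) for e in by_pid[pid]]
        if not train_e or not test_e:
            continue
        ref = geometry.frechet_mean([e.cov for e in train_e])
        docs_train = [e.doc for e in train_e if e.doc is not None]
        vocab = build_vocabulary(docs_train) if docs_train else None

        def feats(e):
            f = {"tangent": geometry.tangent_project(e.cov, ref), "scalar": e.scalar_features}
            if vocab is not None and e.doc is not None:
                f["text"] = vectorize(e.doc, vocab).astype(float)
            return f

        train_f = [feats(e) for e in train_e]
        test_f = [feats(e) for e in test_e]
        y_train = np.array([e.outcome.value(label) for e in train_e])
        samples = [
            FusedSample(patient_id=e.patient_id, cov=e.cov, tangent=f["tangent"],
                        text=f.get("text"), label=y_train[i])
            for i, (e, f) in enumerate(zip(train_e, train_f))
        ]
        arm_rng = np.random.default_rng(np.random.SeedSequence([seed, r, 17]))
        if "cov_aug" in arm:
            text_policy = "duplicate" if "upsample_text" in arm else "mix"
            samples = augment_regression(
                samples, len(samples), mix, arm_rng, reference=ref, text_policy=text_policy
            )
        _assert_no_leakage(samples, train_ids, test_ids)
        if arm == "ecg_params_baseline":
            X_train = np.array([f["scalar"] for f in train_f])
            y_arm = y_train
            arm_model = ModelConfig(kind="baseline")
        else:
            feat_dicts = [{"tangent": s.tangent, "text": s.text} for s in samples]
            X_train = _arm_matrix(feat_dicts, arm)
            y_arm = np.array([s.label for s in samples])
            arm_model = model
        X_test = _arm_matrix(test_f, arm)
        pred, _, _ = fit_predict(
            X_train, y_arm, X_test, "regression", arm_model, n_scaler_fit=len(train_f)
        )
        pids_test = [e.patient_id for e in test_e]
        uniq, agg_pred, _ = _aggregate_by_patient(pids_test, pred, None, "regression")
        for pid, yh in zip(uniq, agg_pred):
            y_true = float(np.mean([e.outcome.value(label) for e in by_pid[pid]]))
            df_rows.append((pid, y_true, float(yh), r))
    return df_rows
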