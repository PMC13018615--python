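"""Frozen synthetic benchmark definitions shared by the test suite and the
acceptance script.

Two study conditions are defined once and not revisited:

* the **recovery benchmark** — the generator defaults (5 imbalanced lesion
  classes, 40 patients, prototype separation 2.0 vs within-class dispersion
  0.3, 30 s records, outcome true R^2 = 0.6 on a random tangent direction).
  It measures end-to-end identifiability (lesion-class accuracy from
  tangent features), regression recovery (pooled held-out pearson r), and
  the covariance-mixing vs duplicate-upsampling ablation.

* the **fusion benchmark** — a degraded-ECG regime (dispersion 4.5,
  native 2.5 s segments) with informative letters (class topic
  concentration 0.3, severity topic weight 0.6) and outcomes aligned with
  the between-class tangent direction at true R^2 = 0.9.  Only here does
  the text channel carry signal the ECG channel lacks, which is the regime
  where fusing the two modalities should beat ECG alone.

Directional comparisons aggregate mean macro F1 over the two fixed-cut
labels (VE/VCO2, VO2 %pred) and three cohort sub-seeds of a base seed,
with 100 paired leave-out repeats each; the median-cut VO2 peak label is
excluded from direction checks because its training-fold median cut
re-balances the groups by construction.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    CohortConfig,
    EcgSimConfig,
    OutcomeSimConfig,
    TextSimConfig,
    simulate_cohort,
    to_dataset,
)
from .evaluate import (
    lesion_recovery_accuracy,
    make_split_plan,
    pooled_regression_metrics,
    run_ablation,
)

__all__ = [
    "recovery_config",
    "fusion_config",
    "sub_seeds",
    "run_recovery_benchmark",
    "run_fusion_benchmark",
    "N_REPEATS",
    "DIRECTION_LABELS",
]

N_REPEATS = 100

#: labels used for directional arm comparisons (fixed clinical cuts)
DIRECTION_LABELS = ("ve_vco2", "vo2_pred_pct")

_ABLATION_ARMS = (
    "tangent_ecg",
    "tangent_ecg+text",
    "tangent_ecg+text+cov_aug",
    "tangent_ecg+text+cov_aug_ecg_upsample_text",
)


def sub_seeds(base_seed: int, n: int = 3) -> list[int]:
    """Cohort seeds derived from one base seed (kept below 2^31)."""
    return [(100 * base_seed + k) % (2**31 - 1) for k in range(n)]


def recovery_config(seed: int) -> CohortConfig:
    """The generator defaults: separation 2.0, dispersion 0.3, true R^2 0.6."""
    return CohortConfig(seed=seed)


def fusion_config(seed: int) -> CohortConfig:
    """Degraded-ECG / informative-text conditions for the fusion comparison."""
    return CohortConfig(
        seed=seed,
        dispersion=4.5,
        ecg=EcgSimConfig(duration_s=2.5),
        text=TextSimConfig(
            class_topic_concentration=0.3,
            doc_length=(40, 60),
            severity_weight=0.6,
        ),
        outcome=OutcomeSimConfig(direction="between_class", target_r2=0.9),
    )


def _mean_f1_by_arm(config_fn, base_seed: int, arms, labels=DIRECTION_LABELS) -> dict:
    """Mean macro F1 per arm, aggregated over labels and cohort sub-seeds."""
    totals: dict[str, list] = {a: [] for a in arms}
    for cs in sub_seeds(base_seed):
        dataset = to_dataset(simulate_cohort(config_fn(cs)))
        plan = make_split_plan(dataset.class_by_patient, n_repeats=N_REPEATS, seed=cs + 1)
        rep = run_ablation(
            dataset, plan, "classification", labels=list(labels), arms=arms, seed=cs + 2
        )
        f1 = rep[rep.metric == "f1_macro"]
        for arm in arms:
            totals[arm].extend(f1[f1.arm == arm]["mean"].tolist())
    return {a: float(np.mean(v)) for a, v in totals.items()}


def run_recovery_benchmark(base_seed: int) -> dict:
    """Lesion-class accuracy, pooled regression r per label (averaged over
    the cohort sub-seeds), and the covariance-mixing vs duplicate-upsampling
    F1 comparison, all on the default study conditions."""
    seeds = sub_seeds(base_seed)
    reg: dict[str, list] = {}
    out: dict = {}
    for i, cs in enumerate(seeds):
        dataset = to_dataset(simulate_cohort(recovery_config(cs)))
        plan = make_split_plan(dataset.class_by_patient, n_repeats=N_REPEATS, seed=cs + 1)
        if i == 0:
            out["lesion_class_accuracy"] = lesion_recovery_accuracy(dataset, plan).mean
            out["n_patients"] = len(dataset.patient_ids)
        for lab in ("ve_vco2", "vo2_pred_pct", "vo2_peak"):
            res = pooled_regression_metrics(dataset, plan, "tangent_ecg", lab, seed=cs + 2)
            reg.setdefault(f"pearson_r_{lab}", []).append(res["pearson_r"])
            reg.setdefault(f"rmse_{lab}", []).append(res["rmse"])
    for k, v in reg.items():
        out[k] = float(np.mean(v))
    out["pearson_r_mean"] = float(
        np.mean([out[f"pearson_r_{lab}"] for lab in ("ve_vco2", "vo2_pred_pct", "vo2_peak")])
    )
    f1 = _mean_f1_by_arm(
        recovery_config,
        base_seed,
        arms=("tangent_ecg+text+cov_aug", "tangent_ecg+text+cov_aug_ecg_upsample_text"),
    )
    out["f1_cov_aug"] = f1["tangent_ecg+text+cov_aug"]
    out["f1_upsample"] = f1["tangent_ecg+text+cov_aug_ecg_upsample_text"]
    return out


def run_fusion_benchmark(base_seed: int) -> dict:
    """ECG-only vs fused (and the augmented arms) mean F1 on the
    degraded-ECG / informative-text conditions."""
    f1 = _mean_f1_by_arm(fusion_config, base_seed, arms=_ABLATION_ARMS)
    return {
        "f1_ecg_only": f1["tangent_ecg"],
        "f1_fused": f1["tangent_ecg+text"],
        "f1_fused_cov_aug": f1["tangent_ecg+text+cov_aug"],
        "f1_fused_cov_aug_upsample_text": f1["tangent_ecg+text+cov_aug_ecg_upsample_text"],
    }
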