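"""Covariance-mixing augmentation on the SPD manifold.

New training samples are made by interpolating pairs of covariance matrices
along the AIRM geodesic at a Beta-sampled factor alpha — the manifold
analogue of mixup.  The matched text vector is mixed linearly with the
*same* alpha, keeping the two modalities of one augmented sample
consistent.  Class balancing appends within-class mixes until every class
matches the largest; a duplicate-upsampling baseline implements the
conventional alternative for ablation.

Augmented covariances are re-projected to the tangent space at the
training-fold reference mean computed from original samples only, so
augmentation never perturbs the features of the originals, and augmented
samples never enter test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry

__all__ = [
    "MixConfig",
    "FusedSample",
    "sample_alpha",
    "augment_covariance",
    "augment_text",
    "augment_pair",
    "balance_classes",
    "upsample_baseline",
    "augment_regression",
]


@dataclass(frozen=True)
class MixConfig:
    """Mixing-distribution and pairing policy.

    Beta(0.4, 0.4) concentrates alpha near the endpoints so most augmented
    samples stay close to a real one (mixup-style); ``pairing`` controls
    whether mixes are drawn within a class or across the whole pool.
    """

    beta_a: float = 0.4
    beta_b: float = 0.4
    pairing: str = "within_class"
    n_aug_total: int | None = None

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.pairing not in ("within_class", "random"):
            raise ValueError("pairing must be 'within_class' or 'random'")
        if self.n_aug_total is not None and self.n_aug_total < 0:
            raise ValueError("n_aug_total must be >= 0")


@dataclass
class FusedSample:
    """One modelling sample: tangent ECG features + text counts + label.

    ``cov`` retains the SPD covariance so the sample can participate in
    manifold mixing; ``tangent`` is its projection at the current training
    reference.  ``source_ids`` records which patients contributed (two for
    augmented samples) for leakage auditing.
    """

    patient_id: str
    cov: np.ndarray | None = None
    tangent: np.ndarray | None = None
    text: np.ndarray | None = None
    label: object = None
    is_augmented: bool = False
    alpha_used: float | None = None
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.source_ids:
            self.source_ids = (self.patient_id,)
        if self.is_augmented:
            if self.alpha_used is None or not 0.0 <= self.alpha_used <= 1.0:
                raise ValueError("augmented samples require alpha_used in [0, 1]")
        elif self.alpha_used is not None:
            raise ValueError("original samples must not carry alpha_used")


def sample_alpha(cfg: MixConfig, rng: np.random.Generator) -> float:
    """Draw the interpolation factor alpha ~ Beta(a, b); always in [0, 1]."""
    return float(rng.beta(cfg.beta_a, cfg.beta_b))


def augment_covariance(c1: np.ndarray, c2: np.ndarray, alpha: float) -> np.ndarray:
    """Weighted Frechet mean of two covariances with weights (1-alpha, alpha).

    For two points this minimiser has the closed form of the geodesic point
    at parameter alpha, which is what is computed; the result is SPD and
    satisfies ``d(c1, mix) = alpha * d(c1, c2)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return geometry.geodesic(c1, c2, alpha)


def augment_text(v1, v2, alpha: float) -> np.ndarray:
    """Linear mix ``(1-alpha) v1 + alpha v2`` of two term-count vectors."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"text vectors differ in length: {v1.shape} vs {v2.shape}")
    return (1.0 - alpha) * v1 + alpha * v2


def augment_pair(
    s1: FusedSample,
    s2: FusedSample,
    cfg: MixConfig,
    rng: np.random.Generator,
    *,
    reference: np.ndarray,
    task: str = "classification",
    alpha: float | None = None,
    text_policy: str = "mix",
    text_source: np.ndarray | None = None,
) -> FusedSample:
    """Mix two original samples into one augmented sample with a shared alpha.

    The covariance is mixed on the manifold then re-projected at the
    training-fold ``reference`` mean; the text vector is mixed with the same
    alpha.  Under ``text_policy='duplicate'`` (the conventional-upsampling
    ablation) the text is instead an exact copy of an existing document —
    ``text_source`` if supplied, else ``s1``'s letter — breaking the
    cross-modal consistency the shared alpha otherwise maintains.  Classification
    keeps the shared class label and requires a within-class pair;
    regression interpolates labels linearly.
    """
    if s1.is_augmented or s2.is_augmented:
        raise ValueError("augmentation pairs must be original samples")
    if task not in ("classification", "regression"):
        raise ValueError("task must be 'classification' or 'regression'")
    if text_policy not in ("mix", "duplicate"):
        raise ValueError("text_policy must be 'mix' or 'duplicate'")
    if task == "classification" and cfg.pairing == "within_class" and s1.label != s2.label:
        raise ValueError(f"cross-class pair ({s1.label!r}, {s2.label!r}) under within_class pairing")
    if alpha is None:
        alpha = sample_alpha(cfg, rng)
    cov = augment_covariance(s1.cov, s2.cov, alpha)
    tangent = geometry.tangent_project(cov, reference)
    text = None
    if s1.text is not None and s2.text is not None:
        if text_policy == "duplicate":
            src = s1.text if text_source is None else text_source
            text = np.asarray(src, dtype=float).copy()
        else:
            text = augment_text(s1.text, s2.text, alpha)
    if task == "classification":
        label = s1.label
    else:
        label = (1.0 - alpha) * float(s1.label) + alpha * float(s2.label)
    return FusedSample(
        patient_id=f"aug:{s1.patient_id}+{s2.patient_id}",
        cov=cov,
        tangent=tangent,
        text=text,
        label=label,
        is_augmented=True,
        alpha_used=alpha,
        source_ids=(s1.patient_id, s2.patient_id),
    )


def _by_class(samples) -> dict:
    groups: dict = {}
    for s in samples:
        groups.setdefault(s.label, []).append(s)
    return groups


def balance_classes(
    train,
    cfg: MixConfig,
    rng: np.random.Generator,
    *,
    reference: np.ndarray,
    text_policy: str = "mix",
) -> list[FusedSample]:
    """Append within-class manifold mixes until every class matches the largest.

    Originals are returned untouched (first, in input order).  Each
    augmentation draws a distinct pair uniformly without replacement within
    the pair, with replacement across augmentations.  A single-sample class
    cannot be paired and is left unbalanced with a warning.
    """
    train = list(train)
    originals = [s for s in train if not s.is_augmented]
    groups = _by_class(originals)
    if not groups:
        return train
    target = max(len(g) for g in groups.values())
    out = list(train)
    for label in sorted(groups, key=repr):
        members = groups[label]
        deficit = target - len(members)
        if deficit <= 0:
            continue
        if len(members) < 2:
            warnings.warn(
                f"class {label!r} has a single sample and cannot be paired; left unbalanced",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        for _ in range(deficit):
            i, j = rng.choice(len(members), size=2, replace=False)
            out.append(
                augment_pair(
                    members[i],
                    members[j],
                    cfg,
                    rng,
                    reference=reference,
                    task="classification",
                    text_policy=text_policy,
                )
            )
    return out


def upsample_baseline(train, cfg: MixConfig, rng: np.random.Generator) -> list[FusedSample]:
    """Duplicate-with-replacement minority upsampling to the majority count.

    The conventional-ablation comparator: same target counts as
    :func:`balance_classes` but every appended sample is an exact copy of an
    original, flagged augmented with ``alpha_used=0``.
    """
    train = list(train)
    originals = [s for s in train if not s.is_augmented]
    groups = _by_class(originals)
    if not groups:
        return train
    target = max(len(g) for g in groups.values())
    out = list(train)
    for label in sorted(groups, key=repr):
        members = groups[label]
        for _ in range(target - len(members)):
            src = members[int(rng.integers(len(members)))]
            dup = replace(
                src,
                is_augmented=True,
                alpha_used=0.0,
                source_ids=(src.patient_id,),
            )
            dup.cov = None if src.cov is None else src.cov.copy()
            dup.tangent = None if src.tangent is None else src.tangent.copy()
            dup.text = None if src.text is None else src.text.copy()
            out.append(dup)
    return out


def augment_regression(
    train,
    n_aug: int,
    cfg: MixConfig,
    rng: np.random.Generator,
    *,
    reference: np.ndarray,
    text_policy: str = "mix",
) -> list[FusedSample]:
    """Append ``n_aug`` random-pair mixes with linearly interpolated labels."""
    train = list(train)
    originals = [s for s in train if not s.is_augmented]
    if len(originals) < 2:
        warnings.warn("fewer than two originals; no regression augmentation", RuntimeWarning, stacklevel=2)
        return train
    out = list(train)
    for _ in range(n_aug):
        i, j = rng.choice(len(originals), size=2, replace=False)
        out.append(
            augment_pair(
                originals[i],
                originals[j],
                cfg,
                rng,
                reference=reference,
                task="regression",
                text_policy=text_policy,
            )
        )
    return out
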