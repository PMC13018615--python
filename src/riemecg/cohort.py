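"""Fully synthetic multimodal CHD-like cohort generator.

Because the clinical cohort that motivates this pipeline is private, every
stage runs against generated data with known ground truth:

* five lesion classes with imbalanced sizes, each an SPD covariance
  prototype on the 12-lead manifold; patients scatter around their class
  prototype with a configurable Riemannian radius (``dispersion``) while
  prototypes sit a configurable distance apart (``separation``);
* per-patient 12-lead ECG waveforms whose baseline noise is coloured by
  the patient covariance, with periodic QRS-like deflections at known
  indices so the R-peak detector can be validated in closed loop;
* class-conditioned clinical term lists drawn from Dirichlet-perturbed
  multinomials over a shared vocabulary;
* CPET outcomes that are noisy linear functions of the patient's true
  tangent-space coordinates, so the regression signal is continuous and
  only indirectly tied to the class labels.

The generator targets statistical structure, not cardiological realism:
there are no P/T waves or lesion-specific morphologies.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .ecg import LEAD_ORDER, EcgRecord, write_ecg_csv
from .evaluate import CpetOutcome, write_cpet_csv
from .text import ClinicalHistory, write_clinical_csv

__all__ = [
    "EcgSimConfig",
    "TextSimConfig",
    "OutcomeSimConfig",
    "CohortConfig",
    "GroundTruth",
    "SimulatedCohort",
    "base_covariance",
    "make_class_prototypes",
    "sample_patient_covariance",
    "simulate_ecg",
    "make_text_model",
    "simulate_letters",
    "simulate_cpet",
    "simulate_cohort",
    "generate_cohort",
]

#: fixed per-lead polarity/scale of the QRS-like deflection (DII-positive,
#: AVR-negative convention; precordial leads grow toward V4 then shrink)
_QRS_POLARITY = np.array([0.6, 1.0, 0.5, -0.8, 0.3, 0.7, -0.4, 0.5, 0.8, 1.0, 0.9, 0.7])


@dataclass(frozen=True)
class EcgSimConfig:
    """Waveform settings: 500 Hz sampling, 30 s records, 60-90 bpm,
    0.8 mV QRS deflections of ~80 ms width over coloured baseline noise."""

    fs: float = 500.0
    duration_s: float = 30.0
    heart_rate_bpm: tuple[float, float] = (60.0, 90.0)
    qrs_amplitude: float = 0.8
    qrs_width_s: float = 0.08


@dataclass(frozen=True)
class TextSimConfig:
    """Clinical-letter settings: vocabulary size, class topic concentration
    (higher = class term distributions closer to the shared base, i.e. less
    informative), and document length range in tokens.

    ``severity_weight`` > 0 mixes a severity topic into each letter with a
    weight that follows the patient's standardised outcome signal —
    emulating how real letters reflect disease burden through medication
    and intervention terms, not just the anatomical diagnosis.  Zero keeps
    letters purely class-conditioned.
    """

    vocab_size: int = 60
    class_topic_concentration: float = 1.0
    doc_length: tuple[int, int] = (20, 60)
    severity_weight: float = 0.0
    #: when set, each patient gets their own spiky Dirichlet draw around the
    #: class distribution (smaller = more idiosyncratic), emulating how a
    #: patient's letters reuse their personal diagnosis/medication subset
    #: rather than sampling the whole class vocabulary afresh.
    patient_topic_concentration: float | None = None


@dataclass(frozen=True)
class OutcomeSimConfig:
    """CPET outcome model: each label is intercept + signal_sd * z + noise,
    where z is the cohort-standardised projection of the patient's true
    tangent coordinates on a random unit direction.  ``target_r2`` sets the
    noise so the true linear model explains that fraction of variance;
    ``noise_sd`` overrides it when given.  Scales sit in each label's
    clinically plausible range (VE/VCO2 ~ 30, VO2 %pred ~ 65%, VO2 peak
    ~ 1.5 L/min)."""

    intercepts: dict = field(
        default_factory=lambda: {"ve_vco2": 30.0, "vo2_pred_pct": 65.0, "vo2_peak": 1.5}
    )
    signal_sd: dict = field(
        default_factory=lambda: {"ve_vco2": 8.0, "vo2_pred_pct": 9.0, "vo2_peak": 0.35}
    )
    target_r2: float = 0.6
    noise_sd: dict | None = None
    #: 'random' draws an arbitrary unit direction in tangent space;
    #: 'between_class' aligns it with the leading principal direction of the
    #: class prototypes, making severity track lesion anatomy.
    direction: str = "random"


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults: 5 imbalanced lesion classes (40 patients,
    mirroring the source cohort's imbalance ratios at desk scale), 12 leads,
    prototype separation 2.0 vs within-class dispersion 0.3 (Riemannian
    radii)."""

    n_classes: int = 5
    patients_per_class: tuple[int, ...] = (12, 8, 8, 7, 5)
    dim: int = 12
    separation: float = 2.0
    dispersion: float = 0.3
    ecg: EcgSimConfig = field(default_factory=EcgSimConfig)
    text: TextSimConfig = field(default_factory=TextSimConfig)
    outcome: OutcomeSimConfig = field(default_factory=OutcomeSimConfig)
    seed: int = 0
    distractor_docs: bool = False

    def __post_init__(self) -> None:
        if len(self.patients_per_class) != self.n_classes:
            raise ValueError("patients_per_class length must equal n_classes")
        if any(p < 2 for p in self.patients_per_class):
            raise ValueError("every class needs >= 2 patients")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.separation < 0 or self.dispersion < 0:
            raise ValueError("separation and dispersion must be nonnegative")


CLASS_NAMES = ("ToF", "ASD", "PA", "Fontan", "Mustard")


def base_covariance(dim: int = 12) -> np.ndarray:
    """Fixed base SPD matrix C0: AR(1)-correlated leads (rho 0.3) with
    0.04 mV^2 lead variances — a plausible resting inter-lead baseline."""
    idx = np.arange(dim)
    corr = 0.3 ** np.abs(idx[:, None] - idx[None, :])
    return 0.04 * corr


def _random_sym_direction(rng: np.random.Generator, dim: int, *, exact_unit: bool) -> np.ndarray:
    """Random symmetric matrix with (expected) unit Frobenius norm.

    With ``exact_unit`` the matrix is normalised exactly; otherwise entries
    are scaled so E||Z||_F^2 = 1, giving a naturally varying radius.
    """
    a = rng.standard_normal((dim, dim))
    z = (a + a.T) / np.sqrt(2.0)
    if exact_unit:
        return z / np.linalg.norm(z)
    # E||Z||_F^2 = 2 * dim^2 / 2 ... computed directly from the construction:
    # diagonal entries ~ N(0, 2), off-diagonal ~ N(0, 1) -> E||Z||^2 = 2d + d(d-1)
    return z / np.sqrt(2 * dim + dim * (dim - 1))


def make_class_prototypes(cfg: CohortConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Class prototype SPD matrices at Riemannian distance ``separation``
    from the base, resampled (up to 100 times) until pairwise distances are
    at least ``0.5 * separation``."""
    c0 = base_covariance(cfg.dim)
    if cfg.separation == 0:
        return [c0.copy() for _ in range(cfg.n_classes)]
    for _ in range(100):
        protos = []
        for _k in range(cfg.n_classes):
            s = _random_sym_direction(rng, cfg.dim, exact_unit=True)
            r = geometry.sqrtm_spd(c0)
            protos.append(r @ geometry.expm_sym(cfg.separation * s) @ r)
        dmin = min(
            geometry.riemannian_distance(protos[i], protos[j])
            for i in range(cfg.n_classes)
            for j in range(i + 1, cfg.n_classes)
        )
        if dmin >= 0.5 * cfg.separation:
            return protos
    raise RuntimeError(
        "could not place class prototypes at the requested spread in 100 resamples; "
        "increase dim or reduce n_classes/separation"
    )


def sample_patient_covariance(
    prototype: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Patient covariance scattered around its class prototype at Riemannian
    radius ~ ``dispersion`` (tangent perturbation in the whitened chart)."""
    if dispersion == 0:
        return prototype.copy()
    dim = prototype.shape[0]
    z = _random_sym_direction(rng, dim, exact_unit=False)
    r = geometry.sqrtm_spd(prototype)
    return r @ geometry.expm_sym(dispersion * z) @ r


def simulate_ecg(
    cov: np.ndarray, ecfg: EcgSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a 12-lead signal realising ``cov`` plus QRS-like beats.

    Baseline noise is ``cov^{1/2} @ white`` so its population inter-lead
    covariance is exactly ``cov``; a Gaussian-bump QRS template (fixed lead
    polarities) is added at heart-rate-spaced indices.  Returns
    ``(signal 12 x T, true R-peak indices)``.
    """
    fs = ecfg.fs
    t_samples = int(round(ecfg.duration_s * fs))
    dim = cov.shape[0]
    period_s = 60.0 / rng.uniform(*ecfg.heart_rate_bpm)
    period = int(round(period_s * fs))
    if t_samples < period + int(fs):
        raise ValueError(
            f"duration {ecfg.duration_s}s too short for one beat at {60 / period_s:.0f} bpm"
        )
    chol = geometry.sqrtm_spd(cov)
    signal = chol @ rng.standard_normal((dim, t_samples))

    sigma = ecfg.qrs_width_s * fs / 4.0  # bump with ~width_s visible support
    half = int(round(3 * sigma))
    bump = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    peaks = np.arange(int(0.5 * fs), t_samples - half - 1, period, dtype=int)
    if ecfg.qrs_amplitude != 0:
        for p in peaks:
            lo, hi = p - half, p + half + 1
            if lo < 0 or hi > t_samples:
                continue
            signal[:, lo:hi] += ecfg.qrs_amplitude * np.outer(_QRS_POLARITY[:dim], bump)
    return signal, peaks


@dataclass
class TextModel:
    """Shared vocabulary with per-class multinomial term distributions and a
    severity topic concentrated on the high-index (medication-like) terms."""

    tokens: tuple[str, ...]
    class_probs: np.ndarray  # (n_classes, vocab_size)
    severity_probs: np.ndarray | None = None  # (vocab_size,)


def make_text_model(tcfg: TextSimConfig, n_classes: int, rng: np.random.Generator) -> TextModel:
    """Build class term distributions as Dirichlet perturbations of a fixed
    power-law base; as ``class_topic_concentration`` grows the classes
    coincide with the base (text becomes uninformative)."""
    v = tcfg.vocab_size
    tokens = tuple(f"term{i:03d}" for i in range(v))
    base = 1.0 / (np.arange(v) + 10.0)
    base /= base.sum()
    alpha = tcfg.class_topic_concentration * v * base
    probs = rng.dirichlet(alpha, size=n_classes)
    sev = np.zeros(v)
    k = max(1, v // 4)  # severity terms: the last quarter of the vocabulary
    sev[-k:] = 1.0 / k
    return TextModel(tokens=tokens, class_probs=probs, severity_probs=sev)


def simulate_letters(
    class_id: int,
    model: TextModel,
    tcfg: TextSimConfig,
    rng: np.random.Generator,
    *,
    patient_id: str,
    doc_date: _dt.date,
    severity: float = 0.0,
    patient_probs: np.ndarray | None = None,
) -> ClinicalHistory:
    """Draw one clinical-history term list from the class's multinomial.

    ``patient_probs`` (a patient-idiosyncratic distribution) replaces the
    class distribution when given.  With ``severity_weight`` > 0 the
    distribution is blended with the severity topic at weight
    ``severity_weight * sigmoid(severity)``, tying term usage to the
    patient's continuous disease burden.
    """
    lo, hi = tcfg.doc_length
    length = int(rng.integers(lo, hi + 1))
    p = model.class_probs[class_id] if patient_probs is None else patient_probs
    if tcfg.severity_weight > 0 and model.severity_probs is not None:
        w_sev = tcfg.severity_weight / (1.0 + np.exp(-float(severity)))
        p = (1.0 - w_sev) * p + w_sev * model.severity_probs
    idx = rng.choice(len(model.tokens), size=length, p=p)
    return ClinicalHistory(
        patient_id=patient_id, doc_date=doc_date, terms=[model.tokens[i] for i in idx]
    )


def simulate_cpet(
    z_score: float,
    ocfg: OutcomeSimConfig,
    rng: np.random.Generator,
    *,
    patient_id: str,
    test_date: _dt.date,
) -> tuple[CpetOutcome, dict, int]:
    """One CPET outcome from a patient's standardised tangent projection.

    Returns the outcome, its noiseless means, and the number of labels that
    hit the physiological clamps (audited; zero at default scales).
    """
    values, means = {}, {}
    clamped = 0
    bounds = {"ve_vco2": (5.0, None), "vo2_pred_pct": (5.0, 195.0), "vo2_peak": (0.2, None)}
    for lab in ("ve_vco2", "vo2_pred_pct", "vo2_peak"):
        s = ocfg.signal_sd[lab]
        if ocfg.noise_sd is not None and lab in ocfg.noise_sd:
            nsd = ocfg.noise_sd[lab]
        else:
            r2 = ocfg.target_r2
            nsd = s * np.sqrt((1.0 - r2) / r2)
        mean = ocfg.intercepts[lab] + s * z_score
        val = mean + nsd * rng.standard_normal()
        lo, hi = bounds[lab]
        cl = max(val, lo)
        if hi is not None:
            cl = min(cl, hi)
        if cl != val:
            clamped += 1
        values[lab] = cl
        means[lab] = mean
    return (
        CpetOutcome(patient_id=patient_id, test_date=test_date, **values),
        means,
        clamped,
    )


@dataclass
class GroundTruth:
    """Generator-side truth for every patient: class, true covariance,
    true tangent coordinates at the base, true R peaks, noiseless outcome
    means, and the clamp audit."""

    class_ids: dict = field(default_factory=dict)
    true_cov: dict = field(default_factory=dict)
    true_tangent: dict = field(default_factory=dict)
    true_peaks: dict = field(default_factory=dict)
    outcome_means: dict = field(default_factory=dict)
    n_clamped: int = 0
    outcome_direction: np.ndarray | None = None


@dataclass
class SimulatedCohort:
    """In-memory cohort: records, documents, outcomes, classes, and truth."""

    config: CohortConfig
    records: list[EcgRecord]
    histories: list[ClinicalHistory]
    outcomes: list[CpetOutcome]
    class_by_patient: dict
    truth: GroundTruth


_ECG_BASE_DATE = _dt.date(2020, 1, 15)


def simulate_cohort(cfg: CohortConfig) -> SimulatedCohort:
    """Generate the full multimodal cohort in memory, deterministically under
    ``cfg.seed``.

    One ECG, one clinical letter and one CPET document per patient; the
    letter and CPET dates fall within +/-90 days of the ECG so nearest-date
    linkage is exercised unambiguously (``distractor_docs`` adds a second,
    farther letter per patient).
    """
    master = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(6)]
    rng_proto, rng_cov, rng_ecg, rng_text, rng_out, rng_dates = rngs

    protos = make_class_prototypes(cfg, rng_proto)
    text_model = make_text_model(cfg.text, cfg.n_classes, rng_text)
    c0 = base_covariance(cfg.dim)

    truth = GroundTruth()
    pids, class_by_patient = [], {}
    covs = {}
    for k, n_k in enumerate(cfg.patients_per_class):
        for i in range(n_k):
            pid = f"P{k}{i:02d}"
            pids.append(pid)
            class_by_patient[pid] = k
            covs[pid] = sample_patient_covariance(protos[k], cfg.dispersion, rng_cov)
            truth.class_ids[pid] = k
            truth.true_cov[pid] = covs[pid]
            truth.true_tangent[pid] = geometry.tangent_project(covs[pid], c0)

    # outcome signal: projection of true tangent coords on a random unit
    # direction, standardised across the cohort
    dim_t = cfg.dim * (cfg.dim + 1) // 2
    if cfg.outcome.direction == "between_class":
        proto_vecs = np.array([geometry.tangent_project(p, c0) for p in protos])
        centred = proto_vecs - proto_vecs.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        w = vt[0]
    else:
        w = rng_out.standard_normal(dim_t)
        w /= np.linalg.norm(w)
    truth.outcome_direction = w
    raw = np.array([truth.true_tangent[pid] @ w for pid in pids])
    mu, sd = float(raw.mean()), float(raw.std())
    z = (raw - mu) / (sd if sd > 0 else 1.0)

    records, histories, outcomes = [], [], []
    for pid, z_i in zip(pids, z):
        k = class_by_patient[pid]
        patient_probs = None
        if cfg.text.patient_topic_concentration is not None:
            alpha_p = (
                cfg.text.patient_topic_concentration
                * cfg.text.vocab_size
                * text_model.class_probs[k]
                + 1e-6
            )
            patient_probs = rng_text.dirichlet(alpha_p)
        ecg_date = _ECG_BASE_DATE + _dt.timedelta(days=int(rng_dates.integers(0, 365)))
        signal, peaks = simulate_ecg(covs[pid], cfg.ecg, rng_ecg)
        records.append(
            EcgRecord(signal, fs=cfg.ecg.fs, patient_id=pid, record_date=ecg_date)
        )
        truth.true_peaks[pid] = peaks
        doc_date = ecg_date + _dt.timedelta(days=int(rng_dates.integers(-90, 91)))
        histories.append(
            simulate_letters(
                k, text_model, cfg.text, rng_text,
                patient_id=pid, doc_date=doc_date, severity=z_i,
                patient_probs=patient_probs,
            )
        )
        if cfg.distractor_docs:
            far = ecg_date + _dt.timedelta(days=int(rng_dates.integers(200, 400)))
            histories.append(
                simulate_letters(
                    k, text_model, cfg.text, rng_text,
                    patient_id=pid, doc_date=far, severity=z_i,
                    patient_probs=patient_probs,
                )
            )
        cpet_date = ecg_date + _dt.timedelta(days=int(rng_dates.integers(-90, 91)))
        outcome, means, n_cl = simulate_cpet(
            z_i, cfg.outcome, rng_out, patient_id=pid, test_date=cpet_date
        )
        outcomes.append(outcome)
        truth.outcome_means[pid] = means
        truth.n_clamped += n_cl

    return SimulatedCohort(
        config=cfg,
        records=records,
        histories=histories,
        outcomes=outcomes,
        class_by_patient=class_by_patient,
        truth=truth,
    )


def generate_cohort(cfg: CohortConfig, out_dir) -> Path:
    """Write a cohort to disk in the CSV dialects the ingest modules consume.

    Layout: ``ecg/<pid>.csv`` per recording, ``records.csv`` manifest
    (patient_id, class_id, ecg_file, ecg_date, fs), ``clinical.csv``,
    ``cpet.csv``, and ``ground_truth.json``.  Byte-identical across runs
    with the same config.
    """
    sim = simulate_cohort(cfg)
    out = Path(out_dir)
    (out / "ecg").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in sim.records:
        fname = f"ecg/{rec.patient_id}.csv"
        write_ecg_csv(rec, out / fname)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "class_id": sim.class_by_patient[rec.patient_id],
                "ecg_file": fname,
                "ecg_date": rec.record_date.isoformat(),
                "fs": rec.fs,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "records.csv", index=False)
    write_clinical_csv(sim.histories, out / "clinical.csv")
    write_cpet_csv(sim.outcomes, out / "cpet.csv")
    gt = {
        "class_ids": sim.truth.class_ids,
        "true_cov": {p: c.tolist() for p, c in sim.truth.true_cov.items()},
        "true_tangent": {p: v.tolist() for p, v in sim.truth.true_tangent.items()},
        "true_peaks": {p: np.asarray(v).tolist() for p, v in sim.truth.true_peaks.items()},
        "outcome_means": sim.truth.outcome_means,
        "n_clamped": sim.truth.n_clamped,
        "seed": cfg.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
    return out


def to_dataset(sim: SimulatedCohort, **build_kwargs):
    """Ingest an in-memory cohort into an evaluation-ready dataset
    (runs R-peak detection, beat segmentation and covariance estimation)."""
    from .evaluate import CohortDataset

    return CohortDataset.build(
        sim.records, sim.class_by_patient, sim.histories, sim.outcomes, **build_kwargs
    )
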