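"""12-lead ECG ingestion: CSV reading, R-peak detection, beat segmentation,
and inter-lead covariance estimation.

The modelling pipeline consumes one symmetric positive-definite 12x12
covariance per recording, estimated from R-peak-aligned ~1 s beat windows
(or, optionally, from the raw unaligned signal).  The R-peak detector is a
Pan-Tompkins-style scheme: zero-phase band-pass, squared derivative,
moving-window integration, adaptive threshold with a 200 ms refractory
period, run on lead DII by default.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .geometry import check_spd

__all__ = [
    "LEAD_ORDER",
    "EcgRecord",
    "BeatSegment",
    "EcgParseError",
    "read_ecg_csv",
    "write_ecg_csv",
    "detect_r_peaks",
    "segment_beats",
    "estimate_covariance",
    "record_covariance",
    "basic_interval_features",
]

#: Standard lead order of the source ECGs.
LEAD_ORDER = ("DI", "DII", "DIII", "AVR", "AVL", "AVF", "V1", "V2", "V3", "V4", "V5", "V6")


class EcgParseError(ValueError):
    """Malformed ECG CSV (wrong lead count, non-numeric cell, NaN)."""


@dataclass
class EcgRecord:
    """A digitised 12-lead ECG: 12 x T signal matrix in mV at ``fs`` Hz."""

    signal: np.ndarray
    fs: float = 500.0
    lead_order: tuple[str, ...] = LEAD_ORDER
    patient_id: str = ""
    record_date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(LEAD_ORDER):
            raise ValueError(f"signal must be {len(LEAD_ORDER)} x T, got shape {self.signal.shape}")
        if tuple(self.lead_order) != LEAD_ORDER:
            raise ValueError(f"lead_order must be {LEAD_ORDER}; remap at read time")
        self.lead_order = LEAD_ORDER
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.shape[1] < self.fs:
            raise ValueError(
                f"record too short: {self.signal.shape[1]} samples < 1 s at {self.fs} Hz"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[LEAD_ORDER.index(name)]


@dataclass
class BeatSegment:
    """One R-peak-aligned beat window (12 x W, mV); ``r_index`` within window."""

    window: np.ndarray
    r_index: int

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 2 or self.window.shape[0] != len(LEAD_ORDER):
            raise ValueError(f"window must be {len(LEAD_ORDER)} x W, got {self.window.shape}")
        if not 0 <= self.r_index < self.window.shape[1]:
            raise ValueError("r_index outside window")


def read_ecg_csv(
    path,
    fs: float = 500.0,
    lead_order=None,
    *,
    patient_id: str = "",
    record_date: _dt.date | None = None,
) -> EcgRecord:
    """Read a 12-lead ECG from columnar CSV into an :class:`EcgRecord`.

    Columns are leads (one sample per row).  A header row of lead names is
    optional; when present and a permutation of the standard order, the
    leads are remapped to ``LEAD_ORDER``.  A headerless 12-row matrix is
    auto-detected as leads-in-rows.  Malformed cells raise
    :class:`EcgParseError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",")]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    try:
        df = pd.read_csv(path, header=0 if has_header else None, dtype=str, skip_blank_lines=False)
    except Exception as exc:  # pragma: no cover - pandas edge cases
        raise EcgParseError(f"{path}: unreadable CSV: {exc}") from exc

    names = [str(c).strip().upper() for c in df.columns] if has_header else None
    arr = df.to_numpy()
    mat = np.empty(arr.shape, dtype=float)
    offset = 2 if has_header else 1  # 1-based line numbers in the file
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = arr[i, j]
            try:
                mat[i, j] = float(cell)
            except (TypeError, ValueError):
                raise EcgParseError(
                    f"{path}: non-numeric cell {cell!r} at line {i + offset}, column {j + 1}"
                ) from None
    if np.any(np.isnan(mat)):
        i, j = np.argwhere(np.isnan(mat))[0]
        raise EcgParseError(f"{path}: missing/NaN sample at line {int(i) + offset}, column {int(j) + 1}")

    n_leads = len(LEAD_ORDER)
    if mat.shape[1] == n_leads:
        sig = mat.T
    elif mat.shape[0] == n_leads and not has_header:
        sig = mat  # headerless leads-in-rows layout
    else:
        raise EcgParseError(
            f"{path}: expected {n_leads} lead columns {list(LEAD_ORDER)}, got {mat.shape[1]}"
        )

    order = lead_order
    if order is None and has_header:
        order = names
    if order is not None:
        order = tuple(str(x).strip().upper() for x in order)
        if sorted(order) != sorted(LEAD_ORDER):
            raise EcgParseError(
                f"{path}: lead names {list(order)} are not a permutation of {list(LEAD_ORDER)}"
            )
        perm = [order.index(name) for name in LEAD_ORDER]
        sig = sig[perm]
    return EcgRecord(sig, fs=fs, patient_id=patient_id, record_date=record_date)


def write_ecg_csv(rec: EcgRecord, path) -> None:
    """Write an ECG as CSV (lead-name header, one sample per row, full precision)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(LEAD_ORDER) + "\n")
        np.savetxt(fh, rec.signal.T, fmt="%.17g", delimiter=",")


def detect_r_peaks(
    rec: EcgRecord,
    *,
    lead: str = "DII",
    band_hz: tuple[float, float] = (5.0, 15.0),
    integration_s: float = 0.150,
    refractory_s: float = 0.200,
    threshold_frac: float = 0.5,
    rolling_max_s: float = 2.0,
) -> np.ndarray:
    """Detect R peaks on one lead; returns strictly increasing sample indices.

    Band-pass (zero-phase), differentiate, square, integrate over a moving
    window, threshold at ``threshold_frac`` of a rolling maximum, enforce a
    refractory gap, then refine each detection to the extremum of the
    band-passed signal.  An empty result triggers a warning, not an error.
    """
    fs = rec.fs
    x = rec.lead(lead)
    nyq = fs / 2.0
    sos = scipy.signal.butter(2, [band_hz[0] / nyq, band_hz[1] / nyq], btype="bandpass", output="sos")
    bp = scipy.signal.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    k = max(1, int(round(integration_s * fs)))
    integ = np.convolve(energy, np.ones(k) / k, mode="same")

    roll = scipy.ndimage.maximum_filter1d(integ, size=max(1, int(round(rolling_max_s * fs))))
    refractory = max(1, int(round(refractory_s * fs)))
    cand, _ = scipy.signal.find_peaks(integ, distance=refractory)
    cand = cand[integ[cand] >= threshold_frac * roll[cand]]
    # reject noise-floor detections on near-flat signal
    cand = cand[integ[cand] > 1e-12]

    half = int(round(0.10 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(bp), c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.array(sorted(set(peaks)), dtype=int)
    if peaks.size:  # re-enforce refractory after refinement
        keep = [int(peaks[0])]
        for p in peaks[1:]:
            if p - keep[-1] >= refractory:
                keep.append(int(p))
        peaks = np.array(keep, dtype=int)
    if peaks.size == 0:
        warnings.warn("no R peaks detected", RuntimeWarning, stacklevel=2)
    return peaks


def segment_beats(
    rec: EcgRecord,
    peaks,
    window_seconds: float = 1.0,
    align_offset: float = 0.4,
) -> list[BeatSegment]:
    """Cut one aligned window per R peak; beats whose window overruns an edge
    are dropped.  Every returned segment has its R peak at
    ``round(align_offset * W)``."""
    w = int(round(rec.fs * window_seconds))
    r_off = int(round(align_offset * w))
    segs: list[BeatSegment] = []
    for p in np.asarray(peaks, dtype=int):
        start = p - r_off
        if start < 0 or start + w > rec.n_samples:
            continue
        segs.append(BeatSegment(rec.signal[:, start : start + w], r_index=r_off))
    if not segs:
        warnings.warn("no beat fits entirely inside the recording", RuntimeWarning, stacklevel=2)
    return segs


def estimate_covariance(segments, shrinkage: float = 0.01) -> np.ndarray:
    """Pooled inter-lead sample covariance of mean-centred beat windows.

    Each segment is centred per lead, the windows are concatenated in time,
    and the sample covariance is shrunk toward a scaled identity:
    ``C <- (1 - g) C + g (trace(C)/n) I``.  The default ``shrinkage=0.01``
    guarantees positive-definiteness even for duplicated leads.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    wins = [s.window if isinstance(s, BeatSegment) else np.asarray(s, dtype=float) for s in segments]
    if len(wins) == 0:
        raise ValueError("cannot estimate a covariance from zero segments")
    centred = [w - w.mean(axis=1, keepdims=True) for w in wins]
    x = np.hstack(centred)
    n = x.shape[0]
    denom = max(x.shape[1] - 1, 1)
    c = (x @ x.T) / denom
    if shrinkage > 0:
        c = (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n) * np.eye(n)
    try:
        return check_spd(c, name="estimated covariance")
    except Exception as exc:
        raise ValueError(
            f"estimated covariance is not positive-definite ({exc}); "
            "increase shrinkage or check for constant leads"
        ) from exc


def record_covariance(
    rec: EcgRecord,
    *,
    use_aligned: bool = True,
    window_seconds: float = 1.0,
    align_offset: float = 0.4,
    shrinkage: float = 0.01,
    detector_kwargs: dict | None = None,
) -> np.ndarray:
    """Covariance of one recording: detect, segment, estimate.

    With ``use_aligned=False`` the whole (unaligned) signal is used as a
    single segment instead of the R-peak-aligned beat stream.
    """
    if use_aligned:
        peaks = detect_r_peaks(rec, **(detector_kwargs or {}))
        segs = segment_beats(rec, peaks, window_seconds=window_seconds, align_offset=align_offset)
        if not segs:
            segs = [rec.signal]  # degenerate fallback: whole record
    else:
        segs = [rec.signal]
    return estimate_covariance(segs, shrinkage=shrinkage)


def basic_interval_features(rec: EcgRecord, peaks=None) -> dict[str, float]:
    """Scalar rhythm features analogous to vendor-report ECG parameters:
    ventricular rate (bpm), RR-interval standard deviation (s), and mean
    R-wave amplitude on DII (mV).  Used by the parameter-only baseline arm."""
    if peaks is None:
        peaks = detect_r_peaks(rec)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        return {"vent_rate_bpm": np.nan, "rr_std_s": np.nan, "r_amplitude_mv": np.nan}
    rr = np.diff(peaks) / rec.fs
    return {
        "vent_rate_bpm": float(60.0 / np.median(rr)),
        "rr_std_s": float(np.std(rr)),
        "r_amplitude_mv": float(np.mean(np.abs(rec.lead("DII")[peaks]))),
    }
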