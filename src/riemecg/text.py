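"""Clinical-history term lists to term-frequency vectors.

Each patient's history is the concatenation of their diagnosis,
intervention and medication term lists from the clinical letter nearest in
date to the ECG.  Documents become bag-of-words count vectors over a
vocabulary built from *training* documents only (applying a test-fold
vocabulary would leak test terms into the feature space).  Counts are raw
term frequencies — no TF-IDF, no normalisation.  Demographics are never
featurised.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalHistory",
    "Vocabulary",
    "TextMissingError",
    "build_vocabulary",
    "vectorize",
    "corpus_matrix",
    "link_nearest_date",
    "read_clinical_csv",
    "write_clinical_csv",
]

#: default token pattern: word characters, length >= 2 (CountVectorizer default)
TOKEN_PATTERN = r"(?u)\b\w\w+\b"


class TextMissingError(LookupError):
    """Patient has no clinical document; excluded from fusion runs."""


@dataclass
class ClinicalHistory:
    """One patient's concatenated diagnosis/intervention/medication terms."""

    patient_id: str
    doc_date: _dt.date
    terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if isinstance(self.doc_date, str):
            self.doc_date = _dt.date.fromisoformat(self.doc_date)
        self.terms = [t for t in (str(t).strip() for t in self.terms) if t]

    @property
    def text(self) -> str:
        return " ".join(self.terms)

    @property
    def is_empty(self) -> bool:
        return len(self.terms) == 0


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic (lexicographically ordered) token vocabulary."""

    tokens: tuple[str, ...]
    lowercase: bool = True
    token_pattern: str = TOKEN_PATTERN

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if list(self.tokens) != sorted(self.tokens):
            raise ValueError("vocabulary must be lexicographically ordered")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def analyze(self, doc: "ClinicalHistory | str") -> list[str]:
        """Tokenise a document with this vocabulary's normalisation settings."""
        text = doc.text if isinstance(doc, ClinicalHistory) else str(doc)
        if self.lowercase:
            text = text.lower()
        return re.findall(self.token_pattern, text)

    def save(self, path) -> None:
        Path(path).write_text("".join(t + "\n" for t in self.tokens))

    @classmethod
    def load(cls, path) -> "Vocabulary":
        toks = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tokens=tuple(sorted(toks)))


def build_vocabulary(
    corpus,
    *,
    lowercase: bool = True,
    token_pattern: str = TOKEN_PATTERN,
) -> Vocabulary:
    """Build the distinct-term vocabulary from a training corpus.

    Document order does not matter; an all-empty corpus yields an empty
    vocabulary with a warning.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    probe = Vocabulary(tokens=(), lowercase=lowercase, token_pattern=token_pattern)
    seen: set[str] = set()
    for doc in corpus:
        seen.update(probe.analyze(doc))
    if not seen:
        warnings.warn("corpus contains no tokens; vocabulary is empty", RuntimeWarning, stacklevel=2)
    return Vocabulary(tokens=tuple(sorted(seen)), lowercase=lowercase, token_pattern=token_pattern)


def vectorize(doc, vocab: Vocabulary, *, return_oov: bool = False):
    """Count vocabulary terms in one document.

    Out-of-vocabulary tokens are ignored; with ``return_oov=True`` their
    count is returned as a diagnostics tally alongside the vector.
    """
    counts = np.zeros(len(vocab), dtype=int)
    idx = vocab.index
    oov = 0
    for tok in vocab.analyze(doc):
        j = idx.get(tok)
        if j is None:
            oov += 1
        else:
            counts[j] += 1
    if return_oov:
        return counts, oov
    return counts


def corpus_matrix(corpus, vocab: Vocabulary) -> np.ndarray:
    """Documents x terms count matrix (rows follow the corpus order)."""
    return np.array([vectorize(d, vocab) for d in corpus], dtype=int)


def link_nearest_date(ecg_date: _dt.date, docs) -> ClinicalHistory:
    """Select the patient document nearest in date to the ECG.

    Ties are broken toward the *earlier* document (information already
    available before the ECG).  No documents raises
    :class:`TextMissingError`; the evaluation harness flags such patients
    "text-missing" and keeps them for ECG-only arms.
    """
    if isinstance(ecg_date, str):
        ecg_date = _dt.date.fromisoformat(ecg_date)
    docs = list(docs)
    if not docs:
        raise TextMissingError(f"no clinical document available near {ecg_date}")
    return min(docs, key=lambda d: (abs((d.doc_date - ecg_date).days), d.doc_date))


_COLUMNS = ("patient_id", "doc_date", "diagnosis_list", "intervention_list", "medication_list")


def read_clinical_csv(path) -> list[ClinicalHistory]:
    """Read the structured clinical-history table.

    Expected columns: patient_id, doc_date (ISO-8601), diagnosis_list,
    intervention_list, medication_list — the three lists semicolon-delimited
    and concatenated into the term history.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {list(_COLUMNS)}")
    out = []
    for _, row in df.iterrows():
        terms: list[str] = []
        for col in ("diagnosis_list", "intervention_list", "medication_list"):
            terms.extend(t.strip() for t in row[col].split(";") if t.strip())
        out.append(ClinicalHistory(patient_id=row["patient_id"], doc_date=row["doc_date"], terms=terms))
    return out


def write_clinical_csv(histories, path) -> None:
    """Write histories in the dialect :func:`read_clinical_csv` consumes.

    All terms are stored in the diagnosis_list column; the reader
    concatenates the three lists, so the split is immaterial downstream.
    """
    rows = [
        {
            "patient_id": h.patient_id,
            "doc_date": h.doc_date.isoformat(),
            "diagnosis_list": ";".join(h.terms),
            "intervention_list": "",
            "medication_list": "",
        }
        for h in histories
    ]
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, index=False)
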