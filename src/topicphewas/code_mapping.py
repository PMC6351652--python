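"""Roll-up of raw ICD-9 codes to top-level PheWAS codes and frequency control.

PheWAS codes (phecodes) group fine-grained ICD billing codes into clinically
meaningful disease categories.  The rollup here is driven entirely by a
user-supplied mapping table; for synthetic vocabularies a simple truncation
rule (ICD-9 string cut to its 3-character stem before the dot) is available
as a fallback.  After rollup, codes present in fewer than a configurable
fraction of subjects (default 0.5%) are eliminated before topic modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CodeCountMatrix",
    "PhewasCodeMap",
    "read_code_map",
    "truncation_map",
    "map_codes",
    "frequency_filter",
]


@dataclass
class CodeCountMatrix:
    """Sparse subject x code count matrix with explicit row/column labels.

    Parameters
    ----------
    subject_ids : list of str
        Row labels; must be unique.
    code_vocab : list of str
        Column labels; must be unique.
    counts : scipy.sparse.csr_matrix
        Nonnegative integer counts, shape ``(len(subject_ids), len(code_vocab))``.
    """

    subject_ids: list[str]
    code_vocab: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, v = self.counts.shape
        if n != len(self.subject_ids) or v != len(self.code_vocab):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.code_vocab)} codes"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(set(self.code_vocab)) != v:
            raise ValueError("code_vocab must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_codes(self) -> int:
        return len(self.code_vocab)

    def token_total(self) -> int:
        """Total number of code tokens (sum of all counts)."""
        return int(self.counts.sum())

    def presence(self) -> np.ndarray:
        """Boolean subject x code matrix of 'has at least one occurrence'."""
        return (self.counts > 0).toarray()

    def reorder_subjects(self, subject_ids: list[str]) -> "CodeCountMatrix":
        """Return a copy with rows reordered/subset to ``subject_ids``."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in count matrix: {missing[:5]}")
        rows = [index[s] for s in subject_ids]
        return CodeCountMatrix(list(subject_ids), list(self.code_vocab),
                               self.counts[rows, :])

    def sort_codes(self) -> "CodeCountMatrix":
        """Return a copy with columns in lexicographic code order."""
        order = np.argsort(np.asarray(self.code_vocab, dtype=object))
        return CodeCountMatrix(
            list(self.subject_ids),
            [self.code_vocab[j] for j in order],
            self.counts[:, order],
        )

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()


@dataclass
class PhewasCodeMap:
    """Mapping from ICD-9 codes to top-level PheWAS codes.

    ``entries`` is a list of ``(icd9_code, phewas_code, phewas_label)``
    triples; ICD-9 codes must be unique within the map.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        icd9 = [e[0] for e in self.entries]
        if len(set(icd9)) != len(icd9):
            raise ValueError("duplicate icd9_code in mapping table")
        if any(not e[1] for e in self.entries):
            raise ValueError("phewas_code must be nonempty")
        self._lookup = {e[0]: e[1] for e in self.entries}
        self._labels: dict[str, str] = {}
        for _, phewas, label in self.entries:
            self._labels.setdefault(phewas, label)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, icd9_code: str) -> str | None:
        return self._lookup.get(icd9_code)

    def label(self, phewas_code: str) -> str:
        return self._labels.get(phewas_code, phewas_code)


def read_code_map(path) -> PhewasCodeMap:
    """Read a 3-column TSV (icd9, phewas_code, label) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"code map {path} must have 3 columns, got {df.shape[1]}")
    cols = df.columns[:3]
    return PhewasCodeMap(entries=[tuple(r) for r in df[cols].itertuples(index=False)])


def truncation_map(vocab: list[str]) -> PhewasCodeMap:
    """Fallback rollup for synthetic vocabularies: truncate each ICD-9 string
    to at most 3 characters before the dot (e.g. ``"296.22" -> "296"``)."""
    entries = []
    for code in vocab:
        stem = code.split(".", 1)[0][:3]
        entries.append((code, stem, stem))
    return PhewasCodeMap(entries=entries)


def map_codes(
    raw: CodeCountMatrix,
    code_map: PhewasCodeMap,
    unmapped_policy: str = "drop",
) -> CodeCountMatrix:
    """Roll up an ICD-9 count matrix to PheWAS codes.

    Counts of ICD-9 codes mapping to the same PheWAS code are summed per
    subject.  Unmapped ICD-9 codes are dropped (default, with a logged count)
    or kept verbatim under their own name (``unmapped_policy="keep"``).
    Output columns are sorted by code string so results do not depend on the
    input column order.
    """
    if len(code_map) == 0:
        raise ValueError("code map is empty")
    if unmapped_policy not in ("drop", "keep"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")

    targets: list[str | None] = []
    n_unmapped = 0
    for code in raw.code_vocab:
        phewas = code_map.get(code)
        if phewas is None:
            n_unmapped += 1
            phewas = code if unmapped_policy == "keep" else None
        targets.append(phewas)
    if n_unmapped:
        logger.info(
            "map_codes: %d of %d input codes unmapped (policy=%s)",
            n_unmapped, raw.n_codes, unmapped_policy,
        )

    out_vocab = sorted({t for t in targets if t is not None})
    if not out_vocab:
        raise ValueError("no input code maps to any PheWAS code")
    col_of = {c: j for j, c in enumerate(out_vocab)}
    # column-aggregation matrix: old V x new V indicator
    rows, cols = [], []
    for j_old, t in enumerate(targets):
        if t is not None:
            rows.append(j_old)
            cols.append(col_of[t])
    agg = sp.csr_matrix(
        (np.ones(len(rows), dtype=raw.counts.dtype), (rows, cols)),
        shape=(raw.n_codes, len(out_vocab)),
    )
    merged = sp.csr_matrix(raw.counts @ agg)
    return CodeCountMatrix(list(raw.subject_ids), out_vocab, merged)


def frequency_filter(
    counts: CodeCountMatrix,
    min_prevalence: float = 0.005,
) -> tuple[CodeCountMatrix, list[str]]:
    """Eliminate codes occurring in fewer than ``min_prevalence`` of subjects.

    Prevalence is presence-based: a subject contributes if it has >= 1
    occurrence of the code.  Codes at exactly the threshold are retained
    (elimination applies strictly below it).  Subjects whose rows become
    all-zero are retained but logged; their topic scores downstream equal the
    symmetric prior mean.

    Returns the filtered matrix and the list of removed codes.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    n = counts.n_subjects
    n_present = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    keep = n_present >= min_prevalence * n
    removed = [c for c, k in zip(counts.code_vocab, keep) if not k]
    kept_vocab = [c for c, k in zip(counts.code_vocab, keep) if k]
    if not kept_vocab:
        raise ValueError(
            "frequency filter removed every code; nothing left to model"
        )
    filtered = CodeCountMatrix(
        list(counts.subject_ids), kept_vocab, counts.counts[:, keep]
    )
    n_empty = int((np.asarray(filtered.counts.sum(axis=1)).ravel() == 0).sum())
    if n_empty:
        logger.warning(
            "frequency_filter: %d subjects left with zero retained codes", n_empty
        )
    return filtered, removed
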