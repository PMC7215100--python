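"""Exact global pairwise protein alignment and the ortholog identity rule.

The aligner is a Needleman-Wunsch dynamic program with a linear gap
penalty and a substitution matrix (BLOSUM62 by default).  The statistic it
feeds is the fraction (identical + similar aligned residues) / alignment
length, where a non-identical aligned pair counts as *similar* iff its
substitution score reaches a minimum (2 in BLOSUM62 units by default; the
laxer any-positive-score convention leaves unrelated equal-length protein
pairs at an identity of 0.30 +/- 0.04, which would make the 30% ortholog
cutoff meaningless).  A pair of targets is called an ortholog pair when
that fraction strictly exceeds a threshold (0.30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "OrthologDecision",
    "ScoringConfig",
    "global_align",
    "identity_fraction",
    "ortholog_decision",
    "pair_identity",
]


class AlignmentError(ValueError):
    """Raised for empty sequences or residues absent from the matrix."""


@dataclass(frozen=True)
class ScoringConfig:
    """Substitution matrix (packaged with Biopython), linear gap penalty,
    and the minimum substitution score for calling a non-identical aligned
    pair "similar"."""

    matrix_name: str = "BLOSUM62"
    gap_penalty: float = -8.0
    similarity_min_score: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_penalty >= 0:
            raise AlignmentError("gap_penalty must be negative")
        if self.similarity_min_score <= 0:
            raise AlignmentError("similarity_min_score must be positive")


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=4)
def _matrix_arrays(name: str) -> tuple[dict[str, int], np.ndarray]:
    matrix = _load_matrix(name)
    index = {ch: i for i, ch in enumerate(matrix.alphabet)}
    return index, np.asarray(matrix, dtype=float)


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with its column tallies.

    ``aligned_a``/``aligned_b`` are gapped strings of equal length;
    ``n_identical`` counts columns with equal residues, ``n_similar``
    counts non-identical gap-free columns whose substitution score reaches
    the configured minimum.  Gap columns count as neither.
    """

    aligned_a: str
    aligned_b: str
    alignment_length: int
    n_identical: int
    n_similar: int
    score: float


def _check_sequence(seq: str, alphabet: str, which: str) -> str:
    if not seq:
        raise AlignmentError(f"sequence {which} is empty")
    seq = seq.upper()
    for ch in seq:
        if ch not in alphabet:
            raise AlignmentError(
                f"residue {ch!r} in sequence {which} is absent from the "
                "substitution matrix"
            )
    return seq


def _needleman_wunsch(a: str, b: str, scoring: ScoringConfig) -> AlignmentResult:
    matrix = _load_matrix(scoring.matrix_name)
    index, scores = _matrix_arrays(scoring.matrix_name)
    g = float(scoring.gap_penalty)
    n, m = len(a), len(b)

    ai = np.fromiter((index[c] for c in a), dtype=np.intp, count=n)
    bi = np.fromiter((index[c] for c in b), dtype=np.intp, count=m)
    sub = scores[np.ix_(ai, bi)]

    S = np.empty((n + 1, m + 1))
    S[0, :] = g * np.arange(m + 1)
    S[:, 0] = g * np.arange(n + 1)
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        # candidate without a horizontal (left) gap move in this row
        best = np.maximum(S[i - 1, :-1] + sub[i - 1, :], S[i - 1, 1:] + g)
        # fold in left-gap moves via a running max:
        #   S[i,j] = max_{k<=j} best[k] + g*(j-k)
        S[i, 1:] = np.maximum.accumulate(best - g * j_idx) + g * j_idx
        S[i, 1:] = np.maximum(S[i, 1:], S[i, 0] + g * j_idx)

    # traceback; tie preference: diagonal, then up (gap in b), then left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = S[i, j]
        if i > 0 and j > 0 and here == S[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and here == S[i - 1, j] + g:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    n_identical = 0
    n_similar = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            n_identical += 1
        elif matrix[ca, cb] >= scoring.similarity_min_score:
            n_similar += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        alignment_length=len(aligned_a),
        n_identical=n_identical,
        n_similar=n_similar,
        score=float(S[n, m]),
    )


def global_align(
    seq_a: str, seq_b: str, scoring: ScoringConfig | None = None
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Deterministic: ties in the traceback prefer diagonal, then a gap in
    ``seq_b``, then a gap in ``seq_a``; the pair is additionally aligned in
    a canonical (lexicographic) order internally so that swapping the
    arguments yields the mirrored alignment with identical tallies.
    """
    scoring = scoring or ScoringConfig()
    alphabet = str(_load_matrix(scoring.matrix_name).alphabet)
    a = _check_sequence(seq_a, alphabet, "a")
    b = _check_sequence(seq_b, alphabet, "b")
    if a <= b:
        return _needleman_wunsch(a, b, scoring)
    r = _needleman_wunsch(b, a, scoring)
    return AlignmentResult(
        aligned_a=r.aligned_b,
        aligned_b=r.aligned_a,
        alignment_length=r.alignment_length,
        n_identical=r.n_identical,
        n_similar=r.n_similar,
        score=r.score,
    )


def identity_fraction(result: AlignmentResult) -> float:
    """(identical + similar aligned residues) / alignment length."""
    return (result.n_identical + result.n_similar) / result.alignment_length


@dataclass(frozen=True)
class OrthologDecision:
    identity_fraction: float
    threshold: float
    is_ortholog: bool


def ortholog_decision(identity: float, threshold: float = 0.30) -> OrthologDecision:
    """Strict-inequality call: ortholog iff identity > threshold."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return OrthologDecision(
        identity_fraction=identity,
        threshold=threshold,
        is_ortholog=identity > threshold,
    )


def pair_identity(
    seq_a: str, seq_b: str, scoring: ScoringConfig | None = None
) -> float:
    """Identity fraction of the optimal global alignment of two sequences."""
    return identity_fraction(global_align(seq_a, seq_b, scoring))
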