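"""Position-specific profile models for family assignment and query alignment.

A family profile is built from the reference MSA: the well-occupied columns
(gap fraction below a threshold) become match columns, each carrying a
pseudocount-smoothed emission distribution over the 20 amino acids.  A query
is aligned to the profile by global affine-gap dynamic programming with
log-odds match scores in bits; the resulting column map places each query
residue into reference MSA coordinates, which is what the parsimony grafting
step consumes.

This is a deliberately simple position-specific scoring model with affine
gaps rather than a full profile HMM: it is deterministic, exhaustively
testable against a brute-force alignment oracle, and sufficient for family
selection and column mapping.  No E-value calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .reference_library import FamilyMSA

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUITY_CODES",
    "ProfileModel",
    "AlignedQuery",
    "build_profile",
    "score_and_align",
    "best_family",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity/rare codes scored as zero log-odds rather than rejected
AMBIGUITY_CODES = "XBZUO"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ProfileModel:
    family_id: str
    #: 1-based MSA column indices retained as match columns, strictly increasing
    match_columns: list[int]
    #: (n_match_columns, 20) emission probabilities, rows sum to 1
    emissions: np.ndarray
    #: (20,) background distribution
    background: np.ndarray
    gap_open_bits: float = 4.0
    gap_extend_bits: float = 0.5

    def __post_init__(self) -> None:
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        cols = self.match_columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("match_columns must be strictly increasing")


@dataclass
class AlignedQuery:
    query_id: str
    bit_score: float
    #: match column index (1-based MSA coordinate) -> 1-based query residue
    #: position, or None where the query has a gap at that column
    column_map: dict[int, Optional[int]]
    fraction_matched: float


def build_profile(
    msa: FamilyMSA,
    gap_fraction_max: float = 0.5,
    pseudocount_alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    family_id: Optional[str] = None,
) -> ProfileModel:
    """Build a profile from a family MSA.

    Match columns are those with gap fraction <= ``gap_fraction_max``.  The
    emission probability for residue ``a`` in column ``c`` is
    ``(count_a(c) + alpha * q_a) / (n_c + alpha)`` where ``n_c`` counts the
    standard residues observed in the column and ``q`` is the background
    (uniform 1/20 by default).  Ambiguity codes in the MSA are treated as
    missing and contribute to neither counts nor ``n_c``.
    """
    if not msa.rows:
        raise ValueError("empty MSA")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    n_rows = len(msa.rows)
    length = msa.alignment_length
    counts = np.zeros((length, 20))
    gaps = np.zeros(length, dtype=int)
    for row in msa.rows.values():
        for c, ch in enumerate(row):
            if ch == "-":
                gaps[c] += 1
            else:
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[c, idx] += 1
    match = [c for c in range(length) if gaps[c] / n_rows <= gap_fraction_max]
    if not match:
        raise ValueError("uninformative alignment: no match columns")
    n_c = counts[match].sum(axis=1, keepdims=True)
    emissions = (counts[match] + pseudocount_alpha * background) / (n_c + pseudocount_alpha)
    return ProfileModel(
        family_id=family_id or msa.family_id,
        match_columns=[c + 1 for c in match],
        emissions=emissions,
        background=background,
    )


# DP cell states; tie order at every max is M > D > I (match > delete > insert)
_M, _D, _I = 0, 1, 2
_NEG = -1e30


@njit(cache=True)
def _gotoh(S, go, ge):  # pragma: no cover - exercised via score_and_align
    """Global affine-gap DP.  S[i, j] = match score of column i with residue j.

    A gap run of length g costs go + g*ge.  Returns the three score layers
    and per-layer traceback pointers (predecessor state index).
    """
    M, L = S.shape
    m = np.full((M + 1, L + 1), _NEG)
    d = np.full((M + 1, L + 1), _NEG)
    ins = np.full((M + 1, L + 1), _NEG)
    tb_m = np.zeros((M + 1, L + 1), dtype=np.int8)
    tb_d = np.zeros((M + 1, L + 1), dtype=np.int8)
    tb_i = np.zeros((M + 1, L + 1), dtype=np.int8)
    m[0, 0] = 0.0
    for i in range(1, M + 1):
        d[i, 0] = -go - i * ge
        tb_d[i, 0] = _D if i > 1 else _M
    for j in range(1, L + 1):
        ins[0, j] = -go - j * ge
        tb_i[0, j] = _I if j > 1 else _M
    for i in range(1, M + 1):
        for j in range(1, L + 1):
            # match: consume column i and residue j
            best = m[i - 1, j - 1]
            state = _M
            if d[i - 1, j - 1] > best:
                best = d[i - 1, j - 1]
                state = _D
            if ins[i - 1, j - 1] > best:
                best = ins[i - 1, j - 1]
                state = _I
            m[i, j] = best + S[i - 1, j - 1]
            tb_m[i, j] = state
            # delete: consume column i, gap in query
            best = m[i - 1, j] - go - ge
            state = _M
            if d[i - 1, j] - ge > best:
                best = d[i - 1, j] - ge
                state = _D
            if ins[i - 1, j] - go - ge > best:
                best = ins[i - 1, j] - go - ge
                state = _I
            d[i, j] = best
            tb_d[i, j] = state
            # insert: consume residue j, no column
            best = m[i, j - 1] - go - ge
            state = _M
            if d[i, j - 1] - go - ge > best:
                best = d[i, j - 1] - go - ge
                state = _D
            if ins[i, j - 1] - ge > best:
                best = ins[i, j - 1] - ge
                state = _I
            ins[i, j] = best
            tb_i[i, j] = state
    return m, d, ins, tb_m, tb_d, tb_i


def _match_scores(query: str, profile: ProfileModel) -> np.ndarray:
    """(M, L) log2-odds scores; ambiguity codes score exactly 0."""
    log_odds = np.log2(profile.emissions / profile.background)  # (M, 20)
    L = len(query)
    S = np.zeros((len(profile.match_columns), L))
    for j, ch in enumerate(query):
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            S[:, j] = log_odds[:, idx]
        elif ch not in AMBIGUITY_CODES:
            raise ValueError(f"invalid residue {ch!r} at query position {j + 1}")
    return S


def score_and_align(query: str, profile: ProfileModel, query_id: str = "query") -> AlignedQuery:
    """Globally align a query sequence to a profile.

    Returns the bit score (sum of per-column log-odds minus affine gap
    penalties) and the map from profile match columns to query residue
    positions.  Traceback is deterministic: on score ties the path prefers
    match over delete over insert.
    """
    query = query.upper().replace("*", "")
    if not query:
        raise ValueError("empty query sequence")
    S = _match_scores(query, profile)
    go, ge = profile.gap_open_bits, profile.gap_extend_bits
    m, d, ins, tb_m, tb_d, tb_i = _gotoh(S, go, ge)
    M, L = S.shape
    finals = (m[M, L], d[M, L], ins[M, L])
    state = int(np.argmax(finals))  # argmax returns first max: M > D > I
    score = float(finals[state])
    # traceback
    column_map: dict[int, Optional[int]] = {}
    i, j = M, L
    while i > 0 or j > 0:
        if state == _M:
            prev = int(tb_m[i, j])
            column_map[profile.match_columns[i - 1]] = j
            i, j = i - 1, j - 1
        elif state == _D:
            prev = int(tb_d[i, j])
            column_map[profile.match_columns[i - 1]] = None
            i -= 1
        else:
            prev = int(tb_i[i, j])
            j -= 1
        state = prev
    matched = sum(1 for v in column_map.values() if v is not None)
    return AlignedQuery(
        query_id=query_id,
        bit_score=score,
        column_map=dict(sorted(column_map.items())),
        fraction_matched=matched / len(profile.match_columns),
    )


def best_family(
    query: str,
    profiles: list[ProfileModel],
    min_bits: float = 0.0,
    query_id: str = "query",
) -> Optional[tuple[str, AlignedQuery]]:
    """Score a query against a library of profiles; return the best family.

    Ties on bit score break toward the lexicographically smallest family id.
    Returns None when the best score falls below ``min_bits``.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    best: Optional[tuple[str, AlignedQuery]] = None
    for prof in sorted(profiles, key=lambda p: p.family_id):
        aligned = score_and_align(query, prof, query_id=query_id)
        if best is None or aligned.bit_score > best[1].bit_score:
            best = (prof.family_id, aligned)
    assert best is not None
    if best[1].bit_score < min_bits:
        return None
    return best
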