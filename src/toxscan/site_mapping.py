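"""Anchor the ten-site catalog on a reference sequence and map it onto queries.

Two routes produce a :class:`SiteProfile`: a precomputed multiple alignment
(``locate_reference_columns`` + ``extract_site_profile``) or the built-in
affine-gap global aligner for a single query (``profile_from_pairwise``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices

from .catalog import N_SITES, SiteCatalog
from .io_formats import GAP, SequenceRecord

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    query: str       # gapped query string
    reference: str   # gapped reference string, same length
    score: float

    def __post_init__(self) -> None:
        if len(self.query) != len(self.reference):
            raise ValueError("aligned strings must have equal length")


def _substitution_array(name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    return np.asarray(mat, dtype=float), index


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.fromiter((index[ch] for ch in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in substitution matrix") from exc


def global_align_pair(query: SequenceRecord, reference: SequenceRecord,
                      scoring: Scoring = Scoring()) -> PairwiseAlignment:
    """Optimal global alignment (Needleman-Wunsch-Gotoh, affine gaps).

    Traceback ties are broken deterministically: substitution first, then a
    gap placed in the query string, then a gap placed in the reference.
    """
    q, r = query.ungapped, reference.ungapped
    if not q or not r:
        raise ValueError("cannot align empty sequences")

    submat, index = _substitution_array(scoring.matrix)
    qi, ri = _encode(q, index), _encode(r, index)
    n, m = len(q), len(r)
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)

    # M: q[i-1] ~ r[j-1]; X: q[i-1] ~ gap (gap in reference string);
    # Y: gap ~ r[j-1] (gap in query string).
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    jj = np.arange(1, m + 1, dtype=float)
    Y[0, 1:] = -(go + jj * ge)
    ii = np.arange(1, n + 1, dtype=float)
    X[1:, 0] = -(go + ii * ge)

    ext = np.arange(m + 1, dtype=float) * ge  # for the same-row prefix scan
    for i in range(1, n + 1):
        scores = submat[qi[i - 1], ri]  # s(q_i, r_j) for all j
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = scores + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - go - ge,
            X[i - 1, 1:] - ge,
        )
        # Y[i,j] = max(max(M,X)[i,j-1] - go - ge, Y[i,j-1] - ge): prefix max
        B = np.maximum(M[i], X[i]) + ext
        shifted = np.empty(m + 1)
        shifted[0] = Y[i, 0] + 0.0
        shifted[1:] = B[:-1] - go
        Y[i] = np.maximum.accumulate(shifted) - ext

    # traceback; tie preference M > Y > X throughout
    def _best(candidates: list[tuple[str, float]]) -> str:
        best_state, best_value = candidates[0]
        for cand, value in candidates[1:]:
            if value > best_value:
                best_state, best_value = cand, value
        return best_state

    aligned_q: list[str] = []
    aligned_r: list[str] = []
    i, j = n, m
    state = _best([("M", M[n, m]), ("Y", Y[n, m]), ("X", X[n, m])])
    score = {"M": M[n, m], "Y": Y[n, m], "X": X[n, m]}[state]
    while i > 0 or j > 0:
        if state == "M":
            aligned_q.append(q[i - 1])
            aligned_r.append(r[j - 1])
            i, j = i - 1, j - 1
            state = _best([("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])])
        elif state == "Y":
            aligned_q.append(GAP)
            aligned_r.append(r[j - 1])
            j -= 1
            state = _best([
                ("M", M[i, j] - go - ge),
                ("Y", Y[i, j] - ge),
                ("X", X[i, j] - go - ge),
            ])
        else:  # X
            aligned_q.append(q[i - 1])
            aligned_r.append(GAP)
            i -= 1
            state = _best([
                ("M", M[i, j] - go - ge),
                ("Y", Y[i, j] - go - ge),
                ("X", X[i, j] - ge),
            ])
    return PairwiseAlignment(
        query="".join(reversed(aligned_q)),
        reference="".join(reversed(aligned_r)),
        score=float(score),
    )


# ---------------------------------------------------------------------------
# column mapping and profile extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteProfile:
    """Residues at the ten catalog sites plus inter-site insertion lengths."""

    sequence_id: str
    site_residues: tuple[str, ...]     # length 10; residue letter or '-'
    insertion_lengths: tuple[int, ...]  # length 9; excess query residues

    def __post_init__(self) -> None:
        if len(self.site_residues) != N_SITES:
            raise ValueError("profile must have exactly 10 site entries")
        if len(self.insertion_lengths) != N_SITES - 1:
            raise ValueError("profile must have exactly 9 insertion entries")
        if any(v < 0 for v in self.insertion_lengths):
            raise ValueError("insertion lengths must be non-negative")


def _find_record(alignment: list[SequenceRecord], record_id: str) -> SequenceRecord:
    for rec in alignment:
        if rec.id == record_id:
            return rec
    raise KeyError(f"sequence {record_id!r} not present in alignment")


def locate_reference_columns(alignment: list[SequenceRecord], reference_id: str,
                             catalog: SiteCatalog) -> tuple[int, ...]:
    """0-based alignment columns holding the catalog positions of the reference.

    A residue-identity guard compares the reference row against the catalog's
    expected residues and fails hard on mismatch -- the typical symptom of a
    wrong isoform or numbering scheme.
    """
    reference = _find_record(alignment, reference_id)
    columns: list[int] = []
    position_to_column: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(reference.residues):
        if ch != GAP:
            pos += 1
            position_to_column[pos] = col
    for site in catalog.sites:
        if site.position not in position_to_column:
            raise ValueError(
                f"reference {reference_id!r} has only {pos} residues; "
                f"site {site.index} needs position {site.position}"
            )
        col = position_to_column[site.position]
        found = reference.residues[col]
        if found != site.residue:
            raise ValueError(
                f"numbering mismatch for site {site.index}: expected "
                f"{site.residue!r} at reference position {site.position}, "
                f"found {found!r} (wrong isoform or numbering?)"
            )
        columns.append(col)
    return tuple(columns)


def extract_site_profile(alignment: list[SequenceRecord], sequence_id: str,
                         columns: tuple[int, ...],
                         reference_id: str) -> SiteProfile:
    """Pull the ten site residues and inter-site insertion lengths for one row.

    Insertion length for interval k is the query's non-gap count strictly
    between anchor columns k and k+1 minus the reference's, floored at zero.
    """
    query = _find_record(alignment, sequence_id)
    reference = _find_record(alignment, reference_id)
    if len(columns) != N_SITES:
        raise ValueError("expected 10 anchor columns")
    width = len(query.residues)
    if any(not 0 <= c < width for c in columns):
        raise ValueError("anchor column out of range for alignment")

    site_residues = tuple(query.residues[c] for c in columns)
    insertions: list[int] = []
    for k in range(N_SITES - 1):
        lo, hi = columns[k] + 1, columns[k + 1]
        q_count = sum(1 for ch in query.residues[lo:hi] if ch != GAP)
        r_count = sum(1 for ch in reference.residues[lo:hi] if ch != GAP)
        insertions.append(max(0, q_count - r_count))
    return SiteProfile(
        sequence_id=sequence_id,
        site_residues=site_residues,
        insertion_lengths=tuple(insertions),
    )


def map_reference_positions(query: SequenceRecord, reference: SequenceRecord,
                            positions: Iterable[int],
                            scoring: Scoring = Scoring()) -> dict[int, int | None]:
    """Map 1-based reference positions to query positions via pairwise alignment.

    Positions falling opposite a gap in the query map to ``None``.  Useful
    for translating catalog numbering onto a homologue whose author
    numbering differs non-uniformly.
    """
    aln = global_align_pair(query, reference, scoring)
    mapping: dict[int, int | None] = {}
    targets = set(positions)
    q_pos = r_pos = 0
    for q_ch, r_ch in zip(aln.query, aln.reference):
        if q_ch != GAP:
            q_pos += 1
        if r_ch != GAP:
            r_pos += 1
            if r_pos in targets:
                mapping[r_pos] = q_pos if q_ch != GAP else None
    missing = targets - set(mapping)
    if missing:
        raise ValueError(f"reference shorter than positions {sorted(missing)}")
    return mapping


def profile_from_pairwise(query: SequenceRecord, reference: SequenceRecord,
                          catalog: SiteCatalog,
                          scoring: Scoring = Scoring()) -> SiteProfile:
    """Map the catalog onto a single ungapped query via pairwise alignment."""
    aln = global_align_pair(query, reference, scoring)
    rows = [
        SequenceRecord(id=query.id, residues=aln.query, aligned=True),
        SequenceRecord(id=reference.id, residues=aln.reference, aligned=True),
    ]
    columns = locate_reference_columns(rows, reference.id, catalog)
    return extract_site_profile(rows, query.id, columns, reference.id)
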