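"""Per-column conservation scoring and near-invariant window detection."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .io_formats import GAP, SequenceRecord


@dataclass(frozen=True)
class ColumnConservation:
    column: int
    majority_residue: str | None
    majority_fraction: float
    entropy_bits: float
    gap_fraction: float
    unreliable: bool  # gap fraction above 0.5 (or all-gap column)


def column_conservation(alignment: list[SequenceRecord]) -> list[ColumnConservation]:
    """Score every column: majority residue/fraction and Shannon entropy.

    Gaps are excluded from the residue distribution; the gap fraction is
    reported separately and columns that are mostly gap are flagged
    unreliable.  Entropy is ``-sum p log2 p`` over the residues present.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    width = len(alignment[0].residues)
    for rec in alignment:
        if len(rec.residues) != width:
            raise ValueError(f"input not aligned: record {rec.id!r}")

    n = len(alignment)
    out: list[ColumnConservation] = []
    for col in range(width):
        counts = Counter(rec.residues[col] for rec in alignment)
        n_gap = counts.pop(GAP, 0)
        gap_fraction = n_gap / n
        if not counts:
            out.append(
                ColumnConservation(col, None, 0.0, 0.0, 1.0, True)
            )
            continue
        total = n - n_gap
        majority, majority_count = max(
            counts.items(), key=lambda kv: (kv[1], kv[0])
        )
        # sorted keys: summation order (and hence the float result) must not
        # depend on the order sequences appear in
        entropy = -sum(
            (c / total) * math.log2(c / total)
            for _, c in sorted(counts.items())
        )
        out.append(
            ColumnConservation(
                column=col,
                majority_residue=majority,
                majority_fraction=majority_count / total,
                entropy_bits=max(0.0, entropy),
                gap_fraction=gap_fraction,
                unreliable=gap_fraction > 0.5,
            )
        )
    return out


def scan_invariant_windows(scores: list[ColumnConservation],
                           reference: SequenceRecord,
                           min_majority: float = 0.95,
                           window_length: int = 13) -> list[tuple[int, int]]:
    """Maximal runs of near-invariant columns, in ungapped reference coordinates.

    A run is a maximal stretch of consecutive columns whose majority fraction
    is at least ``min_majority``; runs spanning fewer than ``window_length``
    columns are dropped.  Each run is reported as an inclusive 1-based
    interval of reference positions (runs covering no reference residue are
    skipped).
    """
    if window_length < 1:
        raise ValueError("window length must be >= 1")
    if len(reference.residues) != len(scores):
        raise ValueError("reference row does not match score list length")

    # column -> 1-based reference position (None on reference gaps)
    ref_pos: list[int | None] = []
    pos = 0
    for ch in reference.residues:
        if ch != GAP:
            pos += 1
            ref_pos.append(pos)
        else:
            ref_pos.append(None)

    windows: list[tuple[int, int]] = []
    run_start: int | None = None

    def _close(run_start: int, run_end: int) -> None:
        if run_end - run_start + 1 < window_length:
            return
        positions = [p for p in ref_pos[run_start:run_end + 1] if p is not None]
        if positions:
            windows.append((positions[0], positions[-1]))

    for sc in scores:
        good = sc.majority_fraction >= min_majority and not sc.unreliable
        if good and run_start is None:
            run_start = sc.column
        elif not good and run_start is not None:
            _close(run_start, sc.column - 1)
            run_start = None
    if run_start is not None:
        _close(run_start, scores[-1].column)
    return windows
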