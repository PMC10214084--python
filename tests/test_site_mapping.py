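import functools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Align import substitution_matrices

from toxscan.io_formats import GAP, SequenceRecord
from toxscan.site_mapping import (
    PairwiseAlignment,
    Scoring,
    SiteProfile,
    extract_site_profile,
    global_align_pair,
    locate_reference_columns,
    map_reference_positions,
    profile_from_pairwise,
)
from toxscan.synthetic_data import FamilySpec, SubtypeSpec, simulate_family

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_score_dp(q: str, r: str, open_: float = 10.0, ext: float = 0.5) -> float:
    """Independent affine-gap DP, written as a memoised recursion over
    (i, j, state) -- a deliberately different formulation from the
    vectorised forward pass it checks."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else float("-inf")
        options = []
        if state == "M" and i > 0 and j > 0:
            s = BLOSUM62[q[i - 1], r[j - 1]]
            options = [best(i - 1, j - 1, prev) + s for prev in "MXY"]
        elif state == "X" and i > 0:  # q[i-1] against a gap
            options = [
                best(i - 1, j, "M") - open_ - ext,
                best(i - 1, j, "Y") - open_ - ext,
                best(i - 1, j, "X") - ext,
            ]
        elif state == "Y" and j > 0:  # gap against r[j-1]
            options = [
                best(i, j - 1, "M") - open_ - ext,
                best(i, j - 1, "X") - open_ - ext,
                best(i, j - 1, "Y") - ext,
            ]
        return max(options, default=float("-inf"))

    return max(best(len(q), len(r), state) for state in "MXY")


def oracle_score_enumeration(q: str, r: str, open_: float = 10.0,
                             ext: float = 0.5) -> float:
    """Exhaustively enumerate every global alignment of two tiny strings."""

    def alignments(i, j):
        if i == len(q) and j == len(r):
            yield ("", "")
            return
        if i < len(q) and j < len(r):
            for a, b in alignments(i + 1, j + 1):
                yield (q[i] + a, r[j] + b)
        if i < len(q):
            for a, b in alignments(i + 1, j):
                yield (q[i] + a, GAP + b)
        if j < len(r):
            for a, b in alignments(i, j + 1):
                yield (GAP + a, r[j] + b)

    def score(a: str, b: str) -> float:
        total = 0.0
        for x, y in zip(a, b):
            if x != GAP and y != GAP:
                total += BLOSUM62[x, y]
        for row in (a, b):
            run = 0
            for ch in row + "#":
                if ch == GAP:
                    run += 1
                elif run:
                    total -= open_ + run * ext
                    run = 0
        return total

    return max(score(a, b) for a, b in alignments(0, 0))


def _aligned_pair_score(aln: PairwiseAlignment) -> float:
    """Re-score an emitted alignment from its gapped strings alone."""
    total = 0.0
    for x, y in zip(aln.query, aln.reference):
        if x != GAP and y != GAP:
            total += BLOSUM62[x, y]
    for row in (aln.query, aln.reference):
        run = 0
        for ch in row + "#":
            if ch == GAP:
                run += 1
            elif run:
                total -= 10.0 + run * 0.5
                run = 0
    return total


# ---------------------------------------------------------------------------
# aligner
# ---------------------------------------------------------------------------

class TestGlobalAlign:
    def test_identity(self):
        aln = global_align_pair(SequenceRecord("q", "MKR"), SequenceRecord("r", "MKR"))
        assert aln.query == "MKR"
        assert aln.reference == "MKR"
        assert aln.score == sum(BLOSUM62[c, c] for c in "MKR")

    def test_single_gap(self):
        aln = global_align_pair(SequenceRecord("q", "MR"), SequenceRecord("r", "MKR"))
        assert aln.query == "M-R"
        assert aln.score == BLOSUM62["M", "M"] + BLOSUM62["R", "R"] - 10.0 - 0.5
        # exhaustive enumeration agrees
        assert aln.score == oracle_score_enumeration("MR", "MKR")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align_pair(SequenceRecord("q", "M"), SequenceRecord("r", ""))
        with pytest.raises(ValueError, match="non-empty"):
            SequenceRecord("", "M")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_tiny(self, seed):
        rng = random.Random(seed)
        q = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 5)))
        r = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 5)))
        aln = global_align_pair(SequenceRecord("q", q), SequenceRecord("r", r))
        assert aln.score == oracle_score_enumeration(q, r)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dp_oracle(self, seed):
        rng = random.Random(1000 + seed)
        q = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 12)))
        r = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 12)))
        aln = global_align_pair(SequenceRecord("q", q), SequenceRecord("r", r))
        assert aln.score == oracle_score_dp(q, r)
        # the emitted alignment achieves the reported score
        assert _aligned_pair_score(aln) == aln.score

    def test_traceback_prefers_substitution(self):
        # equal-length identical sequences must come back gap-free even when
        # gapped paths tie is impossible; sanity of the preference ordering
        aln = global_align_pair(SequenceRecord("q", "AAAA"), SequenceRecord("r", "AAAA"))
        assert GAP not in aln.query + aln.reference


# ---------------------------------------------------------------------------
# column mapping
# ---------------------------------------------------------------------------

def _toy_catalog():
    sample = simulate_family(
        FamilySpec(
            subtypes=(SubtypeSpec(name="S", site_residues=tuple("RIYWRVYCEF")),),
            seed=0,
        )
    )
    return sample


class TestLocateColumns:
    def test_ungapped_reference_identity_mapping(self):
        sample = _toy_catalog()
        aln = [
            SequenceRecord("REF", sample.reference.residues, aligned=True),
        ]
        cols = locate_reference_columns(aln, "REF", sample.catalog)
        assert cols == tuple(p - 1 for p in sample.catalog.positions())

    def test_leading_gap_offset(self):
        sample = _toy_catalog()
        aln = [
            SequenceRecord("REF", "-----" + sample.reference.residues, aligned=True),
        ]
        cols = locate_reference_columns(aln, "REF", sample.catalog)
        assert cols == tuple(p - 1 + 5 for p in sample.catalog.positions())

    def test_missing_reference(self):
        sample = _toy_catalog()
        aln = [SequenceRecord("other", sample.reference.residues, aligned=True)]
        with pytest.raises(KeyError):
            locate_reference_columns(aln, "REF", sample.catalog)

    def test_residue_identity_guard(self):
        sample = _toy_catalog()
        residues = list(sample.reference.residues)
        residues[sample.catalog.positions()[0] - 1] = "G"  # break site 1 anchor
        aln = [SequenceRecord("REF", "".join(residues), aligned=True)]
        with pytest.raises(ValueError, match="numbering mismatch"):
            locate_reference_columns(aln, "REF", sample.catalog)

    def test_reference_too_short(self):
        sample = _toy_catalog()
        aln = [SequenceRecord("REF", sample.reference.residues[:20], aligned=True)]
        with pytest.raises(ValueError, match="only"):
            locate_reference_columns(aln, "REF", sample.catalog)

    def test_planted_columns_recovered(self):
        spec = FamilySpec(
            subtypes=(
                SubtypeSpec(name="A", site_residues=tuple("RIYWRVYCEF")),
                SubtypeSpec(
                    name="B",
                    site_residues=tuple("RMYWRAY-EL".replace("-", GAP)),
                    indels=((5, 4),),
                ),
            ),
            background_prob=0.1,
            n_per_subtype=3,
            seed=5,
        )
        sample = simulate_family(spec)
        cols = locate_reference_columns(sample.alignment, "REF", sample.catalog)
        # truth: the reference row's non-gap positions at catalog anchors
        ref_row = sample.alignment[0].residues
        pos = 0
        expected = {}
        for col, ch in enumerate(ref_row):
            if ch != GAP:
                pos += 1
                expected[pos] = col
        assert cols == tuple(expected[p] for p in sample.catalog.positions())
        assert list(cols) == sorted(cols)  # strictly increasing


class TestExtractProfile:
    def test_query_equals_reference(self):
        sample = _toy_catalog()
        aln = [
            SequenceRecord("REF", sample.reference.residues, aligned=True),
            SequenceRecord("Q", sample.reference.residues, aligned=True),
        ]
        cols = locate_reference_columns(aln, "REF", sample.catalog)
        profile = extract_site_profile(aln, "Q", cols, "REF")
        assert profile.site_residues == tuple("RIYWRVYCEF")
        assert profile.insertion_lengths == (0,) * 9

    def test_planted_truth_recovered(self):
        spec = FamilySpec(
            subtypes=(
                SubtypeSpec(
                    name="INS",
                    site_residues=tuple("RIYWRVYCEF"),
                    indels=((5, 12), (7, 6)),
                ),
            ),
            background_prob=0.15,
            n_per_subtype=4,
            seed=9,
        )
        sample = simulate_family(spec)
        cols = locate_reference_columns(sample.alignment, "REF", sample.catalog)
        for truth in sample.truth:
            profile = extract_site_profile(
                sample.alignment, truth["sequence_id"], cols, "REF"
            )
            assert profile.site_residues == truth["site_residues"]
            assert profile.insertion_lengths == truth["insertion_lengths"]
            assert profile.insertion_lengths[4] == 12
            assert profile.insertion_lengths[6] == 6

    def test_gap_site_reported(self):
        spec = FamilySpec(
            subtypes=(
                SubtypeSpec(name="DEL", site_residues=tuple("RMYWRAYV" + GAP + "L")),
            ),
            seed=3,
        )
        sample = simulate_family(spec)
        cols = locate_reference_columns(sample.alignment, "REF", sample.catalog)
        profile = extract_site_profile(sample.alignment, "DEL_000", cols, "REF")
        assert profile.site_residues[8] == GAP

    def test_column_out_of_range(self):
        sample = _toy_catalog()
        aln = [
            SequenceRecord("REF", sample.reference.residues, aligned=True),
        ]
        with pytest.raises(ValueError, match="out of range"):
            extract_site_profile(aln, "REF", (0,) * 9 + (10_000,), "REF")

    def test_all_gap_column_insertion_invariant(self):
        spec = FamilySpec(
            subtypes=(
                SubtypeSpec(
                    name="A", site_residues=tuple("RIYWRVYCEF"), indels=((2, 3),)
                ),
            ),
            background_prob=0.1,
            n_per_subtype=2,
            seed=13,
        )
        sample = simulate_family(spec)
        cols = locate_reference_columns(sample.alignment, "REF", sample.catalog)
        before = [
            extract_site_profile(sample.alignment, t["sequence_id"], cols, "REF")
            for t in sample.truth
        ]
        width = len(sample.alignment[0].residues)
        for cut in (0, width // 2, width):
            padded = [
                SequenceRecord(
                    r.id,
                    r.residues[:cut] + GAP + r.residues[cut:],
                    aligned=True,
                )
                for r in sample.alignment
            ]
            cols2 = locate_reference_columns(padded, "REF", sample.catalog)
            after = [
                extract_site_profile(padded, t["sequence_id"], cols2, "REF")
                for t in sample.truth
            ]
            for b, a in zip(before, after):
                assert b.site_residues == a.site_residues
                assert b.insertion_lengths == a.insertion_lengths


class TestProfileFromPairwise:
    def test_reference_vs_itself(self):
        sample = _toy_catalog()
        profile = profile_from_pairwise(
            sample.reference, sample.reference, sample.catalog
        )
        assert profile.site_residues == tuple("RIYWRVYCEF")
        assert profile.insertion_lengths == (0,) * 9

    def test_planted_insert_recovered(self):
        spec = FamilySpec(
            subtypes=(
                SubtypeSpec(
                    name="I7", site_residues=tuple("RIYWRVYCEF"), indels=((5, 7),)
                ),
            ),
            background_prob=0.05,
            n_per_subtype=3,
            seed=21,
        )
        sample = simulate_family(spec)
        for rec, truth in zip(sample.sequences, sample.truth):
            profile = profile_from_pairwise(rec, sample.reference, sample.catalog)
            assert profile.site_residues == truth["site_residues"]
            assert profile.insertion_lengths[4] == 7

    def test_terminal_padding_invariant(self):
        sample = _toy_catalog()
        rec = sample.sequences[0]
        base = profile_from_pairwise(rec, sample.reference, sample.catalog)
        padded = SequenceRecord(rec.id, "GSGSGS" + rec.residues + "HHHHHH")
        after = profile_from_pairwise(padded, sample.reference, sample.catalog)
        assert base.site_residues == after.site_residues
        assert base.insertion_lengths == after.insertion_lengths


class TestMapReferencePositions:
    def test_identity(self):
        rec = SequenceRecord("a", "ACDEFGHIKL")
        mapping = map_reference_positions(rec, rec, [1, 5, 10])
        assert mapping == {1: 1, 5: 5, 10: 10}

    def test_shifted_by_insert(self):
        ref = SequenceRecord("r", "ACDEFGHIKL")
        query = SequenceRecord("q", "ACDEFWWWGHIKL")  # 3 extra before G
        mapping = map_reference_positions(query, ref, [2, 6, 10])
        assert mapping[2] == 2
        assert mapping[6] == 9
        assert mapping[10] == 13

    def test_deleted_position_maps_to_none(self):
        ref = SequenceRecord("r", "ACDEFGHIKLMNPQRSTVWY")
        query = SequenceRecord("q", "ACDEFGHIKMNPQRSTVWY")  # L deleted
        mapping = map_reference_positions(query, ref, [10])
        assert mapping[10] is None


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_profile_site_count_invariant(seed):
    rng = random.Random(seed)
    residues = tuple(rng.choice("ACDEFGHIKLMNPQRSTVWY-") for _ in range(10))
    inserts = tuple(rng.randint(0, 5) for _ in range(9))
    profile = SiteProfile("s", residues, inserts)
    assert len(profile.site_residues) == 10
    assert all(v >= 0 for v in profile.insertion_lengths)
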