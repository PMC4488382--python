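import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from luciscreen.align import (
    AlignParams,
    PairwiseAlignment,
    global_align,
    identity_matrix,
    local_align,
    percent_identity,
    progressive_msa,
    summarize_identity_matrix,
)
from luciscreen.seqio import IdentityMatrix, MultipleAlignment, SequenceRecord

from .conftest import AA20, random_protein

B62 = substitution_matrices.load("BLOSUM62")


def score_alignment(row_a: str, row_b: str, gap_open: float, gap_extend: float) -> float:
    """Score a complete gapped alignment directly from its columns
    (independent of any DP): substitution scores plus per-gap-run costs of
    gap_open + (k-1)*gap_extend."""
    total = 0.0
    for run_in, run in [("a", row_a), ("b", row_b)]:
        k = 0
        for ch in run:
            if ch == "-":
                k += 1
            else:
                if k:
                    total -= gap_open + (k - 1) * gap_extend
                k = 0
        if k:
            total -= gap_open + (k - 1) * gap_extend
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            total += B62[ca, cb]
    return total


def enumerate_global_best(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Brute force: enumerate every global alignment (no both-gap columns)
    and return the best direct score."""
    best = [-np.inf]

    def rec(i, j, ra, rb):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_alignment(ra, rb, gap_open, gap_extend))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            rec(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            rec(i, j + 1, ra + "-", rb + b[j])

    rec(0, 0, "", "")
    return best[0]


def local_dp_no_affine_shortcut(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Reference local DP without affine-state shortcuts: every gap length
    is scanned explicitly (O(n*m*(n+m))). H[i,j] is the best local
    alignment ending with the match column (a[i-1], b[j-1]); optimal local
    alignments begin and end with match columns since end gaps only cost."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0

    def cost(k: int) -> float:
        return gap_open + (k - 1) * gap_extend

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = H[i - 1, j - 1]
            for k in range(1, i - 1 + 1):
                if i - 1 - k >= 0:
                    prev = max(prev, H[i - 1 - k, j - 1] - cost(k))
            for k in range(1, j - 1 + 1):
                if j - 1 - k >= 0:
                    prev = max(prev, H[i - 1, j - 1 - k] - cost(k))
            H[i, j] = max(0.0, prev + B62[a[i - 1], b[j - 1]])
            best = max(best, H[i, j])
    return best


class TestGlobalAlign:
    def test_identical_sequences_gapless(self):
        a = SequenceRecord(id="a", seq="MKVIALHDHG")
        pw = global_align(a, SequenceRecord(id="b", seq="MKVIALHDHG"))
        assert pw.row_a == pw.row_b == "MKVIALHDHG"
        assert percent_identity(pw) == 100.0

    def test_single_gap_placement(self):
        # exhaustive enumeration of all alignments of ACDE vs ADE agrees
        pw = global_align(SequenceRecord(id="a", seq="ACDE"), SequenceRecord(id="b", seq="ADE"))
        assert (pw.row_a, pw.row_b) == ("ACDE", "A-DE")
        assert pw.score == enumerate_global_best("ACDE", "ADE", 10.0, 0.5)

    def test_score_symmetry(self):
        rng = np.random.default_rng(1)
        for i in range(10):
            a = random_protein(rng, int(rng.integers(5, 30)), "a")
            b = random_protein(rng, int(rng.integers(5, 30)), "b")
            assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    def test_mixed_moltypes_rejected(self):
        with pytest.raises(ValueError, match="moltype|align"):
            global_align(
                SequenceRecord(id="a", seq="MKV"),
                SequenceRecord(id="b", seq="ACGT", moltype="dna"),
            )

    def test_matches_brute_force_enumeration_short_sequences(self):
        """DP optimum equals exhaustive alignment enumeration, lengths <= 8."""
        rng = np.random.default_rng(9)
        cases = [("ACDE", "ADE"), ("WW", "W"), ("A", "A")]
        for _ in range(12):
            la, lb = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            cases.append(
                (
                    "".join(rng.choice(list(AA20)) for _ in range(la)),
                    "".join(rng.choice(list(AA20)) for _ in range(lb)),
                )
            )
        for a, b in cases:
            pw = global_align(SequenceRecord(id="a", seq=a), SequenceRecord(id="b", seq=b))
            assert pw.score == pytest.approx(enumerate_global_best(a, b, 10.0, 0.5)), (a, b)
            # and the emitted rows actually achieve that score
            assert score_alignment(pw.row_a, pw.row_b, 10.0, 0.5) == pytest.approx(pw.score)

    def test_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(2)
        a = random_protein(rng, 25, "a")
        b = random_protein(rng, 18, "b")
        pw = global_align(a, b)
        assert pw.row_a.replace("-", "") == a.seq
        assert pw.row_b.replace("-", "") == b.seq


class TestLocalAlign:
    def test_embedded_query_fully_covered(self):
        q = SequenceRecord(id="q", seq="MKVIALHDHG")
        t = SequenceRecord(id="t", seq="AAAA" + q.seq + "WWWW")
        pw = local_align(q, t)
        assert pw.row_a == q.seq
        assert percent_identity(pw) == 100.0

    def test_unrelated_sequences_empty_alignment(self):
        pw = local_align(
            SequenceRecord(id="a", seq="AAAAAAAA"), SequenceRecord(id="b", seq="WWWWWWWW")
        )
        assert pw.score == 0.0
        assert pw.row_a == pw.row_b == ""

    def test_matches_reference_dp_on_random_50mers(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = "".join(rng.choice(list(AA20)) for _ in range(50))
            b = "".join(rng.choice(list(AA20)) for _ in range(50))
            pw = local_align(SequenceRecord(id="a", seq=a), SequenceRecord(id="b", seq=b))
            assert pw.score == pytest.approx(local_dp_no_affine_shortcut(a, b, 10.0, 0.5))


class TestPercentIdentity:
    def test_two_conventions_forced_example(self):
        pw = PairwiseAlignment("a", "b", "ACDE", "A-DE", 0.0)
        assert percent_identity(pw, "ignore_gaps") == 100.0
        assert percent_identity(pw, "include_gaps") == 75.0

    def test_identical_rows_100_under_both(self):
        pw = PairwiseAlignment("a", "b", "MKV", "MKV", 0.0)
        assert percent_identity(pw, "ignore_gaps") == 100.0
        assert percent_identity(pw, "include_gaps") == 100.0

    def test_zero_denominator_is_an_error(self):
        pw = PairwiseAlignment("a", "b", "AA--", "--WW", 0.0)
        with pytest.raises(ZeroDivisionError):
            percent_identity(pw, "ignore_gaps")

    def test_x_never_identical(self):
        pw = PairwiseAlignment("a", "b", "XK", "XK", 0.0)
        assert percent_identity(pw, "ignore_gaps") == 50.0

    def test_ignore_gaps_at_least_include_gaps(self):
        rng = np.random.default_rng(8)
        for i in range(50):
            a = random_protein(rng, int(rng.integers(5, 40)), "a")
            b = random_protein(rng, int(rng.integers(5, 40)), "b")
            pw = global_align(a, b)
            assert percent_identity(pw, "ignore_gaps") >= percent_identity(pw, "include_gaps")


class TestIdentityMatrix:
    def test_three_identical_sequences(self):
        recs = [SequenceRecord(id=f"s{i}", seq="MKVIALHDHG") for i in range(3)]
        m = identity_matrix(recs)
        off = m.values[~np.eye(3, dtype=bool)]
        assert (off == 100.0).all()

    def test_gapless_family_matches_hamming_truth(self):
        rng = np.random.default_rng(12)
        root = "".join(rng.choice(list(AA20)) for _ in range(100))
        seqs = {}
        for i, k in enumerate([0, 5, 10]):
            s = list(root)
            for pos in rng.choice(100, size=k, replace=False):
                s[pos] = "W" if s[pos] != "W" else "Y"
            seqs[f"m{i}"] = "".join(s)
        msa = MultipleAlignment(list(seqs.items()))
        m = identity_matrix(msa, "ignore_gaps")
        for (ida, sa), (idb, sb) in itertools.combinations(seqs.items(), 2):
            ham = sum(x != y for x, y in zip(sa, sb)) / 100
            assert m.pair(ida, idb) == pytest.approx(100 * (1 - ham))

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        recs = [random_protein(rng, 30, f"s{i}") for i in range(4)]
        m1 = identity_matrix(recs)
        m2 = identity_matrix(recs[::-1])
        for a, b in itertools.combinations([r.id for r in recs], 2):
            assert m1.pair(a, b) == pytest.approx(m2.pair(a, b))

    def test_summary_of_trivial_matrix(self):
        m = IdentityMatrix(labels=["a", "b"], values=np.array([[100.0, 73.0], [73.0, 100.0]]))
        s = summarize_identity_matrix(m)
        assert s["min"] == s["mean"] == 73
        assert s["n_pairs"] == 1


class TestIdentityProperties:
    """Hypothesis-driven invariants of the identity conventions."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    protein = st.text(alphabet=AA20, min_size=1, max_size=25)

    @given(a=protein, b=protein)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identity_bounds_and_symmetry(self, a, b):
        pw = global_align(SequenceRecord(id="a", seq=a), SequenceRecord(id="b", seq=b))
        ig = percent_identity(pw, "ignore_gaps")
        inc = percent_identity(pw, "include_gaps")
        assert 0 <= inc <= ig <= 100
        rev = global_align(SequenceRecord(id="b", seq=b), SequenceRecord(id="a", seq=a))
        assert pw.score == pytest.approx(rev.score)

    @given(a=protein)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_self_identity_is_100(self, a):
        pw = global_align(SequenceRecord(id="x", seq=a), SequenceRecord(id="y", seq=a))
        assert percent_identity(pw, "ignore_gaps") == 100.0


class TestProgressiveMSA:
    def test_two_records_equals_global_align(self):
        a = SequenceRecord(id="a", seq="MKVIALHDHG")
        b = SequenceRecord(id="b", seq="MKVIHDHG")
        msa = progressive_msa([a, b])
        pw = global_align(a, b)
        assert msa.rows == [("a", pw.row_a), ("b", pw.row_b)]

    def test_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(21)
        root = "".join(rng.choice(list(AA20)) for _ in range(60))
        recs = []
        for i in range(5):
            s = list(root)
            for pos in rng.choice(60, size=6, replace=False):
                s[pos] = AA20[int(rng.integers(20))]
            recs.append(SequenceRecord(id=f"m{i}", seq="".join(s)))
        msa = progressive_msa(recs)
        for rec in recs:
            assert msa.ungapped(rec.id) == rec.seq

    def test_planted_indel_family_column_recovery(self):
        """>=95% of truly homologous residue pairs end up in shared columns
        for a family at ~85% identity with planted indels."""
        rng = np.random.default_rng(31)
        L = 120
        root = "".join(rng.choice(list(AA20)) for _ in range(L))
        members = {}
        origin = {}  # member -> list of root positions per residue
        for i in range(6):
            s = list(root)
            for pos in rng.choice(L, size=15, replace=False):
                s[pos] = AA20[int(rng.integers(20))]
            pos_map = list(range(L))
            if i in (2, 4):  # planted 7-residue deletion
                start = 40 + 10 * i
                del s[start : start + 7]
                del pos_map[start : start + 7]
            members[f"m{i}"] = "".join(s)
            origin[f"m{i}"] = pos_map
        recs = [SequenceRecord(id=k, seq=v) for k, v in members.items()]
        msa = progressive_msa(recs)
        # column index of each residue (by root position) per member
        col_of = {}
        for rid in members:
            row = msa.row(rid)
            cols = [c for c, ch in enumerate(row) if ch != "-"]
            col_of[rid] = dict(zip(origin[rid], cols))
        shared = total = 0
        for ra, rb in itertools.combinations(members, 2):
            common = set(col_of[ra]) & set(col_of[rb])
            total += len(common)
            shared += sum(col_of[ra][p] == col_of[rb][p] for p in common)
        assert total > 0
        assert shared / total >= 0.95
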