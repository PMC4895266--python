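"""Bin enumeration, the conflict relation, read assignment and normalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmfp.binning import (
    Bin,
    ReadRecord,
    assign_read,
    build_count_matrix,
    conflicting,
    count_junctions,
    enumerate_bins,
    normalize,
    read_count_matrix_tsv,
    write_count_matrix_tsv,
    CountMatrix,
)
from nmfp.gene_model import GeneModel, Subexon


def _gene(lengths, gap=100):
    subs, pos = [], 0
    for i, L in enumerate(lengths, 1):
        subs.append(Subexon(i, pos, pos + L))
        pos += L + gap
    return GeneModel("g", "chr1", "+", subs)


class TestEnumerateBins:
    @pytest.mark.parametrize("n,p", [(1, 1), (3, 6), (8, 36)])
    def test_bin_count(self, n, p):
        scheme = enumerate_bins(_gene([100] * n))
        assert scheme.p == p == n + n * (n - 1) // 2

    def test_row_order_and_lengths(self):
        scheme = enumerate_bins(_gene([100, 200, 300]))
        assert [(b.k, b.l) for b in scheme.bins] == [
            (1, 1), (2, 2), (3, 3), (1, 2), (1, 3), (2, 3)
        ]
        assert [b.length for b in scheme.bins] == [100, 200, 300, 300, 400, 500]

    def test_P_proportional_to_length_and_sums_to_one(self):
        scheme = enumerate_bins(_gene([100, 300]))
        assert scheme.P == pytest.approx(
            np.array([100, 300, 400]) / 800.0
        )
        assert scheme.P.sum() == pytest.approx(1.0)

    def test_single_subexon(self):
        scheme = enumerate_bins(_gene([250]))
        assert scheme.p == 1 and scheme.P[0] == pytest.approx(1.0)


def _brute_force_conflict(bin_i, bin_j, n):
    """Independent oracle: bins conflict iff no isoform is consistent with both."""

    def consistent(v, b):
        if not (v[b.k - 1] and v[b.l - 1]):
            return False
        return all(v[x - 1] == 0 for x in range(b.k + 1, b.l))

    return not any(
        consistent(v, bin_i) and consistent(v, bin_j)
        for v in itertools.product((0, 1), repeat=n)
    )


class TestConflicting:
    def test_known_pairs(self):
        b13 = Bin(1, 3, 0, 0)
        b22 = Bin(2, 2, 1, 0)
        b12 = Bin(1, 2, 2, 0)
        b23 = Bin(2, 3, 3, 0)
        assert conflicting(b13, b22) and conflicting(b22, b13)
        assert not conflicting(b12, b23)
        assert not conflicting(b22, b22)

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_matches_isoform_consistency_oracle(self, n):
        scheme = enumerate_bins(_gene([100] * n))
        for bi, bj in itertools.combinations(scheme.bins, 2):
            assert conflicting(bi, bj) == _brute_force_conflict(bi, bj, n), (
                f"disagreement for bins ({bi.k},{bi.l}) vs ({bj.k},{bj.l})"
            )

    def test_conflict_matrix_symmetric_zero_diagonal(self):
        scheme = enumerate_bins(_gene([100] * 5))
        C = scheme.conflicts
        assert (C == C.T).all() and not C.diagonal().any()


class TestAssignRead:
    def test_within_one_subexon(self, scheme3):
        b = assign_read(ReadRecord("s1", 2, 2), scheme3)
        assert (b.k, b.l) == (2, 2)

    def test_spanning_read(self, scheme3):
        b = assign_read(ReadRecord("s1", 1, 3, ((1, 3),)), scheme3)
        assert (b.k, b.l) == (1, 3)

    def test_out_of_range_returns_none(self, scheme3):
        assert assign_read(ReadRecord("s1", 1, 5), scheme3) is None


class TestBuildCountMatrix:
    def test_counts_and_totals(self, scheme3):
        reads = [ReadRecord("A", 1, 1)] * 3
        counts = build_count_matrix(reads, scheme3, ["A", "B"])
        assert counts.U[scheme3.row(1, 1), 0] == 3
        assert counts.R.tolist() == [3, 0]

    def test_no_reads_zero_matrix(self, scheme3):
        counts = build_count_matrix([], scheme3, ["A"])
        assert not counts.U.any() and counts.R.tolist() == [0]

    def test_identical_read_sets_identical_columns(self, scheme3):
        reads = [ReadRecord(s, k, k) for s in "AB" for k in (1, 2, 2, 3)]
        counts = build_count_matrix(reads, scheme3, ["A", "B"])
        assert (counts.U[:, 0] == counts.U[:, 1]).all()

    def test_empty_sample_list_rejected(self, scheme3):
        with pytest.raises(ValueError, match="empty sample list"):
            build_count_matrix([], scheme3, [])

    def test_junction_tally(self):
        reads = [
            ReadRecord("A", 1, 3, ((1, 3),)),
            ReadRecord("A", 1, 3, ((1, 2), (2, 3))),
            ReadRecord("A", 2, 3),
        ]
        tally = count_junctions(reads)
        assert tally == {(1, 3): 1, (1, 2): 1, (2, 3): 2}


class TestNormalize:
    def test_worked_example(self):
        # two bins of lengths 100 and 300 (P = 0.25/0.75), U=[[10,30],[30,90]]
        # -> U'=[[20,20],[60,60]] after depth scaling, V all 40
        from nmfp.binning import BinScheme

        gene = _gene([100, 300])
        scheme = BinScheme(
            gene,
            [Bin(1, 1, 0, 100), Bin(2, 2, 1, 300)],
            P=np.array([0.25, 0.75]),
            conflicts=np.zeros((2, 2), dtype=bool),
        )
        counts = CountMatrix(scheme, ["a", "b"], np.array([[10, 30], [30, 90]]))
        V = normalize(counts).V
        assert V == pytest.approx(np.full((2, 2), 40.0))

    def test_equal_depth_equal_lengths_identity(self):
        scheme = enumerate_bins(_gene([100]))
        counts = CountMatrix(scheme, ["a", "b"], np.array([[7, 7]]))
        assert normalize(counts).V == pytest.approx(np.array([[7.0, 7.0]]))

    def test_depth_rescaling_invariance(self, rng):
        # doubling one sample's depth rescales V only by the common factor
        # Rbar'/Rbar: the normalized structure is depth-invariant
        scheme = enumerate_bins(_gene([100, 200, 150]))
        U = rng.integers(1, 50, size=(scheme.p, 4))
        counts1 = CountMatrix(scheme, list("abcd"), U)
        V1 = normalize(counts1).V
        U2 = U.copy()
        U2[:, 1] *= 2
        counts2 = CountMatrix(scheme, list("abcd"), U2)
        V2 = normalize(counts2).V
        factor = counts2.R.mean() / counts1.R.mean()
        assert V2 == pytest.approx(factor * V1)

    def test_depth_step_conserves_column_sums(self, rng):
        scheme = enumerate_bins(_gene([100, 200]))
        U = rng.integers(0, 30, size=(scheme.p, 3)).astype(float)
        U[:, 2] = 0
        counts = CountMatrix(scheme, list("abc"), U)
        R = counts.R
        Rbar = R.mean()
        Uprime = normalize(counts).V * (scheme.p * scheme.P)[:, None]
        sums = Uprime.sum(axis=0)
        assert sums[:2] == pytest.approx([Rbar, Rbar])
        assert sums[2] == 0

    def test_all_zero_rejected(self):
        scheme = enumerate_bins(_gene([100]))
        counts = CountMatrix(scheme, ["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="empty gene"):
            normalize(counts)

    @given(perm_seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_bin_permutation_equivariance(self, perm_seed):
        # relabeling bin order permutes V rows identically
        scheme = enumerate_bins(_gene([100, 200, 150]))
        rng = np.random.default_rng(perm_seed)
        U = rng.integers(1, 40, size=(scheme.p, 3))
        V = normalize(CountMatrix(scheme, list("abc"), U)).V
        perm = rng.permutation(scheme.p)
        Vp = (U[perm] * (U.sum(axis=0).mean() / U.sum(axis=0))) / (
            scheme.p * scheme.P[perm]
        )[:, None]
        assert Vp == pytest.approx(V[perm])


class TestCountMatrixTsv:
    def test_round_trip(self, scheme3, tmp_path, rng):
        U = rng.integers(0, 20, size=(scheme3.p, 2))
        counts = CountMatrix(scheme3, ["s1", "s2"], U)
        path = tmp_path / "u.tsv"
        write_count_matrix_tsv(counts, path, header="# seed=0\n")
        back = read_count_matrix_tsv(path, scheme3)
        assert (back.U == U).all() and back.samples == ["s1", "s2"]


class TestReadRecordsTsv:
    def test_round_trip(self, tmp_path):
        from nmfp.binning import read_records_tsv, write_read_records_tsv

        reads = [
            ReadRecord("s1", 1, 3, ((1, 3),)),
            ReadRecord("s2", 2, 2),
        ]
        path = tmp_path / "reads.tsv"
        write_read_records_tsv(reads, path, header="# seed=1\n")
        assert read_records_tsv(path) == reads

    def test_rejects_non_table(self, tmp_path):
        from nmfp.binning import read_records_tsv

        path = tmp_path / "x.tsv"
        path.write_text("foo\tbar\n")
        with pytest.raises(ValueError, match="read-record"):
            read_records_tsv(path)


class TestReadsFromAlignments:
    def test_spliced_sam_alignment(self, gene3_introns, tmp_path):
        # gene subexons [0,100), [300,400), [600,700); a 1-based SAM record
        # aligning 50M200N50M from pos 51 spans subexons 1 and 2 with one
        # junction; an unspliced 40M read at pos 11 stays in subexon 1
        from nmfp.binning import reads_from_alignments

        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t11\t60\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
            "r2\t0\tchr1\t51\t60\t50M200N50M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        reads = reads_from_alignments(sam, gene3_introns, sample_id="s1")
        assert len(reads) == 2
        by_span = {(r.start_subexon, r.end_subexon): r for r in reads}
        assert by_span[(1, 1)].junction_chain == ()
        assert by_span[(1, 2)].junction_chain == ((1, 2),)
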