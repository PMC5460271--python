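"""Mean-field DCA: frequencies, reweighting, couplings, direct information."""

import numpy as np
import pytest

from lectnet.dca import (
    ALPHABET,
    Q,
    couplings,
    direct_information,
    filter_gap_columns,
    frequencies,
    rank_pairs,
    read_alignment,
    run_dca,
    sequence_weights,
)


class TestReadAlignment:
    def test_two_records(self):
        a = read_alignment(">s1\nACDE\n>s2\nAC-E\n")
        assert (a.M, a.L) == (2, 4)
        assert a.matrix[1, 2] == 0  # gap

    def test_nonstandard_letter_maps_to_gap_with_warning(self):
        with pytest.warns(UserWarning, match="nonstandard"):
            a = read_alignment(">s1\nAXDE\n")
        assert a.matrix[0, 1] == 0

    def test_dot_is_gap_and_lowercase_uppercased(self):
        a = read_alignment(">s1\na.de\n")
        assert list(a.matrix[0]) == [ALPHABET.index("A"), 0, ALPHABET.index("D"), ALPHABET.index("E")]

    def test_ragged_input_raises(self):
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(">s1\nACDE\n>s2\nACD\n")


class TestGapFilter:
    def test_gap_free_alignment_unchanged(self, aln_factory):
        a = aln_factory(["ACDE", "ACDE"])
        f = filter_gap_columns(a)
        assert f.L == 4 and list(f.col_map) == [0, 1, 2, 3]

    def test_majority_gap_column_removed(self, aln_factory):
        a = aln_factory(["A-DE", "A-DE", "ACDE", "A-DE", "A-DE"])  # col 1: 80% gaps
        f = filter_gap_columns(a)
        assert f.L == 3 and 1 not in f.col_map

    def test_exactly_half_gaps_retained(self, aln_factory):
        a = aln_factory(["A-", "AC"])  # col 1: 50% gaps
        assert filter_gap_columns(a).L == 2

    def test_all_columns_removed_raises(self, aln_factory):
        a = aln_factory(["--", "--", "A-"])
        with pytest.raises(ValueError):
            filter_gap_columns(a)


class TestSequenceWeights:
    def test_identical_sequences_collapse_to_one(self, aln_factory):
        a = aln_factory(["ACDE"] * 6)
        w = sequence_weights(a)
        assert np.all(w.neighbor_counts == 6)
        assert w.m_eff == pytest.approx(1.0)

    def test_all_distinct_sequences_keep_full_weight(self, aln_factory):
        a = aln_factory(["AAAAA", "CCCCC", "DDDDD", "EEEEE"])
        w = sequence_weights(a, identity_threshold=0.8)
        assert w.m_eff == pytest.approx(4.0)

    def test_hand_computed_three_sequence_case(self, aln_factory):
        # rows 1 and 2 are 90% identical (> 0.8); row 3 matches nobody above
        # the threshold: m = (2, 2, 1), M_eff = 1/2 + 1/2 + 1 = 2
        a = aln_factory(["AAAAAAAAAA", "AAAAAAAAAC", "DDDDDDDDDD"])
        w = sequence_weights(a, identity_threshold=0.8)
        assert list(w.neighbor_counts) == [2, 2, 1]
        assert w.m_eff == pytest.approx(2.0)

    def test_exactly_80_percent_identity_is_not_a_neighbor(self, aln_factory):
        a = aln_factory(["AAAAA", "AAAAC"])  # identity 0.8, strict >
        w = sequence_weights(a, identity_threshold=0.8)
        assert w.m_eff == pytest.approx(2.0)

    def test_meff_weakly_decreasing_in_threshold(self, aln_factory):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDE"), 20)) for _ in range(15)]
        a = aln_factory(seqs)
        meffs = [
            sequence_weights(a, identity_threshold=t).m_eff
            for t in (0.9, 0.7, 0.5, 0.3)
        ]
        assert all(m1 >= m2 - 1e-12 for m1, m2 in zip(meffs, meffs[1:]))


class TestFrequencies:
    def test_single_sequence_zero_pseudocount(self, aln_factory):
        a = aln_factory(["AA"])
        w = sequence_weights(a)
        with pytest.warns(UserWarning, match="pseudocount"):
            f = frequencies(a, w, pseudocount=0.0)
        ia = ALPHABET.index("A")
        assert f.fi[0, ia] == pytest.approx(1.0)
        assert f.fi[0].sum() == pytest.approx(1.0)

    def test_analytic_identities_hold_to_1e12(self, aln_factory):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list(ALPHABET), 8)) for _ in range(20)]
        a = aln_factory(seqs)
        f = frequencies(a, sequence_weights(a))
        assert np.allclose(f.fi.sum(axis=1), 1.0, atol=1e-12)
        for i in range(a.L):
            for j in range(a.L):
                if i == j:
                    continue
                assert np.allclose(f.fij[i, j].sum(axis=1), f.fi[i], atol=1e-12)
                assert np.allclose(f.fij[i, j], f.fij[j, i].T, atol=1e-15)

    def test_two_sequences_match_direct_summation(self, aln_factory):
        # independent transcription of the reweighted-frequency formulas
        a = aln_factory(["AC", "CD"])
        w = sequence_weights(a)
        f = frequencies(a, w, pseudocount=0.5)
        lam, meff = 0.5, w.m_eff
        for i in range(2):
            for state in range(Q):
                direct = (
                    lam / Q
                    + sum(
                        wt * (a.matrix[s, i] == state)
                        for s, wt in enumerate(w.weights)
                    )
                ) / (lam + meff)
                assert f.fi[i, state] == pytest.approx(direct, abs=1e-15)
        for A in range(Q):
            for B in range(Q):
                direct = (
                    lam / Q**2
                    + sum(
                        wt * (a.matrix[s, 0] == A) * (a.matrix[s, 1] == B)
                        for s, wt in enumerate(w.weights)
                    )
                ) / (lam + meff)
                assert f.fij[0, 1, A, B] == pytest.approx(direct, abs=1e-15)


class TestCouplings:
    def test_independent_columns_give_small_null_signal(self, aln_factory):
        # null model: 6 independent uniform columns over all 21 states.
        # With the bare pseudocount the inverse-covariance couplings carry
        # O(1) sampling noise (observed null spread ~2.5 at M = 5000), but
        # the DI statistic stays two orders of magnitude below the 0.8
        # coevolution flag (observed ~0.05); both bounds frozen with margin.
        rng = np.random.default_rng(2)
        from lectnet.dca import ALPHABET, direct_information

        seqs = ["".join(rng.choice(list(ALPHABET), 6)) for _ in range(5000)]
        a = aln_factory(seqs)
        f = frequencies(a, sequence_weights(a))
        cm = couplings(f)
        off = max(
            np.abs(cm.eij[i, j]).max()
            for i in range(6)
            for j in range(6)
            if i != j
        )
        assert off < 4.0
        assert direct_information(cm, f).di.max() < 0.15

    def test_coupling_tensor_symmetry(self, aln_factory):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list(ALPHABET), 5)) for _ in range(50)]
        a = aln_factory(seqs)
        cm = couplings(frequencies(a, sequence_weights(a)))
        for i in range(5):
            for j in range(5):
                assert np.allclose(cm.eij[i, j], cm.eij[j, i].T, atol=1e-10)

    def test_two_column_inversion_matches_closed_form(self, aln_factory):
        # L = 2 with effectively 2 states: compare the coupling block against
        # a closed-form inverse of the assembled covariance
        a = aln_factory(["AA", "CC", "AA", "CC", "AC"])
        f = frequencies(a, sequence_weights(a), pseudocount=0.5)
        cm = couplings(f)
        qr = Q - 1
        c = cm.covariance
        inv = np.linalg.inv(c)
        block = -inv[0:qr, qr : 2 * qr]
        assert np.allclose(cm.eij[0, 1, 1:, 1:], block, atol=1e-12)
        # and the covariance block itself is what the frequencies dictate
        ref = f.fij[0, 1, 1:, 1:] - np.outer(f.fi[0, 1:], f.fi[1, 1:])
        assert np.allclose(c[0:qr, qr : 2 * qr], ref, atol=1e-15)


class TestDirectInformation:
    def test_zero_couplings_give_zero_di(self, aln_factory):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACDE"), 4)) for _ in range(30)]
        a = aln_factory(seqs)
        f = frequencies(a, sequence_weights(a))
        from lectnet.dca import CouplingModel

        zero = CouplingModel(np.zeros((4, 4, Q, Q)), np.zeros((4 * 20, 4 * 20)))
        d = direct_information(zero, f)
        assert np.allclose(d.di, 0.0, atol=1e-9)

    def test_di_nonnegative_and_symmetric(self, aln_factory):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACDEFG"), 5)) for _ in range(200)]
        a = aln_factory(seqs)
        f = frequencies(a, sequence_weights(a))
        d = direct_information(couplings(f), f)
        assert np.all(d.di >= 0.0)
        assert np.allclose(d.di, d.di.T)

    def test_two_site_marginals_match_frequencies(self, aln_factory):
        from lectnet.dca import _fit_two_site

        rng = np.random.default_rng(6)
        fi = rng.dirichlet(np.ones(Q))
        fj = rng.dirichlet(np.ones(Q))
        e = rng.normal(0, 0.5, (Q, Q))
        p, err = _fit_two_site(e, fi, fj, tol=1e-6)
        assert err < 1e-6
        assert np.allclose(p.sum(1), fi, atol=1e-4)
        assert np.allclose(p.sum(0), fj, atol=1e-4)
        assert p.sum() == pytest.approx(1.0)

    def test_pipeline_deterministic(self, aln_factory):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACDEFGHIK"), 6)) for _ in range(50)]
        a = aln_factory(seqs)
        t1, m1 = run_dca(a)
        t2, m2 = run_dca(aln_factory(seqs))
        assert t1.equals(t2) and m1 == m2


class TestRankPairs:
    def _di(self, values: dict, length: int = 6):
        from lectnet.dca import DirectInformation

        di = np.zeros((length, length))
        for (i, j), v in values.items():
            di[i, j] = di[j, i] = v
        return DirectInformation(di, np.arange(length))

    def test_no_values_above_threshold_no_flags(self):
        table = rank_pairs(self._di({(0, 3): 0.5}))
        assert not table["flagged"].any()

    def test_single_flag_above_threshold(self):
        table = rank_pairs(self._di({(0, 3): 0.9, (1, 4): 0.3}))
        assert table["flagged"].sum() == 1
        assert table.iloc[0]["di"] == pytest.approx(0.9)

    def test_adjacent_columns_excluded_from_flags(self):
        table = rank_pairs(self._di({(2, 3): 1.5}), min_separation=2)
        row = table.iloc[0]
        assert row["di"] == pytest.approx(1.5) and not row["flagged"]

    def test_sorted_descending(self):
        table = rank_pairs(self._di({(0, 2): 0.2, (0, 4): 0.7, (1, 5): 0.4}))
        assert list(table["di"]) == sorted(table["di"], reverse=True)
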