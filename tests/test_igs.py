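"""Higher-order repeat detection, p-distances and neighbour joining."""

import numpy as np
import pytest

import rdnahomeo as r

from conftest import nj_bipartitions, random_additive_case


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_hor_sequence(rng, period=421, n_mut=3, partial=0.4,
                      flank=300):
    """Flanked tandem array: motif + mutated copy + partial third copy."""
    motif = _random_seq(rng, period)
    copy2 = list(motif)
    mut_pos = rng.choice(period, n_mut, replace=False)
    for p in mut_pos:
        copy2[p] = "ACGT"[("ACGT".index(copy2[p]) + 1) % 4]
    copy2 = "".join(copy2)
    array = motif + copy2 + copy2[: int(round(partial * period))]
    return _random_seq(rng, flank) + array + _random_seq(rng, flank), motif, copy2


class TestFindHor:
    def test_synthetic_421_array(self):
        rng = np.random.default_rng(5)
        seq, motif, copy2 = make_hor_sequence(rng)
        rep = r.find_hor(seq)
        assert rep is not None
        assert rep.period == 421
        assert rep.copy_number == pytest.approx(2.4, abs=0.05)
        assert rep.inter_copy_divergence[0] == pytest.approx(100 * 3 / 421,
                                                             abs=0.15)
        assert rep.inter_copy_divergence[1] == pytest.approx(0.0, abs=0.15)

    def test_perfect_tandem_zero_divergence(self):
        rng = np.random.default_rng(6)
        motif = _random_seq(rng, 25)
        rep = r.find_hor(motif * 4, period_range=(20, 60))
        assert rep.period == 25
        assert rep.copy_number == pytest.approx(4.0, abs=0.1)
        assert all(d == 0.0 for d in rep.inter_copy_divergence)

    def test_random_sequence_no_hor(self):
        rng = np.random.default_rng(7)
        assert r.find_hor(_random_seq(rng, 2000)) is None

    def test_brute_force_period_agreement(self):
        """The selected period maximises the run score over every candidate."""
        rng = np.random.default_rng(8)
        seq, _, _ = make_hor_sequence(rng, period=87, n_mut=1, partial=0.6,
                                      flank=100)
        rep = r.find_hor(seq, period_range=(20, 120))
        codes = np.frombuffer(seq.encode(), np.uint8)
        best_key, best_p = None, None
        for p in range(20, min(120, int(len(seq) / 1.5)) + 1):
            match = (codes[p:] == codes[:-p]).astype(float)
            L = len(match)
            csum = np.concatenate([[0.0], np.cumsum(match - 0.7)])
            # exhaustive objective over every interval [i, j)
            S = csum[None, 1:] - csum[: -1, None]  # S[i, j-1]
            S = np.where(np.triu(np.ones((L, L), bool)), S, -np.inf)  # j > i
            top = S.max()
            if top <= 0:
                continue
            js = np.nonzero(np.isclose(S, top).any(axis=0))[0]
            j = int(js.min()) + 1                    # earliest end
            i = int(np.nonzero(np.isclose(S[:, j - 1], top))[0].max())  # latest start
            run = j - i
            if run < 0.5 * p:
                continue
            score = float(match[i:j].mean())
            if score < 0.7:
                continue
            key = (score, run, -p)
            if best_key is None or key > best_key:
                best_key, best_p = key, p
        assert rep.period == best_p

    def test_copy_number_times_period_is_array_length(self):
        rng = np.random.default_rng(9)
        seq, _, _ = make_hor_sequence(rng, period=50, partial=0.5, flank=100)
        rep = r.find_hor(seq, period_range=(20, 120))
        s, e = rep.array_interval
        assert rep.copy_number * rep.period == pytest.approx(e - s, abs=1e-9)
        assert len(rep.inter_copy_divergence) == int(np.ceil(rep.copy_number)) - 1

    def test_invalid_period_range(self):
        with pytest.raises(ValueError):
            r.find_hor("ACGT" * 100, period_range=(5, 100))


class TestPDistance:
    def test_identical_sequences(self):
        dm = r.p_distance_matrix(["ACGT" * 5] * 3)
        assert np.allclose(dm.data, 0.0)

    def test_direct_count(self):
        s1 = "A" * 100
        s2 = "C" * 5 + "A" * 95
        dm = r.p_distance_matrix([s1, s2, s1])
        assert dm[0, 1] == pytest.approx(0.05)

    def test_gap_columns_excluded_pairwise(self):
        dm = r.p_distance_matrix(["AC-GTA", "ACCGTT", "ACGGTA"])
        assert dm[0, 1] == pytest.approx(1 / 5)  # cols 0,1,3,4,5; A/T differs
        assert dm[0, 2] == pytest.approx(0.0)
        assert dm[1, 2] == pytest.approx(2 / 6)

    def test_too_few_or_incomparable(self):
        with pytest.raises(ValueError):
            r.p_distance_matrix(["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            r.p_distance_matrix(["A---", "-C--", "ACGT"])


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            ["a", "b", "c", "d"],
        )
        tree = r.nj_tree(dm)
        tt = tree.tip_tip_distances(["a", "b", "c", "d"])
        assert np.allclose(tt.filter(dm.ids).data, dm.data)

    def test_three_taxon_closed_form(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix([[0, 3, 5], [3, 0, 6], [5, 6, 0]], ["a", "b", "c"])
        tree = r.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 4.0}

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = int(rng.integers(4, 13))
            ids, D, true_bps = random_additive_case(rng, n)
            from skbio import DistanceMatrix

            dm = DistanceMatrix(D, ids)
            tree = r.nj_tree(dm)
            assert nj_bipartitions(tree, ids) == true_bps
            tt = tree.tip_tip_distances(ids)
            assert np.allclose(tt.filter(ids).data, D, atol=1e-9)

    def test_non_finite_matrix_rejected(self):
        from skbio import DistanceMatrix

        bad = DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, np.inf], [1, np.inf, 0]]), list("abc")
        )
        with pytest.raises(ValueError):
            r.nj_tree(bad)


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(13)
    base = _random_seq(rng, 200)
    other = "".join(
        "ACGT"[("ACGT".index(b) + 1) % 4] if i % 4 == 0 else b
        for i, b in enumerate(base)
    )

    def noisy(s, k, seed):
        rng2 = np.random.default_rng(seed)
        s = list(s)
        for p in rng2.choice(len(s), k, replace=False):
            s[p] = "ACGT"[("ACGT".index(s[p]) + 2) % 4]
        return "".join(s)

    return {
        "a1": base, "a2": noisy(base, 2, 1),
        "b1": other, "b2": noisy(other, 2, 2),
    }


class TestBootstrap:
    def test_clean_clade_has_full_support(self, two_clade_alignment):
        al = two_clade_alignment
        ids = sorted(al)
        dm = r.p_distance_matrix([al[i] for i in ids], ids)
        tree = r.nj_tree(dm, al, bootstrap_replicates=100, seed=4)
        nwk = r.to_newick(tree)
        assert ")100:" in nwk

    def test_supports_invariant_to_taxon_order(self, two_clade_alignment):
        al = two_clade_alignment
        orders = [sorted(al), sorted(al, reverse=True)]
        taxa = frozenset(al)
        anchor = min(taxa)
        results = []
        for ids in orders:
            dm = r.p_distance_matrix([al[i] for i in ids], ids)
            tree = r.nj_tree(dm, al, bootstrap_replicates=50, seed=9)
            sup = {}
            for n in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in n.tips())
                if anchor in side:
                    side = taxa - side
                if n.name is not None:
                    sup[side] = n.name
            results.append(sup)
        assert results[0] and results[0] == results[1]
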