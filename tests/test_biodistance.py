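import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform

from necropop.biodistance import (
    ClassicalMDS,
    correlation_screen,
    counts_from_percentages,
    dichotomize,
    drop_sparse_traits,
    ft_theta,
    mmd_matrix,
    mmd_pair,
    ward_dendrogram,
)
from necropop.records import GroupTraitFrequencies, TraitDefinition


def brute_mmd(counts_a, counts_b, correction="n"):
    """Independent direct-formula oracle for theta/MMD/SD (plain math loop)."""
    total, var = 0.0, 0.0
    r = len(counts_a)
    for (ka, na), (kb, nb) in zip(counts_a, counts_b):
        th_a = 0.5 * (math.asin(1 - 2 * ka / (na + 1)) + math.asin(1 - 2 * (ka + 1) / (na + 1)))
        th_b = 0.5 * (math.asin(1 - 2 * kb / (nb + 1)) + math.asin(1 - 2 * (kb + 1) / (nb + 1)))
        if correction == "n":
            corr = 1 / na + 1 / nb
        else:
            corr = 1 / (na + 0.5) + 1 / (nb + 0.5)
        total += (th_a - th_b) ** 2 - corr
        var += corr**2
    return total / r, math.sqrt(2 * var / r**2)


class TestCountsFromPercentages:
    @pytest.mark.parametrize(
        "percent,n,k", [(11.1, 18, 2), (0.0, 31, 0), (85.7, 7, 6), (100.0, 7, 7)]
    )
    def test_nearest_integer_recovery(self, percent, n, k):
        assert counts_from_percentages(percent, n) == k

    def test_inconsistent_cell_warns(self):
        with pytest.warns(UserWarning, match="printed"):
            counts_from_percentages(6.2, 14)  # 1/14 = 7.14%, not 6.2%

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            counts_from_percentages(101.0, 10)
        with pytest.raises(ValueError):
            counts_from_percentages(10.0, 0)


class TestFtTheta:
    def test_zero_count_value(self):
        # theta(0,10) = (asin(1) + asin(1 - 2/11)) / 2
        assert ft_theta(0, 10) == pytest.approx(1.2645, abs=1e-4)

    def test_full_count_approaches_minus_half_pi(self):
        assert ft_theta(10000, 10000) == pytest.approx(-math.pi / 2, abs=0.02)

    @given(n=st.integers(1, 200), variant=st.sampled_from(["freeman_tukey", "asymmetric", "anscombe"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_k(self, n, variant):
        thetas = [float(ft_theta(k, n, variant)) for k in range(n + 1)]
        assert all(a > b for a, b in zip(thetas, thetas[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ft_theta(5, 4)
        with pytest.raises(ValueError):
            ft_theta(0, 10, variant="nope")


def _freqs(name, counts):
    return GroupTraitFrequencies(name, {f"t{i}": kn for i, kn in enumerate(counts)})


class TestMmdPair:
    def test_identical_frequencies_forced_by_correction_term(self):
        a = _freqs("A", [(3, 10)])
        b = _freqs("B", [(3, 10)])
        mmd_n, _ = mmd_pair(a, b, ["t0"], correction="n")
        assert mmd_n == pytest.approx(-0.2, abs=1e-12)
        mmd_half, _ = mmd_pair(a, b, ["t0"], correction="n_plus_half")
        assert mmd_half == pytest.approx(-(2 / 10.5), abs=1e-12)

    def test_symmetry_and_sd_depends_only_on_n(self):
        rng = np.random.default_rng(1)
        ns = rng.integers(5, 40, size=6)
        a = _freqs("A", [(int(rng.integers(0, n + 1)), int(n)) for n in ns])
        b = _freqs("B", [(int(rng.integers(0, n + 1)), int(n)) for n in ns])
        c = _freqs("C", [(0, int(n)) for n in ns])  # same n, different k
        traits = a.traits
        m_ab, sd_ab = mmd_pair(a, b, traits)
        m_ba, sd_ba = mmd_pair(b, a, traits)
        assert m_ab == pytest.approx(m_ba, abs=1e-15)
        assert sd_ab == pytest.approx(sd_ba, abs=1e-15)
        _, sd_ac = mmd_pair(a, c, traits)
        assert sd_ab == pytest.approx(sd_ac, abs=1e-15)

    @given(data=st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        r = data.draw(st.integers(1, 8))
        counts_a, counts_b = [], []
        for _ in range(r):
            na = data.draw(st.integers(1, 60))
            nb = data.draw(st.integers(1, 60))
            counts_a.append((data.draw(st.integers(0, na)), na))
            counts_b.append((data.draw(st.integers(0, nb)), nb))
        a = _freqs("A", counts_a)
        b = _freqs("B", counts_b)
        for correction in ("n", "n_plus_half"):
            got = mmd_pair(a, b, a.traits, correction=correction)
            want = brute_mmd(counts_a, counts_b, correction)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_dilution_toward_correction_term(self):
        # appending a trait with identical frequency and equal n pulls the
        # mean toward that trait's negative correction contribution
        a = _freqs("A", [(8, 10), (5, 20)])
        b = _freqs("B", [(1, 10), (15, 20)])
        base, _ = mmd_pair(a, b, a.traits)
        a2 = _freqs("A", [(8, 10), (5, 20), (4, 15)])
        b2 = _freqs("B", [(1, 10), (15, 20), (4, 15)])
        diluted, _ = mmd_pair(a2, b2, a2.traits)
        assert diluted < base
        assert diluted == pytest.approx((2 * base - 2 / 15) / 3, abs=1e-12)

    def test_missing_trait_reported(self):
        a = _freqs("A", [(1, 5)])
        b = GroupTraitFrequencies("B", {"other": (1, 5)})
        with pytest.raises(ValueError, match="t0"):
            mmd_pair(a, b, ["t0"])


class TestMmdMatrix:
    def test_diagonal_zero_and_significance_flag(self):
        rng = np.random.default_rng(2)
        groups = [
            _freqs(g, [(int(rng.integers(0, 21)), 20) for _ in range(5)])
            for g in "ABCD"
        ]
        m = mmd_matrix(groups, groups[0].traits)
        assert np.allclose(np.diag(m.mmd), 0)
        assert np.allclose(m.mmd, m.mmd.T)
        off = ~np.eye(4, dtype=bool)
        assert (m.sd.to_numpy()[off] > 0).all()
        assert (
            m.significant.to_numpy()[off]
            == (m.mmd.to_numpy()[off] > 2 * m.sd.to_numpy()[off])
        ).all()

    def test_duplicated_group_is_negative_and_nonsignificant(self):
        g1 = _freqs("A", [(3, 12), (7, 15)])
        g2 = GroupTraitFrequencies("B", dict(g1.counts))
        m = mmd_matrix([g1, g2], g1.traits)
        assert m.mmd.loc["A", "B"] < 0
        assert not m.significant.loc["A", "B"]


class TestDichotomize:
    CARABELLI = TraitDefinition(
        "Carabelli's trait UM1", "M", frozenset(range(2, 8)), frozenset(range(0, 8))
    )

    def test_breakpoint_and_missing_propagation(self):
        scores = pd.DataFrame(
            {"Carabelli's trait UM1": [3, 0, np.nan]}, index=["a", "b", "c"]
        )
        out = dichotomize(scores, [self.CARABELLI])
        assert out.loc["a", "Carabelli's trait UM1"] == 1.0
        assert out.loc["b", "Carabelli's trait UM1"] == 0.0
        assert pd.isna(out.loc["c", "Carabelli's trait UM1"])

    def test_out_of_scale_grade_names_individual(self):
        scores = pd.DataFrame({"Carabelli's trait UM1": [9]}, index=["a"])
        with pytest.raises(ValueError, match="'a'"):
            dichotomize(scores, [self.CARABELLI])

    def test_sparse_traits_dropped(self):
        presence = pd.DataFrame(
            {"dense": [0, 1, 0, 1, 1, 0], "sparse": [1, np.nan, np.nan, np.nan, np.nan, 0]}
        )
        kept, dropped = drop_sparse_traits(presence, min_observations=5)
        assert dropped == ["sparse"]
        assert list(kept.columns) == ["dense"]


class TestCorrelationScreen:
    def test_duplicated_trait_removed(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 30)
        presence = pd.DataFrame(
            {"a": x, "b": x.copy(), "c": rng.integers(0, 2, 30)}, dtype=float
        )
        retained, removed, r = correlation_screen(presence)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert len(removed) == 1 and removed[0] in {"a", "b"}

    def test_independent_traits_retained(self):
        rng = np.random.default_rng(4)
        presence = pd.DataFrame(
            rng.integers(0, 2, (500, 4)).astype(float), columns=list("abcd")
        )
        retained, removed, _ = correlation_screen(presence)
        assert removed == []
        assert retained == list("abcd")

    def test_perfect_diagonal_table_phi(self):
        # 2x2 table (10,0;0,10): phi = sqrt(chi2/N) = 1
        presence = pd.DataFrame(
            {"a": [1] * 10 + [0] * 10, "b": [1] * 10 + [0] * 10}, dtype=float
        )
        _, _, r = correlation_screen(presence)
        assert r.loc["a", "b"] == pytest.approx(1.0)


class TestClassicalMDS:
    def test_equidistant_points_form_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords = ClassicalMDS(2).fit_transform(D)
        embedded = squareform(pdist(coords))
        assert np.allclose(embedded[~np.eye(3, dtype=bool)], 1.0, atol=1e-9)

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        D = squareform(pdist(X))
        coords = ClassicalMDS(3).fit_transform(D)
        assert np.allclose(squareform(pdist(coords)), D, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 4))
        D = squareform(pdist(X))
        ours = ClassicalMDS(2).fit_transform(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), number_of_dimensions=2
        ).samples.to_numpy()
        # principal coordinates agree up to per-axis sign
        for axis in range(2):
            assert np.allclose(ours[:, axis], theirs[:, axis], atol=1e-8) or np.allclose(
                ours[:, axis], -theirs[:, axis], atol=1e-8
            )

    def test_excess_dims_reduced_with_warning(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            est = ClassicalMDS(5).fit(D)
        assert est.embedding_.shape[1] == 2

    def test_negative_entries_clamped(self):
        D = np.array([[0.0, -0.1, 0.5], [-0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        coords = ClassicalMDS(2).fit_transform(D)
        embedded = squareform(pdist(coords))
        assert embedded[0, 1] <= embedded[0, 2] + 1e-12


class TestWardDendrogram:
    def test_tight_pairs_merge_first(self):
        D = np.array(
            [
                [0.0, 0.01, 1.0, 1.0],
                [0.01, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.01],
                [1.0, 1.0, 0.01, 0.0],
            ]
        )
        link = ward_dendrogram(D)
        first_two = {frozenset(link[0, :2].astype(int)), frozenset(link[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_ultrametric_topology_recovered(self):
        # ((a,b):h1, (c,d):h1):h2 ultrametric distances
        D = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.4],
                [1.0, 1.0, 0.4, 0.0],
            ]
        )
        link = ward_dendrogram(D)
        cut = fcluster(link, 2, criterion="maxclust")
        assert cut[0] == cut[1] and cut[2] == cut[3] and cut[0] != cut[2]

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            ward_dendrogram(np.zeros((1, 1)))


class TestReferenceOrdination:
    """Ordination and clustering of the packaged 19-group MMD matrix."""

    @pytest.fixture
    def matrices(self, frequency_groups):
        groups, panel = frequency_groups
        pooled = [g for n, g in groups.items() if n not in ("MVL", "MVNL")]
        split = [g for n, g in groups.items() if n != "MV"]
        return mmd_matrix(pooled, panel), mmd_matrix(split, panel)

    def test_celts_occupy_extreme_mds_positions(self, matrices):
        from tests.conftest import CELTS

        for m in matrices:
            coords = ClassicalMDS(2).fit(m.mmd).embedding_
            ax1 = pd.Series(coords[:, 0], index=m.groups)
            # orient the (sign-arbitrary) axis so the Celtic centroid is
            # positive: the Celts then occupy the three top positions
            ax1 *= np.sign(ax1[list(CELTS)].mean())
            assert set(ax1.sort_values().index[-3:]) == CELTS
            assert (ax1[list(CELTS)] > 0).all()

    def test_ward_two_cut_isolates_celts(self, matrices):
        from tests.conftest import CELTS

        pooled, split = matrices
        for m in (pooled, split):
            link = ward_dendrogram(m.mmd)
            cut = pd.Series(fcluster(link, 2, criterion="maxclust"), index=m.groups)
            clusters = {frozenset(cut.index[cut == c]) for c in set(cut)}
            assert frozenset(CELTS) in clusters
        # the pooled sample and both subsamples fall in the Italic clade
        cut = pd.Series(
            fcluster(ward_dendrogram(pooled.mmd), 2, criterion="maxclust"),
            index=pooled.groups,
        )
        assert cut["MV"] == cut["LAA"]
        cut = pd.Series(
            fcluster(ward_dendrogram(split.mmd), 2, criterion="maxclust"),
            index=split.groups,
        )
        assert cut["MVL"] == cut["LAA"] and cut["MVNL"] == cut["LAA"]
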