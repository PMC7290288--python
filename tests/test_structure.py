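"""Allele-sharing distances, PCoA, Nei distance, and neighbor joining."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import meipop as m
from meipop.structure import write_phylip


class TestAlleleSharingDistance:
    def test_identical_and_maximal(self, make_calls):
        geno = np.array([[0, 0, 2], [1, 1, 2], [2, 2, 0]], dtype=np.int8)
        d = m.allele_sharing_distance(make_calls(geno))
        assert d["s1", "s2"] == 0.0
        # s1 vs s3: |0-2| + |1-2| + |2-0| over 3 loci, scaled by /2
        assert d["s1", "s3"] == pytest.approx((2 + 1 + 2) / 6)

    def test_matches_brute_force(self, make_calls):
        rng = np.random.default_rng(17)
        geno = rng.integers(0, 3, size=(200, 50)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.05] = m.MISSING
        calls = make_calls(geno)
        d = m.allele_sharing_distance(calls)
        x = geno.astype(float)
        x[geno == m.MISSING] = np.nan
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                diff = np.abs(x[:, i] - x[:, j]) / 2
                assert d[calls.samples[i], calls.samples[j]] == pytest.approx(
                    np.nanmean(diff)
                )

    def test_triangle_inequality_complete_data(self, make_calls):
        rng = np.random.default_rng(23)
        geno = rng.integers(0, 3, size=(100, 12)).astype(np.int8)
        calls = make_calls(geno)
        d = m.allele_sharing_distance(calls).data
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_disjoint_called_loci_error(self, make_calls):
        geno = np.array([[1, m.MISSING], [m.MISSING, 1]], dtype=np.int8)
        with pytest.raises(m.MEIError, match="no called loci"):
            m.allele_sharing_distance(make_calls(geno))


class TestPCoA:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), list("abc"))
        coords, explained = m.pcoa(d, k=2)
        # two equal positive eigenvalues -> equal explained fractions
        assert explained[0] == pytest.approx(explained[1])

    def test_recovers_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), list("abcd"))
        coords, explained = m.pcoa(d, k=1)
        got = coords["PCo1"].to_numpy()
        centered = pts - pts.mean()
        assert np.allclose(got, centered) or np.allclose(got, -centered)
        assert explained[0] == pytest.approx(1.0)

    def test_euclidean_embedding_reproduces_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 4))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = DistanceMatrix(dmat, [f"p{i}" for i in range(15)])
        coords, _ = m.pcoa(d, k=4)
        rec = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=-1
        )
        np.testing.assert_allclose(rec, dmat, atol=1e-8)

    def test_matches_reference_ordination(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = DistanceMatrix(dmat, [f"p{i}" for i in range(10)])
        coords, _ = m.pcoa(d, k=2)
        ref = skbio_pcoa(d, number_of_dimensions=2).samples.to_numpy()
        for axis in range(2):
            ours = coords.to_numpy()[:, axis]
            theirs = ref[:, axis]
            agree = min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            )
            assert agree < 1e-8

    def test_axis1_separates_africa(self, structured_cohort):
        """Principal coordinate 1 of the allele-sharing distances splits
        the Africa group from all others."""
        panel = structured_cohort["panel"]
        pruned = m.analysis_panel_filter(structured_cohort["calls"])
        coords, _ = m.pcoa(m.allele_sharing_distance(pruned), k=2)
        group_of = panel.group_of()
        pc1 = pd.Series(
            coords["PCo1"].values, index=[group_of[s] for s in coords.index]
        )
        means = pc1.groupby(level=0).mean()
        africa = means["Africa"]
        others = means.drop("Africa")
        assert africa > others.max() or africa < others.min()

    def test_all_zero_matrix_errors(self):
        d = DistanceMatrix(np.zeros((3, 3)), list("abc"))
        with pytest.raises(m.MEIError):
            m.pcoa(d, k=1)


class TestNeiDistance:
    def test_identical_frequencies_zero(self, make_calls, tiny_panel):
        geno = np.array([[1, 1, 1, 1], [0, 2, 0, 2]], dtype=np.int8)
        d = m.nei_standard_distance(make_calls(geno), tiny_panel)
        assert d.loc["Africa", "East Asia"] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixation_saturates(self, make_calls, tiny_panel):
        geno = np.array([[0, 0, 2, 2]] * 3, dtype=np.int8)
        d = m.nei_standard_distance(make_calls(geno), tiny_panel)
        assert np.isinf(d.loc["Africa", "East Asia"])

    def test_half_frequency_closed_form(self, make_calls, tiny_panel):
        # p = q = 0.5 at a single locus: identity = 0.5 / 0.5 = 1, D = 0
        geno = np.array([[0, 2, 1, 1]], dtype=np.int8)
        d = m.nei_standard_distance(make_calls(geno), tiny_panel)
        assert d.loc["Africa", "East Asia"] == pytest.approx(0.0, abs=1e-12)


def tree_distances(tree):
    tips = {t.name: t for t in tree.tips()}
    names = sorted(tips)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = tips[a].distance(tips[b])
    return out


class TestNeighborJoining:
    def test_inverts_additive_four_taxon_matrix(self):
        # tree ((a:2,b:3):1,(c:4,d:5):0) -> additive distances below
        dmat = pd.DataFrame(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
            dtype=float,
        )
        tree = m.neighbor_joining(dmat)
        got = tree_distances(tree)
        for (a, b), want in {
            ("a", "b"): 5,
            ("a", "c"): 7,
            ("a", "d"): 8,
            ("b", "c"): 8,
            ("b", "d"): 9,
            ("c", "d"): 9,
        }.items():
            assert got[(a, b)] == pytest.approx(want, abs=1e-9)
        # correct split: {a,b} vs {c,d}
        for child in tree.children:
            names = {t.name for t in child.tips()} or {child.name}
            assert names not in ({"a", "c"}, {"a", "d"})

    def test_three_taxa_star(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("xyz"), columns=list("xyz"), dtype=float
        )
        tree = m.neighbor_joining(d)
        got = tree_distances(tree)
        assert got[("x", "y")] == pytest.approx(3)
        assert got[("x", "z")] == pytest.approx(4)
        assert got[("y", "z")] == pytest.approx(5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(7, 3))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"t{i}" for i in range(7)]
        d1 = pd.DataFrame(dmat, index=labels, columns=labels)
        order = rng.permutation(7)
        d2 = d1.iloc[order, order]
        t1 = tree_distances(m.neighbor_joining(d1))
        t2 = tree_distances(m.neighbor_joining(d2))
        for pair, v in t1.items():
            assert t2[pair] == pytest.approx(v, abs=1e-9)

    def test_matches_reference_topology(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(32)
        pts = rng.normal(size=(6, 3))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"t{i}" for i in range(6)]
        ours = m.neighbor_joining(pd.DataFrame(dmat, index=labels, columns=labels))
        ref = skbio_nj(DistanceMatrix(dmat, labels))
        got = tree_distances(ours)
        want = tree_distances(ref)
        for pair, v in want.items():
            assert got[pair] == pytest.approx(v, abs=1e-6)

    def test_americas_joins_central_asia_first(self, structured_cohort):
        """In the group tree the Americas tip sits closer to Central
        Asia/Siberia than to East Asia, reflecting the Beringian founding."""
        nei = m.nei_standard_distance(structured_cohort["calls"], structured_cohort["panel"])
        tree = m.neighbor_joining(nei)
        tips = {t.name: t for t in tree.tips()}
        assert tips["Americas"].distance(
            tips["Central Asia/Siberia"]
        ) < tips["Americas"].distance(tips["East Asia"])

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"), dtype=float)
        with pytest.raises(m.MEIError):
            m.neighbor_joining(d)


def test_phylip_export(tmp_path):
    d = pd.DataFrame(
        [[0, 1.5], [1.5, 0]], index=["alpha", "beta"], columns=["alpha", "beta"]
    )
    path = tmp_path / "d.phy"
    write_phylip(d, str(path))
    lines = path.read_text().splitlines()
    assert lines[0].strip() == "2"
    assert lines[1].startswith("alpha")
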