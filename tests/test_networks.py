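"""Median-joining networks, haplotype alignments, and diversity statistics."""

import itertools

import numpy as np
import pytest

import meipop as m
from meipop.subfamilies import detect_mask, diversity_stats, median_joining_network


def hset(seqs, mask=(), consensus=None):
    return m.HaplotypeSet(
        sequences=list(seqs),
        locus_ids=[f"l{i}" for i in range(len(seqs))],
        subfamilies=["AluYa5"] * len(seqs),
        mask=set(mask),
        consensus=consensus,
    )


class TestMaskDetection:
    def test_masks_a_runs_and_tail(self):
        cons = "CGTC" + "AAAAAA" + "GTCG" + "AAA"
        mask = detect_mask(cons)
        assert set(range(4, 10)) <= mask  # middle A-rich run
        assert set(range(14, 17)) <= mask  # poly(A) tail
        assert 0 not in mask and 10 not in mask


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining_network(hset(["AAAA", "AAAT"]))
        assert net.graph.number_of_nodes() == 2
        ((u, v, d),) = net.graph.edges(data=True)
        assert d["weight"] == 1

    def test_triplet_median_matches_steiner_oracle(self):
        seqs = ["GACA", "AGCA", "AACG"]
        net = median_joining_network(hset(seqs))
        medians = [
            d["sequence"]
            for _, d in net.graph.nodes(data=True)
            if not d["observed"]
        ]
        assert len(medians) == 1
        # exhaustive Steiner search: best single extra node over the
        # alphabet observed per column
        def cost(candidate):
            return sum(
                sum(a != b for a, b in zip(candidate, s)) for s in seqs
            )

        best = min(
            ("".join(c) for c in itertools.product("ACG", repeat=4)), key=cost
        )
        assert cost(medians[0]) == cost(best) == 3
        assert medians[0] == "AACA"
        # the median connects all three observed haplotypes at one step
        (mid,) = [
            n for n, d in net.graph.nodes(data=True) if not d["observed"]
        ]
        assert net.graph.degree[mid] == 3

    def test_star_family_topology(self):
        """A founder plus one-step descendants yields a star network
        centred on the founder haplotype."""
        root = "ACGTACGTACGT"
        tips = []
        for i in range(10):
            s = list(root)
            s[i] = "T" if s[i] != "T" else "A"
            tips.append("".join(s))
        net = median_joining_network(hset([root] + tips))
        assert net.graph.number_of_nodes() == 11
        degrees = dict(net.graph.degree())
        center = [n for n, d in net.graph.nodes(data=True) if d["sequence"] == root]
        assert degrees[center[0]] == 10
        assert all(v == 1 for n, v in degrees.items() if n != center[0])

    def test_contains_true_genealogy_adjacencies(self):
        for seed in range(3):
            h, gen = m.simulate_haplotypes(
                "star", n_tips=25, mutation_rate=1.0, seed=seed, infinite_sites=True
            )
            net = median_joining_network(h)
            cols = net.columns
            eff = lambda s: "".join(s[c] for c in cols)
            adj = {
                frozenset(
                    (net.graph.nodes[u]["sequence"], net.graph.nodes[v]["sequence"])
                )
                for u, v in net.graph.edges
            }
            for parent, child in gen:
                pe, ce = eff(parent), eff(child)
                if pe != ce:
                    assert frozenset((pe, ce)) in adj

    def test_min_loci_threshold(self):
        seqs = ["AAAA"] * 10 + ["AAAT"]
        net = median_joining_network(hset(seqs), min_loci=10)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.nodes[0]["count"] == 10

    def test_masked_columns_ignored(self):
        # the only difference sits in a masked column -> single node
        net = median_joining_network(hset(["AAAA", "AATA"], mask={2}))
        assert net.graph.number_of_nodes() == 1

    def test_cpg_edge_annotation(self):
        cons = "TTCGTT"
        net = median_joining_network(
            hset(["TTCGTT", "TTCATT"], consensus=cons)
        )
        ((_, _, d),) = net.graph.edges(data=True)
        (col, a, b, is_cpg) = d["mutations"][0]
        assert {a, b} == {"G", "A"} and is_cpg

    def test_graphml_export(self, tmp_path):
        net = median_joining_network(hset(["AAAA", "AAAT"]))
        out = tmp_path / "net.graphml"
        net.write_graphml(out)
        assert out.read_text().startswith("<?xml")


def stats_oracle(seqs):
    """All-pairs brute-force pi and direct formula Tajima's D."""
    n = len(seqs)
    L = len(seqs[0])
    pairs = list(itertools.combinations(range(n), 2))
    diffs = [sum(a != b for a, b in zip(seqs[i], seqs[j])) for i, j in pairs]
    pi_total = np.mean(diffs)
    s = sum(len(set(col)) > 1 for col in zip(*seqs))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    d = (pi_total - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1)) if s else np.nan
    return pi_total / L, s / a1 / L, d


class TestDiversityStats:
    def test_identical_sequences(self):
        st = diversity_stats(hset(["ACGT"] * 5))
        assert st.s == 0 and st.pi == 0.0 and st.theta_w == 0.0
        assert np.isnan(st.tajima_d)
        assert st.n_haplotypes == 1

    def test_watterson_closed_form(self):
        # n = 4, S = 3 over 100 effective sites: theta = 3 / (11/6) / 100
        base = "A" * 100
        seqs = [base, "T" + base[1:], base[:50] + "C" + base[51:], base[:99] + "G"]
        st = diversity_stats(hset(seqs))
        assert st.s == 3
        assert st.theta_w == pytest.approx(0.016364, abs=5e-7)

    def test_frequency_shortcut_equals_all_pairs(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            h, _ = m.simulate_haplotypes(
                "coalescent", n_tips=12, mutation_rate=2.0, seed=int(rng.integers(1e6))
            )
            st = diversity_stats(h)
            cols = h.effective_columns()
            eff = ["".join(s[c] for c in cols) for s in h.sequences]
            pi, theta, d = stats_oracle(eff)
            assert st.pi == pytest.approx(pi, rel=1e-9)
            assert st.theta_w == pytest.approx(theta, rel=1e-9)
            if not np.isnan(d):
                assert st.tajima_d == pytest.approx(d, rel=1e-9)

    def test_star_expansion_negative_d(self):
        """Recent star-like expansions push Tajima's D negative in nearly
        every replicate."""
        neg = 0
        reps = 40
        for seed in range(reps):
            h, _ = m.simulate_haplotypes("star", n_tips=60, mutation_rate=1.0, seed=seed)
            if diversity_stats(h).tajima_d < 0:
                neg += 1
        assert neg >= 0.95 * reps

    def test_gapped_columns_excluded(self):
        seqs = ["AC-T", "ACTT", "GCTT"]
        st = diversity_stats(hset(seqs))
        assert st.effective_length == 3  # gap column dropped
        assert st.s == 1

    def test_too_few_for_d(self):
        st = diversity_stats(hset(["AAAA", "AAAT", "AATT"]))
        assert np.isnan(st.tajima_d)
        assert st.s == 2

    def test_fasta_round_trip(self, tmp_path):
        h, _ = m.simulate_haplotypes("star", n_tips=6, mutation_rate=1.0, seed=2)
        path = tmp_path / "h.fasta"
        h.to_fasta(path)
        back = m.HaplotypeSet.from_fasta(path, mask="auto")
        assert back.sequences == h.sequences
        assert back.subfamilies == h.subfamilies
        assert back.mask == h.mask

    def test_diversity_table_columns(self):
        from meipop.subfamilies import diversity_table

        h, _ = m.simulate_haplotypes("star", n_tips=20, mutation_rate=1.0, seed=3)
        tab = diversity_table(h)
        assert list(tab.columns) == [
            "subfamily",
            "sequences",
            "haplotypes",
            "segregating_sites",
            "pi",
            "theta",
            "tajima_d",
        ]
        assert tab.loc[0, "sequences"] == 20
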