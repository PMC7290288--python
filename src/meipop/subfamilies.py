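"""Alu subfamily analyses: label aggregation, cross-group sharing,
median-joining haplotype networks, and sequence diversity statistics.

Active Alu subfamilies are compared as aligned ~281-bp haplotypes.  The
hypervariable middle A-rich region and the 3' poly(A) tail are masked
before any distance is computed.  Relationships among haplotypes are
displayed as a median-joining network (minimum spanning network
augmented with inferred median/Steiner haplotypes); expansion dynamics
are quantified with pi, Watterson's theta and Tajima's D, where negative
D is the signature of a recent, star-like subfamily expansion.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MEIError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Subfamily label aggregation and sharing

_ALU_SUB = re.compile(r"^AluY([a-z])(.*)$")


def aggregate_subfamily(label: str) -> str:
    """Collapse rare AluY lineages into the standard aggregate bins.

    AluYe through AluYk fold into ``"AluYe-k"``; AluYb other than Yb8/Yb6
    fold into ``"AluYb(other)"``; AluYa other than Ya5 fold into
    ``"AluYa(other)"``.  Everything else (including LINE-1 labels, which
    are never aggregated) passes through unchanged; non-Alu labels log a
    warning.
    """
    m = _ALU_SUB.match(label)
    if m is None:
        if not label.lower().startswith("alu"):
            logger.warning("non-Alu label %r passed to Alu aggregation", label)
        return label
    letter = m.group(1)
    if "e" <= letter <= "k":
        return "AluYe-k"
    if letter == "b":
        return label if label in ("AluYb8", "AluYb6", "AluYb(other)") else "AluYb(other)"
    if letter == "a":
        return label if label in ("AluYa5", "AluYa(other)") else "AluYa(other)"
    return label


def aggregate_subfamilies(labels: list[str]) -> list[str]:
    return [aggregate_subfamily(l) for l in labels]


def sharing_percent(n_shared: int, n_total: int) -> int:
    """Whole-percent fraction of subfamilies present in every group."""
    if n_total <= 0:
        raise MEIError("n_total must be positive")
    return int(np.floor(100.0 * n_shared / n_total + 0.5))


def subfamily_sharing(calls, panel) -> tuple[pd.DataFrame, int]:
    """Subfamily x group presence matrix and the percent shared by all groups.

    A subfamily is present in a group when at least one of its loci has
    at least one carrier in that group.
    """
    group_of = panel.group_of()
    groups = panel.groups
    cols = {
        g: [i for i, s in enumerate(calls.samples) if group_of.get(s) == g]
        for g in groups
    }
    subfamilies = sorted({l.subfamily for l in calls.loci})
    presence = pd.DataFrame(False, index=subfamilies, columns=groups)
    for i, locus in enumerate(calls.loci):
        for g in groups:
            if not presence.at[locus.subfamily, g]:
                if (calls.genotypes[i, cols[g]] > 0).any():
                    presence.at[locus.subfamily, g] = True
    n_shared = int(presence.all(axis=1).sum())
    return presence, sharing_percent(n_shared, len(subfamilies))


# ---------------------------------------------------------------------------
# Haplotype alignments


def detect_mask(consensus: str, min_run: int = 5) -> set[int]:
    """Columns of the middle A-rich region and terminal poly(A) tail.

    Masks every internal run of >= ``min_run`` consecutive A's and the
    trailing A run (ignoring gaps) of the consensus.
    """
    mask: set[int] = set()
    for m in re.finditer(f"A{{{min_run},}}", consensus.upper()):
        mask.update(range(m.start(), m.end()))
    tail = re.search(r"A+[-]*$", consensus.upper())
    if tail:
        mask.update(
            i for i in range(tail.start(), len(consensus)) if consensus[i].upper() == "A"
        )
    return mask


@dataclass
class HaplotypeSet:
    """Aligned haplotype sequences with locus ids, labels, and a column mask."""

    sequences: list[str]
    locus_ids: list[str]
    subfamilies: list[str]
    mask: set[int] = field(default_factory=set)
    consensus: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MEIError("haplotype set is empty")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise MEIError("aligned sequences must have equal length")
        if any(i >= length or i < 0 for i in self.mask):
            raise MEIError("mask indices outside alignment columns")
        bad = set("".join(self.sequences).upper()) - set("ACGT-N")
        if bad:
            raise MEIError(f"unexpected alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def effective_columns(self) -> np.ndarray:
        """Unmasked columns with no gap in any sequence."""
        arr = self.matrix()
        no_gap = ~(arr == "-").any(axis=0)
        keep = np.array([i not in self.mask for i in range(self.length)])
        return np.flatnonzero(no_gap & keep)

    def matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences])

    def subset(self, subfamily: str) -> "HaplotypeSet":
        idx = [i for i, s in enumerate(self.subfamilies) if s == subfamily]
        if not idx:
            raise MEIError(f"no sequences labelled {subfamily!r}")
        return HaplotypeSet(
            sequences=[self.sequences[i] for i in idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            subfamilies=[self.subfamilies[i] for i in idx],
            mask=set(self.mask),
            consensus=self.consensus,
        )

    @classmethod
    def from_fasta(
        cls, path: str | os.PathLike, mask: set[int] | str | None = "auto"
    ) -> "HaplotypeSet":
        """Read aligned haplotypes; headers ``>locus_id subfamily=NAME``.

        A record named ``consensus`` seeds automatic mask detection when
        ``mask="auto"``.
        """
        sequences, ids, subs = [], [], []
        consensus = None
        for rec in SeqIO.parse(os.fspath(path), "fasta"):
            m = re.search(r"subfamily=(\S+)", rec.description)
            if rec.id.lower() == "consensus":
                consensus = str(rec.seq)
                continue
            sequences.append(str(rec.seq))
            ids.append(rec.id)
            subs.append(m.group(1) if m else "indeterminate")
        resolved: set[int]
        if mask == "auto":
            resolved = detect_mask(consensus) if consensus else set()
        else:
            resolved = set(mask or ())
        return cls(sequences, ids, subs, resolved, consensus)

    def to_fasta(self, path: str | os.PathLike) -> None:
        records = []
        if self.consensus is not None:
            records.append(SeqRecord(Seq(self.consensus), id="consensus", description=""))
        for seq, lid, sub in zip(self.sequences, self.locus_ids, self.subfamilies):
            records.append(
                SeqRecord(Seq(seq), id=lid, description=f"subfamily={sub}")
            )
        SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# Median-joining network


@dataclass
class HaploNetwork:
    """Median-joining network: nodes are haplotypes, edges mutation steps.

    Node attributes: ``sequence`` (over effective columns), ``count``
    (supporting loci; 0 for inferred medians), ``observed``.  Edge
    attributes: ``weight`` (mutational steps) and ``mutations`` (list of
    ``(column, from, to, is_cpg)``).
    """

    graph: nx.Graph
    columns: np.ndarray  # alignment columns retained in node sequences

    @property
    def n_median_nodes(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if not d["observed"])

    def write_graphml(self, path: str | os.PathLike) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n, sequence=d["sequence"], count=int(d["count"]), observed=bool(d["observed"])
            )
        for u, v, d in self.graph.edges(data=True):
            muts = ";".join(f"{c}{a}>{b}{'*' if cpg else ''}" for c, a, b, cpg in d["mutations"])
            g.add_edge(u, v, weight=int(d["weight"]), mutations=muts)
        nx.write_graphml(g, os.fspath(path))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": u, "node_b": v, "steps": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "steps"])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_links(
    seqs: list[str], epsilon: int = 0
) -> list[tuple[int, int, int]]:
    """Feasible links of the minimum spanning network (plus epsilon slack).

    Distances are processed in ascending order; a pair at distance d is a
    feasible link unless its endpoints were already connected using only
    links shorter than d - epsilon.
    """
    n = len(seqs)
    pairs = [
        (_hamming(seqs[i], seqs[j]), i, j) for i in range(n) for j in range(i + 1, n)
    ]
    pairs.sort()
    links: list[tuple[int, int, int]] = []

    def connected(i: int, j: int, limit: int) -> bool:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for d, u, v in links:
            if d <= limit:
                parent[find(u)] = find(v)
        return find(i) == find(j)

    for d, i, j in pairs:
        if not connected(i, j, d - epsilon - 1):
            links.append((d, i, j))
    return links


def _median_of_three(a: str, b: str, c: str) -> str | None:
    """Column-majority median; None when some column has three states."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining_network(
    h: HaplotypeSet,
    epsilon: int = 0,
    min_loci: int = 1,
    consensus: str | None = None,
) -> HaploNetwork:
    """Median-joining network of the distinct haplotypes in ``h``.

    Masked and gapped columns are excluded from all distances.  The
    network starts from the minimum spanning network over Hamming
    distances, then iteratively adds median (Steiner) haplotypes of
    linked triplets whose connection cost is within ``epsilon`` of the
    minimum, pruning inferred nodes that end up with fewer than three
    neighbours.  ``min_loci`` drops observed haplotypes supported by
    fewer loci (the display convention for subfamily-scale networks).

    Mutations on edges are annotated as CpG transitions when the
    consensus context at the column is a CG dinucleotide and the change
    is a transition.
    """
    cols = h.effective_columns()
    arr = h.matrix()[:, cols]
    collapsed: dict[str, list[str]] = {}
    for row, lid in zip(arr, h.locus_ids):
        collapsed.setdefault("".join(row), []).append(lid)
    collapsed = {
        seq: ids for seq, ids in collapsed.items() if len(ids) >= min_loci
    }
    if not collapsed:
        raise MEIError("no haplotype meets the minimum locus support")
    observed = list(collapsed)
    seqs = list(observed)
    if len(seqs) == 1:
        g = nx.Graph()
        g.add_node(
            0,
            sequence=seqs[0],
            count=len(collapsed[seqs[0]]),
            observed=True,
            locus_ids=collapsed[seqs[0]],
        )
        return HaploNetwork(graph=g, columns=cols)

    observed_set = set(observed)
    for _ in range(32):  # median augmentation passes
        links = _msn_links(seqs, epsilon)
        adjacency: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for _, i, j in links:
            adjacency[i].add(j)
            adjacency[j].add(i)
        candidates: dict[str, int] = {}
        for u in adjacency:
            neigh = sorted(adjacency[u])
            for ai in range(len(neigh)):
                for aj in range(ai + 1, len(neigh)):
                    v, w = neigh[ai], neigh[aj]
                    m = _median_of_three(seqs[u], seqs[v], seqs[w])
                    if m is None or m in seqs:
                        continue
                    cost = (
                        _hamming(m, seqs[u])
                        + _hamming(m, seqs[v])
                        + _hamming(m, seqs[w])
                    )
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = [m for m, cost in candidates.items() if cost <= lam + epsilon]
        seqs.extend(new)
        # prune inferred nodes that are no longer useful (degree < 3)
        while True:
            links = _msn_links(seqs, epsilon)
            degree = {i: 0 for i in range(len(seqs))}
            for _, i, j in links:
                degree[i] += 1
                degree[j] += 1
            drop = [
                i
                for i in range(len(seqs))
                if seqs[i] not in observed_set and degree[i] < 3
            ]
            if not drop:
                break
            seqs = [s for i, s in enumerate(seqs) if i not in set(drop)]

    links = _msn_links(seqs, epsilon)
    g = nx.Graph()
    cons_cols = None
    cons = consensus if consensus is not None else h.consensus
    if cons is not None:
        cons_cols = "".join(cons[c].upper() for c in cols)
    for i, seq in enumerate(seqs):
        ids = collapsed.get(seq, [])
        g.add_node(
            i,
            sequence=seq,
            count=len(ids),
            observed=seq in observed_set,
            locus_ids=ids,
        )
    for d, i, j in links:
        muts = []
        for k, (x, y) in enumerate(zip(seqs[i], seqs[j])):
            if x == y:
                continue
            is_cpg = False
            if cons_cols is not None:
                transition = {x, y} in ({"A", "G"}, {"C", "T"})
                context = cons_cols[k : k + 2]
                prev = cons_cols[k - 1 : k + 1] if k > 0 else ""
                is_cpg = transition and (context == "CG" or prev == "CG")
            muts.append((int(cols[k]), x, y, is_cpg))
        g.add_edge(i, j, weight=d, mutations=muts)
    return HaploNetwork(graph=g, columns=cols)


# ---------------------------------------------------------------------------
# Sequence diversity statistics


@dataclass
class DiversityStats:
    """pi, Watterson's theta (both per site) and Tajima's D for one set."""

    n_sequences: int
    n_haplotypes: int
    s: int
    pi: float
    theta_w: float
    tajima_d: float  # NaN when undefined (S = 0 or n < 4)
    effective_length: int


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def diversity_stats(h: HaplotypeSet) -> DiversityStats:
    """Segregating sites, pi, Watterson's theta, and Tajima's D.

    All statistics use the effective columns (unmasked, ungapped).  pi is
    computed with the O(S n) allele-frequency shortcut: the mean pairwise
    difference at a column with state counts ``n_s`` is
    ``1 - sum C(n_s, 2) / C(n, 2)``.
    """
    cols = h.effective_columns()
    arr = h.matrix()[:, cols]
    n = arr.shape[0]
    l_eff = arr.shape[1]
    if l_eff == 0:
        raise MEIError("no effective columns (all masked or gapped)")
    n_hap = len({tuple(row) for row in arr})
    per_col_diff = np.zeros(l_eff)
    s = 0
    npairs = n * (n - 1) / 2.0
    for k in range(l_eff):
        _, counts = np.unique(arr[:, k], return_counts=True)
        if len(counts) > 1:
            s += 1
            same = float(np.sum(counts * (counts - 1) / 2.0))
            per_col_diff[k] = 1.0 - same / npairs
    pi_total = float(per_col_diff.sum())  # mean pairwise differences per pair
    pi = pi_total / l_eff
    if n < 2:
        raise MEIError("need at least two sequences")
    const = _tajima_constants(n)
    theta_w = s / const["a1"] / l_eff
    if s == 0 or n < 4:
        d = float("nan")
    else:
        var = const["e1"] * s + const["e2"] * s * (s - 1)
        d = float((pi_total - s / const["a1"]) / np.sqrt(var))
    return DiversityStats(
        n_sequences=n,
        n_haplotypes=n_hap,
        s=s,
        pi=pi,
        theta_w=theta_w,
        tajima_d=d,
        effective_length=l_eff,
    )


def diversity_table(h: HaplotypeSet, subfamilies: list[str] | None = None) -> pd.DataFrame:
    """Per-subfamily diversity summary (sequences, haplotypes, S, pi, theta, D)."""
    if subfamilies is None:
        subfamilies = sorted(set(h.subfamilies))
    rows = []
    for sub in subfamilies:
        st = diversity_stats(h.subset(sub))
        rows.append(
            {
                "subfamily": sub,
                "sequences": st.n_sequences,
                "haplotypes": st.n_haplotypes,
                "segregating_sites": st.s,
                "pi": st.pi,
                "theta": st.theta_w,
                "tajima_d": st.tajima_d,
            }
        )
    return pd.DataFrame(rows)
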