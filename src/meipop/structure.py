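"""Population-structure analyses: allele-sharing distances, principal
coordinates, Nei's standard genetic distance, and neighbor-joining trees.

The allele-sharing distance between two individuals is the mean absolute
dosage difference per locus, scaled to [0, 1]; ordination of the
resulting matrix by classical principal coordinates (metric MDS) gives
the familiar structure plots.  Group-level relationships use Nei's
standard distance on per-group allele frequencies, summarised by a
Saitou-Nei neighbor-joining tree.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .model import MEIError, MEICallSet, MISSING, SamplePanel

logger = logging.getLogger(__name__)


def allele_sharing_distance(calls: MEICallSet) -> DistanceMatrix:
    """Pairwise allele-sharing distance among samples.

    ``d(i, j) = mean over pairwise-complete loci of |dosage_i - dosage_j| / 2``.
    Raises if some pair shares no called locus.
    """
    x = calls.genotypes.astype(float)
    x[calls.genotypes == MISSING] = np.nan
    n = calls.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i : i + 1] - x[:, i:]) / 2.0
        counts = np.sum(~np.isnan(diff), axis=0)
        if (counts == 0).any():
            j = i + int(np.argmax(counts == 0))
            raise MEIError(
                f"samples {calls.samples[i]!r} and {calls.samples[j]!r} share "
                "no called loci"
            )
        with np.errstate(invalid="ignore"):
            row = np.nanmean(diff, axis=0)
        d[i, i:] = row
        d[i:, i] = row
    return DistanceMatrix(d, ids=calls.samples)


def pcoa(
    d: DistanceMatrix | pd.DataFrame, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal coordinates of a distance matrix.

    Gower-centers ``-d**2 / 2``, eigendecomposes, and returns the first
    ``k`` coordinate axes (eigenvectors scaled by sqrt eigenvalue, sorted
    by decreasing eigenvalue) along with the fraction of positive-
    eigenvalue variance each axis explains.  Negative eigenvalues
    (non-Euclidean noise) are dropped with a warning.  Sign convention:
    on each axis the largest-magnitude loading is positive.
    """
    if isinstance(d, DistanceMatrix):
        labels = list(d.ids)
        mat = d.data
    else:
        labels = list(d.index)
        mat = d.to_numpy(float)
    n = mat.shape[0]
    if k >= n:
        raise MEIError(f"k must be < number of points ({n})")
    if not np.any(mat):
        raise MEIError("all-zero distance matrix has no principal coordinates")
    a = -0.5 * mat**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    negative = eigval < -1e-9 * max(eigval.max(), 1.0)
    if negative.any():
        logger.warning(
            "dropping %d negative eigenvalues (non-Euclidean distances)",
            int(negative.sum()),
        )
    positive = eigval > 1e-12 * max(eigval.max(), 1.0)
    eigval = eigval[positive]
    eigvec = eigvec[:, positive]
    k = min(k, eigvec.shape[1])
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for axis in range(k):
        lead = np.argmax(np.abs(coords[:, axis]))
        if coords[lead, axis] < 0:
            coords[:, axis] *= -1
    explained = eigval[:k] / eigval.sum()
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return frame, explained


def group_allele_frequencies(
    calls: MEICallSet, panel: SamplePanel
) -> pd.DataFrame:
    """Alternate-allele frequency per locus (rows) per major group (columns)."""
    group_of = panel.group_of()
    out = {}
    for g in panel.groups:
        cols = [i for i, s in enumerate(calls.samples) if group_of.get(s) == g]
        geno = calls.genotypes[:, cols]
        called = geno != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, geno, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = np.where(n > 0, alt / (2 * n), np.nan)
    return pd.DataFrame(out)


def nei_standard_distance(calls: MEICallSet, panel: SamplePanel) -> pd.DataFrame:
    """Nei's standard genetic distance D between every pair of groups.

    ``D = -ln( sum_l sum_u x_lu y_lu / sqrt(sum x^2) / sqrt(sum y^2) )``
    with both allele classes of each biallelic locus included in the
    sums.  Pairs fixed for opposite alleles at every locus saturate to
    +inf (flagged with a warning).
    """
    if len(panel.groups) < 2:
        raise MEIError("need at least two groups")
    freqs = group_allele_frequencies(calls, panel)
    groups = list(freqs.columns)
    n = len(groups)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = freqs[groups[i]].to_numpy()
            q = freqs[groups[j]].to_numpy()
            ok = np.isfinite(p) & np.isfinite(q)
            p, q = p[ok], q[ok]
            jxy = float(np.sum(p * q + (1 - p) * (1 - q)))
            jx = float(np.sum(p * p + (1 - p) ** 2))
            jy = float(np.sum(q * q + (1 - q) ** 2))
            if jx == 0 or jy == 0:
                raise MEIError("zero homozygosity denominator in Nei distance")
            identity = jxy / np.sqrt(jx * jy)
            if identity <= 0:
                logger.warning(
                    "Nei distance saturated for %s vs %s", groups[i], groups[j]
                )
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = -np.log(identity)
    return pd.DataFrame(d, index=groups, columns=groups)


# ---------------------------------------------------------------------------
# Neighbor joining


def _node_key(node: TreeNode) -> str:
    """Deterministic sort key: smallest leaf name in the subtree."""
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def neighbor_joining(d: DistanceMatrix | pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Q-matrix ties break on the lexicographically lowest label pair.
    Negative branch lengths are clamped to zero with a warning.  Exactly
    inverts additive distance matrices.
    """
    if isinstance(d, pd.DataFrame):
        d = DistanceMatrix(d.to_numpy(float), ids=list(d.index))
    n = d.shape[0]
    if n < 3:
        raise MEIError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    dist: dict[tuple[int, int], float] = {}
    ids = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.data[i, j])
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    node_of = dict(zip(ids, nodes))
    active = list(ids)
    clamped = False
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = tuple(sorted((_node_key(node_of[i]), _node_key(node_of[j]))))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = get(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        node_of[i].length = li
        node_of[j].length = lj
        parent.extend([node_of[i], node_of[j]])
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = (
                get(i, k) + get(j, k) - dij
            ) / 2
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    # resolve the final three branches around an unrooted center
    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2
    lb = get(a, b) - la
    lc = get(a, c) - la
    lengths = [la, lb, lc]
    if min(lengths) < 0:
        clamped = True
        lengths = [max(x, 0.0) for x in lengths]
    root = TreeNode()
    for k, length in zip((a, b, c), lengths):
        node_of[k].length = length
        root.append(node_of[k])
    if clamped:
        logger.warning("negative neighbor-joining branch lengths clamped to zero")
    return root


def write_phylip(d: DistanceMatrix | pd.DataFrame, path: str) -> None:
    """Write a distance matrix in PHYLIP square format."""
    if isinstance(d, DistanceMatrix):
        labels, mat = list(d.ids), d.data
    else:
        labels, mat = list(d.index), d.to_numpy(float)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for label, row in zip(labels, mat):
            name = str(label)[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
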