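"""Correlation-distance hierarchical clustering of smoothed profiles.

Samples are compared genome-wide with the correlation distance
d = 1 - Pearson's r on their kernel-smoothed profiles and clustered with
average linkage (UPGMA). Matched-pair concordance asks whether each lymph
node metastasis sits nearest to its own primary tumour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import PairTable

logger = logging.getLogger("pairedcna")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of 1 - Pearson correlation; entries in [0, 2]."""

    ids: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if self.d.min() < -1e-9 or self.d.max() > 2 + 1e-9:
            raise ValueError("correlation distances must lie in [0, 2]")

    def index(self, sample_id: str) -> int:
        return self.ids.index(sample_id)


@dataclass
class Dendrogram:
    """UPGMA merge list; leaves are 0..n-1, internal node k is n+k.

    ``merges[k] = (node_a, node_b, height)`` with non-decreasing heights.
    """

    n_leaves: int
    merges: list
    leaf_order: list

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("UPGMA needs exactly n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


def correlation_distance(matrix: np.ndarray, ids) -> DistanceMatrix:
    """1 - Pearson correlation between rows of a samples-by-features matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 features")
    if len(ids) != matrix.shape[0]:
        raise ValueError("ids do not match matrix rows")
    sd = matrix.std(axis=1)
    flat = [ids[i] for i in np.where(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance (constant) smoothed profile(s): {flat}")
    d = 1.0 - np.corrcoef(matrix)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry/range
    return DistanceMatrix(list(ids), d)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA: inter-cluster distance = mean of all cross-pair distances.

    Ties are broken deterministically by the lowest pair of cluster indices
    (clusters indexed by creation order, leaves first).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    # working distance between active clusters, keyed by creation index
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dm.d[i, j]
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        for k in active:
            if k in (a, b):
                continue
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            dist[(k, new)] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        active.discard(a)
        active.discard(b)
        active.add(new)
        size[new] = size[a] + size[b]
        members[new] = members[a] + members[b]
    leaf_order = members[next_id - 1]
    return Dendrogram(n, merges, leaf_order)


@dataclass
class ConcordanceReport:
    """Per-pair nearest-neighbour concordance of LNMs with their tumours."""

    table: pd.DataFrame  # patient_id, tumour_id, lnm_id, nn_id, nn_dist, pair_dist, concordant, sibling_concordant
    rate: float
    sibling_rate: float


def _sibling_cluster(dendro: Dendrogram, leaf: int) -> list:
    """Leaves of the cluster the given leaf is first merged with."""
    members = {i: [i] for i in range(dendro.n_leaves)}
    for k, (a, b, _h) in enumerate(dendro.merges):
        node = dendro.n_leaves + k
        if leaf in members.get(a, []):
            return members[b]
        if leaf in members.get(b, []):
            return members[a]
        members[node] = members[a] + members[b]
    raise AssertionError("leaf never merged")


def pair_concordance(dm: DistanceMatrix, pairs: PairTable,
                     dendro: Dendrogram | None = None) -> ConcordanceReport:
    """Is each LNM's nearest neighbour (strictly smallest distance among all
    other samples) its matched tumour?

    Exact ties count as discordant (with a warning). When a dendrogram is
    supplied, sibling concordance — the LNM's first merge partner being
    exactly its matched tumour — is reported alongside for comparison.
    """
    rows = []
    for pr in pairs:
        try:
            li = dm.index(pr.lnm_id)
            ti = dm.index(pr.tumour_id)
        except ValueError:
            raise KeyError(f"pair {pr.patient_id}: sample missing from matrix")
        d_row = dm.d[li].copy()
        d_row[li] = np.inf
        nn = int(np.argmin(d_row))
        nn_dist = d_row[nn]
        tied = np.where(d_row == nn_dist)[0]
        concordant = nn == ti and len(tied) == 1
        if len(tied) > 1 and ti in tied:
            logger.warning(
                "pair %s: LNM equidistant to multiple samples; counted discordant",
                pr.patient_id,
            )
        sib = None
        if dendro is not None:
            sib = _sibling_cluster(dendro, li) == [ti]
        rows.append(
            {
                "patient_id": pr.patient_id,
                "tumour_id": pr.tumour_id,
                "lnm_id": pr.lnm_id,
                "nn_id": dm.ids[nn],
                "nn_dist": float(nn_dist),
                "pair_dist": float(dm.d[li, ti]),
                "concordant": bool(concordant),
                "sibling_concordant": sib,
            }
        )
    table = pd.DataFrame(rows)
    rate = float(table["concordant"].mean()) if len(table) else float("nan")
    if dendro is not None and len(table):
        sibling_rate = float(table["sibling_concordant"].mean())
    else:
        sibling_rate = float("nan")
    return ConcordanceReport(table, rate, sibling_rate)


def to_newick(dendro: Dendrogram, ids) -> str:
    """Ultrametric Newick string; each branch gets half the merge height."""
    height = {i: 0.0 for i in range(dendro.n_leaves)}
    label = {i: str(ids[i]) for i in range(dendro.n_leaves)}
    for k, (a, b, h) in enumerate(dendro.merges):
        node = dendro.n_leaves + k
        la = h / 2.0 - height[a] / 2.0
        lb = h / 2.0 - height[b] / 2.0
        label[node] = f"({label[a]}:{la:.6g},{label[b]}:{lb:.6g})"
        height[node] = h
    return label[dendro.n_leaves + len(dendro.merges) - 1] + ";"


def export_heatmap(dm: DistanceMatrix, dendro: Dendrogram, prefix,
                   pairs: PairTable | None = None, png: bool = False):
    """Write the leaf-ordered distance matrix TSV, a Newick tree and
    optionally a raster heatmap with a tumour/LNM annotation track.

    Returns the list of files written.
    """
    import os

    prefix = str(prefix)
    order = dendro.leaf_order
    ids = [dm.ids[i] for i in order]
    files = []
    tsv = prefix + "_distance.tsv"
    pd.DataFrame(dm.d[np.ix_(order, order)], index=ids, columns=ids).to_csv(
        tsv, sep="\t", float_format="%.6f"
    )
    files.append(tsv)
    nwk = prefix + "_tree.nwk"
    with open(nwk, "w") as fh:
        fh.write(to_newick(dendro, dm.ids) + "\n")
    files.append(nwk)
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        corr = 1.0 - dm.d[np.ix_(order, order)]
        fig, (ax_bar, ax) = plt.subplots(
            2, 1, figsize=(8, 8.6),
            gridspec_kw={"height_ratios": [0.3, 8], "hspace": 0.02},
        )
        if pairs is not None:
            lnm_ids = {pr.lnm_id for pr in pairs}
            colors = [[0.85, 0.33, 0.1] if s in lnm_ids else [0.0, 0.45, 0.74]
                      for s in ids]
            ax_bar.imshow([colors], aspect="auto")
        ax_bar.set_axis_off()
        im = ax.imshow(corr, cmap="viridis", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(len(ids)))
        ax.set_yticks(range(len(ids)))
        ax.set_xticklabels(ids, rotation=90, fontsize=5)
        ax.set_yticklabels(ids, fontsize=5)
        fig.colorbar(im, ax=ax, shrink=0.6, label="Pearson correlation")
        out = prefix + "_heatmap.png"
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
        files.append(out)
    return files


__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ConcordanceReport",
    "correlation_distance",
    "average_linkage",
    "pair_concordance",
    "to_newick",
    "export_heatmap",
]
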